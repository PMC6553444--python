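"""Indel-event detection: gap runs, event clustering, ambiguity culling.

A candidate indel event is a maximal per-taxon run of gap characters whose
column interval is shared (exactly, or within a configurable slop) by one or
more taxa.  Events are then culled: an event whose homology or polarity
cannot be reliably assessed from the sequence evidence is flagged
*ambiguous* and excluded from the rare-genomic-change (RGC) set.  The RGC
set keeps non-ambiguous events of at least ``min_rgc_len`` columns (default
50 bp, the conventional boundary between rare genomic changes and
microstructural changes); shorter non-ambiguous events are reported
separately as microstructural.

Ambiguity rules (formalizations of manual curation practice):

(a) two distinct events whose intervals overlap are mutually ambiguous
    unless one *strictly* contains the other — a strictly nested event is an
    independent smaller indel inside the larger span, not a homology
    conflict, whereas boundary-sharing or boundary-crossing overlap means
    the events cannot be aligned one-to-one;
(b) an event is ambiguous when more than ``max_partial_fraction`` of the
    taxa outside it have a *partial* condition over its span (neither
    clearly present nor clearly absent): the region is riddled with
    independent indels and the event's homology is obscured;
(c) an event is ambiguous when a designated outgroup taxon is partial over
    its span, since the ancestral condition cannot then be read from the
    outgroup.

A taxon's condition over a span is *absent* when its row is almost entirely
gaps there (gap fraction >= ``absent_min_gap_fraction``), *present* when
almost entirely residues (gap fraction <= ``present_max_gap_fraction``),
and *partial* otherwise.  The tolerances accommodate small independent
indels inside a large span.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .errors import DataError
from .io import GAP, Alignment

logger = logging.getLogger(__name__)

#: Default gap-fraction tolerances for reading a taxon's span condition.
PRESENT_MAX_GAP_FRACTION = 0.2
ABSENT_MIN_GAP_FRACTION = 0.8

CANDIDATE = "candidate"
AMBIGUOUS = "ambiguous"
NON_AMBIGUOUS = "non_ambiguous"


@dataclass(frozen=True)
class GapRun:
    """A maximal run of '-' in one taxon's row."""

    taxon: str
    cols: tuple[int, int]
    terminal: bool

    @property
    def length(self) -> int:
        return self.cols[1] - self.cols[0]


@dataclass(frozen=True)
class RgcConfig:
    min_rgc_len: int = 50
    include_terminal_runs: bool = False
    boundary_slop: int = 0
    max_partial_fraction: float = 0.5
    present_max_gap_fraction: float = PRESENT_MAX_GAP_FRACTION
    absent_min_gap_fraction: float = ABSENT_MIN_GAP_FRACTION

    def __post_init__(self):
        if self.min_rgc_len < 1:
            raise DataError("min_rgc_len must be >= 1")
        if self.boundary_slop < 0:
            raise DataError("boundary_slop must be >= 0")


@dataclass(frozen=True)
class IndelEvent:
    """A clustered gap feature: one column interval shared by ``gap_taxa``."""

    id: str
    cols: tuple[int, int]
    gap_taxa: frozenset[str]
    status: str = CANDIDATE
    polarity: str = "unknown"  # set by polarization
    mechanism: str = "undetermined"  # set by mechanism classification
    flanking_repeat: object = None
    tandem: object = None

    @property
    def length(self) -> int:
        return self.cols[1] - self.cols[0]


def span_condition(
    row: str,
    cols: tuple[int, int],
    present_max: float = PRESENT_MAX_GAP_FRACTION,
    absent_min: float = ABSENT_MIN_GAP_FRACTION,
) -> str:
    """Classify one taxon's row over a span as present / absent / partial."""
    start, end = cols
    if end <= start:
        raise DataError(f"empty span [{start},{end})")
    frac = row[start:end].count(GAP) / (end - start)
    if frac <= present_max:
        return "present"
    if frac >= absent_min:
        return "absent"
    return "partial"


def extract_gap_runs(aln: Alignment) -> list[GapRun]:
    """Every maximal per-taxon gap run, with terminal runs flagged."""
    ncol = aln.column_count
    runs = []
    for taxon, row in zip(aln.taxa, aln.rows):
        for m in re.finditer(r"-+", row):
            runs.append(
                GapRun(
                    taxon=taxon,
                    cols=(m.start(), m.end()),
                    terminal=(m.start() == 0 or m.end() == ncol),
                )
            )
    return runs


def cluster_events(runs: Sequence[GapRun], cfg: RgcConfig | None = None) -> list[IndelEvent]:
    """Merge runs with identical (within ``boundary_slop``) intervals into events.

    Terminal runs are treated as missing data, not deletions, and excluded
    unless ``cfg.include_terminal_runs``.  Events are sorted by start column.
    """
    cfg = cfg or RgcConfig()
    usable = [r for r in runs if cfg.include_terminal_runs or not r.terminal]
    groups: dict[tuple[int, int], list[GapRun]] = {}
    if cfg.boundary_slop == 0:
        for r in usable:
            groups.setdefault(r.cols, []).append(r)
    else:
        # greedy: first run of a cluster fixes the canonical interval
        for r in sorted(usable, key=lambda r: r.cols):
            for iv in groups:
                if (
                    abs(r.cols[0] - iv[0]) <= cfg.boundary_slop
                    and abs(r.cols[1] - iv[1]) <= cfg.boundary_slop
                ):
                    groups[iv].append(r)
                    break
            else:
                groups[r.cols] = [r]
    events = []
    for iv in sorted(groups):
        members = groups[iv]
        events.append(
            IndelEvent(
                id=f"ev{iv[0]:06d}_{iv[1]:06d}",
                cols=iv,
                gap_taxa=frozenset(r.taxon for r in members),
            )
        )
    return events


def _strictly_contains(outer: tuple[int, int], inner: tuple[int, int]) -> bool:
    return outer[0] < inner[0] and inner[1] < outer[1]


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def flag_ambiguous(
    events: Sequence[IndelEvent],
    aln: Alignment,
    outgroups: Iterable[str] = (),
    cfg: RgcConfig | None = None,
) -> list[IndelEvent]:
    """Apply culling rules (a)-(c); returns events with status set."""
    cfg = cfg or RgcConfig()
    outgroups = list(outgroups)
    for og in outgroups:
        if og not in aln.taxa:
            raise DataError(f"outgroup taxon {og!r} not in alignment")
    ambiguous: set[str] = set()

    # (a) overlapping events with non-identical boundaries, containment exempt
    for i, e in enumerate(events):
        for f in events[i + 1 :]:
            if e.cols == f.cols or not _overlaps(e.cols, f.cols):
                continue
            if _strictly_contains(e.cols, f.cols) or _strictly_contains(f.cols, e.cols):
                continue
            ambiguous.add(e.id)
            ambiguous.add(f.id)

    out = []
    for e in events:
        status = NON_AMBIGUOUS
        if e.id in ambiguous:
            status = AMBIGUOUS
        else:
            non_members = [t for t in aln.taxa if t not in e.gap_taxa]
            # (b) span riddled with independent indels in non-member taxa
            if non_members:
                partial = sum(
                    span_condition(
                        aln.row(t), e.cols,
                        cfg.present_max_gap_fraction, cfg.absent_min_gap_fraction,
                    )
                    == "partial"
                    for t in non_members
                )
                if partial / len(non_members) > cfg.max_partial_fraction:
                    status = AMBIGUOUS
            # (c) outgroup condition unreadable
            if status == NON_AMBIGUOUS:
                for og in outgroups:
                    cond = (
                        "absent"
                        if og in e.gap_taxa
                        else span_condition(
                            aln.row(og), e.cols,
                            cfg.present_max_gap_fraction, cfg.absent_min_gap_fraction,
                        )
                    )
                    if cond == "partial":
                        status = AMBIGUOUS
                        break
        out.append(replace(e, status=status))
    return out


@dataclass(frozen=True)
class RgcFilterResult:
    """Non-ambiguous events split at the RGC size threshold."""

    rgc: tuple[IndelEvent, ...]
    microstructural: tuple[IndelEvent, ...]
    ambiguous: tuple[IndelEvent, ...]


def filter_rgc(events: Sequence[IndelEvent], cfg: RgcConfig | None = None) -> RgcFilterResult:
    """Split status-flagged events into RGC (>= min_rgc_len), microstructural
    (< min_rgc_len, reporting only) and ambiguous (culled) lists."""
    cfg = cfg or RgcConfig()
    rgc, micro, ambig = [], [], []
    for e in events:
        if e.status == AMBIGUOUS:
            ambig.append(e)
        elif e.status == NON_AMBIGUOUS:
            (rgc if e.length >= cfg.min_rgc_len else micro).append(e)
        else:
            raise DataError(f"event {e.id} has unset status; run flag_ambiguous first")
    return RgcFilterResult(tuple(rgc), tuple(micro), tuple(ambig))
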