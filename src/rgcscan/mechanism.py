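"""Mutational-mechanism classification for non-ambiguous indel events.

Three mechanism classes are recognized, with fixed precedence
ISD > SSM > presumed recombination:

* **ISD** (intrastrand deletion): in taxa that retain the span, an exact
  direct repeat flanks the deleted region — one copy starting at the span's
  5' edge and the second starting just downstream of the 3' boundary (or
  the mirror arrangement).  Deletion between the two copies leaves a single
  copy behind, which is exactly the evidence pattern seen when the deleted
  lineage is aligned against relatives without the deletion.
* **SSM** (slipped-strand mispairing): the event span is an integer number
  of copies of a tandem-repeat unit that is itself tandemly adjacent to the
  span, i.e. a contraction/expansion of a tandem array.
* **recombination_presumed**: everything else — large indels leaving no
  repeat evidence, the default expectation for rare genomic changes.

Repeats are properties of sequence, not of the alignment, so all searches
run in the *ungapped* coordinates of each reference row (a taxon whose span
condition is "present"), then map back to alignment columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .detect import (
    IndelEvent,
    PRESENT_MAX_GAP_FRACTION,
    ABSENT_MIN_GAP_FRACTION,
    span_condition,
)
from .errors import DataError
from .io import GAP, Alignment

logger = logging.getLogger(__name__)

ISD = "ISD"
SSM = "SSM"
RECOMBINATION = "recombination_presumed"


@dataclass(frozen=True)
class MechanismConfig:
    min_repeat_len: int = 8
    max_boundary_offset: int = 5
    max_mismatches: int = 0  # exact matches only; kept for config surface
    min_tandem_unit: int = 2

    def __post_init__(self):
        if min(self.min_repeat_len, self.max_boundary_offset,
               self.max_mismatches, self.min_tandem_unit) < 0:
            raise DataError("mechanism config values must be nonnegative")
        if self.max_mismatches != 0:
            raise DataError("only exact repeat matching is supported")


@dataclass(frozen=True)
class RepeatDescriptor:
    """An exact direct repeat flanking an event in one reference row."""

    sequence: str
    copy1_cols: tuple[int, int]  # alignment columns in the reference row
    copy2_cols: tuple[int, int]
    reference_taxon: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TandemDescriptor:
    """A tandem-array contraction/expansion at an event junction."""

    unit: str
    copies_changed: int
    reference_taxon: str
    adjacent_side: str  # "3prime" or "5prime"

    @property
    def unit_length(self) -> int:
        return len(self.unit)


def ungapped_view(row: str) -> tuple[str, list[int]]:
    """Return (ungapped sequence, alignment column of each ungapped base)."""
    seq = []
    cols = []
    for col, ch in enumerate(row):
        if ch != GAP:
            seq.append(ch)
            cols.append(col)
    return "".join(seq), cols


def _ungapped_pos(row: str, col: int) -> int:
    """Number of residues strictly before an alignment column."""
    return col - row[:col].count(GAP)


def reference_taxa(
    aln: Alignment,
    event: IndelEvent,
    present_max: float = PRESENT_MAX_GAP_FRACTION,
    absent_min: float = ABSENT_MIN_GAP_FRACTION,
) -> list[str]:
    """Taxa whose rows clearly retain the event span, alphabetically sorted.

    For a deletion these are the non-deleted relatives; for an insertion
    event (where the gap runs sit in the taxa *lacking* the inserted span)
    they are the inserted lineage itself.
    """
    refs = []
    for t in aln.taxa:
        if t in event.gap_taxa:
            continue
        if span_condition(aln.row(t), event.cols, present_max, absent_min) == "present":
            refs.append(t)
    return sorted(refs)


def _common_prefix(s: str, a: int, b: int, cap: int) -> int:
    L = 0
    n = len(s)
    while L < cap and a + L < n and b + L < n and s[a + L] == s[b + L]:
        L += 1
    return L


def _common_suffix(s: str, e1: int, e2: int, cap: int) -> int:
    L = 0
    while L < cap and e1 - L > 0 and e2 - L > 0 and s[e1 - 1 - L] == s[e2 - 1 - L]:
        L += 1
    return L


def find_flanking_direct_repeat(
    aln: Alignment,
    event: IndelEvent,
    cfg: MechanismConfig | None = None,
    references: Optional[Sequence[str]] = None,
) -> Optional[RepeatDescriptor]:
    """Longest exact direct repeat flanking the event in any reference row.

    Forward arrangement: one copy begins within ``max_boundary_offset`` of
    the span's 5' boundary (inside the deleted span) and the other begins
    within ``max_boundary_offset`` downstream of the 3' boundary (retained
    sequence).  The mirror arrangement anchors the copies at the 3' edge of
    the span and upstream of the 5' boundary.  Copies may not overlap.
    Returns None when no repeat reaches ``min_repeat_len``; ties across
    reference rows are broken by alphabetical taxon label.  ``references``
    restricts the scan to a subset of the eligible reference rows.
    """
    cfg = cfg or MechanismConfig()
    refs = _gap_free_references(aln, event)
    if references is not None:
        refs = [r for r in refs if r in set(references)]
        if not refs:
            raise DataError(f"no eligible reference row among {list(references)}")
    off = cfg.max_boundary_offset
    best: tuple[int, str, int, int] | None = None  # (L, ref, a, b)
    best_ref_seq_cols = None
    for ref in refs:
        row = aln.row(ref)
        s, cols_of = ungapped_view(row)
        ds = _ungapped_pos(row, event.cols[0])
        de = _ungapped_pos(row, event.cols[1])
        if de <= ds:
            continue  # event has no width in this row (insertion elsewhere)
        for a in range(ds, min(ds + off, de) + 1):
            for b in range(de, de + off + 1):
                if b >= len(s):
                    break
                L = _common_prefix(s, a, b, cap=b - a)
                if L >= cfg.min_repeat_len and (best is None or L > best[0]):
                    best = (L, ref, a, b)
                    best_ref_seq_cols = (s, cols_of)
        for e1 in range(max(de - off, ds), de + 1):
            for e2 in range(max(ds - off, 0), ds + 1):
                L = _common_suffix(s, e1, e2, cap=e1 - e2)
                L = min(L, e1 - ds + off)  # copy1 stays at the span's 3' edge
                if L >= cfg.min_repeat_len and (best is None or L > best[0]):
                    best = (L, ref, e2 - L, e1 - L)
                    best_ref_seq_cols = (s, cols_of)
    if best is None:
        return None
    L, ref, a, b = best
    s, cols_of = best_ref_seq_cols
    return RepeatDescriptor(
        sequence=s[a : a + L],
        copy1_cols=(cols_of[a], cols_of[a + L - 1] + 1),
        copy2_cols=(cols_of[b], cols_of[b + L - 1] + 1),
        reference_taxon=ref,
    )


def _gap_free_references(aln: Alignment, event: IndelEvent) -> list[str]:
    refs = reference_taxa(aln, event)
    if not refs:
        raise DataError(f"no reference row for event {event.id}")
    return refs


def _primitive_period(s: str) -> int:
    """Smallest period p with s[i] == s[i-p]; via the KMP failure function."""
    n = len(s)
    fail = [0] * n
    k = 0
    for i in range(1, n):
        while k and s[i] != s[k]:
            k = fail[k - 1]
        if s[i] == s[k]:
            k += 1
        fail[i] = k
    return n - fail[-1] if n else 0


def detect_tandem_junction(
    aln: Alignment, event: IndelEvent, cfg: MechanismConfig | None = None
) -> Optional[TandemDescriptor]:
    """Report when the event span is whole copies of a tandem unit adjacent
    to the span in a reference row (slipped-strand mispairing signature)."""
    cfg = cfg or MechanismConfig()
    refs = _gap_free_references(aln, event)
    for ref in refs:
        row = aln.row(ref)
        s, _ = ungapped_view(row)
        ds = _ungapped_pos(row, event.cols[0])
        de = _ungapped_pos(row, event.cols[1])
        span = s[ds:de]
        if not span:
            continue
        p = _primitive_period(span)
        if p and len(span) % p == 0:
            unit_len = p
        else:
            unit_len = len(span)  # not periodic: single-unit (duplication) case
        if unit_len < cfg.min_tandem_unit:
            continue
        unit = span[:unit_len]
        copies = len(span) // unit_len
        if s[de : de + unit_len] == unit:
            return TandemDescriptor(unit, copies, ref, adjacent_side="3prime")
        if ds >= unit_len and s[ds - unit_len : ds] == unit:
            return TandemDescriptor(unit, copies, ref, adjacent_side="5prime")
    return None


def classify_mechanism(
    aln: Alignment, event: IndelEvent, cfg: MechanismConfig | None = None
) -> IndelEvent:
    """Attach a mechanism call (ISD > SSM > recombination) to the event."""
    cfg = cfg or MechanismConfig()
    rep = find_flanking_direct_repeat(aln, event, cfg)
    if rep is not None:
        return replace(event, mechanism=ISD, flanking_repeat=rep)
    tan = detect_tandem_junction(aln, event, cfg)
    if tan is not None:
        return replace(event, mechanism=SSM, tandem=tan)
    return replace(event, mechanism=RECOMBINATION)
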