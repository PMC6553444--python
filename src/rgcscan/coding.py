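"""Outgroup polarization of indel events into a binary character matrix.

Each retained event becomes one presence/absence character: state 0 is the
ancestral condition (defined as the outgroup's condition over the event
span), state 1 the derived condition, and '?' marks taxa whose span is
partially gapped (uncertain homology treated as missing data, the
conservative standard in indel coding).  The matrix is exported as a NEXUS
DATA block with the "restriction" datatype, and as a concatenated
nucleotide+binary relaxed-PHYLIP matrix with a partition file, the inputs
expected by standard ML/BI tree programs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .detect import (
    ABSENT_MIN_GAP_FRACTION,
    NON_AMBIGUOUS,
    PRESENT_MAX_GAP_FRACTION,
    IndelEvent,
    span_condition,
)
from .errors import DataError
from .io import Alignment

logger = logging.getLogger(__name__)

SPAN_PRESENT = "span_present"
SPAN_ABSENT = "span_absent"


@dataclass(frozen=True)
class BinaryCharacter:
    """One polarized 0/1/? character derived from an indel event."""

    event_id: str
    states: dict[str, str]  # taxon -> "0" | "1" | "?"
    ancestral_condition: str  # span_present | span_absent
    polarity: str  # deletion | insertion

    def __post_init__(self):
        if set(self.states.values()) - {"0", "1", "?"}:
            raise DataError(f"character {self.event_id}: invalid states")


def polarize(
    event: IndelEvent,
    aln: Alignment,
    outgroups: Sequence[str],
    present_max: float = PRESENT_MAX_GAP_FRACTION,
    absent_min: float = ABSENT_MIN_GAP_FRACTION,
) -> Optional[BinaryCharacter]:
    """Score every taxon 0/1/? against the outgroup-defined ancestral state.

    The outgroup consensus over the event span fixes the ancestral
    condition; if the designated outgroups disagree (or are partial), the
    character is dropped (returns None) with a warning rather than guessed.
    Polarity is "deletion" when the ancestral condition is span_present,
    "insertion" when span_absent.
    """
    if not outgroups:
        raise DataError("at least one outgroup taxon is required")
    for og in outgroups:
        if og not in aln.taxa:
            raise DataError(f"outgroup taxon {og!r} not in alignment")
    conds = {
        og: span_condition(aln.row(og), event.cols, present_max, absent_min)
        for og in outgroups
    }
    distinct = set(conds.values())
    if "partial" in distinct or len(distinct) != 1:
        logger.warning(
            "event %s: outgroup span conditions %s do not fix an ancestral "
            "state; character dropped", event.id, conds,
        )
        return None
    ancestral = SPAN_PRESENT if distinct.pop() == "present" else SPAN_ABSENT
    derived_cond = "absent" if ancestral == SPAN_PRESENT else "present"
    states = {}
    for taxon in aln.taxa:
        cond = span_condition(aln.row(taxon), event.cols, present_max, absent_min)
        if cond == "partial":
            states[taxon] = "?"
        elif cond == derived_cond:
            states[taxon] = "1"
        else:
            states[taxon] = "0"
    return BinaryCharacter(
        event_id=event.id,
        states=states,
        ancestral_condition=ancestral,
        polarity="deletion" if ancestral == SPAN_PRESENT else "insertion",
    )


@dataclass(frozen=True)
class BinaryMatrix:
    """Ordered taxa x characters matrix of 0/1/? states."""

    taxa: tuple[str, ...]
    characters: tuple[BinaryCharacter, ...]

    def __post_init__(self):
        ids = [c.event_id for c in self.characters]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate character ids")
        for c in self.characters:
            missing = set(self.taxa) - set(c.states)
            if missing:
                raise DataError(
                    f"character {c.event_id} missing taxa: {sorted(missing)}"
                )

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def row(self, taxon: str) -> str:
        return "".join(c.states[taxon] for c in self.characters)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {c.event_id: [c.states[t] for t in self.taxa] for c in self.characters},
            index=list(self.taxa),
        )


def build_matrix(
    chars: Iterable[Optional[BinaryCharacter]], taxa: Sequence[str] | None = None
) -> BinaryMatrix:
    """Assemble characters into a matrix, dropping Nones (outgroup conflicts)
    and characters that are invariant (no taxon scored 1) after polarization."""
    kept = []
    for c in chars:
        if c is None:
            continue
        if "1" not in c.states.values():
            logger.info("character %s is all-ancestral after polarization; dropped", c.event_id)
            continue
        kept.append(c)
    if taxa is None:
        if not kept:
            return BinaryMatrix((), ())
        taxa = tuple(kept[0].states)
    return BinaryMatrix(tuple(taxa), tuple(kept))


# ---------------------------------------------------------------------------
# NEXUS restriction-datatype export

def _nexus_quote(label: str) -> str:
    if re.fullmatch(r"[\w.|+-]+", label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_restriction_nexus(matrix: BinaryMatrix, path) -> None:
    """Write the matrix as a NEXUS DATA block, DATATYPE=RESTRICTION."""
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={len(matrix.taxa)} NCHAR={matrix.n_characters};",
        '    FORMAT DATATYPE=RESTRICTION MISSING=? SYMBOLS="01";',
        "    MATRIX",
    ]
    width = max((len(_nexus_quote(t)) for t in matrix.taxa), default=0) + 2
    for t in matrix.taxa:
        lines.append(f"        {_nexus_quote(t):<{width}}{matrix.row(t)}")
    lines += ["    ;", "END;"]
    Path(path).write_text("\n".join(lines) + "\n")


def read_restriction_nexus(path) -> BinaryMatrix:
    """Read back a restriction-datatype NEXUS DATA block written by
    :func:`write_restriction_nexus` (labels may be single-quoted)."""
    text = Path(path).read_text()
    m = re.search(r"MATRIX(.*?);", text, flags=re.S | re.I)
    if not m:
        raise DataError(f"no MATRIX block in {path}")
    taxa: list[str] = []
    rows: list[str] = []
    for line in m.group(1).strip().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("'"):
            lm = re.match(r"'((?:[^']|'')*)'\s+(\S+)$", line)
            if not lm:
                raise DataError(f"cannot parse matrix line: {line!r}")
            label = lm.group(1).replace("''", "'")
            states = lm.group(2)
        else:
            label, states = line.split(None, 1)
            states = states.strip()
        if set(states) - {"0", "1", "?"}:
            raise DataError(f"invalid restriction states for {label!r}: {states!r}")
        taxa.append(label)
        rows.append(states)
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        raise DataError("ragged restriction matrix")
    nchar = widths.pop() if widths else 0
    chars = []
    for k in range(nchar):
        chars.append(
            BinaryCharacter(
                event_id=f"char{k + 1}",
                states={t: rows[i][k] for i, t in enumerate(taxa)},
                ancestral_condition=SPAN_PRESENT,
                polarity="deletion",
            )
        )
    return BinaryMatrix(tuple(taxa), tuple(chars))


# ---------------------------------------------------------------------------
# Combined nucleotide + binary export

def _phylip_label(label: str) -> str:
    safe = re.sub(r"\s+", "_", label)
    if safe != label:
        logger.warning("relabeling %r as %r for PHYLIP output", label, safe)
    return safe


def write_combined(
    aln_stripped: Alignment, matrix: BinaryMatrix, path_prefix
) -> tuple[Path, Path]:
    """Write the concatenated DNA+binary relaxed-PHYLIP matrix and its
    RAxML-style partition file; returns (phylip_path, partition_path)."""
    if matrix.characters and set(matrix.taxa) != set(aln_stripped.taxa):
        only_a = sorted(set(aln_stripped.taxa) - set(matrix.taxa))
        only_m = sorted(set(matrix.taxa) - set(aln_stripped.taxa))
        raise DataError(
            f"taxa mismatch between alignment and binary matrix: "
            f"alignment-only={only_a}, matrix-only={only_m}"
        )
    records = []
    for taxon, row in zip(aln_stripped.taxa, aln_stripped.rows):
        binary = matrix.row(taxon) if matrix.characters else ""
        records.append(SeqRecord(Seq(row + binary), id=_phylip_label(taxon)))
    phy_path = Path(f"{path_prefix}.phy")
    with open(phy_path, "w") as fh:
        AlignIO.write(MultipleSeqAlignment(records), fh, "phylip-relaxed")
    part_path = Path(f"{path_prefix}.partitions")
    ncol = aln_stripped.column_count
    lines = [f"DNA, seq = 1-{ncol}"]
    if matrix.n_characters:
        lines.append(f"BIN, rgc = {ncol + 1}-{ncol + matrix.n_characters}")
    part_path.write_text("\n".join(lines) + "\n")
    return phy_path, part_path
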