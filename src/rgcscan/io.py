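"""Core data types and readers/writers for the standard formats.

The central container is :class:`Alignment`, an ordered taxa-by-columns
residue matrix over the nucleotide alphabet (IUPAC codes plus ``-`` for
gaps).  All coordinates in this package are 0-based, half-open, and live in
alignment-column space unless a function explicitly says otherwise; helpers
are provided to convert the 1-based inclusive ranges that appear in
published table captions.

Trees are plain :class:`dendropy.Tree` objects (aliased ``TreeTopology``);
annotated genomes are :class:`GenomeRecord`, a gap-free sequence with
optional features.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio import SeqIO

from .errors import DataError

logger = logging.getLogger(__name__)

GAP = "-"
#: Unambiguous bases, U for RNA input, N, IUPAC ambiguity codes, and the gap.
ALPHABET = frozenset("ACGTUNRYSWKMBDHV" + GAP)

TreeTopology = dendropy.Tree


def _normalize_row(row: str, taxon: str) -> str:
    """Uppercase a row and normalize gap/missing dialects ('.' and '?')."""
    row = row.upper()
    if "." in row:
        logger.warning("taxon %r: normalizing '.' to '-'", taxon)
        row = row.replace(".", GAP)
    if "?" in row:
        logger.warning("taxon %r: normalizing '?' to 'N'", taxon)
        row = row.replace("?", "N")
    bad = set(row) - ALPHABET
    if bad:
        pos = min(i for i, c in enumerate(row) if c in bad)
        raise DataError(
            f"illegal character {row[pos]!r} at position {pos} in taxon {taxon!r}"
        )
    return row


@dataclass(frozen=True)
class Alignment:
    """An ordered multiple sequence alignment.

    Rows are residue strings of identical length; taxa labels are unique and
    non-empty.  Instances are immutable; transforms return new objects.
    """

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise DataError("taxa/rows length mismatch")
        if any(not t for t in self.taxa):
            raise DataError("empty taxon label")
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise DataError(f"duplicate taxon label(s): {', '.join(dup)}")
        width = len(self.rows[0]) if self.rows else 0
        for taxon, row in zip(self.taxa, self.rows):
            if len(row) != width:
                raise DataError(f"unequal alignment lengths: taxon {taxon!r}")

    @property
    def column_count(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> str:
        try:
            return self.rows[self.taxa.index(taxon)]
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in alignment") from None

    def to_array(self) -> np.ndarray:
        """Residues as a (taxa, columns) array of single bytes."""
        if not self.rows:
            return np.empty((0, 0), dtype="S1")
        return np.frombuffer(
            "".join(self.rows).encode("ascii"), dtype="S1"
        ).reshape(len(self.rows), self.column_count)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Alignment":
        taxa, rows = [], []
        for taxon, row in pairs:
            taxa.append(taxon)
            rows.append(_normalize_row(row, taxon))
        return cls(tuple(taxa), tuple(rows))


@dataclass(frozen=True)
class Feature:
    type: str
    start: int  # 0-based
    end: int  # half-open
    strand: int
    qualifiers: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class GenomeRecord:
    """A gap-free genome sequence with optional annotated features."""

    id: str
    sequence: str
    features: tuple[Feature, ...] = ()

    def __post_init__(self):
        if GAP in self.sequence:
            raise DataError(f"record {self.id!r}: sequence contains gaps")
        n = len(self.sequence)
        for f in self.features:
            if not (0 <= f.start <= f.end <= n):
                raise DataError(
                    f"record {self.id!r}: feature interval [{f.start},{f.end}) "
                    f"outside sequence of length {n}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def to_zero_based(start_1based: int, end_1based_inclusive: int) -> tuple[int, int]:
    """Convert a 1-based inclusive range (table-caption style) to 0-based half-open."""
    return start_1based - 1, end_1based_inclusive


def to_one_based(interval: tuple[int, int]) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    return interval[0] + 1, interval[1]


def read_alignment(path, format: str = "fasta") -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Row order is preserved; case is folded to upper; ragged rows, duplicate
    labels and illegal characters raise :class:`DataError`.
    """
    if format != "fasta":
        raise DataError(f"unsupported alignment format: {format!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DataError(f"no sequences found in {path}")
    return Alignment.from_pairs((r.id, str(r.seq)) for r in records)


def write_alignment(aln: Alignment, path, wrap: int = 70) -> None:
    """Write an alignment as FASTA, wrapped at ``wrap`` columns."""
    with open(path, "w") as fh:
        for taxon, row in zip(aln.taxa, aln.rows):
            fh.write(f">{taxon}\n")
            for i in range(0, max(len(row), 1), wrap):
                fh.write(row[i : i + wrap] + "\n")


def read_genbank(path) -> GenomeRecord:
    """Read the first record of a GenBank flat file (must carry a sequence)."""
    try:
        rec = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise DataError(f"no records in GenBank file {path}") from None
    except ValueError as exc:
        raise DataError(f"cannot parse GenBank file {path}: {exc}") from None
    seq = str(rec.seq).upper()
    if not seq:
        raise DataError(f"record {rec.id!r} has no sequence")
    feats = []
    for f in rec.features:
        feats.append(
            Feature(
                type=f.type,
                start=int(f.location.start),
                end=int(f.location.end),
                strand=f.location.strand or 0,
                qualifiers=tuple(
                    (k, ";".join(map(str, v))) for k, v in sorted(f.qualifiers.items())
                ),
            )
        )
    return GenomeRecord(id=rec.id, sequence=seq, features=tuple(feats))


def strip_gap_columns(aln: Alignment, mode: str = "any_gap") -> Alignment:
    """Remove gapped columns from an alignment.

    mode="any_gap" keeps only columns where no taxon has a gap (the default;
    applied to the sequence matrix after indel events have been
    characterized).  mode="all_gap" removes only columns gapped in every
    taxon.  The input is untouched; taxon order is preserved.
    """
    if mode not in ("any_gap", "all_gap"):
        raise DataError(f"unknown strip mode: {mode!r}")
    arr = aln.to_array()
    if arr.size == 0:
        return aln
    is_gap = arr == GAP.encode()
    keep = ~is_gap.any(axis=0) if mode == "any_gap" else ~is_gap.all(axis=0)
    kept = arr[:, keep]
    rows = tuple(kept[i].tobytes().decode("ascii") for i in range(kept.shape[0]))
    return Alignment(aln.taxa, rows)


def excise_interval(obj, interval: tuple[int, int]):
    """Remove a 0-based half-open interval of columns (Alignment) or bases
    (GenomeRecord / plain string); returns the same type."""
    start, end = interval
    if isinstance(obj, Alignment):
        n = obj.column_count
    elif isinstance(obj, GenomeRecord):
        n = len(obj.sequence)
    elif isinstance(obj, str):
        n = len(obj)
    else:
        raise DataError(f"cannot excise from {type(obj).__name__}")
    if not (0 <= start <= end <= n):
        raise DataError(f"interval [{start},{end}) out of range for length {n}")
    if isinstance(obj, str):
        return obj[:start] + obj[end:]
    if isinstance(obj, Alignment):
        rows = tuple(r[:start] + r[end:] for r in obj.rows)
        return Alignment(obj.taxa, rows)
    # GenomeRecord: drop features overlapping the cut, shift the rest
    width = end - start
    feats = []
    for f in obj.features:
        if f.end <= start:
            feats.append(f)
        elif f.start >= end:
            feats.append(replace(f, start=f.start - width, end=f.end - width))
        else:
            logger.warning(
                "record %r: dropping feature %s [%d,%d) overlapping excised interval",
                obj.id, f.type, f.start, f.end,
            )
    return GenomeRecord(
        id=obj.id,
        sequence=obj.sequence[:start] + obj.sequence[end:],
        features=tuple(feats),
    )


def read_newick(path) -> TreeTopology:
    """Parse a newick tree; duplicate leaf labels and syntax errors raise."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parser classes
        raise DataError(f"cannot parse newick file {path}: {exc}") from None
    _validate_tree(tree)
    return tree


def parse_newick(text: str) -> TreeTopology:
    """Parse a newick string (convenience twin of :func:`read_newick`)."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise DataError(f"cannot parse newick: {exc}") from None
    _validate_tree(tree)
    return tree


def _validate_tree(tree: TreeTopology) -> None:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise DataError(f"duplicate leaf label(s): {', '.join(dup)}")
    if any(leaf.taxon is None for leaf in tree.leaf_node_iter()):
        raise DataError("unlabeled leaf in tree")


def write_newick(tree: TreeTopology, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            tree.as_string(
                schema="newick", suppress_rooting=True, unquoted_underscores=True
            ).strip()
            + "\n"
        )


def leaf_labels(tree: TreeTopology) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def bipartitions(tree: TreeTopology) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions (as the smaller-side leaf sets are not
    canonical, each split is keyed by the child-side leaf set against the
    full leaf universe)."""
    universe = frozenset(leaf_labels(tree))
    splits = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(below) < len(universe):
            splits.add(min(below, universe - below, key=sorted))
    return splits
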