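"""Plastome descriptors: %AT, inverted-repeat detection, quadripartite partition.

A canonical plastid genome is circular and quadripartite: a large single-copy
region (LSC), a small single-copy region (SSC), and two identical inverted
repeats (IRb, IRa) separating them.  ``find_inverted_repeat`` locates the
maximal pair of exact reverse-complementary intervals by k-mer seeding and
greedy bidirectional extension; ``partition_quadripartite`` derives the four
regions, treating the input as a circle linearized at an arbitrary point.

Intervals here are 0-based half-open in the input orientation.  A region
that wraps past the end of the linearized sequence is represented with
``end < start``; its length is ``(end - start) mod n``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

from .errors import DataError
from .io import GenomeRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware, uppercase input)."""
    return seq.translate(_COMPLEMENT)[::-1]


def at_content(seq: str) -> float:
    """Percent A+T(+U) among unambiguous bases, rounded half-up to 1 decimal.

    Ambiguity codes and N are excluded from numerator and denominator.
    """
    seq = seq.upper()
    at = sum(seq.count(b) for b in "ATU")
    acgt = at + seq.count("C") + seq.count("G")
    if acgt == 0:
        raise DataError("no unambiguous bases")
    pct = Decimal(100 * at) / Decimal(acgt)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def gc_content(seq: str) -> float:
    """Percent G+C among unambiguous bases (complement of :func:`at_content`)."""
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + sum(seq.count(b) for b in "ATU")
    if acgt == 0:
        raise DataError("no unambiguous bases")
    pct = Decimal(100 * gc) / Decimal(acgt)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def find_inverted_repeat(
    seq: str, min_len: int = 1000, seed_k: int = 21, max_seed_hits: int = 200
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Locate the maximal pair of exact inverted repeats of length >= min_len.

    Returns ``(irb, ira)`` as 0-based half-open intervals with
    ``seq[irb] == revcomp(seq[ira])``, irb upstream of ira.  Seeds are
    forward-strand k-mers matched against an index of the reverse
    complement, extended greedily in both directions; overlapping
    (palindromic) hits are trimmed to the maximal non-overlapping sub-pair.

    Raises :class:`DataError` when no qualifying pair exists.
    """
    n = len(seq)
    if min_len < 1:
        raise DataError("min_len must be >= 1")
    if n < 2 * min_len:
        raise DataError(f"no inverted repeat >= {min_len} bp (sequence too short)")
    seq = seq.upper()
    rc = revcomp(seq)
    k = min(seed_k, min_len)

    index: dict[str, list[int]] = {}
    for j in range(n - k + 1):
        index.setdefault(rc[j : j + k], []).append(j)

    best: tuple[int, int, int] | None = None  # (L, start1, start2)
    # per diagonal (i - j), intervals of i already covered by an extension
    covered: dict[int, list[tuple[int, int]]] = {}

    for i in range(n - k + 1):
        hits = index.get(seq[i : i + k])
        if not hits:
            continue
        if len(hits) > max_seed_hits:
            logger.debug("skipping high-multiplicity seed at %d (%d hits)", i, len(hits))
            continue
        for j in hits:
            d = i - j
            done = False
            for a, b in covered.get(d, ()):
                if a <= i < b:
                    done = True
                    break
            if done:
                continue
            # extend the exact match seq[i:i+k] == rc[j:j+k]
            i0, j0 = i, j
            while i0 > 0 and j0 > 0 and seq[i0 - 1] == rc[j0 - 1]:
                i0 -= 1
                j0 -= 1
            i1, j1 = i + k, j + k
            while i1 < n and j1 < n and seq[i1] == rc[j1]:
                i1 += 1
                j1 += 1
            covered.setdefault(d, []).append((i0, i1))
            # map the rc interval back onto seq coordinates
            m0, m1 = n - j1, n - j0
            cand = _pair_from_match(i0, i1, m0, m1)
            if cand is None:
                continue
            L, s1, s2 = cand
            if L >= min_len and (
                best is None or (L, -s1, -s2) > (best[0], -best[1], -best[2])
            ):
                best = (L, s1, s2)

    if best is None:
        raise DataError(f"no inverted repeat >= {min_len} bp")
    L, s1, s2 = best
    return (s1, s1 + L), (s2, s2 + L)


def _pair_from_match(i0, i1, m0, m1):
    """Reduce a (possibly self-overlapping, i.e. palindromic) matched region
    pair to the maximal non-overlapping interval pair; None if degenerate."""
    if (i0, i1) > (m0, m1):
        i0, i1, m0, m1 = m0, m1, i0, i1
    if i1 <= m0:  # already disjoint
        return i1 - i0, i0, m0
    # overlapping: the stretch is reverse-complement symmetric; take the
    # longest prefix/suffix pair that does not overlap
    L = (m1 - i0) // 2
    L = min(L, i1 - i0, m1 - m0)
    if L <= 0:
        return None
    return L, i0, m1 - L


@dataclass(frozen=True)
class QuadripartitePartition:
    """LSC/IRb/SSC/IRa intervals of a circular plastome, in linear coordinates
    of the input orientation (wrapped regions have ``end < start``)."""

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    sequence_length: int

    def _len(self, iv: tuple[int, int]) -> int:
        return (iv[1] - iv[0]) % self.sequence_length

    @property
    def ir_length(self) -> int:
        return self._len(self.irb)

    @property
    def lsc_length(self) -> int:
        return self._len(self.lsc)

    @property
    def ssc_length(self) -> int:
        return self._len(self.ssc)


def _circular_slice(seq: str, iv: tuple[int, int]) -> str:
    s, e = iv
    return seq[s:e] if s <= e else seq[s:] + seq[:e]


def partition_quadripartite(
    seq: str, ir_pair: tuple[tuple[int, int], tuple[int, int]]
) -> QuadripartitePartition:
    """Assign LSC/SSC to the two inter-IR segments of the circle.

    The longer segment is the LSC by definition; on an exact tie the segment
    containing coordinate 0 is taken as LSC (with a warning).
    """
    n = len(seq)
    (b0, b1), (a0, a1) = sorted(ir_pair)
    if b1 > a0:
        raise DataError("inverted repeat intervals overlap")
    if _circular_slice(seq, (b0, b1)) != revcomp(_circular_slice(seq, (a0, a1))):
        raise DataError("intervals are not an exact inverted-repeat pair")
    seg_mid = (b1, a0)  # between the two IR copies
    seg_wrap = (a1 % n, b0)  # through the origin
    len_mid = (a0 - b1) % n
    len_wrap = (b0 - a1) % n
    if len_mid == len_wrap:
        logger.warning(
            "inter-IR segments tie at %d bp; taking the origin-containing "
            "segment as LSC", len_mid,
        )
        lsc, ssc = seg_wrap, seg_mid
    elif len_mid > len_wrap:
        lsc, ssc = seg_mid, seg_wrap
    else:
        lsc, ssc = seg_wrap, seg_mid
    # IRb is the copy adjacent downstream of the LSC on the circle
    if lsc is seg_mid:
        irb, ira = (a0, a1), (b0, b1)
    else:
        irb, ira = (b0, b1), (a0, a1)
    return QuadripartitePartition(lsc=lsc, irb=irb, ssc=ssc, ira=ira, sequence_length=n)


@dataclass(frozen=True)
class PlastomeSummary:
    """One table row of plastome descriptors; partition fields are None when
    no inverted repeat was detected."""

    id: str
    plastome_length: int
    at_percent: float
    ir_length: int | None = None
    lsc_length: int | None = None
    ssc_length: int | None = None


def summarize_plastome(record: GenomeRecord, min_ir_len: int = 1000) -> PlastomeSummary:
    """Length, IR/LSC/SSC lengths and %AT for a gap-free genome record."""
    at = at_content(record.sequence)
    try:
        ir_pair = find_inverted_repeat(record.sequence, min_len=min_ir_len)
        part = partition_quadripartite(record.sequence, ir_pair)
    except DataError as exc:
        logger.warning("record %r: %s; reporting length and %%AT only", record.id, exc)
        return PlastomeSummary(
            id=record.id, plastome_length=len(record.sequence), at_percent=at
        )
    return PlastomeSummary(
        id=record.id,
        plastome_length=len(record.sequence),
        at_percent=at,
        ir_length=part.ir_length,
        lsc_length=part.lsc_length,
        ssc_length=part.ssc_length,
    )
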