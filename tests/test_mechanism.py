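"""Mechanism classification: flanking direct repeats, tandem junctions."""

import pytest

from rgcscan.detect import IndelEvent, NON_AMBIGUOUS
from rgcscan.errors import DataError
from rgcscan.io import Alignment
from rgcscan.mechanism import (
    ISD,
    RECOMBINATION,
    SSM,
    MechanismConfig,
    classify_mechanism,
    detect_tandem_junction,
    find_flanking_direct_repeat,
    reference_taxa,
    ungapped_view,
    _ungapped_pos,
)
from rgcscan.simulate import random_sequence

from conftest import detect_rgc


def brute_force_flanking_repeat(aln, event, cfg=None):
    """Independent oracle: enumerate every (start, start, length) substring
    pair satisfying the flanking constraints; return the best length."""
    cfg = cfg or MechanismConfig()
    off = cfg.max_boundary_offset
    best = 0
    for ref in reference_taxa(aln, event):
        row = aln.row(ref)
        s, _ = ungapped_view(row)
        ds = _ungapped_pos(row, event.cols[0])
        de = _ungapped_pos(row, event.cols[1])
        if de <= ds:
            continue
        for a in range(ds, min(ds + off, de) + 1):
            for b in range(de, min(de + off, len(s) - 1) + 1):
                for L in range(min(b - a, len(s) - b), cfg.min_repeat_len - 1, -1):
                    if s[a : a + L] == s[b : b + L]:
                        best = max(best, L)
                        break
        for e1 in range(max(de - off, ds), de + 1):
            for e2 in range(max(ds - off, 0), ds + 1):
                cap = min(e1 - e2, e2, e1 - ds + off)
                for L in range(cap, cfg.min_repeat_len - 1, -1):
                    if s[e1 - L : e1] == s[e2 - L : e2]:
                        best = max(best, L)
                        break
    return best or None


def _single_event(aln, outgroups=()):
    split = detect_rgc(aln, outgroups)
    assert len(split.rgc) == 1
    return split.rgc[0]


class TestFlankingDirectRepeat:
    def test_festuca_repeat_in_every_reference_row(self, festuca_aln):
        event = _single_event(festuca_aln)
        refs = reference_taxa(festuca_aln, event)
        assert refs == [
            "Festuca_altissima",
            "Festuca_arundinacea",
            "Festuca_ovina",
            "Festuca_pratensis",
        ]
        for ref in refs:
            rep = find_flanking_direct_repeat(festuca_aln, event, references=[ref])
            assert rep is not None and rep.sequence.startswith("AAAAAGAAA")
            assert rep.copy1_cols[0] == 3  # 5' edge of the deleted span
            assert rep.copy2_cols[0] == 81  # retained copy past the 3' boundary

    def test_polypogon_repeat_from_calamagrostis(self, poeae_aln, poeae_outgroup):
        event = _single_event(poeae_aln, [poeae_outgroup])
        rep = find_flanking_direct_repeat(poeae_aln, event)
        assert rep.sequence == "TCCAAAATTC"
        assert rep.reference_taxon == "Calamagrostis_breviligulata"
        assert rep.copy1_cols == (3, 13)
        # the retained 3' copy is split by the downstream 4-column gap
        assert rep.copy2_cols == (66, 80)

    def test_featureless_flanks_yield_nothing(self, rng):
        left = "GG" + random_sequence(28, rng)
        span = random_sequence(60, rng)
        right = "TT" + random_sequence(28, rng)
        aln = Alignment.from_pairs(
            [("A", left + "-" * 60 + right), ("B", left + span + right)]
        )
        event = IndelEvent("e", (30, 90), frozenset({"A"}), status=NON_AMBIGUOUS)
        # a chance >=8 bp repeat at the fixed offsets is vanishingly unlikely
        assert find_flanking_direct_repeat(aln, event) is None

    def test_no_reference_row_is_an_error(self):
        aln = Alignment.from_pairs([("A", "AA----AA"), ("B", "AA----AA")])
        event = IndelEvent("e", (2, 6), frozenset({"A", "B"}), status=NON_AMBIGUOUS)
        with pytest.raises(DataError, match="no reference row"):
            find_flanking_direct_repeat(aln, event)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        # construct a 2-row window <=300 cols with a planted flanking repeat
        rep_len = int(rng.integers(8, 15))
        rep = random_sequence(rep_len, rng)
        span_core = random_sequence(int(rng.integers(40, 80)), rng)
        left = random_sequence(100, rng)
        right = random_sequence(100, rng)
        span = rep + span_core
        full = left + span + rep + right
        gapped = left + "-" * len(span) + rep + right
        aln = Alignment.from_pairs([("A", gapped), ("B", full), ("C", full)])
        event = IndelEvent(
            "e", (100, 100 + len(span)), frozenset({"A"}), status=NON_AMBIGUOUS
        )
        got = find_flanking_direct_repeat(aln, event)
        expected = brute_force_flanking_repeat(aln, event)
        assert got is not None and expected is not None
        assert got.length == expected
        assert got.length >= rep_len
        assert got.sequence.startswith(rep) or rep in got.sequence


class TestTandemJunction:
    def test_canonical_trinucleotide_contraction(self):
        # reference ...CAGCAGCAG..., event deletes exactly CAGCAG next to a
        # retained CAG
        ref = "TTTTGG" + "CAG" * 3 + "TTAAGGTT"
        gapped = "TTTTGG" + "------" + "CAG" + "TTAAGGTT"
        aln = Alignment.from_pairs([("A", gapped), ("B", ref), ("C", ref)])
        event = IndelEvent("e", (6, 12), frozenset({"A"}), status=NON_AMBIGUOUS)
        tan = detect_tandem_junction(aln, event)
        assert tan is not None
        assert tan.unit == "CAG"
        assert tan.copies_changed == 2

    def test_homopolymer_unit_below_minimum_rejected(self):
        ref = "GGTT" + "AAAAAA" + "GGTTCC"
        gapped = "GGTT" + "--" + "AAAA" + "GGTTCC"
        aln = Alignment.from_pairs([("A", gapped), ("B", ref)])
        event = IndelEvent("e", (4, 6), frozenset({"A"}), status=NON_AMBIGUOUS)
        assert detect_tandem_junction(aln, event) is None  # unit "A" < 2 bp

    def test_non_periodic_span_without_adjacency_rejected(self, rng):
        left = "GG" + random_sequence(28, rng)
        span = random_sequence(54, rng)
        right = "TT" + random_sequence(28, rng)
        aln = Alignment.from_pairs(
            [("A", left + "-" * 54 + right), ("B", left + span + right)]
        )
        event = IndelEvent("e", (30, 84), frozenset({"A"}), status=NON_AMBIGUOUS)
        assert detect_tandem_junction(aln, event) is None


class TestClassify:
    def test_festuca_event_is_isd(self, festuca_aln):
        event = classify_mechanism(festuca_aln, _single_event(festuca_aln))
        assert event.mechanism == ISD

    def test_polypogon_event_is_isd(self, poeae_aln, poeae_outgroup):
        event = classify_mechanism(poeae_aln, _single_event(poeae_aln, [poeae_outgroup]))
        assert event.mechanism == ISD
        assert event.flanking_repeat.sequence == "TCCAAAATTC"

    def test_featureless_deletion_presumed_recombination(self, rng):
        left = "GG" + random_sequence(28, rng)
        span = random_sequence(60, rng)
        right = "TT" + random_sequence(28, rng)
        aln = Alignment.from_pairs(
            [("A", left + "-" * 60 + right), ("B", left + span + right)]
        )
        event = IndelEvent("e", (30, 90), frozenset({"A"}), status=NON_AMBIGUOUS)
        assert classify_mechanism(aln, event).mechanism == RECOMBINATION

    def test_isd_takes_precedence_over_ssm(self):
        # a deleted span that is both a tandem copy (unit 10) and flanked by
        # a 10 bp direct repeat: dispersed-repeat evidence wins
        unit = "ACGTACGTTC"
        ref = "GGGTTT" + unit * 2 + "GAGTTCTT"
        gapped = "GGGTTT" + "-" * 10 + unit + "GAGTTCTT"
        aln = Alignment.from_pairs([("A", gapped), ("B", ref)])
        event = IndelEvent("e", (6, 16), frozenset({"A"}), status=NON_AMBIGUOUS)
        got = classify_mechanism(aln, event, MechanismConfig(min_repeat_len=8))
        assert got.mechanism == ISD
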