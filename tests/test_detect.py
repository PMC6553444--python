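"""Gap-run extraction, event clustering, ambiguity culling, RGC filter."""

import pytest
from hypothesis import given, settings, strategies as st

from rgcscan.detect import (
    AMBIGUOUS,
    NON_AMBIGUOUS,
    GapRun,
    IndelEvent,
    RgcConfig,
    cluster_events,
    extract_gap_runs,
    filter_rgc,
    flag_ambiguous,
    span_condition,
)
from rgcscan.errors import DataError
from rgcscan.io import Alignment

from conftest import detect_rgc


def _runs_of(runs, taxon):
    return [r for r in runs if r.taxon == taxon]


class TestExtractGapRuns:
    def test_polypogon_deletion_run(self, poeae_aln):
        runs = _runs_of(extract_gap_runs(poeae_aln), "Polypogon_fugax")
        longest = max(runs, key=lambda r: r.length)
        assert longest.cols == (3, 66)
        assert longest.length == 63
        assert not longest.terminal

    def test_festuca_deletion_run(self, festuca_aln):
        runs = _runs_of(extract_gap_runs(festuca_aln), "Festuca_ovina_NC019649")
        assert [(r.cols, r.length) for r in runs] == [((3, 81), 78)]

    def test_gapless_alignment_yields_nothing(self):
        aln = Alignment.from_pairs([("A", "ACGT"), ("B", "ACGT")])
        assert extract_gap_runs(aln) == []

    def test_terminal_runs_flagged(self):
        aln = Alignment.from_pairs([("A", "--GT"), ("B", "AC--")])
        runs = extract_gap_runs(aln)
        assert all(r.terminal for r in runs)

    @given(st.lists(st.sampled_from("ACGT-"), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_runs_partition_all_gap_characters(self, chars):
        row = "".join(chars)
        aln = Alignment.from_pairs([("A", row)])
        runs = extract_gap_runs(aln)
        assert sum(r.length for r in runs) == row.count("-")
        seen = set()
        for r in runs:
            cols = set(range(*r.cols))
            assert not cols & seen  # each gap char in exactly one run
            seen |= cols
        assert seen == {i for i, c in enumerate(row) if c == "-"}


class TestClusterEvents:
    def test_shared_agrostis_run_is_one_event(self, poeae_aln):
        events = cluster_events(extract_gap_runs(poeae_aln))
        shared = [e for e in events if e.cols == (17, 49)]
        assert len(shared) == 1
        assert shared[0].gap_taxa == {"Agrostis_gigantea", "Agrostis_stolonifera"}
        assert shared[0].length == 32

    def test_off_by_one_boundaries_stay_distinct_at_zero_slop(self):
        runs = [
            GapRun("A", (10, 60), False),
            GapRun("B", (10, 61), False),
        ]
        events = cluster_events(runs, RgcConfig(boundary_slop=0))
        assert len(events) == 2

    def test_slop_merges_near_identical_runs(self):
        runs = [
            GapRun("A", (10, 60), False),
            GapRun("B", (11, 61), False),
        ]
        events = cluster_events(runs, RgcConfig(boundary_slop=1))
        assert len(events) == 1
        assert events[0].gap_taxa == {"A", "B"}

    def test_terminal_runs_excluded_by_default(self, poeae_aln):
        events = cluster_events(extract_gap_runs(poeae_aln))
        assert all(e.cols[0] > 0 for e in events)
        with_terminals = cluster_events(
            extract_gap_runs(poeae_aln), RgcConfig(include_terminal_runs=True)
        )
        assert any(e.cols[0] == 0 for e in with_terminals)

    def test_events_sorted_by_start(self, poeae_aln):
        events = cluster_events(extract_gap_runs(poeae_aln))
        assert [e.cols for e in events] == sorted(e.cols for e in events)


class TestFlagAmbiguous:
    def test_nested_micro_indels_do_not_poison_large_event(self, poeae_aln, poeae_outgroup):
        events = flag_ambiguous(
            cluster_events(extract_gap_runs(poeae_aln)), poeae_aln, [poeae_outgroup]
        )
        big = next(e for e in events if e.cols == (3, 66))
        assert big.status == NON_AMBIGUOUS

    def test_boundary_sharing_overlaps_are_mutually_ambiguous(self, poeae_aln):
        # the window-leading truncated runs overlap with unequal boundaries;
        # with terminal runs admitted they cull each other
        cfg = RgcConfig(include_terminal_runs=True)
        events = flag_ambiguous(
            cluster_events(extract_gap_runs(poeae_aln), cfg), poeae_aln, cfg=cfg
        )
        leading = {e.cols: e for e in events if e.cols[0] == 0}
        assert (0, 49) in leading and (0, 28) in leading
        assert leading[(0, 49)].status == AMBIGUOUS
        assert leading[(0, 28)].status == AMBIGUOUS
        # Torreyochloa and Briza share (0,49): same cluster, never self-ambiguous
        assert leading[(0, 49)].gap_taxa == {"Torreyochloa_pallida", "Briza_maxima"}

    def test_isolated_event_is_non_ambiguous(self):
        aln = Alignment.from_pairs(
            [("A", "AAAA----AAAA"), ("B", "AAAAACGTAAAA"), ("C", "AAAAACGTAAAA")]
        )
        events = flag_ambiguous(cluster_events(extract_gap_runs(aln)), aln, ["C"])
        assert [e.status for e in events] == [NON_AMBIGUOUS]

    def test_partial_outgroup_makes_event_ambiguous(self):
        # outgroup gapped over half the span: ancestral condition unreadable
        aln = Alignment.from_pairs(
            [("A", "AAAA--------AAAA"),
             ("B", "AAAAACGTACGTAAAA"),
             ("OUT", "AAAAACGT----AAAA")]
        )
        events = flag_ambiguous(cluster_events(extract_gap_runs(aln)), aln, ["OUT"])
        big = next(e for e in events if e.cols == (4, 12))
        assert big.status == AMBIGUOUS

    def test_partial_dense_region_is_ambiguous(self):
        # most non-member rows half-gapped inside the span -> rule (b)
        aln = Alignment.from_pairs(
            [("A", "AAAA--------AAAA"),
             ("B", "AAAAAC----GTAAAA"),
             ("C", "AAAA----ACGTAAAA"),
             ("D", "AAAAACGTACGTAAAA")]
        )
        events = flag_ambiguous(cluster_events(extract_gap_runs(aln)), aln)
        big = next(e for e in events if e.cols == (4, 12))
        assert big.status == AMBIGUOUS

    def test_unknown_outgroup_rejected(self, poeae_aln):
        with pytest.raises(DataError, match="outgroup"):
            flag_ambiguous(
                cluster_events(extract_gap_runs(poeae_aln)), poeae_aln, ["nope"]
            )


class TestSpanCondition:
    @pytest.mark.parametrize(
        "row,expected",
        [("ACGTACGTAC", "present"),
         ("----------", "absent"),
         ("ACGT----AC", "partial"),
         ("A---------", "absent"),
         ("ACGTACGTA-", "present")],
    )
    def test_conditions(self, row, expected):
        assert span_condition(row, (0, 10)) == expected


class TestFilterRgc:
    def _mk(self, lengths, status=NON_AMBIGUOUS):
        return [
            IndelEvent(id=f"e{i}", cols=(100 * i, 100 * i + L),
                       gap_taxa=frozenset({"A"}), status=status)
            for i, L in enumerate(lengths)
        ]

    def test_threshold_is_inclusive_at_50(self):
        split = filter_rgc(self._mk([4, 49, 50, 63]))
        assert sorted(e.length for e in split.rgc) == [50, 63]
        assert sorted(e.length for e in split.microstructural) == [4, 49]

    def test_observed_length_window(self):
        # events of 49/50/543/544 bp: the RGC window starts at 50 inclusive
        split = filter_rgc(self._mk([49, 50, 543, 544]))
        assert sorted(e.length for e in split.rgc) == [50, 543, 544]

    def test_fixture_yields_single_rgc(self, poeae_aln, poeae_outgroup):
        split = detect_rgc(poeae_aln, [poeae_outgroup])
        assert [e.length for e in split.rgc] == [63]
        assert [e.cols for e in split.rgc] == [(3, 66)]

    def test_empty_input(self):
        split = filter_rgc([])
        assert split.rgc == () and split.microstructural == ()

    def test_ambiguous_events_are_culled(self):
        split = filter_rgc(self._mk([60], status=AMBIGUOUS))
        assert split.rgc == () and len(split.ambiguous) == 1

    @pytest.mark.parametrize("threshold", [1, 10, 50, 64, 100])
    def test_monotone_in_threshold(self, poeae_aln, poeae_outgroup, threshold):
        lo = detect_rgc(poeae_aln, [poeae_outgroup], RgcConfig(min_rgc_len=threshold))
        hi = detect_rgc(
            poeae_aln, [poeae_outgroup], RgcConfig(min_rgc_len=threshold + 10)
        )
        assert len(hi.rgc) <= len(lo.rgc)
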