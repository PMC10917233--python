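import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igconvert import NamedSequence, Params, RepertoireRecord
from igconvert.refine_annotate import AnnotatedEvent
from igconvert.repertoire_summary import (
    aid_distance_distribution,
    control_mode_rate,
    diversity_profile,
    event_track,
    hill_number,
    positional_coverage,
    pseudogene_usage,
    sequence_event_stats,
    usage_vs_distance,
)

from conftest import random_dna

MOTIFS = Params().aid_motifs


def ev(start, end, donor="P1", max_start=None, max_end=None):
    return AnnotatedEvent(
        min_start=start,
        min_end=end,
        max_start=max_start if max_start is not None else start,
        max_end=max_end if max_end is not None else end,
        donor=donor,
        levenshtein=0,
        match_status="optimal" if donor else "unmatched",
    )


def rec(i, events, bird="b1"):
    return RepertoireRecord(id=f"s{i}", seq="ACGT", bird=bird, events=events)


class TestPositionalCoverage:
    def test_single_event(self):
        cov = positional_coverage([rec(1, [ev(5, 7)])], 10)
        counts = cov.set_index("position")["count"]
        assert [counts[p] for p in range(1, 11)] == [0, 0, 0, 0, 1, 1, 1, 0, 0, 0]

    def test_overlap_counts_twice(self):
        cov = positional_coverage([rec(1, [ev(5, 7), ev(7, 9)])], 10)
        counts = cov.set_index("position")["count"]
        assert counts[7] == 2

    def test_empty_records(self):
        cov = positional_coverage([], 10)
        assert cov["count"].sum() == 0

    def test_mass_conservation(self):
        events = [ev(2, 6), ev(4, 9), ev(1, 10)]
        cov = positional_coverage([rec(1, events)], 12)
        assert cov["count"].sum() == sum(e.min_end - e.min_start + 1 for e in events)

    def test_max_definition_uses_max_interval(self):
        cov = positional_coverage([rec(1, [ev(5, 7, max_start=3, max_end=9)])], 10, "max")
        assert cov["count"].sum() == 7

    def test_grouping(self):
        records = [rec(1, [ev(1, 3)], bird="b1"), rec(2, [ev(1, 3)], bird="b2")]
        cov = positional_coverage(records, 5, group_by="bird")
        assert set(cov["group"]) == {"b1", "b2"}

    def test_event_track(self):
        track = event_track([rec(1, [ev(5, 7), ev(9, 12, "P2")])])
        assert list(track["donor"]) == ["P1", "P2"]
        assert list(track["start"]) == [5, 9]


class TestDiversityProfile:
    def test_monomorphic_is_one(self):
        df = diversity_profile([["A", "A", "A", "A"]])
        assert df["score"][0] == pytest.approx(1.0, abs=1e-9)

    def test_two_base_even_split_is_two(self):
        df = diversity_profile([["A", "C", "A", "C"]])
        assert df["score"][0] == pytest.approx(2.0, abs=1e-9)

    def test_uniform_is_four(self):
        df = diversity_profile([["A", "C", "G", "T"]])
        assert df["score"][0] == pytest.approx(4.0, abs=1e-9)

    def test_empty_column_missing(self):
        df = diversity_profile([[], ["A"]])
        assert np.isnan(df["score"][0])
        assert df["score"][1] == 1.0

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.sampled_from("ACGT"), min_size=1, max_size=40))
    def test_bounds(self, column):
        score = diversity_profile([column])["score"][0]
        assert 1.0 - 1e-9 <= score <= 4.0 + 1e-9
        if len(set(column)) == 1:
            assert score == pytest.approx(1.0, abs=1e-9)

    def test_hill_orders(self):
        freqs = [0.5, 0.25, 0.125, 0.125]
        assert hill_number(freqs, q=0) == 4.0
        assert hill_number(freqs, q=1) == pytest.approx(math.exp(1.75 * math.log(2)), rel=1e-9)
        assert hill_number(freqs, q=2) == pytest.approx(1 / sum(f * f for f in freqs), rel=1e-9)


class TestPseudogeneUsage:
    def test_percent_and_preferred(self):
        events = [ev(1, 3, "P1")] * 5 + [ev(1, 3, "P2")] * 95
        usage = pseudogene_usage([rec(1, events)])
        p1 = usage[usage["donor"] == "P1"].iloc[0]
        assert p1["percent"] == pytest.approx(5.0)
        assert bool(p1["preferred"]) is True

    def test_preferred_any_vs_all(self):
        a = [ev(1, 3, "P1")] * 3 + [ev(1, 3, "P2")] * 97
        b = [ev(1, 3, "P1")] * 1 + [ev(1, 3, "P2")] * 99
        usage = pseudogene_usage([rec(1, a, bird="A"), rec(2, b, bird="B")])
        p1 = usage[usage["donor"] == "P1"]
        assert p1["preferred_any"].all()
        assert not p1["preferred_all"].any()

    def test_unmatched_excluded_from_denominator(self):
        events = [ev(1, 3, "P1")] * 2 + [ev(1, 3, None)] * 2
        usage = pseudogene_usage([rec(1, events)])
        p1 = usage[usage["donor"] == "P1"].iloc[0]
        assert p1["percent"] == pytest.approx(100.0)
        assert p1["unmatched_events"] == 2

    def test_percents_sum_to_100(self):
        rng = np.random.default_rng(0)
        events = [ev(1, 3, f"P{rng.integers(1, 6)}") for _ in range(200)]
        usage = pseudogene_usage([rec(1, events)])
        assert usage.groupby("group")["percent"].sum().iloc[0] == pytest.approx(100.0, abs=1e-9)

    def test_empty_group_warns(self):
        with pytest.warns(UserWarning, match="no donor-assigned"):
            pseudogene_usage(
                [rec(1, [ev(1, 3, "P1")], bird="A"), rec(2, [ev(1, 3, None)], bird="B")]
            )


class TestUsageVsDistance:
    def _usage_for(self, percents):
        events = []
        for donor, pct in percents.items():
            events += [ev(1, 3, donor)] * pct
        return pseudogene_usage([rec(1, events)])

    def test_perfect_anticorrelation(self):
        usage = self._usage_for({"P1": 50, "P2": 25, "P3": 15, "P4": 7, "P5": 3})
        distances = {"P1": 1.0, "P2": 2.0, "P3": 3.0, "P4": 4.0, "P5": 5.0}
        table, corr = usage_vs_distance(usage, distances)
        assert corr["spearman_rho"] == pytest.approx(-1.0)
        assert corr["p_value"] <= 2 / math.factorial(5) + 1e-12

    def test_constant_usage_rho_zero(self):
        usage = self._usage_for({"P1": 10, "P2": 10, "P3": 10})
        table, corr = usage_vs_distance(usage, {"P1": 1.0, "P2": 2.0, "P3": 3.0})
        assert corr["spearman_rho"] == 0.0

    def test_too_few_pairs_no_correlation(self):
        usage = self._usage_for({"P1": 10, "P2": 20})
        table, corr = usage_vs_distance(usage, {"P1": 1.0, "P2": 2.0})
        assert corr is None
        assert len(table) == 2

    def test_six_donor_rho_matches_rank_formula(self):
        usage = self._usage_for({"P1": 30, "P2": 10, "P3": 25, "P4": 5, "P5": 20, "P6": 10})
        distances = {"P1": 1.0, "P2": 2.0, "P3": 3.0, "P4": 4.0, "P5": 5.0, "P6": 6.0}
        table, corr = usage_vs_distance(usage, distances)
        # brute-force Spearman: correlation of ranks
        x = table["distance_kb"].rank().to_numpy()
        y = table["mean_percent"].rank().to_numpy()
        expected = np.corrcoef(x, y)[0, 1]
        assert corr["spearman_rho"] == pytest.approx(expected, rel=1e-9)


class TestAidDistanceDistribution:
    def test_events_adjacent_to_motifs_pile_at_zero(self):
        functional = "AAAGC" + "T" * 30  # AGC at 3-5
        records = [rec(i, [ev(6, 9)]) for i in range(4)]
        ev_hist, _ = aid_distance_distribution(records, functional, MOTIFS)
        assert list(ev_hist["distance"]) == [0]
        assert ev_hist["percent"].iloc[0] == pytest.approx(100.0)

    def test_motif_free_allele_empty_baseline(self):
        _, baseline = aid_distance_distribution([], "ATATATATAT", MOTIFS)
        assert len(baseline) == 0

    def test_baseline_equals_brute_force(self):
        from test_refine_annotate import brute_force_aid_distance

        rng = np.random.default_rng(5)
        functional = random_dna(rng, 120)
        _, baseline = aid_distance_distribution([], functional, MOTIFS)
        expected = [
            d
            for p in range(1, 121)
            if (d := brute_force_aid_distance(p, functional, MOTIFS)) is not None
        ]
        total = len(expected)
        from collections import Counter

        counts = Counter(expected)
        for _, row in baseline.iterrows():
            assert row["percent"] == pytest.approx(100.0 * counts[row["distance"]] / total)


class TestSequenceEventStats:
    def test_ninety_percent(self):
        records = [rec(i, [ev(1, 3)]) for i in range(9)] + [rec(9, [])]
        stats = sequence_event_stats(records)
        assert stats["percent_with_event"].iloc[0] == pytest.approx(90.0)

    def test_all_eventless(self):
        records = [rec(i, []) for i in range(10)]
        stats = sequence_event_stats(records)
        assert stats["percent_with_event"].iloc[0] == 0.0
        assert stats["mean_events"].iloc[0] == 0.0

    def test_mixed_counts_direct(self):
        records = [rec(0, []), rec(1, [ev(1, 3)]), rec(2, [ev(1, 3), ev(7, 9, "P2")])]
        stats = sequence_event_stats(records)
        assert stats["percent_with_event"].iloc[0] == pytest.approx(100 * 2 / 3)
        assert stats["percent_with_multiple"].iloc[0] == pytest.approx(100 / 3)
        assert stats["mean_events"].iloc[0] == pytest.approx(1.0)


class TestControlMode:
    def _family(self, rng, functional, n=4, divergence=0.15):
        swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
        alleles = []
        for i in range(n):
            seq = "".join(
                swap[c] if rng.random() < divergence else c for c in functional
            )
            alleles.append(NamedSequence(f"FAM{i + 1}", seq))
        return alleles

    def test_identical_sequences_rate_zero(self):
        rng = np.random.default_rng(0)
        functional = NamedSequence("F", random_dna(rng, 200))
        family = self._family(rng, functional.seq)
        seqs = [RepertoireRecord(id=f"s{i}", seq=functional.seq) for i in range(5)]
        assert control_mode_rate(seqs, functional, family) == 0.0

    def test_isolated_point_mutations_rate_zero(self):
        rng = np.random.default_rng(1)
        fseq = random_dna(rng, 200)
        functional = NamedSequence("F", fseq)
        family = self._family(rng, fseq)
        swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
        seqs = []
        for i in range(5):
            chars = list(fseq)
            for p in (20 + i, 90 + i, 160 + i):  # isolated singles, far apart
                chars[p] = swap[chars[p]]
            seqs.append(RepertoireRecord(id=f"s{i}", seq="".join(chars)))
        assert control_mode_rate(seqs, functional, family) == 0.0

    def test_empty_family_rejected(self):
        functional = NamedSequence("F", "ACGT" * 30)
        with pytest.raises(ValueError, match="same-family"):
            control_mode_rate([], functional, [functional])
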