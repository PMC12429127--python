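"""P2-P1 pair statistics, conditional P1 distributions, triplet patterns."""

import numpy as np
import pytest

from cleavemap import (
    AMINO_ACIDS,
    BackgroundComposition,
    PairMatrix,
    PairMotifProfiler,
    TripletPattern,
    background_from_proteins,
    build_matrix,
    conditional_p1_distribution,
    pair_counts,
    pair_zscores,
    triplet_patterns,
)
from cleavemap._aa import AA_INDEX


def _window(p3="A", p2="A", p1="A", prime="AAAAA"):
    """An 11-wide subsite string with chosen P3/P2/P1 residues."""
    return f"AAA{p3}{p2}{p1}{prime}"


class TestPairCounts:
    def test_single_window(self):
        pm = pair_counts([_window(p2="P", p1="F")])
        assert pm.counts[AA_INDEX["P"], AA_INDEX["F"]] == 1
        assert pm.n_pairs == 1
        assert pm.counts.sum() == 1

    def test_padded_subsites_do_not_contribute(self):
        pm = pair_counts(["-" * 5 + "A" * 6, _window()])  # P2 padded in the first
        assert pm.n_pairs == 1

    def test_deterministic_k_rule_concentrates_p1_column(self, gk_dataset):
        pm = pair_counts(gk_dataset["windows"])
        marginal = pm.counts.sum(axis=0)  # over P2 → P1 distribution
        g, k = AA_INDEX["G"], AA_INDEX["K"]
        assert marginal[g] + marginal[k] > 0.9 * pm.n_pairs

    def test_matches_brute_force_tally(self, gk_dataset):
        pm = pair_counts(gk_dataset["windows"])
        for a in "GKLP":
            for b in "GKLP":
                expected = sum(
                    w.residues[4] == a and w.residues[5] == b
                    for w in gk_dataset["windows"]
                )
                assert pm.counts[AA_INDEX[a], AA_INDEX[b]] == expected

    def test_p2_marginal_consistency_with_specificity_matrix(self, gk_dataset):
        """Summing pairs over P2 reproduces the P1 column restricted to
        defined-P2 windows."""
        defined = [w for w in gk_dataset["windows"] if w.residues[4] in AA_INDEX]
        pm = pair_counts(gk_dataset["windows"])
        m = build_matrix(defined)
        p1 = m.subsites.index("P1")
        assert np.array_equal(pm.counts.sum(axis=0), m.counts[:, p1])


class TestPairZscores:
    def test_zero_when_pairs_match_background(self):
        counts = np.zeros((20, 20), dtype=int)
        counts[AA_INDEX["A"], AA_INDEX["G"]] = 50
        counts[AA_INDEX["G"], AA_INDEX["A"]] = 50
        pm = PairMatrix(counts, 100)
        dipep = {a + b: 0.0 for a in AMINO_ACIDS for b in AMINO_ACIDS}
        dipep["AG"] = dipep["GA"] = 0.5
        freq = {aa: 0.05 for aa in AMINO_ACIDS}
        bg = BackgroundComposition("external_table", freq, dipeptide_freq=dipep)
        z = pair_zscores(pm, bg).values
        assert z[AA_INDEX["A"], AA_INDEX["G"]] == pytest.approx(0.0)
        assert z[AA_INDEX["G"], AA_INDEX["A"]] == pytest.approx(0.0)

    def test_binomial_proportion_formula(self):
        # p_IM = 0.05, q_IM = 0.01, n = 1000 → Z = 0.04/sqrt(0.0099/1000) = 12.71
        counts = np.zeros((20, 20), dtype=int)
        counts[AA_INDEX["I"], AA_INDEX["M"]] = 50
        counts[AA_INDEX["A"], AA_INDEX["A"]] = 950
        pm = PairMatrix(counts, 1000)
        dipep = {a + b: 0.0 for a in AMINO_ACIDS for b in AMINO_ACIDS}
        dipep["IM"] = 0.01
        dipep["AA"] = 0.99
        bg = BackgroundComposition(
            "external_table", {aa: 0.05 for aa in AMINO_ACIDS}, dipeptide_freq=dipep
        )
        z = pair_zscores(pm, bg).values[AA_INDEX["I"], AA_INDEX["M"]]
        assert round(float(z), 2) == 12.71

    def test_observed_pair_with_zero_background_is_fatal(self, gk_dataset):
        pm = pair_counts(gk_dataset["windows"])
        dipep = {a + b: 0.0 for a in AMINO_ACIDS for b in AMINO_ACIDS}
        dipep["AA"] = 1.0
        bg = BackgroundComposition(
            "external_table", {aa: 0.05 for aa in AMINO_ACIDS}, dipeptide_freq=dipep
        )
        with pytest.raises(ValueError, match="background"):
            pair_zscores(pm, bg)


class TestConditionalP1:
    def test_all_windows_conditioned_flags_empty_partition(self):
        result = conditional_p1_distribution([_window(p2="P", p1="F")] * 3, "P")
        assert result["insufficient_without"]
        assert result["n_with"] == 3 and result["n_without"] == 0
        assert result["freq_with"][AA_INDEX["F"]] == 1.0

    def test_partitions_are_exhaustive_and_disjoint(self, gk_dataset):
        result = conditional_p1_distribution(gk_dataset["windows"], "P")
        n_defined = sum(
            w.residues[4] in AA_INDEX and w.residues[5] in AA_INDEX
            for w in gk_dataset["windows"]
        )
        assert result["n_with"] + result["n_without"] == n_defined

    def test_matches_brute_force_recount(self, gk_dataset):
        result = conditional_p1_distribution(gk_dataset["windows"], "P")
        with_p = [
            w.residues[5] for w in gk_dataset["windows"]
            if w.residues[4] == "P" and w.residues[5] in AA_INDEX
        ]
        for aa in AMINO_ACIDS:
            expected = with_p.count(aa) / len(with_p) if with_p else 0.0
            assert result["freq_with"][AA_INDEX[aa]] == pytest.approx(expected)


class TestTripletPatterns:
    def test_wildcard_class_pattern_counts_constructed_fixture(self):
        windows = [_window("G", "A", "L"), _window("G", "P", "M"), _window("G", "T", "P")]
        ranked = triplet_patterns(windows, patterns=["G-X-[LMP]"])
        by_pattern = {tp.pattern: tp.count for tp in ranked}
        assert by_pattern["G-X-[LMP]"] == 3

    def test_slash_class_notation_accepted(self):
        assert TripletPattern("G-X-[L/M/P]").matches("GAL")

    def test_unmatched_pattern_counts_zero(self):
        ranked = triplet_patterns([_window("A", "A", "A")], patterns=["W-W-W"])
        assert {tp.pattern: tp.count for tp in ranked}["W-W-W"] == 0

    def test_generalized_count_equals_sum_of_matching_concrete_triples(self, gk_dataset):
        ranked = triplet_patterns(gk_dataset["windows"], patterns=["G-X-[GK]"])
        by_pattern = {tp.pattern: tp.count for tp in ranked}
        concrete_sum = sum(
            count for pattern, count in by_pattern.items()
            if len(pattern) == 5 and pattern != "G-X-[GK]"
            and TripletPattern("G-X-[GK]").matches(pattern.replace("-", ""))
        )
        assert by_pattern["G-X-[GK]"] == concrete_sum

    def test_widening_a_class_never_decreases_the_count(self, gk_dataset):
        narrow = triplet_patterns(gk_dataset["windows"], patterns=["X-X-[G]"])
        wide = triplet_patterns(gk_dataset["windows"], patterns=["X-X-[GK]"])
        n = {tp.pattern: tp.count for tp in narrow}["X-X-[G]"]
        w = {tp.pattern: tp.count for tp in wide}["X-X-[GK]"]
        assert w >= n

    def test_ranking_is_descending_with_alphabetical_ties(self, gk_dataset):
        ranked = triplet_patterns(gk_dataset["windows"])
        keys = [(-tp.count, tp.pattern) for tp in ranked]
        assert keys == sorted(keys)


class TestPairMotifProfiler:
    def test_fit_exposes_pair_layers_and_conditional(self, gk_dataset):
        bg = background_from_proteins(gk_dataset["proteome"])
        profiler = PairMotifProfiler(background=bg, top_k=5).fit(gk_dataset["windows"])
        assert profiler.pair_counts_.n_pairs > 0
        assert len(profiler.top_pairs_) == 5
        assert profiler.conditional_["condition_residue"] == "P"
        # top pairs from the Z layer all end in the rule's P1 residues
        assert all(p1 in "GK" for _, p1, _ in profiler.top_pairs_)
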