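"""Specificity matrices, backgrounds, normalization and Z-scores."""

import numpy as np
import pytest

from cleavemap import (
    AMINO_ACIDS,
    BackgroundComposition,
    ProteaseRule,
    SpecificityProfiler,
    background_from_proteins,
    build_matrix,
    compare_compositions,
    normalize,
    run_pipeline,
    zscore,
)
from cleavemap._aa import AA_INDEX, subsite_labels


def _uniform_background(**overrides):
    freq = {aa: 0.05 for aa in AMINO_ACIDS}
    if overrides:
        freq.update(overrides)
        rest = 1.0 - sum(overrides.values())
        others = [aa for aa in AMINO_ACIDS if aa not in overrides]
        for aa in others:
            freq[aa] = rest / len(others)
    return BackgroundComposition("external_table", freq)


class TestBuildMatrix:
    def test_single_window_concentrates_p1(self):
        m = build_matrix(["--MAGKLSTRW"])
        p1 = m.subsites.index("P1")
        assert m.frequencies[AA_INDEX["K"], p1] == 1.0
        assert m.counts[:, p1].sum() == 1
        # padded P6/P5 slots are not observations
        assert m.n_defined[0] == 0 and m.n_defined[1] == 0

    def test_empty_input_is_fatal(self):
        with pytest.raises(ValueError, match="no cleavage sites"):
            build_matrix([])

    def test_matches_brute_force_tally(self, gk_dataset):
        m = build_matrix(gk_dataset["windows"])
        labels = subsite_labels()
        for j in range(11):
            column = [w.residues[j] for w in gk_dataset["windows"]]
            for aa in AMINO_ACIDS:
                assert m.counts[AA_INDEX[aa], j] == column.count(aa), (aa, labels[j])
            assert m.n_defined[j] == sum(c != "-" for c in column)

    def test_frequency_columns_sum_to_one(self, gk_dataset):
        m = build_matrix(gk_dataset["windows"])
        sums = m.frequencies.sum(axis=0)
        assert np.allclose(sums[m.n_defined > 0], 1.0, atol=1e-9)


class TestBackground:
    def test_single_protein_degenerate(self):
        bg = background_from_proteins([("A1", "AAAA")])
        assert bg.residue_freq["A"] == 1.0
        assert bg.dipeptide_freq["AA"] == 1.0

    def test_two_proteins_pairs_do_not_span_boundaries(self):
        bg = background_from_proteins([("A1", "AG"), ("A2", "GA")])
        assert bg.residue_freq["A"] == 0.5 and bg.residue_freq["G"] == 0.5
        assert bg.dipeptide_freq["AG"] == 0.5 and bg.dipeptide_freq["GA"] == 0.5
        assert bg.dipeptide_freq["GG"] == 0.0  # would require spanning A1|A2

    def test_matches_brute_force_recount(self, proteome_small):
        bg = background_from_proteins(proteome_small)
        pooled = "".join(seq for _, seq in sorted(proteome_small))
        n = len(pooled)
        for aa in AMINO_ACIDS:
            assert bg.residue_freq[aa] == pytest.approx(pooled.count(aa) / n)
        # dipeptides recounted independently
        pair_total = sum(len(seq) - 1 for _, seq in proteome_small)
        counts: dict[str, int] = {}
        for _, seq in proteome_small:
            for i in range(len(seq) - 1):
                counts[seq[i : i + 2]] = counts.get(seq[i : i + 2], 0) + 1
        for pair, c in counts.items():
            assert bg.dipeptide_freq[pair] == pytest.approx(c / pair_total)

    def test_each_protein_counted_once(self):
        once = background_from_proteins([("A1", "AAAG")])
        twice = background_from_proteins([("A1", "AAAG"), ("A1", "AAAG")])
        assert once.residue_freq == twice.residue_freq

    def test_tsv_round_trip(self, tmp_path, proteome_small):
        bg = background_from_proteins(proteome_small)
        path = tmp_path / "bg.tsv"
        bg.to_tsv(path)
        reread = BackgroundComposition.from_tsv(path)
        for aa in AMINO_ACIDS:
            assert reread.residue_freq[aa] == pytest.approx(bg.residue_freq[aa], abs=1e-9)


class TestNormalize:
    def test_identity_when_frequency_equals_background(self):
        # windows drawn so each of 4 residues occurs equally at the one subsite
        windows = ["A", "C", "D", "E"]
        m = build_matrix(windows)
        freq = {aa: 0.0 for aa in AMINO_ACIDS}
        freq.update({"A": 0.25, "C": 0.25, "D": 0.25, "E": 0.25})
        bg = BackgroundComposition("external_table", freq)
        ratios = normalize(m, bg).values
        observed = m.counts.sum(axis=1) > 0
        assert np.allclose(ratios[observed], 1.0)
        assert np.all(ratios[~observed] == 0.0)

    def test_ratio_arithmetic(self):
        n = 1000
        counts = {"G": 345}
        windows = ["G"] * counts["G"] + ["A"] * (n - counts["G"])
        m = build_matrix(windows)
        bg = _uniform_background(G=0.0707)
        ratio = normalize(m, bg).values[AA_INDEX["G"], 0]
        assert round(ratio, 2) == 4.88

    def test_observed_residue_with_zero_background_is_fatal(self):
        m = build_matrix(["G"])
        freq = {aa: 0.0 for aa in AMINO_ACIDS}
        freq["A"] = 1.0
        with pytest.raises(ValueError, match="G"):
            normalize(m, BackgroundComposition("external_table", freq))


class TestZscore:
    def test_zero_when_observation_matches_background(self):
        windows = ["A", "C", "D", "E"]
        m = build_matrix(windows)
        freq = {aa: 0.0 for aa in AMINO_ACIDS}
        freq.update({"A": 0.25, "C": 0.25, "D": 0.25, "E": 0.25})
        z = zscore(m, BackgroundComposition("external_table", freq)).values
        observed = m.counts.sum(axis=1) > 0
        assert np.allclose(z[observed], 0.0)

    def test_binomial_proportion_formula(self):
        # f_obs = 0.30, q = 0.20, n = 100  ->  Z = 0.1 / sqrt(0.2*0.8/100) = 2.5
        windows = ["G"] * 30 + ["A"] * 70
        m = build_matrix(windows)
        bg = _uniform_background(G=0.20)
        z = zscore(m, bg).values[AA_INDEX["G"], 0]
        assert z == pytest.approx(2.5)

    def test_degenerate_background_flags_infinity(self):
        m = build_matrix(["G", "A"])
        freq = {aa: 0.0 for aa in AMINO_ACIDS}
        freq["G"] = 1.0
        with pytest.raises(ValueError):
            # A observed with zero background → normalize is fatal, but the
            # zscore layer flags it as signed infinity instead
            normalize(m, BackgroundComposition("external_table", freq))
        z = zscore(m, BackgroundComposition("external_table", freq)).values
        assert z[AA_INDEX["A"], 0] == np.inf
        assert z[AA_INDEX["G"], 0] == -np.inf

    def test_permutation_equivariance(self, gk_dataset):
        """Relabeling residues permutes the Z matrix rows accordingly."""
        windows = [w.residues for w in gk_dataset["windows"][:500]]
        bg = background_from_proteins(gk_dataset["proteome"])
        z = zscore(build_matrix(windows), bg).values
        # swap two residue letters everywhere (windows and background)
        swap = str.maketrans("GK", "KG")
        swapped_windows = [w.translate(swap) for w in windows]
        swapped_freq = dict(bg.residue_freq)
        swapped_freq["G"], swapped_freq["K"] = swapped_freq["K"], swapped_freq["G"]
        z_swapped = zscore(
            build_matrix(swapped_windows),
            BackgroundComposition("external_table", swapped_freq),
        ).values
        g, k = AA_INDEX["G"], AA_INDEX["K"]
        assert np.allclose(z_swapped[g], z[k]) and np.allclose(z_swapped[k], z[g])
        others = [i for i in range(20) if i not in (g, k)]
        assert np.allclose(z_swapped[others], z[others])


class TestCompareCompositions:
    def test_identical_compositions_correlate_perfectly(self, proteome_small):
        bg = background_from_proteins(proteome_small)
        r, rho = compare_compositions(bg, bg)
        assert r == pytest.approx(1.0) and rho == pytest.approx(1.0)

    def test_reversed_ranking_gives_negative_spearman(self):
        base = np.arange(1, 21, dtype=float)
        a = BackgroundComposition(
            "external_table", dict(zip(AMINO_ACIDS, base / base.sum()))
        )
        b = BackgroundComposition(
            "external_table", dict(zip(AMINO_ACIDS, base[::-1] / base.sum()))
        )
        _, rho = compare_compositions(a, b)
        assert rho == pytest.approx(-1.0)

    def test_matches_textbook_formulas(self):
        rng = np.random.default_rng(7)
        x = rng.dirichlet(np.ones(20))
        y = rng.dirichlet(np.ones(20))
        a = BackgroundComposition("external_table", dict(zip(AMINO_ACIDS, x)))
        b = BackgroundComposition("external_table", dict(zip(AMINO_ACIDS, y)))
        r, rho = compare_compositions(a, b)
        # Pearson from the covariance definition
        r_hand = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        # Spearman as Pearson on ranks
        rank = lambda v: np.argsort(np.argsort(v)) + 1.0
        rx, ry = rank(x), rank(y)
        rho_hand = float(
            ((rx - rx.mean()) * (ry - ry.mean())).sum()
            / np.sqrt(((rx - rx.mean()) ** 2).sum() * ((ry - ry.mean()) ** 2).sum())
        )
        assert r == pytest.approx(r_hand)
        assert rho == pytest.approx(rho_hand)

    def test_zero_variance_reported_as_undefined(self):
        flat = BackgroundComposition("external_table", {aa: 0.05 for aa in AMINO_ACIDS})
        r, rho = compare_compositions(flat, flat)
        assert np.isnan(r) and np.isnan(rho)


class TestSpecificityProfiler:
    def test_single_residue_protease_maximizes_its_p1_z(self):
        run = run_pipeline(ProteaseRule("g", {"G": 0.9}), n_proteins=120, seed=21)
        z = run.profiler.zscores_
        p1 = run.profiler.matrix_.subsites.index("P1")
        g = AA_INDEX["G"]
        finite = np.where(np.isfinite(z), z, -np.inf)
        assert np.unravel_index(np.argmax(finite), z.shape) == (g, p1)

    def test_identified_background_requires_proteins(self, gk_dataset):
        with pytest.raises(ValueError, match="proteins"):
            SpecificityProfiler().fit(gk_dataset["windows"])
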