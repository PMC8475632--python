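import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import strainps as sp
from conftest import random_matrix
from strainps.errors import (
    DegenerateGroupingError,
    RareVariantError,
    ValidationError,
)
from strainps.ps_association import manova_statistic

from oracles import bh_by_hand


def _coords(seed=0, n_groups=2, sizes=(10, 10), m=800, fst=0.2, p=4,
            source="GRM"):
    cfg = sp.SimulationConfig(
        n_groups=n_groups, strains_per_group=sizes, n_snps=m, fst=fst,
        seed=seed,
    )
    gm, truth = sp.simulate_structured_panel(cfg)
    mat = sp.compute_grm(gm) if source == "GRM" else sp.compute_ibs(gm)
    return sp.pca(mat, p), truth, gm


class TestManova:
    def test_matches_statsmodels_pillai_and_wilks(self):
        import pandas as pd
        from statsmodels.multivariate.manova import MANOVA

        coords, _, _ = _coords(seed=42, n_groups=3, sizes=(8, 9, 8), p=4)
        rng = np.random.default_rng(3)
        labels = rng.integers(1, 4, 25)
        fit_p = sp.ps_manova_test(labels, coords, statistic="pillai")
        fit_w = sp.ps_manova_test(labels, coords, statistic="wilks")
        df = pd.DataFrame(coords.scores, columns=list("abcd"))
        df["g"] = labels.astype(str)
        ref = MANOVA.from_formula("a+b+c+d ~ g", data=df).mv_test()
        table = ref.results["g"]["stat"]
        assert fit_p.statistic_value == pytest.approx(
            float(table.loc["Pillai's trace", "Value"]), rel=1e-9
        )
        assert fit_p.p_value == pytest.approx(
            float(table.loc["Pillai's trace", "Pr > F"]), rel=1e-9
        )
        assert fit_w.statistic_value == pytest.approx(
            float(table.loc["Wilks' lambda", "Value"]), rel=1e-9
        )
        assert fit_w.p_value == pytest.approx(
            float(table.loc["Wilks' lambda", "Pr > F"]), rel=1e-9
        )

    def test_fit_reconstructs_response(self):
        coords, truth, _ = _coords(seed=7)
        fit = sp.ps_manova_test(truth.group_labels, coords)
        # group means (mu + effects) plus residuals reproduce y
        y = coords.scores
        means = {
            g: y[truth.group_labels == g].mean(axis=0)
            for g in np.unique(truth.group_labels)
        }
        fitted = np.vstack([means[g] for g in truth.group_labels])
        np.testing.assert_allclose(fitted + fit.residuals, y, atol=1e-12)

    def test_structure_aligned_grouping_is_significant(self):
        hits = 0
        for seed in range(30):
            coords, truth, _ = _coords(seed=seed, fst=0.3)
            fit = sp.ps_manova_test(truth.group_labels, coords)
            hits += fit.p_value < 0.01
        assert hits >= 27

    def test_coin_flip_grouping_p_uniform(self):
        pvals = []
        for seed in range(300):
            coords, _, _ = _coords(seed=seed, m=500, fst=0.3)
            rng = np.random.default_rng(10_000 + seed)
            lab = rng.integers(0, 2, 20)
            while lab.min() == lab.max():
                lab = rng.integers(0, 2, 20)
            pvals.append(sp.ps_manova_test(lab + 1, coords).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_parametric_close_to_permutation(self):
        coords, _, _ = _coords(seed=0, m=800)
        rng = np.random.default_rng(500)
        lab = rng.integers(1, 3, 20)
        fit = sp.ps_manova_test(lab, coords)
        obs = fit.statistic_value
        count = 0
        B = 10_000
        for _ in range(B):
            count += manova_statistic(
                coords.scores, rng.permutation(lab)
            ) >= obs - 1e-12
        perm_p = (1 + count) / (1 + B)
        assert fit.p_value == pytest.approx(perm_p, abs=0.02)

    def test_small_residual_df_falls_back_to_permutation(self):
        _, truth, _ = _coords(seed=2, n_groups=2, sizes=(5, 5), m=300)
        # n=10, k=2: residual df is 8, so p=9 PCs forces the fallback
        coords9 = sp.pca(sp.compute_grm(random_matrix(
            np.random.default_rng(0), 10, 300)), 9)
        fit = sp.ps_manova_test(truth.group_labels, coords9, seed=3,
                                n_permutations=2000)
        assert fit.method == "permutation"
        assert fit.n_permutations == 2000
        assert 0.0 < fit.p_value <= 1.0

    def test_single_group_rejected(self):
        coords, _, _ = _coords(seed=3)
        with pytest.raises(DegenerateGroupingError):
            sp.ps_manova_test(np.ones(20, dtype=int), coords)

    def test_unassigned_strains_dropped(self):
        coords, truth, _ = _coords(seed=4)
        lab = truth.group_labels.copy()
        lab[:3] = 0  # unassigned
        fit = sp.ps_manova_test(lab, coords)
        assert fit.n_strains == 17


class TestVariantTest:
    def test_rare_variant_rejected(self):
        coords, _, _ = _coords(seed=5, sizes=(24, 24), m=500)
        x = np.zeros(48, dtype=int)
        x[:2] = 1
        with pytest.raises(RareVariantError):
            sp.variant_ps_test(x, coords)

    def test_monomorphic_indicator_degenerate(self):
        coords, _, _ = _coords(seed=5)
        with pytest.raises(DegenerateGroupingError):
            sp.variant_ps_test(np.zeros(20, dtype=int), coords)

    def test_equals_manova_on_same_partition(self):
        coords, truth, _ = _coords(seed=6, fst=0.3)
        x = (truth.group_labels == 2).astype(int)
        a = sp.variant_ps_test(x, coords)
        b = sp.ps_manova_test(truth.group_labels, coords)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)
        assert a.p_value < 0.01


class TestBH:
    def test_single_value_unchanged(self):
        assert sp.bh_adjust([0.03])[0] == pytest.approx(0.03)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                 max_size=50)
    )
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_step_up_properties_hold_for_any_p_vector(self, p):
        adj = sp.bh_adjust(p)
        p = np.asarray(p)
        assert np.all(adj <= 1.0 + 1e-15)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-12)
        np.testing.assert_allclose(adj, bh_by_hand(p), atol=1e-12)

    def test_textbook_step_up_example(self):
        out = sp.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_matches_direct_formula_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            ours = sp.bh_adjust(p)
            np.testing.assert_allclose(ours, bh_by_hand(p), atol=1e-12)
            np.testing.assert_allclose(
                ours, multipletests(p, method="fdr_bh")[1], atol=1e-12
            )

    def test_adjusted_dominates_raw_and_monotone_in_sorted_order(self, rng):
        p = rng.random(25)
        adj = sp.bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            sp.bh_adjust([0.5, 1.2])


class TestClassification:
    def test_boundary_behavior(self):
        # in a single-test family p_adj = p_raw, exposing the raw boundary
        single_hi = sp.make_ps_results(["x"], [0.05], q=0.05)[0]
        single_lo = sp.make_ps_results(["y"], [0.049], q=0.05)[0]
        assert single_lo.classification == "PS+"
        assert single_hi.classification == "PS-"

    def test_counts_match_brute_force_threshold(self, rng):
        p = rng.random(40)
        results = sp.make_ps_results(list(range(40)), p, q=0.05)
        adj = bh_by_hand(p)
        want_plus = int((adj < 0.05).sum())
        got_plus = sum(r.classification == "PS+" for r in results)
        assert got_plus == want_plus

    def test_reclassification_at_new_q(self, rng):
        p = rng.random(20) * 0.2
        results = sp.make_ps_results(list(range(20)), p, q=0.05)
        relaxed = sp.classify_ps(results, q=0.5)
        for r in relaxed:
            assert r.classification == ("PS+" if r.p_adj < 0.5 else "PS-")

    def test_orthogonal_planted_carrier_set_is_ps_minus(self):
        # a carrier set orthogonal to sub-population membership should be
        # PS-, one equal to a sub-population should be PS+
        minus_hits, plus_hits = 0, 0
        for seed in range(20):
            coords, truth, gm = _coords(
                seed=seed, n_groups=2, sizes=(12, 12), m=1200, fst=0.3
            )
            # orthogonal: half of each sub-population
            lab_orth = np.where(np.arange(24) % 2 == 0, 1, 2)
            p_orth = sp.ps_manova_test(lab_orth, coords).p_value
            p_align = sp.ps_manova_test(truth.group_labels, coords).p_value
            res = sp.make_ps_results(["orth", "align"], [p_orth, p_align])
            by = {r.target: r.classification for r in res}
            minus_hits += by["orth"] == "PS-"
            plus_hits += by["align"] == "PS+"
        assert minus_hits >= 18
        assert plus_hits >= 18
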