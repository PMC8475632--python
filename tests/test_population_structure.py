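import numpy as np
import pytest

import strainps as sp
from conftest import make_matrix, random_matrix
from strainps.errors import ParameterError, ValidationError
from strainps.genotype_io import MISSING
from strainps.population_structure import (
    LD_PRUNE_PRESETS,
    choose_n_pcs,
    iter_windows,
    tw1_sf,
)


class TestGRM:
    def test_identical_strains_have_identical_rows(self):
        calls = np.array(
            [[0, 1, 0, 1, 1], [0, 1, 0, 1, 1], [1, 0, 1, 0, 0], [0, 0, 1, 1, 0]],
            dtype=np.int8,
        )
        grm = sp.compute_grm(make_matrix(calls))
        np.testing.assert_allclose(grm.values[0], grm.values[1])

    def test_matches_direct_formula_on_toy_calls(self):
        calls = np.array(
            [[0, 1, 1, 0, 1, 0],
             [1, 1, 0, 0, 1, 1],
             [0, 0, 1, 1, 0, 0],
             [1, 0, 0, 1, 1, 1]],
            dtype=np.int8,
        )
        grm = sp.compute_grm(make_matrix(calls))
        # independent evaluation of the per-entry formula
        freq = calls.mean(axis=0)
        z = (calls - freq) / np.sqrt(freq * (1 - freq))
        want = z @ z.T / calls.shape[1]
        np.testing.assert_allclose(grm.values, want, atol=1e-12)

    def test_monomorphic_sites_skipped_but_no_maf_filter(self):
        # a rare allele (1 of 10 strains) still contributes; constant
        # columns do not
        calls = np.zeros((10, 4), dtype=np.int8)
        calls[0, 0] = 1
        calls[:5, 1] = 1
        calls[:, 2] = 1  # monomorphic
        calls[3, 3] = 1
        grm = sp.compute_grm(make_matrix(calls))
        freq = calls[:, [0, 1, 3]].mean(axis=0)
        z = (calls[:, [0, 1, 3]] - freq) / np.sqrt(freq * (1 - freq))
        np.testing.assert_allclose(grm.values, z @ z.T / 3, atol=1e-12)

    def test_all_monomorphic_errors(self):
        with pytest.raises(ValidationError, match="monomorphic"):
            sp.compute_grm(make_matrix(np.ones((4, 5), dtype=np.int8)))

    def test_invariant_under_strain_reordering(self, rng):
        gm = random_matrix(rng, 8, 100, missing_rate=0.05)
        perm = rng.permutation(8)
        gm2 = make_matrix(
            gm.calls[perm], names=[gm.strain_names[i] for i in perm]
        )
        a = sp.compute_grm(gm).values
        b = sp.compute_grm(gm2).values
        np.testing.assert_allclose(a[np.ix_(perm, perm)], b, atol=1e-10)


class TestIBS:
    def test_identical_and_complementary_strains(self):
        calls = np.array([[0, 1, 0, 1], [0, 1, 0, 1], [1, 0, 1, 0]], dtype=np.int8)
        ibs = sp.compute_ibs(make_matrix(calls))
        assert ibs.values[0, 1] == pytest.approx(1.0)
        assert ibs.values[0, 2] == pytest.approx(0.0)

    def test_hand_counted_match_fractions(self):
        calls = np.array(
            [[0, 1, 1, 0, 1], [0, 0, 1, 1, 1], [1, 1, 0, 0, 0]], dtype=np.int8
        )
        ibs = sp.compute_ibs(make_matrix(calls))
        assert ibs.values[0, 1] == pytest.approx(3 / 5)
        assert ibs.values[0, 2] == pytest.approx(2 / 5)
        assert ibs.values[1, 2] == pytest.approx(0.0)

    def test_missing_calls_shrink_the_denominator(self):
        calls = np.array([[0, 1, MISSING, 1], [0, 1, 1, 0]], dtype=np.int8)
        calls = np.vstack([calls, [[1, 0, 1, 0]]]).astype(np.int8)
        ibs = sp.compute_ibs(make_matrix(calls))
        assert ibs.values[0, 1] == pytest.approx(2 / 3)


class TestPCA:
    def test_full_rank_reconstructs_grm(self, rng):
        gm = random_matrix(rng, 8, 200)
        grm = sp.compute_grm(gm)
        pc = sp.pca(grm, p=8)
        np.testing.assert_allclose(
            pc.scores @ pc.scores.T, grm.values, atol=1e-8
        )

    def test_variance_fractions_sum_to_one_nonincreasing(self, rng):
        gm = random_matrix(rng, 10, 300)
        pc = sp.pca(sp.compute_grm(gm), 4)
        assert pc.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(pc.eigenvalues) <= 1e-9)

    def test_two_group_separation_on_pc1(self):
        hits = 0
        for seed in range(20):
            cfg = sp.SimulationConfig(
                n_groups=2, strains_per_group=(10, 10), n_snps=1500,
                fst=0.3, seed=seed,
            )
            gm, truth = sp.simulate_structured_panel(cfg)
            pc = sp.pca(sp.compute_grm(gm), 4)
            a = pc.scores[truth.group_labels == 1, 0]
            b = pc.scores[truth.group_labels == 2, 0]
            pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
            if abs(a.mean() - b.mean()) > 4 * pooled:
                hits += 1
        assert hits >= 18

    def test_manova_p_invariant_to_score_scaling(self, rng):
        gm = random_matrix(rng, 12, 400)
        grm = sp.compute_grm(gm)
        lab = rng.integers(1, 3, 12)
        while len(set(lab)) < 2:
            lab = rng.integers(1, 3, 12)
        p1 = sp.ps_manova_test(lab, sp.pca(grm, 4, scale=True)).p_value
        p2 = sp.ps_manova_test(lab, sp.pca(grm, 4, scale=False)).p_value
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_choose_n_pcs_tracks_structured_dimensions(self):
        cfg = sp.SimulationConfig(
            n_groups=4, strains_per_group=(8, 8, 8, 8), n_snps=4000,
            fst=0.3, seed=1,
        )
        gm, _ = sp.simulate_structured_panel(cfg)
        pc = sp.pca(sp.compute_grm(gm), 4)
        assert choose_n_pcs(pc.eigenvalues) == 3  # 4 groups -> 3 contrasts


class TestTracyWidom:
    def test_null_panel_rarely_significant(self):
        hits = 0
        for seed in range(30):
            cfg = sp.SimulationConfig(
                n_groups=2, strains_per_group=(13, 12), n_snps=1500,
                fst=0.0, seed=seed,
            )
            gm, _ = sp.simulate_structured_panel(cfg)
            pc = sp.pca(sp.compute_grm(gm), 4)
            tw = sp.tw_test(pc.eigenvalues, 25, 1500)
            hits += tw.iloc[0]["p_value"] > 0.05
        assert hits >= 27

    def test_structured_panel_detected(self):
        hits = 0
        for seed in range(30):
            cfg = sp.SimulationConfig(
                n_groups=2, strains_per_group=(13, 12), n_snps=1500,
                fst=0.3, seed=seed,
            )
            gm, _ = sp.simulate_structured_panel(cfg)
            pc = sp.pca(sp.compute_grm(gm), 4)
            tw = sp.tw_test(pc.eigenvalues, 25, 1500)
            hits += tw.iloc[0]["p_value"] < 0.05
        assert hits >= 27

    def test_equal_eigenvalues_not_significant(self):
        tw = sp.tw_test(np.ones(20), 20, 5000)
        assert (tw["p_value"] > 0.05).all()

    def test_tw1_tail_matches_published_quantiles(self):
        # 95th and 99th percentiles of the TW(beta=1) law
        assert tw1_sf(0.9793) == pytest.approx(0.05, abs=2e-3)
        assert tw1_sf(2.0234) == pytest.approx(0.01, abs=1e-3)

    def test_too_few_eigenvalues_error(self):
        with pytest.raises(ValidationError):
            sp.tw_test(np.array([2.0, 1.0]), 2, 100)


class TestClustering:
    def test_k1_is_one_label(self, rng):
        ibs = sp.compute_ibs(random_matrix(rng, 6, 50))
        asg = sp.hierarchical_subpopulations(ibs, 1)
        assert set(asg.labels) == {1}

    def test_identical_strains_co_cluster(self, rng):
        calls = random_matrix(rng, 5, 60).calls
        calls = np.vstack([calls, calls[0]]).astype(np.int8)
        gm = make_matrix(calls)
        ibs = sp.compute_ibs(gm)
        for k in range(2, 6):
            asg = sp.hierarchical_subpopulations(ibs, k)
            assert asg.labels[0] == asg.labels[5]

    def test_four_group_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        hits = 0
        for seed in range(10):
            cfg = sp.SimulationConfig(
                n_groups=4, strains_per_group=(8, 8, 8, 8), n_snps=2000,
                fst=0.3, seed=seed,
            )
            gm, truth = sp.simulate_structured_panel(cfg)
            asg = sp.hierarchical_subpopulations(sp.compute_ibs(gm), 4)
            hits += adjusted_rand_score(truth.group_labels, asg.labels) == 1.0
        assert hits >= 9

    def test_grm_input_rejected(self, rng):
        grm = sp.compute_grm(random_matrix(rng, 6, 50))
        with pytest.raises(ValidationError, match="IBS"):
            sp.hierarchical_subpopulations(grm, 2)

    def test_pruned_and_full_clusterings_agree_under_strong_structure(self):
        cfg = sp.SimulationConfig(
            n_groups=4, strains_per_group=(8, 8, 8, 8), n_snps=3000,
            fst=0.3, seed=2,
        )
        gm, _ = sp.simulate_structured_panel(cfg)
        pruned = sp.ld_prune(gm, *LD_PRUNE_PRESETS["10kb_r2_0.5"])
        a = sp.hierarchical_subpopulations(sp.compute_ibs(gm), 4)
        b = sp.hierarchical_subpopulations(sp.compute_ibs(pruned), 4)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(a.labels, b.labels) == 1.0


class TestAnovaOnPCs:
    def test_true_labels_detected_under_structure(self):
        hits = 0
        for seed in range(20):
            cfg = sp.SimulationConfig(
                n_groups=2, strains_per_group=(10, 10), n_snps=1500,
                fst=0.3, seed=seed,
            )
            gm, truth = sp.simulate_structured_panel(cfg)
            pc = sp.pca(sp.compute_grm(gm), 4)
            asg = sp.SubPopulationAssignment(
                labels=truth.group_labels, k=2, strain_names=gm.strain_names
            )
            out = sp.population_structure.anova_on_pcs(pc, asg)
            hits += out.iloc[0]["p_value"] < 0.001
        assert hits >= 18

    def test_random_labels_give_uniform_p(self, rng):
        cfg = sp.SimulationConfig(
            n_groups=1, strains_per_group=(20,), n_snps=800, fst=0.0, seed=0
        )
        gm, _ = sp.simulate_structured_panel(cfg)
        pc = sp.pca(sp.compute_grm(gm), 1)
        from scipy import stats

        pvals = []
        for _ in range(300):
            lab = rng.integers(1, 3, 20)
            while len(set(lab)) < 2:
                lab = rng.integers(1, 3, 20)
            asg = sp.SubPopulationAssignment(
                labels=lab, k=2, strain_names=gm.strain_names
            )
            pvals.append(
                sp.population_structure.anova_on_pcs(pc, asg).iloc[0]["p_value"]
            )
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestLDPrune:
    def test_identical_nearby_columns_pruned(self, rng):
        calls = random_matrix(rng, 10, 2).calls
        calls[:, 1] = calls[:, 0]
        gm = make_matrix(calls, pos=[1000, 1100])
        out = sp.ld_prune(gm, window_bp=10_000, r2_threshold=0.5)
        assert out.n_sites == 1 and out.pos_bp[0] == 1000

    def test_no_violating_pair_survives(self, rng):
        # brute-force post-check over every within-window pair
        gm = random_matrix(rng, 12, 120)
        # duplicate some columns to create strong LD
        for j in range(0, 100, 7):
            gm.calls[:, j + 1] = gm.calls[:, j]
        out = sp.ld_prune(gm, window_bp=3000, r2_threshold=0.5)
        for _, members in iter_windows(out, 3000):
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    x = out.calls[:, members[a]].astype(float)
                    y = out.calls[:, members[b]].astype(float)
                    if x.std() == 0 or y.std() == 0:
                        continue
                    r2 = np.corrcoef(x, y)[0, 1] ** 2
                    assert r2 < 0.5

    def test_presets_exposed(self):
        assert LD_PRUNE_PRESETS["50kb_r2_0.75"] == (50_000, 0.75)

    def test_bad_parameters_rejected(self, rng):
        gm = random_matrix(rng, 5, 10)
        with pytest.raises(ParameterError):
            sp.ld_prune(gm, window_bp=0)
        with pytest.raises(ParameterError):
            sp.ld_prune(gm, r2_threshold=0.0)
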