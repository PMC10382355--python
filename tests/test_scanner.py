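"""Core scan machinery: z-space, cluster size rule, KNN, scores, tests."""

import itertools

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from hrscan import (
    Cohort,
    HRSScanner,
    ScanConfig,
    TumorSample,
    auto_nhrs,
    build_space,
    cluster_fractions,
    cohens_d,
    knn_cluster,
    rank_sum_test,
    scan,
    stratification_score,
    wilcoxon_groups,
)
from hrscan.scanner import denormalize
from hrscan.synthetic import SimulationConfig, simulate_parameter_cohort


def _tumor(tid, values, cls="H", dim="ADC"):
    values = np.asarray(values, dtype=float)
    n = len(values)
    coords = np.column_stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)])
    return TumorSample(
        id=tid, cell_line="X", params={dim: values}, coords=coords,
        class_label=cls,
    )


class TestBuildSpace:
    def test_pooled_moments(self, small_cohort):
        Z, _, _ = build_space(small_cohort)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-12)

    def test_two_voxel_example(self):
        c = Cohort("t", [_tumor("a", [0.0, 2.0])], ["ADC"])
        Z, _, norm = build_space(c)
        np.testing.assert_allclose(Z[:, 0], [-1.0, 1.0])
        assert norm["ADC"] == (1.0, 1.0)

    def test_denormalize_round_trip(self, small_cohort):
        Z, _, norm = build_space(small_cohort)
        X, _ = small_cohort.pooled()
        back = np.column_stack(
            [
                denormalize(Z, norm, small_cohort.dims)[:, i]
                for i in range(len(small_cohort.dims))
            ]
        )
        np.testing.assert_allclose(back, X, atol=1e-10 * np.abs(X).max())

    def test_zero_variance_rejected(self):
        c = Cohort("t", [_tumor("a", [5.0, 5.0, 5.0])], ["ADC"])
        with pytest.raises(ValueError, match="zero variance"):
            build_space(c)


class TestAutoNhrs:
    def test_single_resistant_tumor(self):
        c = Cohort("t", [_tumor("a", np.arange(1000.0), cls="L")], ["ADC"])
        assert auto_nhrs(c) == 150

    def test_mixed_cohort_sums_class_budgets(self):
        c = Cohort(
            "t",
            [
                _tumor("l", np.arange(1000.0), cls="L"),
                _tumor("m", np.arange(2000.0), cls="M"),
                _tumor("h", np.arange(500.0), cls="H"),
            ],
            ["ADC"],
        )
        assert auto_nhrs(c) == 150 + 150 + 0

    def test_all_sensitive_cohort_rejected(self):
        c = Cohort("t", [_tumor("a", np.arange(400.0), cls="H")], ["ADC"])
        with pytest.raises(ValueError, match="N_HRS"):
            auto_nhrs(c)


class TestKnnCluster:
    def test_saturation_includes_all(self):
        Z = np.random.default_rng(0).normal(size=(40, 2))
        members = knn_cluster(Z, 5, 40)
        np.testing.assert_array_equal(members, np.arange(40))

    def test_line_end_takes_leftmost(self):
        Z = np.arange(10.0)[:, None]
        np.testing.assert_array_equal(knn_cluster(Z, 0, 3), [0, 1, 2])

    def test_tie_resolves_to_lower_index(self):
        Z = np.array([[0.0], [1.0], [1.0], [1.0]])
        np.testing.assert_array_equal(knn_cluster(Z, 0, 2), [0, 1])

    def test_oversized_cluster_rejected(self):
        with pytest.raises(ValueError):
            knn_cluster(np.zeros((3, 1)), 0, 4)

    @pytest.mark.parametrize("use_tree", [False, True])
    def test_matches_brute_force_sort(self, use_tree, rng):
        for _ in range(30):
            n = int(rng.integers(20, 300))
            d = int(rng.integers(1, 5))
            Z = rng.normal(size=(n, d))
            k = int(rng.integers(2, n))
            c = int(rng.integers(n))
            dist = np.linalg.norm(Z - Z[c], axis=1)
            oracle = np.sort(np.lexsort((np.arange(n), dist))[:k])
            tree = cKDTree(Z) if use_tree else None
            got = knn_cluster(Z, c, k, tree=tree)
            np.testing.assert_array_equal(got, oracle)


class TestClusterFractions:
    def test_conservation_and_examples(self, rng):
        sizes = np.array([50, 80, 30])
        tumor_index = np.repeat(np.arange(3), sizes)
        members = rng.choice(160, size=40, replace=False)
        f = cluster_fractions(members, tumor_index, sizes)
        assert np.sum(f * sizes) == pytest.approx(40)
        only_a = np.arange(20)
        f = cluster_fractions(only_a, tumor_index, sizes)
        assert f[0] == pytest.approx(20 / 50)
        assert f[1] == f[2] == 0.0


class TestCohensD:
    def test_hand_arithmetic(self):
        rep = cohens_d([1, 2, 3], [3, 4, 5])
        assert rep.mu_i == 2 and rep.mu_j == 4
        assert rep.sigma_ij == pytest.approx(1.0)
        assert rep.s_ij == pytest.approx(2.0)

    def test_identical_groups_zero(self):
        assert cohens_d([1, 2], [1, 2]).s_ij == 0.0

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=5)
        assert cohens_d(a, b).s_ij == pytest.approx(-cohens_d(b, a).s_ij)

    def test_degenerate_pooled_sd(self):
        rep = cohens_d([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(rep.s_ij) and rep.s_ij > 0 and rep.flagged
        rep = cohens_d([1.0, 1.0], [1.0, 1.0])
        assert rep.s_ij == 0.0 and not rep.flagged

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            cohens_d([1.0], [1.0, 2.0])


class TestStratificationScore:
    def test_arithmetic_mean_of_pairwise_d(self, rng):
        vals = rng.normal(size=9)
        labels = ["H"] * 3 + ["M"] * 3 + ["L"] * 3
        s, hm, ml = stratification_score(vals, labels)
        assert s == pytest.approx(
            0.5 * (cohens_d(vals[:3], vals[3:6]).s_ij + cohens_d(vals[3:6], vals[6:]).s_ij)
        )

    def test_identical_distribution_scores_zero(self):
        vals = [0.1, 0.2, 0.1, 0.2, 0.1, 0.2]
        labels = ["H", "H", "M", "M", "L", "L"]
        s, _, _ = stratification_score(vals, labels)
        assert s == pytest.approx(0.0)

    def test_component_scores_average(self):
        # groups engineered for S_HM = 2 and S_ML = 4
        vals = [1, 2, 3, 3, 4, 5, 7, 8, 9]
        labels = ["H"] * 3 + ["M"] * 3 + ["L"] * 3
        s, hm, ml = stratification_score(vals, labels)
        assert hm.s_ij == pytest.approx(2.0)
        assert ml.s_ij == pytest.approx(4.0)
        assert s == pytest.approx(3.0)


def exact_ranksum_oracle(x, y):
    """Independent exact two-sided rank-sum p by full enumeration."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks under ties
    n, k = len(pooled), len(x)
    expect = k * (n + 1) / 2.0
    obs = abs(ranks[:k].sum() - expect)
    count = 0
    total = 0
    for comb in itertools.combinations(range(n), k):
        total += 1
        if abs(ranks[list(comb)].sum() - expect) >= obs - 1e-9:
            count += 1
    return count / total


class TestRankSum:
    def test_identical_groups_p_one(self):
        assert rank_sum_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_separated_groups_exact(self):
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(15):
            nx_, ny = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            x = rng.integers(0, 6, size=nx_).astype(float)  # ties likely
            y = rng.integers(0, 6, size=ny).astype(float)
            assert rank_sum_test(x, y) == pytest.approx(
                exact_ranksum_oracle(x, y), abs=1e-9
            )

    def test_wilcoxon_groups_reports_conservative_max(self, rng):
        vals = rng.normal(size=10)
        labels = ["H"] * 4 + ["M"] * 3 + ["L"] * 3
        out = wilcoxon_groups(vals, labels)
        assert out["p"] == max(out["p_HM"], out["p_ML"])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestScan:
    def test_single_iteration_equals_manual_composition(self, small_cohort):
        cfg = ScanConfig(dims=["ADC", "FMISO_c1"], n_it=1, seed=42)
        model = scan(small_cohort, cfg)
        Z, tumor_index, norm = build_space(small_cohort, cfg.dims)
        rng = np.random.default_rng(42)
        center = int(rng.choice(Z.shape[0], size=1, replace=False)[0])
        n_hrs = auto_nhrs(small_cohort)
        members = knn_cluster(Z, center, n_hrs)
        f = cluster_fractions(members, tumor_index, small_cohort.tumor_sizes())
        s, _, _ = stratification_score(f, small_cohort.class_labels())
        assert model.best.center_index == center
        np.testing.assert_array_equal(model.best.members, members)
        assert model.score == pytest.approx(s, abs=0)

    def test_same_seed_is_bit_identical(self, small_cohort):
        cfg = ScanConfig(dims=["ADC", "FMISO_c1", "FMISO_c2"], n_it=40, seed=9)
        a, b = scan(small_cohort, cfg), scan(small_cohort, cfg)
        assert a.score == b.score and a.p_value == b.p_value
        np.testing.assert_array_equal(a.best.members, b.best.members)
        np.testing.assert_array_equal(a.center_raw, b.center_raw)
        np.testing.assert_array_equal(a.landscape, b.landscape)

    def test_center_within_interval_and_conservation(self, small_cohort):
        cfg = ScanConfig(dims=["ADC"], n_it=25, seed=5)
        model = scan(small_cohort, cfg)
        assert model.interval_raw[0, 0] <= model.center_raw[0] <= model.interval_raw[0, 1]
        sizes = small_cohort.tumor_sizes()
        assert np.sum(model.best.f_cluster * sizes) == pytest.approx(model.n_hrs)

    def test_estimator_api(self, small_cohort):
        est = HRSScanner(dims=["ADC"], n_it=10, seed=1)
        assert est.get_params()["n_it"] == 10
        est.fit(small_cohort)
        assert hasattr(est, "score_") and est.model_.dims == ["ADC"]
        f = est.transform(small_cohort)
        assert f.shape == (len(small_cohort.tumors),)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ScanConfig(dims=[], n_it=10)
        with pytest.raises(ValueError):
            ScanConfig(dims=["ADC"], n_it=0)
        with pytest.raises(ValueError):
            ScanConfig(dims=["ADC"], n_hrs=1)

    def test_with_replacement_protocol_runs(self, small_cohort):
        cfg = ScanConfig(dims=["ADC"], n_it=30, seed=3, with_replacement=True)
        model = scan(small_cohort, cfg)
        assert model.landscape.shape == (30, 2)


class TestNullCalibration:
    def test_null_scan_significance_matches_permutation_reference(self):
        """On exchangeable no-niche cohorts the scan's significant-p rate
        should match a label-permutation reference within binomial error."""
        cfg = SimulationConfig(
            n_tumors={"H": 4, "M": 3, "L": 3},
            voxels_range=(80, 160),
            niche_fractions={"H": 0.0, "M": 0.0, "L": 0.0},
        )
        n_rep = 24
        rng = np.random.default_rng(7)
        hits_scan, hits_perm = 0, 0
        for r in range(n_rep):
            cohort = simulate_parameter_cohort(cfg, seed=1000 + r)
            # the cluster-size prior depends on class labels, not on what
            # is actually planted, so the no-niche cohort scans normally
            sc = ScanConfig(dims=["ADC", "FMISO_c1"], n_it=40, seed=r)
            m = scan(cohort, sc)
            hits_scan += m.p_value < 0.05
            perm = rng.permutation([t.class_label for t in cohort.tumors])
            for t, lb in zip(cohort.tumors, perm):
                t.class_label = lb
            m2 = scan(cohort, sc)
            hits_perm += m2.p_value < 0.05
        # same distribution up to binomial noise
        assert abs(hits_scan - hits_perm) / n_rep <= 0.25
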