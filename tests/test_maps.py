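"""Parameter-map extraction: ADC fits, SUV/TMR, enhancement, uncentered PCA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hrscan.maps import (
    DiffusionSeries,
    DynamicSeries,
    UncenteredPCA,
    fit_adc,
    relative_enhancement,
    tmr_map,
    to_suv,
    uncentered_pca,
)

B = np.arange(0.0, 801.0, 100.0)


def _dyn(values, n_frames=None):
    values = np.atleast_2d(values)
    n = values.shape[1] if n_frames is None else n_frames
    t = np.arange(n) * 10.0 + 5.0
    return DynamicSeries(t, np.full(n, 10.0), values)


def adc_grid_oracle(b, y, lo=0.0, hi=4000.0, coarse=0.5):
    """Dense grid search over ADC with the profiled (closed-form) S0."""

    def sse(adc_grid):
        e = np.exp(-np.outer(adc_grid * 1e-6, b))  # (g, nb)
        s0 = (e * y).sum(axis=1) / (e * e).sum(axis=1)
        r = s0[:, None] * e - y
        return (r * r).sum(axis=1)

    grid = np.arange(lo, hi + coarse, coarse)
    best = grid[np.argmin(sse(grid))]
    fine = np.linspace(best - coarse, best + coarse, 2001)
    return fine[np.argmin(sse(fine))]


class TestFitAdc:
    def test_exact_exponential(self):
        y = 100.0 * np.exp(-0.001 * B)
        m = fit_adc(DiffusionSeries(B, y))
        assert m.values[0] == pytest.approx(1000.0, abs=1e-6)
        assert not m.flags[0]

    def test_constant_signal_gives_zero(self):
        m = fit_adc(DiffusionSeries(B, np.full(len(B), 100.0)))
        assert m.values[0] == pytest.approx(0.0, abs=1e-8)

    def test_all_zero_voxel_flagged_nan(self):
        m = fit_adc(DiffusionSeries(B, np.zeros(len(B))))
        assert np.isnan(m.values[0]) and m.flags[0]

    def test_needs_three_bvalues(self):
        with pytest.raises(ValueError):
            fit_adc(DiffusionSeries([0.0, 400.0], [[100.0, 50.0]]))

    def test_noisy_fit_matches_grid_search_oracle(self, rng):
        truth = rng.uniform(300, 2500, size=12)
        y = 100.0 * np.exp(-np.outer(truth * 1e-6, B))
        y = y + rng.normal(0, 1.0, size=y.shape)
        y = np.maximum(y, 1e-3)
        m = fit_adc(DiffusionSeries(B, y))
        for i in range(len(truth)):
            oracle = adc_grid_oracle(B, y[i : i + 1])
            assert m.values[i] == pytest.approx(oracle, abs=1.0)

    @settings(deadline=None, max_examples=20)
    @given(
        adc=st.floats(10, 3000),
        scale=st.floats(0.01, 100.0),
    )
    def test_scale_invariance_in_s0(self, adc, scale):
        y = 50.0 * np.exp(-adc * 1e-6 * B)
        a = fit_adc(DiffusionSeries(B, y)).values[0]
        b = fit_adc(DiffusionSeries(B, scale * y)).values[0]
        assert b == pytest.approx(a, rel=1e-6, abs=1e-6)


class TestSuvTmr:
    def test_suv_formula(self):
        s = _dyn(np.full((1, 3), 10_000.0))
        out = to_suv(s, body_weight_g=25.0, injected_activity_Bq=1e7)
        assert out.values[0, 0] == pytest.approx(0.025)

    def test_suv_zero_and_linearity(self):
        s = _dyn([[0.0, 5000.0, 10_000.0]])
        a = to_suv(s, 25.0, 1e7).values
        b = to_suv(s, 50.0, 1e7).values
        assert a[0, 0] == 0.0
        np.testing.assert_allclose(b, 2 * a)

    def test_suv_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            to_suv(_dyn([[1.0, 2.0]]), 0.0, 1e7)

    def test_tmr_second_last_frame(self):
        tumor = _dyn([[1.0, 3.0, 99.0]])
        muscle = _dyn([[1.0, 2.0, 99.0]])
        m = tmr_map(tumor, muscle)
        assert m.values[0] == pytest.approx(1.5)

    def test_tmr_unity_when_equal_to_muscle(self):
        tumor = _dyn([[5.0, 2.0, 0.0]])
        muscle = _dyn([[9.0, 2.0, 1.0]])
        assert tmr_map(tumor, muscle).values[0] == pytest.approx(1.0)

    def test_tmr_invariant_to_global_rescale(self, rng):
        vals = rng.uniform(1, 5, size=(4, 6))
        muscle = rng.uniform(1, 3, size=(3, 6))
        a = tmr_map(_dyn(vals), _dyn(muscle)).values
        b = tmr_map(_dyn(7.3 * vals), _dyn(7.3 * muscle)).values
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_tmr_single_frame_rejected(self):
        t = DynamicSeries([5.0], [10.0], [[1.0]])
        with pytest.raises(ValueError):
            tmr_map(t, t)

    def test_tmr_nonpositive_muscle_rejected(self):
        with pytest.raises(ValueError):
            tmr_map(_dyn([[1.0, 1.0]]), _dyn([[0.0, 0.0]]))


class TestRelativeEnhancement:
    def test_constant_signal_zero_delta(self):
        s = _dyn(np.full((2, 20), 100.0))
        e = relative_enhancement(s, n_baseline=11)
        np.testing.assert_allclose(e.delta, 0.0)

    def test_formula(self):
        vals = np.concatenate([np.full(11, 100.0), [150.0]])
        e = relative_enhancement(_dyn([vals]), n_baseline=11)
        assert e.delta[0, -1] == pytest.approx(0.5)

    def test_full_protocol_shape(self):
        vals = np.full((3, 150), 100.0)
        e = relative_enhancement(_dyn(vals), n_baseline=11)
        assert e.delta.shape == (3, 150)

    def test_nonpositive_baseline_flagged(self):
        vals = np.zeros((1, 20))
        e = relative_enhancement(_dyn(vals), n_baseline=11)
        assert np.all(np.isnan(e.delta[0]))

    def test_requires_frames_beyond_baseline(self):
        with pytest.raises(ValueError):
            relative_enhancement(_dyn(np.ones((1, 11))), n_baseline=11)


class TestUncenteredPCA:
    def test_rank_one_matrix_fully_explained(self, rng):
        curve = rng.uniform(1, 2, size=30)
        X = np.outer(rng.uniform(0.5, 3, size=40), curve)
        basis, proj = uncentered_pca(X, k=1)
        assert basis.explained_variance_fraction[0] == pytest.approx(1.0)
        recon = proj @ basis.components
        np.testing.assert_allclose(recon, X, atol=1e-10)

    def test_matches_svd_oracle(self, rng):
        X = rng.normal(size=(200, 65))
        est = UncenteredPCA(n_components=2).fit(X)
        u, s, vt = np.linalg.svd(X, full_matrices=False)
        expected = vt[:2].copy()
        for j in range(2):
            if (X @ expected[j]).mean() < 0:
                expected[j] *= -1
        np.testing.assert_allclose(est.components_, expected, atol=1e-8)
        np.testing.assert_allclose(
            est.transform(X), X @ expected.T, atol=1e-8
        )
        np.testing.assert_allclose(
            est.explained_variance_ratio_, s[:2] ** 2 / (s**2).sum(), atol=1e-12
        )

    def test_augmented_matrix_matches_svd_oracle(self, rng):
        # appending a duplicated voxel: components still match the SVD
        # oracle of the augmented matrix
        X = rng.uniform(0.5, 2.0, size=(80, 20))
        Xa = np.vstack([X, X[:1]])
        a = UncenteredPCA(2).fit(Xa).components_
        _, _, vt = np.linalg.svd(Xa, full_matrices=False)
        b = vt[:2].copy()
        for j in range(2):
            if (Xa @ b[j]).mean() < 0:
                b[j] *= -1
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_rank_k_reconstruction_is_optimal(self, rng):
        X = rng.normal(size=(30, 10))
        est = UncenteredPCA(3).fit(X)
        recon = est.inverse_transform(est.transform(X))
        err = np.linalg.norm(X - recon)
        _, s, _ = np.linalg.svd(X)
        assert err == pytest.approx(np.sqrt((s[3:] ** 2).sum()), rel=1e-10)

    def test_k_exceeding_rank_rejected(self):
        X = np.outer(np.arange(1, 5.0), np.arange(1, 7.0))
        with pytest.raises(ValueError, match="rank"):
            UncenteredPCA(2).fit(X)

    def test_flagged_voxels_dropped(self, rng):
        X = rng.normal(size=(50, 12))
        X[3, 0] = np.nan
        basis, proj = uncentered_pca(X, k=2)
        assert np.all(np.isnan(proj[3]))
        assert np.all(np.isfinite(proj[[i for i in range(50) if i != 3]]))

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = UncenteredPCA(n_components=3)
        assert clone(est).get_params() == {"n_components": 3}
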