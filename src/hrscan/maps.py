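"""Quantitative parameter maps from raw imaging signals.

Converts the three raw modalities into the five per-voxel quantitative
parameters used for high-risk-subvolume (HRS) scanning:

* diffusion-weighted MRI -> apparent diffusion coefficient (ADC) via a
  mono-exponential fit over all b-values,
* dynamic FMISO PET -> standardized uptake value (SUV) curves, summarised
  by the projection coefficients of the first two uncentered principal
  components (FMISO_c1, FMISO_c2), plus tumor-to-muscle ratio (TMR) maps,
* dynamic contrast-enhanced MRI -> relative signal enhancement curves,
  summarised analogously (DCE_c1, DCE_c2).

PCA is uncentered (singular vectors of the raw voxel-by-time matrix):
uptake and enhancement curves are non-negative and their overall level is
informative, so the mean is not removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .types import Cohort, TumorSample

logger = logging.getLogger(__name__)

#: Units per parameter-map name. ADC is carried in 1e-6 mm^2/s throughout.
MAP_UNITS = {
    "ADC": "1e-6 mm^2/s",
    "SUV": "dimensionless",
    "TMR": "dimensionless",
    "FMISO_c1": "dimensionless",
    "FMISO_c2": "dimensionless",
    "DCE_c1": "dimensionless",
    "DCE_c2": "dimensionless",
}


@dataclass
class DiffusionSeries:
    """Diffusion-weighted signals at multiple b-values (s/mm^2)."""

    b_values: np.ndarray
    signals: np.ndarray  # (n_voxels, n_b)

    def __post_init__(self) -> None:
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.b_values.ndim != 1 or len(self.b_values) < 2:
            raise ValueError("need at least two b-values")
        if np.any(np.diff(self.b_values) <= 0):
            raise ValueError("b-values must be strictly increasing")
        if self.b_values[0] != 0:
            raise ValueError("first b-value must be 0")
        if self.signals.shape[1] != len(self.b_values):
            raise ValueError("signals and b_values have mismatched length")
        if np.any(self.signals < 0):
            raise ValueError("diffusion signals must be non-negative")


@dataclass
class DynamicSeries:
    """Framed dynamic data (PET activity/SUV or DCE-MRI signal)."""

    frame_mid_times: np.ndarray  # seconds
    frame_durations: np.ndarray  # seconds
    values: np.ndarray  # (n_voxels, n_frames)
    units: str = "arbitrary"

    def __post_init__(self) -> None:
        self.frame_mid_times = np.asarray(self.frame_mid_times, dtype=float)
        self.frame_durations = np.asarray(self.frame_durations, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(np.diff(self.frame_mid_times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if np.any(self.frame_durations <= 0):
            raise ValueError("frame durations must be positive")
        if self.values.shape[1] != len(self.frame_mid_times):
            raise ValueError("values and frame times have mismatched length")

    @property
    def n_frames(self) -> int:
        return len(self.frame_mid_times)


@dataclass
class EnhancementSeries:
    """Relative signal increase of a DCE series: (S_t - S0) / S0."""

    baseline: np.ndarray  # per-voxel S0
    delta: np.ndarray  # (n_voxels, n_frames)
    frame_mid_times: np.ndarray


@dataclass
class PCABasis:
    """Orthonormal temporal components of an uncentered PCA."""

    components: np.ndarray  # (k, n_frames)
    explained_variance_fraction: np.ndarray  # (k,)
    sign_convention: str = "mean_projection_nonnegative"


@dataclass
class ParameterMap:
    """One quantitative value per voxel, with per-voxel fit-quality flags."""

    name: str
    values: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.flags is None:
            self.flags = np.zeros(self.values.shape, dtype=bool)
        if not self.units:
            self.units = MAP_UNITS.get(self.name, "dimensionless")


# ---------------------------------------------------------------------------
# ADC

def _gauss_newton_monoexp(b, y, s0, k, n_iter=60, tol=1e-14):
    """Damped Gauss-Newton refinement of S(b) = s0*exp(-b*k), vectorized
    over voxels. k is the decay constant in 1/(s/mm^2)."""
    def sse(s0, k):
        r = s0[:, None] * np.exp(-np.outer(k, b)) - y
        return np.einsum("ij,ij->i", r, r)

    cur = sse(s0, k)
    for _ in range(n_iter):
        e = np.exp(-np.outer(k, b))  # (n, nb)
        model = s0[:, None] * e
        r = model - y
        j1 = e  # d/ds0
        j2 = -model * b[None, :]  # d/dk
        a11 = np.einsum("ij,ij->i", j1, j1)
        a12 = np.einsum("ij,ij->i", j1, j2)
        a22 = np.einsum("ij,ij->i", j2, j2)
        g1 = np.einsum("ij,ij->i", j1, r)
        g2 = np.einsum("ij,ij->i", j2, r)
        det = a11 * a22 - a12 * a12
        det = np.where(det <= 0, np.nan, det)
        d_s0 = -(a22 * g1 - a12 * g2) / det
        d_k = -(a11 * g2 - a12 * g1) / det
        d_s0 = np.nan_to_num(d_s0)
        d_k = np.nan_to_num(d_k)
        # backtracking line search, halving until SSE does not increase
        step = np.ones_like(s0)
        for _ in range(30):
            new = sse(s0 + step * d_s0, k + step * d_k)
            worse = new > cur
            if not np.any(worse):
                break
            step[worse] *= 0.5
        s0 = s0 + step * d_s0
        k = k + step * d_k
        new = sse(s0, k)
        if np.all(np.abs(cur - new) <= tol * (1.0 + cur)):
            cur = new
            break
        cur = new
    return s0, k


def fit_adc(series: DiffusionSeries) -> ParameterMap:
    """Per-voxel ADC from a mono-exponential fit over all b-values.

    Fits ``S(b) = S0 * exp(-b * ADC * 1e-6)`` by nonlinear least squares
    with a log-linear initialization.  ADC is returned in 1e-6 mm^2/s.
    Voxels with non-positive b=0 signal are flagged NaN; negative fitted
    ADC is clamped to 0 and flagged.
    """
    b = series.b_values
    y = series.signals
    if len(b) < 3:
        raise ValueError("ADC fit requires at least three b-values")
    n = y.shape[0]
    values = np.full(n, np.nan)
    flags = np.ones(n, dtype=bool)

    ok = y[:, 0] > 0
    if np.any(ok):
        yy = y[ok]
        # log-linear init on positive samples only
        with np.errstate(divide="ignore"):
            logy = np.where(yy > 0, np.log(np.maximum(yy, 1e-300)), np.nan)
        k0 = np.empty(ok.sum())
        s00 = np.empty(ok.sum())
        pos = yy > 0
        for i in range(yy.shape[0]):
            m = pos[i]
            if m.sum() >= 2:
                slope, intercept = np.polyfit(b[m], logy[i, m], 1)
            else:
                slope, intercept = 0.0, np.log(yy[i, 0])
            k0[i] = -slope
            s00[i] = np.exp(intercept)
        s0, k = _gauss_newton_monoexp(b, yy, s00, k0)
        adc = k * 1e6
        neg = adc < 0
        adc = np.where(neg, 0.0, adc)
        values[ok] = adc
        fl = np.zeros(n, dtype=bool)
        fl[np.flatnonzero(ok)[neg]] = True
        fl[~ok] = True
        flags = fl
    n_flagged = int(flags.sum())
    if n_flagged:
        logger.warning("fit_adc: %d of %d voxels flagged", n_flagged, n)
    return ParameterMap("ADC", values, flags)


# ---------------------------------------------------------------------------
# PET static maps

def to_suv(
    series: DynamicSeries, body_weight_g: float, injected_activity_Bq: float
) -> DynamicSeries:
    """Convert activity concentration (Bq/ml) to standardized uptake value.

    SUV = concentration * body_weight / injected_activity, assuming a
    tissue density of 1 g/ml.
    """
    if body_weight_g <= 0 or injected_activity_Bq <= 0:
        raise ValueError("body weight and injected activity must be positive")
    return DynamicSeries(
        series.frame_mid_times,
        series.frame_durations,
        series.values * (body_weight_g / injected_activity_Bq),
        units="SUV",
    )


def tmr_map(series: DynamicSeries, muscle_series: DynamicSeries) -> ParameterMap:
    """Tumor-to-muscle ratio at the second-last PET frame.

    The late frame (~80 min post injection) is used to avoid artifacts
    from the subsequent MR contrast-agent injection; each tumor voxel is
    divided by the mean muscle uptake in that frame.
    """
    if series.n_frames < 2 or muscle_series.n_frames < 2:
        raise ValueError("TMR requires at least two frames")
    muscle_mean = float(np.mean(muscle_series.values[:, -2]))
    if muscle_mean <= 0:
        raise ValueError("mean muscle uptake in the second-last frame is <= 0")
    return ParameterMap("TMR", series.values[:, -2] / muscle_mean)


# ---------------------------------------------------------------------------
# DCE enhancement

def relative_enhancement(
    series: DynamicSeries, n_baseline: int = 11
) -> EnhancementSeries:
    """Relative signal increase ΔS = (S_t - S0)/S0.

    S0 is the per-voxel mean over the first ``n_baseline`` frames (those
    acquired before contrast-agent injection).  Voxels with S0 <= 0 are
    flagged NaN across all frames.
    """
    if series.n_frames <= n_baseline:
        raise ValueError("series must have more frames than the baseline")
    s0 = series.values[:, :n_baseline].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = (series.values - s0[:, None]) / s0[:, None]
    bad = s0 <= 0
    delta[bad] = np.nan
    if np.any(bad):
        logger.warning(
            "relative_enhancement: %d voxels with non-positive baseline",
            int(bad.sum()),
        )
    return EnhancementSeries(s0, delta, series.frame_mid_times)


# ---------------------------------------------------------------------------
# Uncentered PCA

class UncenteredPCA(TransformerMixin, BaseEstimator):
    """Principal component analysis without mean centering.

    Components are the leading right singular vectors of the raw
    voxel-by-time matrix; the explained-variance fractions are the
    squared singular values normalised by their total (uncentered second
    moment).  The sign of each component is fixed so that its mean
    projection over the fitted data is non-negative.

    Compatible with scikit-learn pipelines (``fit`` / ``transform``).

    Attributes
    ----------
    components_ : ndarray of shape (n_components, n_frames)
    explained_variance_ratio_ : ndarray of shape (n_components,)
    singular_values_ : ndarray of shape (n_components,)
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_voxels, n_frames)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite; drop flagged voxels first")
        if X.shape[0] < self.n_components:
            raise ValueError("fewer voxels than components")
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        tol = s[0] * max(X.shape) * np.finfo(float).eps if s.size else 0.0
        rank = int(np.sum(s > tol))
        if self.n_components > rank:
            raise ValueError(
                f"n_components={self.n_components} exceeds matrix rank {rank}"
            )
        comps = vt[: self.n_components].copy()
        proj = X @ comps.T
        flip = proj.mean(axis=0) < 0
        comps[flip] *= -1.0
        self.components_ = comps
        self.singular_values_ = s[: self.n_components].copy()
        total = float(np.sum(s**2))
        self.explained_variance_ratio_ = s[: self.n_components] ** 2 / total
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        return X @ self.components_.T

    def inverse_transform(self, proj):
        check_is_fitted(self)
        return np.asarray(proj, dtype=float) @ self.components_


def uncentered_pca(values: np.ndarray, k: int = 2):
    """Fit an uncentered PCA, tolerating flagged (non-finite) voxels.

    Returns ``(PCABasis, projections)`` where flagged voxel rows carry
    NaN projections and are excluded from basis estimation.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    finite = np.all(np.isfinite(values), axis=1)
    if finite.sum() < k:
        raise ValueError("not enough finite voxel curves for PCA")
    est = UncenteredPCA(n_components=k).fit(values[finite])
    proj = np.full((values.shape[0], k), np.nan)
    proj[finite] = est.transform(values[finite])
    basis = PCABasis(est.components_, est.explained_variance_ratio_)
    return basis, proj


# ---------------------------------------------------------------------------
# End-to-end extraction

@dataclass
class RawTumorSignals:
    """Raw co-registered signal bundle of one tumor (voxel-aligned)."""

    id: str
    cell_line: str
    coords: np.ndarray
    diffusion: DiffusionSeries
    pet_suv: DynamicSeries
    dce: DynamicSeries
    class_label: str | None = None
    volume_mm3: float = float("nan")


def extract_parameter_cohort(
    raw_tumors: list[RawTumorSignals],
    label: str = "C_all",
    n_baseline: int = 11,
) -> Cohort:
    """Run the full map-extraction pipeline on raw signal bundles.

    Fits ADC per tumor, pools SUV curves (and DCE enhancement curves)
    over all tumor voxels of the cohort for a common uncentered PCA
    basis, and assembles a five-parameter :class:`Cohort`.  Voxels with
    flagged fits in any parameter are excluded (with a logged count).
    """
    adc_maps = [fit_adc(t.diffusion) for t in raw_tumors]

    pet_pool = np.vstack([t.pet_suv.values for t in raw_tumors])
    _, pet_proj = uncentered_pca(pet_pool, k=2)

    dce_pool = np.vstack(
        [relative_enhancement(t.dce, n_baseline).delta for t in raw_tumors]
    )
    _, dce_proj = uncentered_pca(dce_pool, k=2)

    tumors = []
    offset = 0
    n_dropped = 0
    for t, adc in zip(raw_tumors, adc_maps):
        n = t.coords.shape[0]
        sl = slice(offset, offset + n)
        offset += n
        params = {
            "ADC": adc.values,
            "FMISO_c1": pet_proj[sl, 0],
            "FMISO_c2": pet_proj[sl, 1],
            "DCE_c1": dce_proj[sl, 0],
            "DCE_c2": dce_proj[sl, 1],
        }
        keep = np.all(
            np.isfinite(np.column_stack(list(params.values()))), axis=1
        )
        n_dropped += int((~keep).sum())
        tumors.append(
            TumorSample(
                id=t.id,
                cell_line=t.cell_line,
                params={k: v[keep] for k, v in params.items()},
                coords=t.coords[keep],
                class_label=t.class_label,
                volume_mm3=t.volume_mm3,
            )
        )
    if n_dropped:
        logger.warning(
            "extract_parameter_cohort: excluded %d flagged voxels", n_dropped
        )
    return Cohort(
        label=label,
        tumors=tumors,
        dims=["ADC", "FMISO_c1", "FMISO_c2", "DCE_c1", "DCE_c2"],
    )
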