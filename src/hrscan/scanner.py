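"""High-risk-subvolume (HRS) scanning in z-normalized parameter space.

The scanner searches an n-dimensional imaging parameter space (1-5 of
ADC, FMISO_c1, FMISO_c2, DCE_c1, DCE_c2) for a compact cluster of a
fixed number ``N_HRS`` of voxels whose per-tumor fractional size best
stratifies tumors by radiosensitivity class.  One scan iteration:

1. pick a tumor voxel as cluster center,
2. take its ``N_HRS`` nearest neighbours (Euclidean distance in
   z-space, the center included),
3. compute the fraction ``f_cluster`` of each tumor's voxels inside the
   cluster,
4. score the class separation of ``f_cluster`` by the mean of two
   Cohen's-d effect sizes, S = (S_HM + S_ML) / 2.

``N_HRS`` is tied to the hypothesis that resistant tumors carry larger
resistant niches: the HRS should occupy 15.0% / 7.5% / 0% of the voxels
of low / medium / high radiosensitivity tumors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .radiosens import hrs_fraction_of
from .types import Cohort

logger = logging.getLogger(__name__)

CLASS_ORDER = ("H", "M", "L")


# ---------------------------------------------------------------------------
# effect sizes and rank tests

@dataclass
class EffectSizeReport:
    """Cohen's d between two groups of per-tumor values."""

    mu_i: float
    mu_j: float
    sigma_i: float
    sigma_j: float
    n_i: int
    n_j: int
    sigma_ij: float
    s_ij: float
    flagged: bool = False


def cohens_d(values_i, values_j) -> EffectSizeReport:
    """Cohen's d = (mu_j - mu_i) / pooled SD.

    The pooled standard deviation uses (n-1)-weighted sample variances:
    sigma_ij = sqrt(((n_i-1) s_i^2 + (n_j-1) s_j^2) / (n_i + n_j - 2)).
    A zero pooled SD yields 0 for equal means and a flagged signed
    infinity otherwise.
    """
    vi = np.asarray(values_i, dtype=float)
    vj = np.asarray(values_j, dtype=float)
    n_i, n_j = len(vi), len(vj)
    if n_i < 2 or n_j < 2:
        raise ValueError("Cohen's d needs at least two observations per group")
    mu_i, mu_j = float(vi.mean()), float(vj.mean())
    s_i = float(vi.std(ddof=1))
    s_j = float(vj.std(ddof=1))
    pooled = math.sqrt(
        ((n_i - 1) * s_i**2 + (n_j - 1) * s_j**2) / (n_i + n_j - 2)
    )
    if pooled == 0.0:
        if mu_i == mu_j:
            return EffectSizeReport(mu_i, mu_j, s_i, s_j, n_i, n_j, 0.0, 0.0)
        d = math.copysign(math.inf, mu_j - mu_i)
        return EffectSizeReport(
            mu_i, mu_j, s_i, s_j, n_i, n_j, 0.0, d, flagged=True
        )
    return EffectSizeReport(
        mu_i, mu_j, s_i, s_j, n_i, n_j, pooled, (mu_j - mu_i) / pooled
    )


def _group(values, labels, cls):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    return values[labels == cls]


def stratification_score(values, labels):
    """Mean Cohen's-d stratification score S = (S_HM + S_ML) / 2.

    ``values`` are per-tumor statistics (HRS fractions or a classical
    feature), ``labels`` the radiosensitivity classes H/M/L.  Returns
    ``(S, report_HM, report_ML)``.
    """
    groups = {c: _group(values, labels, c) for c in CLASS_ORDER}
    for c, g in groups.items():
        if len(g) < 2:
            raise ValueError(f"class {c} has fewer than two tumors")
    rep_hm = cohens_d(groups["H"], groups["M"])
    rep_ml = cohens_d(groups["M"], groups["L"])
    return 0.5 * (rep_hm.s_ij + rep_ml.s_ij), rep_hm, rep_ml


def rank_sum_test(x, y, exact_max_n: int = 10) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Exact permutation enumeration when both groups have at most
    ``exact_max_n`` observations (correct under ties), normal
    approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group in rank-sum test")
    if len(x) == 1 and len(y) == 1:
        return 1.0
    if len(x) <= exact_max_n and len(y) <= exact_max_n:
        # two-sided by symmetric deviation of U from its null mean: under
        # ties the U null distribution can be asymmetric, where doubling a
        # tail and deviation counting disagree; deviation counting is used
        half = len(x) * len(y) / 2.0
        res = stats.permutation_test(
            (x, y),
            lambda a, b, axis: np.abs(
                stats.mannwhitneyu(a, b, axis=axis).statistic - half
            ),
            permutation_type="independent",
            n_resamples=np.inf,
            alternative="greater",
        )
        return float(res.pvalue)
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def wilcoxon_groups(values, labels) -> dict[str, float]:
    """Pairwise H-M and M-L rank-sum tests on per-tumor values.

    Returns both pairwise two-sided p-values and, as the conservative
    headline ``p``, their maximum.
    """
    groups = {c: _group(values, labels, c) for c in CLASS_ORDER}
    p_hm = rank_sum_test(groups["H"], groups["M"])
    p_ml = rank_sum_test(groups["M"], groups["L"])
    return {"p_HM": p_hm, "p_ML": p_ml, "p": max(p_hm, p_ml)}


# ---------------------------------------------------------------------------
# parameter space

def build_space(cohort: Cohort, dims=None):
    """Pool and z-normalize the cohort's tumor voxels.

    Normalizes each dimension to pooled mean 0 and population SD 1 over
    all cohort tumor voxels, retaining the (mean, sd) pairs for
    de-normalizing cluster centers.

    Returns ``(Z, tumor_index, normalization)`` where ``normalization``
    maps each dim to its (mean, sd).
    """
    dims = list(cohort.dims if dims is None else dims)
    X, tumor_index = cohort.pooled(dims)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite voxel values in parameter space")
    means = X.mean(axis=0)
    sds = X.std(axis=0)  # population SD
    if np.any(sds == 0):
        bad = [d for d, s in zip(dims, sds) if s == 0]
        raise ValueError(f"zero variance in dimension(s) {bad}")
    Z = (X - means) / sds
    normalization = {d: (float(m), float(s)) for d, m, s in zip(dims, means, sds)}
    return Z, tumor_index, normalization


def denormalize(z_point, normalization, dims) -> np.ndarray:
    means = np.array([normalization[d][0] for d in dims])
    sds = np.array([normalization[d][1] for d in dims])
    return np.asarray(z_point) * sds + means


def auto_nhrs(cohort: Cohort, fractions=None) -> int:
    """Cluster size from the class-fraction rule.

    N_HRS = round(sum over tumors of fraction(class) * n_voxels), the
    unique size making the expected per-class HRS fractions match the
    15.0% / 7.5% / 0% priors when the size hypothesis holds.
    """
    labels = cohort.class_labels()
    frac = fractions or {c: hrs_fraction_of(c) for c in CLASS_ORDER}
    total = sum(frac[lb] * t.n_voxels for lb, t in zip(labels, cohort.tumors))
    n = int(round(total))
    if n < 2:
        raise ValueError(
            f"class-fraction rule yields N_HRS={n}; no scannable cluster"
        )
    return n


def class_voxel_budgets(cohort: Cohort, fractions=None):
    """Per-class HRS voxel budgets implied by the class-fraction rule.

    Returns ``{class: (budget_voxels, class_voxels, realized_percent)}``
    with integer-rounded budgets.
    """
    labels = np.asarray(cohort.class_labels())
    sizes = cohort.tumor_sizes()
    frac = fractions or {c: hrs_fraction_of(c) for c in CLASS_ORDER}
    out = {}
    for c in CLASS_ORDER:
        n_class = int(sizes[labels == c].sum())
        budget = int(round(frac[c] * n_class))
        pct = 100.0 * budget / n_class if n_class else float("nan")
        out[c] = (budget, n_class, pct)
    return out


# ---------------------------------------------------------------------------
# KNN cluster

def knn_cluster(
    Z,
    center,
    n_hrs: int,
    tree: cKDTree | None = None,
    sq_norms: np.ndarray | None = None,
) -> np.ndarray:
    """Indices of the ``n_hrs`` voxels nearest to ``center`` in z-space.

    ``center`` is either a voxel index into ``Z`` (the center then counts
    as its own nearest neighbour) or a z-space point.  Exact Euclidean
    nearest neighbours; distance ties are broken by ascending global
    voxel index.  A k-d tree is used for large spaces with semantics
    identical to the brute-force sort.  ``sq_norms`` (precomputed
    per-row squared norms of ``Z``) speeds up repeated calls.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if n_hrs > n:
        raise ValueError(f"n_hrs={n_hrs} exceeds the {n} available voxels")
    point = (
        Z[int(center)]
        if np.ndim(center) == 0
        else np.asarray(center, dtype=float)
    )

    if tree is not None:
        dk, _ = tree.query(point, k=n_hrs)
        dmax = dk[-1] if n_hrs > 1 else float(dk)
        # re-collect every voxel at distance <= dmax so that ties at the
        # boundary resolve by index, identically to brute force
        cand = np.asarray(
            tree.query_ball_point(point, dmax * (1 + 1e-12) + 1e-300)
        )
        d2 = np.einsum("ij,ij->i", Z[cand] - point, Z[cand] - point)
        order = np.lexsort((cand, d2))
        return np.sort(cand[order[:n_hrs]])

    # squared distance up to the constant |point|^2 (order-preserving,
    # exact-tie-preserving)
    if sq_norms is None:
        sq_norms = np.einsum("ij,ij->i", Z, Z)
    d2 = sq_norms - Z @ (2.0 * point)
    if n_hrs < n:
        part = np.argpartition(d2, n_hrs - 1)[:n_hrs]
        thresh = d2[part].max()
        cand = np.flatnonzero(d2 <= thresh)
    else:
        cand = np.arange(n)
    order = np.lexsort((cand, d2[cand]))
    return np.sort(cand[order[:n_hrs]])


def cluster_fractions(members, tumor_index, tumor_sizes) -> np.ndarray:
    """Per-tumor fraction of voxels inside the cluster.

    f_cluster(t) = |members in tumor t| / n_voxels(t).
    """
    counts = np.bincount(tumor_index[members], minlength=len(tumor_sizes))
    return counts / np.asarray(tumor_sizes)


# ---------------------------------------------------------------------------
# scan

@dataclass
class ScanConfig:
    """Configuration of one parameter-space scan."""

    dims: list[str]
    n_it: int = 5000
    n_hrs: int | str = "auto"
    seed: int | None = None
    with_replacement: bool = False

    def __post_init__(self) -> None:
        if not 1 <= len(self.dims) <= 5:
            raise ValueError("dims must contain 1 to 5 parameter names")
        if self.n_it < 1:
            raise ValueError("n_it must be at least 1")
        if self.n_hrs != "auto" and int(self.n_hrs) < 2:
            raise ValueError("fixed n_hrs must be at least 2")


@dataclass
class ClusterCandidate:
    """One evaluated cluster: center, members, fractions, score."""

    center_index: int
    center_tumor_id: str
    center_z: np.ndarray
    members: np.ndarray
    f_cluster: np.ndarray
    score: float
    effect_hm: EffectSizeReport
    effect_ml: EffectSizeReport


@dataclass
class HRSModel:
    """Best cluster of a scan, with de-normalized center and provenance."""

    dims: list[str]
    best: ClusterCandidate
    center_raw: np.ndarray
    interval_raw: np.ndarray  # (n_dims, 2) per-dim min-max over members
    score: float
    p_value: float
    p_pairwise: dict[str, float]
    normalization: dict[str, tuple[float, float]]
    n_hrs: int
    n_it: int
    seed: int | None
    landscape: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        lo, hi = self.interval_raw[:, 0], self.interval_raw[:, 1]
        if np.any(self.center_raw < lo - 1e-9) or np.any(self.center_raw > hi + 1e-9):
            raise ValueError("center_raw outside member interval")


class HRSScanner(BaseEstimator):
    """Scan a parameter space for the best stratifying voxel cluster.

    scikit-learn-style estimator: ``fit`` runs the randomized scan on a
    :class:`~hrscan.types.Cohort`; ``transform`` evaluates the fitted
    (frozen-center, frozen-normalization) model on a new cohort,
    returning per-tumor HRS fractions.

    Parameters
    ----------
    dims : list of str
        Parameter-space axes (1-5 of ADC, FMISO_c1, FMISO_c2, DCE_c1,
        DCE_c2).
    n_it : int, default 5000
        Number of scan iterations (candidate centers).
    n_hrs : int or "auto", default "auto"
        Cluster size in voxels; "auto" applies the class-fraction rule.
    seed : int or None
        Seed of the center-sampling RNG; the scan is a pure function of
        (cohort, seed).
    with_replacement : bool, default False
        Sample candidate centers with replacement (the literal protocol)
        instead of without (avoids duplicate evaluations; capped at the
        total voxel count).
    keep_landscape : bool, default True
        Retain (center z-coordinates, S) for all iterations for score-
        landscape projections.

    Attributes
    ----------
    model_ : HRSModel
    best_ : ClusterCandidate
    score_ : float
    center_raw_ : ndarray
    normalization_ : dict
    """

    def __init__(
        self,
        dims=("ADC",),
        n_it: int = 5000,
        n_hrs="auto",
        seed: int | None = None,
        with_replacement: bool = False,
        keep_landscape: bool = True,
    ):
        self.dims = dims
        self.n_it = n_it
        self.n_hrs = n_hrs
        self.seed = seed
        self.with_replacement = with_replacement
        self.keep_landscape = keep_landscape

    def fit(self, cohort: Cohort, y=None):
        config = ScanConfig(
            dims=list(self.dims),
            n_it=self.n_it,
            n_hrs=self.n_hrs,
            seed=self.seed,
            with_replacement=self.with_replacement,
        )
        dims = config.dims
        Z, tumor_index, normalization = build_space(cohort, dims)
        sizes = cohort.tumor_sizes()
        labels = np.asarray(cohort.class_labels())
        n_hrs = (
            auto_nhrs(cohort) if config.n_hrs == "auto" else int(config.n_hrs)
        )
        if n_hrs > Z.shape[0]:
            raise ValueError("n_hrs exceeds total voxel count")

        rng = np.random.default_rng(config.seed)
        n = Z.shape[0]
        if config.with_replacement:
            centers = rng.choice(n, size=config.n_it, replace=True)
        else:
            centers = rng.choice(n, size=min(config.n_it, n), replace=False)

        sq_norms = np.einsum("ij,ij->i", Z, Z)
        best_score = -np.inf
        best: ClusterCandidate | None = None
        scores = np.empty(len(centers))
        for it, c in enumerate(centers):
            members = knn_cluster(Z, int(c), n_hrs, sq_norms=sq_norms)
            f = cluster_fractions(members, tumor_index, sizes)
            s, rep_hm, rep_ml = stratification_score(f, labels)
            scores[it] = s
            if np.isfinite(s) and s > best_score:
                best_score = s
                best = ClusterCandidate(
                    center_index=int(c),
                    center_tumor_id=cohort.tumors[tumor_index[c]].id,
                    center_z=Z[c].copy(),
                    members=members,
                    f_cluster=f,
                    score=s,
                    effect_hm=rep_hm,
                    effect_ml=rep_ml,
                )
        if best is None:
            raise ValueError("no finite stratification score in the scan")

        p = wilcoxon_groups(best.f_cluster, labels)
        center_raw = denormalize(best.center_z, normalization, dims)
        member_raw = denormalize(Z[best.members], normalization, dims)
        interval = np.column_stack(
            [member_raw.min(axis=0), member_raw.max(axis=0)]
        )
        landscape = None
        if self.keep_landscape:
            landscape = np.column_stack([Z[centers], scores])
        self.model_ = HRSModel(
            dims=dims,
            best=best,
            center_raw=center_raw,
            interval_raw=interval,
            score=best_score,
            p_value=p["p"],
            p_pairwise={"p_HM": p["p_HM"], "p_ML": p["p_ML"]},
            normalization=normalization,
            n_hrs=n_hrs,
            n_it=config.n_it,
            seed=config.seed,
            landscape=landscape,
        )
        self.best_ = best
        self.score_ = best_score
        self.p_value_ = p["p"]
        self.center_raw_ = center_raw
        self.normalization_ = normalization
        self.n_hrs_ = n_hrs
        return self

    def transform(self, cohort: Cohort) -> np.ndarray:
        """Per-tumor HRS fractions of a cohort under the fitted model.

        Uses the frozen normalization and cluster center; the cluster is
        re-identified as the evaluation cohort's nearest voxels to the
        frozen center, with the size rescaled by the class-fraction rule
        on the evaluation cohort.
        """
        from .robustness import evaluate_on_cohort

        return evaluate_on_cohort(self.model_, cohort).f_hrs


def scan(cohort: Cohort, config: ScanConfig) -> HRSModel:
    """Functional wrapper: run one scan and return the best-cluster model."""
    est = HRSScanner(
        dims=list(config.dims),
        n_it=config.n_it,
        n_hrs=config.n_hrs,
        seed=config.seed,
        with_replacement=config.with_replacement,
    )
    est.fit(cohort)
    return est.model_


def scan_all_subsets(cohort: Cohort, n_it=5000, seed=None, max_dim=5):
    """Scan every 1D..max_dim combination of the cohort's dims.

    Returns a list of HRSModel sorted by descending score within each
    dimensionality, mirroring per-dimensionality model ranking tables.
    """
    from itertools import combinations

    models = []
    for k in range(1, max_dim + 1):
        for dims in combinations(cohort.dims, k):
            cfg = ScanConfig(dims=list(dims), n_it=n_it, seed=seed)
            models.append(scan(cohort.select(dims, cohort.label), cfg))
    models.sort(key=lambda m: (len(m.dims), -m.score))
    return models
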