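"""Bootstrap robustness assessment and extended-cohort evaluation.

Bootstrap cohorts resample *animals* (tumors) with replacement — never
voxels, which would break within-tumor dependence — and rerun the full
pipeline (z-normalization, cluster-size rule, scan) per replicate, so
the percentile confidence intervals reflect all sources of model
variability.  Extended-cohort evaluation freezes the trained model
(normalization and cluster center) and only re-identifies the member
voxels within the new cohort.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .scanner import (
    HRSModel,
    ScanConfig,
    auto_nhrs,
    cluster_fractions,
    denormalize,
    knn_cluster,
    rank_sum_test,
    scan,
    stratification_score,
    wilcoxon_groups,
)
from .types import Cohort

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class BootstrapResult:
    """Per-replicate best scores/centers and their percentile CIs."""

    dims: list[str]
    n_bs: int
    s_values: np.ndarray  # (n_bs,)
    center_values: np.ndarray  # (n_bs, n_dims), de-normalized
    ci_s: np.ndarray  # (2,) [2.5th, 97.5th percentile]
    ci_center: np.ndarray  # (n_dims, 2)
    seed: int | None = None


@dataclasses.dataclass
class EvaluationResult:
    """A fitted model applied to an evaluation cohort."""

    f_hrs: np.ndarray  # per tumor
    score: float
    p_value: float
    p_pairwise: dict[str, float]
    n_hrs: int
    members: np.ndarray


def _percentile_ci(values: np.ndarray, axis=0) -> np.ndarray:
    # order statistics, no interpolation: CI bounds are elements of values
    return np.percentile(
        values, [2.5, 97.5], axis=axis, method="closest_observation"
    )


def _resample_cohort(cohort: Cohort, rng: np.random.Generator) -> Cohort | None:
    """One bootstrap replicate; None when a class has < 2 tumors."""
    n = len(cohort.tumors)
    idx = rng.integers(0, n, size=n)
    labels = [cohort.tumors[i].class_label for i in idx]
    for c in ("H", "M", "L"):
        if labels.count(c) < 2:
            return None
    tumors = [
        dataclasses.replace(cohort.tumors[i], id=f"{cohort.tumors[i].id}#bs{k}")
        for k, i in enumerate(idx)
    ]
    return Cohort(label=f"{cohort.label}|bs", tumors=tumors, dims=cohort.dims)


def bootstrap_scan(
    cohort: Cohort,
    config: ScanConfig,
    n_bs: int = 50,
    seed: int | None = None,
    max_redraws: int = 100,
) -> BootstrapResult:
    """Full-pipeline bootstrap of the scan.

    Each of ``n_bs`` replicates draws tumors with replacement to the
    original cohort size, recomputes z-normalization and the cluster
    size within the replicate, reruns the scan, and records the best
    score and de-normalized center.  Replicates missing a class are
    redrawn (logged); 95% CIs are percentile-based order statistics.
    """
    rng = np.random.default_rng(seed)
    s_values = np.empty(n_bs)
    centers = np.empty((n_bs, len(config.dims)))
    for r in range(n_bs):
        rep = None
        for attempt in range(max_redraws):
            rep = _resample_cohort(cohort, rng)
            if rep is not None:
                if attempt:
                    logger.info(
                        "bootstrap replicate %d: %d redraw(s)", r, attempt
                    )
                break
        if rep is None:
            raise RuntimeError(
                f"bootstrap replicate {r}: no valid class composition"
                f" after {max_redraws} redraws"
            )
        rep_cfg = dataclasses.replace(
            config, seed=int(rng.integers(2**31))
        )
        model = scan(rep, rep_cfg)
        s_values[r] = model.score
        centers[r] = model.center_raw
    ci_s = _percentile_ci(s_values)
    ci_center = _percentile_ci(centers, axis=0).T
    return BootstrapResult(
        dims=list(config.dims),
        n_bs=n_bs,
        s_values=s_values,
        center_values=centers,
        ci_s=ci_s,
        ci_center=ci_center,
        seed=seed,
    )


def evaluate_on_cohort(model: HRSModel, cohort: Cohort) -> EvaluationResult:
    """Apply a fitted model to a (possibly extended) cohort.

    The evaluation cohort's voxels are z-normalized with the model's
    frozen statistics; the cluster is the set of voxels nearest to the
    frozen de-normalized center, with its size rescaled by the
    class-fraction rule on the evaluation cohort.  Evaluating on the
    training cohort itself is a fixed point of the training result.
    """
    missing = [
        t.id for t in cohort.tumors if not t.has_dims(model.dims)
    ]
    if missing:
        raise ValueError(f"tumors missing model dims: {missing}")
    X, tumor_index = cohort.pooled(model.dims)
    means = np.array([model.normalization[d][0] for d in model.dims])
    sds = np.array([model.normalization[d][1] for d in model.dims])
    Z = (X - means) / sds
    center_z = (model.center_raw - means) / sds
    n_hrs = auto_nhrs(cohort)
    members = knn_cluster(Z, center_z, n_hrs)
    sizes = cohort.tumor_sizes()
    labels = np.asarray(cohort.class_labels())
    f = cluster_fractions(members, tumor_index, sizes)
    s, _, _ = stratification_score(f, labels)
    p = wilcoxon_groups(f, labels)
    return EvaluationResult(
        f_hrs=f,
        score=s,
        p_value=p["p"],
        p_pairwise={"p_HM": p["p_HM"], "p_ML": p["p_ML"]},
        n_hrs=n_hrs,
        members=members,
    )


def compare_models(bs_a: BootstrapResult, bs_b: BootstrapResult) -> float:
    """Two-sided Mann-Whitney U p-value between two bootstrap score samples."""
    if len(bs_a.s_values) < 2 or len(bs_b.s_values) < 2:
        raise ValueError("need at least two bootstrap scores per model")
    return rank_sum_test(bs_a.s_values, bs_b.s_values)
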