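"""Classical per-tumor imaging features and their stratification scores.

Baseline comparators for the HRS cluster models: whole-tumor summary
statistics of ADC, late-frame FMISO SUV and tumor-to-muscle ratio (TMR).
"Peak" and "valley" are noise-robust extremum surrogates: the mean over
a seven-voxel neighbourhood centred on the tumor's maximum or minimum
voxel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scanner import stratification_score, wilcoxon_groups

logger = logging.getLogger(__name__)

FEATURE_NAMES = [
    "adc_max",
    "adc_mean",
    "adc_min",
    "adc_valley",
    "suv_mean",
    "suv_max",
    "suv_peak",
    "tmr_max",
    "tmr_peak",
]

_FACE_OFFSETS = np.array(
    [
        [1, 0, 0],
        [-1, 0, 0],
        [0, 1, 0],
        [0, -1, 0],
        [0, 0, 1],
        [0, 0, -1],
    ]
)


@dataclass
class TumorVolumes:
    """Dense per-tumor map volumes on the common grid."""

    id: str
    mask: np.ndarray  # 3-D bool
    adc: np.ndarray
    suv: np.ndarray
    tmr: np.ndarray
    class_label: str | None = None


def extremum_neighborhood(
    values: np.ndarray, mask: np.ndarray, mode: str, size: int = 7
) -> float:
    """Mean over a 7-voxel region centred on the in-mask extremum.

    The region is the extremum voxel plus its six face-connected in-mask
    neighbours; at mask borders it is completed to ``size`` voxels with
    the nearest in-mask voxels by Euclidean grid distance (ties by
    row-major index).  Returns NaN (logged) when the mask holds fewer
    than ``size`` voxels.
    """
    if mode not in ("min", "max"):
        raise ValueError("mode must be 'min' or 'max'")
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)  # row-major
    if coords.shape[0] < size:
        logger.warning(
            "extremum_neighborhood: mask has %d < %d voxels", len(coords), size
        )
        return float("nan")
    vals = values[tuple(coords.T)]
    ext = coords[np.argmin(vals) if mode == "min" else np.argmax(vals)]

    shape = mask.shape
    chosen = [tuple(ext)]
    for off in _FACE_OFFSETS:
        nb = ext + off
        if np.all(nb >= 0) and np.all(nb < shape) and mask[tuple(nb)]:
            chosen.append(tuple(nb))
    chosen = chosen[:size]
    if len(chosen) < size:
        chosen_set = set(chosen)
        rest = [tuple(c) for c in coords if tuple(c) not in chosen_set]
        rest_arr = np.array(rest)
        d2 = np.sum((rest_arr - ext) ** 2, axis=1)
        lin = np.ravel_multi_index(rest_arr.T, shape)
        order = np.lexsort((lin, d2))
        for i in order[: size - len(chosen)]:
            chosen.append(rest[i])
    return float(np.mean([values[c] for c in chosen]))


def classical_features(vol: TumorVolumes) -> dict[str, float]:
    """The nine whole-tumor features of one tumor."""
    m = vol.mask.astype(bool)
    adc = vol.adc[m]
    suv = vol.suv[m]
    tmr = vol.tmr[m]
    return {
        "adc_max": float(adc.max()),
        "adc_mean": float(adc.mean()),
        "adc_min": float(adc.min()),
        "adc_valley": extremum_neighborhood(vol.adc, m, "min"),
        "suv_mean": float(suv.mean()),
        "suv_max": float(suv.max()),
        "suv_peak": extremum_neighborhood(vol.suv, m, "max"),
        "tmr_max": float(tmr.max()),
        "tmr_peak": extremum_neighborhood(vol.tmr, m, "max"),
    }


def classical_table(volumes: list[TumorVolumes]) -> pd.DataFrame:
    """Feature table, one row per tumor (index: tumor id)."""
    rows = {v.id: classical_features(v) for v in volumes}
    table = pd.DataFrame.from_dict(rows, orient="index")[FEATURE_NAMES]
    table.index.name = "id"
    if any(v.class_label for v in volumes):
        table["class_label"] = [v.class_label for v in volumes]
    return table


def classical_stratification(
    features: pd.DataFrame, labels=None
) -> pd.DataFrame:
    """Stratification score and rank-sum p-value per classical feature.

    Applies the same Cohen's-d score and Wilcoxon tests used for cluster
    fractions to each per-tumor feature value.  Features that decrease
    from sensitive (H) to resistant (L) tumors yield negative scores.
    """
    if labels is None:
        labels = features["class_label"].to_numpy()
    labels = np.asarray(labels)
    out = {}
    cols = [c for c in features.columns if c in FEATURE_NAMES]
    for col in cols:
        v = features[col].to_numpy(dtype=float)
        ok = np.isfinite(v)
        s, _, _ = stratification_score(v[ok], labels[ok])
        p = wilcoxon_groups(v[ok], labels[ok])
        out[col] = {
            "S": s,
            "p": p["p"],
            "p_HM": p["p_HM"],
            "p_ML": p["p_ML"],
        }
    return pd.DataFrame.from_dict(out, orient="index")
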