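"""File I/O: NIfTI parameter maps and masks, cohort CSV, JSON results.

All volumetric inputs are NIfTI-1 on a common grid (the PET grid;
registration and resampling are upstream).  Voxel extraction order is
row-major over grid indices — a pure function of the mask, reproducible
across runs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict
from importlib import metadata

import nibabel as nib
import numpy as np
import pandas as pd

from .radiosens import class_of_cell_line, group_by_tcd50, CELL_LINES
from .scanner import ClusterCandidate, EffectSizeReport, HRSModel
from .types import Cohort, ROIMask, TumorSample, PARAMETER_NAMES

logger = logging.getLogger(__name__)

#: columns required in the cohort table CSV
COHORT_COLUMNS = [
    "id",
    "cell_line",
    "body_weight_g",
    "injected_activity_MBq",
    "tcd50_mean_Gy",
    "tcd50_lo_Gy",
    "tcd50_hi_Gy",
    "timepoint",
]


def _load_volume(path):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def read_mask(path) -> ROIMask:
    data, zooms = _load_volume(path)
    return ROIMask(labels=np.rint(data).astype(int), voxel_size_mm=zooms)


def read_cohort_table(table_path) -> pd.DataFrame:
    table = pd.read_csv(table_path)
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    return table


def read_cohort(
    image_paths: dict,
    mask_paths: dict,
    table_path,
    dims=None,
    label: str = "C_all",
    classed_lines=None,
    timepoint: str | None = None,
) -> Cohort:
    """Assemble a cohort from per-animal NIfTI maps and a cohort table.

    Parameters
    ----------
    image_paths : dict
        ``{animal_id: {parameter_name: nifti_path}}`` of 3-D maps.
    mask_paths : dict
        ``{animal_id: nifti_path}`` of label masks (1 tumor, 2 muscle).
    table_path : path
        Cohort CSV with :data:`COHORT_COLUMNS`.
    dims : list of str, optional
        Required parameters (default: all five).  Animals missing a
        required map are excluded with a logged warning, mirroring the
        full-parameter vs per-model maximal cohort distinction.
    timepoint : str, optional
        Restrict to rows with this ``timepoint`` value (e.g.
        ``"baseline"`` or ``"week2"``), so the same pipeline runs as a
        second analysis on post-treatment imaging.

    Raises
    ------
    ValueError
        On a grid mismatch between a map and the mask, or an empty
        tumor mask — both name the offending animal.
    """
    dims = list(PARAMETER_NAMES) if dims is None else list(dims)
    table = read_cohort_table(table_path)
    if timepoint is not None:
        table = table[table["timepoint"] == timepoint]
    classed = classed_lines or group_by_tcd50(CELL_LINES)

    tumors = []
    for _, row in table.iterrows():
        animal = str(row["id"])
        if animal not in image_paths or animal not in mask_paths:
            logger.warning("animal %s: no image data, excluded", animal)
            continue
        maps = image_paths[animal]
        if any(d not in maps for d in dims):
            missing = [d for d in dims if d not in maps]
            logger.warning(
                "animal %s: missing map(s) %s, excluded", animal, missing
            )
            continue
        mask = read_mask(mask_paths[animal])
        coords = mask.tumor_coords()
        if coords.shape[0] == 0:
            raise ValueError(f"animal {animal}: tumor mask is empty")
        params = {}
        for d in dims:
            data, _ = _load_volume(maps[d])
            if data.shape != mask.shape:
                raise ValueError(
                    f"animal {animal}: map {d} grid {data.shape} does not"
                    f" match mask grid {mask.shape}"
                )
            params[d] = data[tuple(coords.T)]
        try:
            cls = class_of_cell_line(str(row["cell_line"]), classed)
        except KeyError:
            cls = None
        tumors.append(
            TumorSample(
                id=animal,
                cell_line=str(row["cell_line"]),
                params=params,
                coords=coords,
                class_label=cls,
                volume_mm3=coords.shape[0] * mask.voxel_volume_mm3(),
            )
        )
    return Cohort(label=label, tumors=tumors, dims=dims)


def write_map(values3d: np.ndarray, path, voxel_size_mm=(1.0, 1.0, 1.0)):
    """Write a 3-D parameter map as NIfTI-1."""
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(values3d, dtype=np.float64), affine), str(path))


# ---------------------------------------------------------------------------
# JSON results

def _jsonify(obj, flags, path=""):
    if isinstance(obj, dict):
        return {k: _jsonify(v, flags, f"{path}.{k}") for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v, flags, f"{path}[{i}]") for i, v in enumerate(obj)]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist(), flags, path)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        if not math.isfinite(f):
            flags.append(path)
            return None
        return f
    return obj


def _package_version() -> str:
    try:
        return metadata.version("hrscan")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def model_to_dict(model: HRSModel) -> dict:
    d = asdict(model)
    d.pop("landscape", None)
    return d


def write_model_json(model: HRSModel, path) -> None:
    """Serialize an HRS model with full provenance.

    Non-finite values (e.g. a NaN score) are stored as JSON null and
    listed under ``"nonfinite_flags"``.
    """
    flags: list[str] = []
    payload = _jsonify(model_to_dict(model), flags)
    payload["software_version"] = _package_version()
    payload["nonfinite_flags"] = flags
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def _none_to_nan(x):
    return math.nan if x is None else x


def read_model_json(path) -> HRSModel:
    with open(path) as fh:
        d = json.load(fh)
    best = d["best"]
    candidate = ClusterCandidate(
        center_index=best["center_index"],
        center_tumor_id=best["center_tumor_id"],
        center_z=np.array(best["center_z"]),
        members=np.array(best["members"], dtype=int),
        f_cluster=np.array(best["f_cluster"]),
        score=_none_to_nan(best["score"]),
        effect_hm=EffectSizeReport(**best["effect_hm"]),
        effect_ml=EffectSizeReport(**best["effect_ml"]),
    )
    return HRSModel(
        dims=list(d["dims"]),
        best=candidate,
        center_raw=np.array(d["center_raw"]),
        interval_raw=np.array(d["interval_raw"]),
        score=_none_to_nan(d["score"]),
        p_value=_none_to_nan(d["p_value"]),
        p_pairwise={k: _none_to_nan(v) for k, v in d["p_pairwise"].items()},
        normalization={k: tuple(v) for k, v in d["normalization"].items()},
        n_hrs=d["n_hrs"],
        n_it=d["n_it"],
        seed=d["seed"],
    )


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=True)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_landscape_csv(model: HRSModel, path) -> None:
    """Export (center z-coordinates, S) per iteration for 2-D projections."""
    if model.landscape is None:
        raise ValueError("model was fitted without a retained landscape")
    cols = [f"z_{d}" for d in model.dims] + ["S"]
    pd.DataFrame(model.landscape, columns=cols).to_csv(path, index=False)
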