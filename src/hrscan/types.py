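"""Core domain containers: tumor samples, cohorts, ROI masks.

A :class:`Cohort` holds co-registered per-animal tumor voxel data in a
common quantitative-imaging parameter space.  Each :class:`TumorSample`
stores one value per tumor voxel for each available quantitative
parameter (ADC, FMISO_c1, FMISO_c2, DCE_c1, DCE_c2) together with the
integer grid coordinates of the voxel on the common (PET) grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical order of the five quantitative imaging parameters.
PARAMETER_NAMES = ("ADC", "FMISO_c1", "FMISO_c2", "DCE_c1", "DCE_c2")


@dataclass
class TumorSample:
    """Voxel-level data of one xenograft tumor.

    Parameters
    ----------
    id : str
        Unique animal/tumor identifier.
    cell_line : str
        Implanted cell line name.
    params : dict of str to ndarray
        Per-voxel raw parameter values, one 1-D array of length
        ``n_voxels`` per available parameter name.
    coords : ndarray of shape (n_voxels, 3)
        0-based integer grid indices (row-major extraction order).
    class_label : str or None
        Radiosensitivity class ``"H"``, ``"M"`` or ``"L"`` once assigned.
    volume_mm3 : float
        Tumor volume in cubic millimetres.
    truth_niche : ndarray or None
        Boolean ground-truth membership of a planted resistant niche
        (synthetic cohorts only).
    """

    id: str
    cell_line: str
    params: dict[str, np.ndarray]
    coords: np.ndarray
    class_label: str | None = None
    volume_mm3: float = float("nan")
    truth_niche: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"tumor {self.id}: coords must be (n_voxels, 3)")
        n = self.coords.shape[0]
        if n < 1:
            raise ValueError(f"tumor {self.id}: at least one voxel required")
        if len(np.unique(self.coords, axis=0)) != n:
            raise ValueError(f"tumor {self.id}: duplicate grid coordinates")
        for name, v in self.params.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (n,):
                raise ValueError(
                    f"tumor {self.id}: parameter {name!r} has shape {v.shape},"
                    f" expected ({n},)"
                )
            self.params[name] = v

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    def has_dims(self, dims) -> bool:
        return all(d in self.params for d in dims)

    def matrix(self, dims) -> np.ndarray:
        """Stack the requested parameters into an (n_voxels, n_dims) matrix."""
        missing = [d for d in dims if d not in self.params]
        if missing:
            raise KeyError(f"tumor {self.id}: missing parameters {missing}")
        return np.column_stack([self.params[d] for d in dims])


@dataclass
class Cohort:
    """An ordered collection of tumors sharing a parameter space.

    ``normalization`` maps each dimension name to the ``(mean, sd)`` pair
    used for z-normalization of the pooled voxel cloud; it is filled in by
    the scanner when the space is built and frozen for later evaluation
    on extended cohorts.
    """

    label: str
    tumors: list[TumorSample]
    dims: list[str]
    normalization: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        ids = [t.id for t in self.tumors]
        if len(set(ids)) != len(ids):
            raise ValueError("tumor ids must be unique within a cohort")
        for d in self.dims:
            if d not in PARAMETER_NAMES:
                raise ValueError(f"unknown parameter name {d!r}")
        for t in self.tumors:
            if not t.has_dims(self.dims):
                raise ValueError(
                    f"tumor {t.id} lacks values for some of {self.dims}"
                )
        if self.normalization is not None:
            for d in self.dims:
                mean, sd = self.normalization[d]
                if not sd > 0:
                    raise ValueError(f"normalization sd for {d!r} must be > 0")

    def __len__(self) -> int:
        return len(self.tumors)

    @property
    def n_voxels(self) -> int:
        return sum(t.n_voxels for t in self.tumors)

    def tumor_sizes(self) -> np.ndarray:
        return np.array([t.n_voxels for t in self.tumors])

    def class_labels(self) -> list[str]:
        labels = [t.class_label for t in self.tumors]
        if any(lb is None for lb in labels):
            raise ValueError("cohort contains unclassed tumors")
        return labels  # type: ignore[return-value]

    def pooled(self, dims=None) -> tuple[np.ndarray, np.ndarray]:
        """Pool voxels over tumors.

        Returns
        -------
        X : ndarray of shape (total_voxels, n_dims)
            Raw parameter values, tumors concatenated in cohort order.
        tumor_index : ndarray of int
            Index into ``self.tumors`` for every pooled voxel.
        """
        dims = self.dims if dims is None else list(dims)
        X = np.vstack([t.matrix(dims) for t in self.tumors])
        tumor_index = np.repeat(
            np.arange(len(self.tumors)), [t.n_voxels for t in self.tumors]
        )
        return X, tumor_index

    def select(self, dims, label: str | None = None) -> "Cohort":
        """Sub-cohort of tumors that expose all of ``dims``.

        Mirrors the distinction between the full-parameter training cohort
        and the per-model maximal cohorts: animals with incomplete map
        sets stay in the store and are filtered per analysis.
        """
        dims = list(dims)
        tumors = [t for t in self.tumors if t.has_dims(dims)]
        return Cohort(
            label=label or f"{self.label}|{','.join(dims)}",
            tumors=tumors,
            dims=dims,
        )


@dataclass
class ROIMask:
    """Label volume on the common grid: 0 background, 1 tumor, 2 muscle."""

    labels: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    TUMOR: int = field(default=1, init=False, repr=False)
    MUSCLE: int = field(default=2, init=False, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("mask labels must be a 3-D volume")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def _coords(self, value: int) -> np.ndarray:
        # row-major order: np.argwhere iterates C-order, giving the
        # deterministic voxel extraction order used throughout
        return np.argwhere(self.labels == value)

    def tumor_coords(self) -> np.ndarray:
        return self._coords(self.TUMOR)

    def muscle_coords(self) -> np.ndarray:
        return self._coords(self.MUSCLE)

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))
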