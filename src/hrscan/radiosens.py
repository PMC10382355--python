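"""Radiosensitivity classes from TCD50 confidence intervals.

Cell lines whose 95% confidence intervals of the tumor control dose 50%
(TCD50) overlap are not distinguishable with respect to radiosensitivity
and are merged into one class (transitively).  With three resulting
classes they are labelled H (high sensitivity, lowest TCD50), M and L.
Each class maps to a prior high-risk-subvolume (HRS) voxel fraction:
resistant (L) tumors are hypothesised to carry a larger resistant niche.
"""

from __future__ import annotations

from dataclasses import dataclass

#: HRS voxel fraction per radiosensitivity class.
HRS_FRACTIONS = {"H": 0.0, "M": 0.075, "L": 0.150}


@dataclass
class CellLineInfo:
    """TCD50 summary and derived class for one cell line."""

    name: str
    tcd50_mean: float
    tcd50_lo: float
    tcd50_hi: float
    class_label: str | None = None
    #: complete baseline / week-2 imaging data sets (cohort bookkeeping)
    n_baseline: int = 0
    n_week2: int = 0

    def __post_init__(self) -> None:
        if not (self.tcd50_lo <= self.tcd50_mean <= self.tcd50_hi):
            raise ValueError(
                f"{self.name}: TCD50 CI [{self.tcd50_lo}, {self.tcd50_hi}]"
                f" must bracket the mean {self.tcd50_mean}"
            )

    @property
    def hrs_fraction(self) -> float:
        if self.class_label is None:
            raise ValueError(f"{self.name}: class not assigned")
        return hrs_fraction_of(self.class_label)


# Published TCD50 values (Gy, mean and 95% CI) for the eight head-and-neck
# squamous cell carcinoma xenograft lines, with the number of complete
# multi-parametric imaging data sets per line at baseline and after two
# weeks of fractionated radiotherapy.
CELL_LINES = [
    CellLineInfo("UTSCC-45", 45, 38, 52, n_baseline=8, n_week2=4),
    CellLineInfo("XF354", 47, 40, 55, n_baseline=4, n_week2=4),
    CellLineInfo("UTSCC-14", 52, 46, 59, n_baseline=4, n_week2=4),
    CellLineInfo("UTSCC-8", 52, 40, 61, n_baseline=2, n_week2=0),
    CellLineInfo("FaDu", 85, 77, 96, n_baseline=12, n_week2=9),
    CellLineInfo("CAL-33", 105, 90, 141, n_baseline=5, n_week2=3),
    CellLineInfo("UTSCC-5", 117, 103, 140, n_baseline=0, n_week2=0),
    CellLineInfo("SAS", 127, 114, 140, n_baseline=7, n_week2=8),
]

#: CAL-33 is excluded from class building: its wide TCD50 range spans the
#: M and L classes and its imaging data could not be analysed reproducibly.
DEFAULT_EXCLUSIONS = frozenset({"CAL-33"})


def hrs_fraction_of(class_label: str) -> float:
    """HRS voxel fraction prior for a radiosensitivity class.

    L (resistant) -> 0.150, M -> 0.075, H (sensitive) -> 0.0.
    """
    try:
        return HRS_FRACTIONS[class_label]
    except KeyError:
        raise ValueError(
            f"unassigned or unknown class label {class_label!r}"
        ) from None


def group_by_tcd50(
    lines: list[CellLineInfo],
    exclusions=DEFAULT_EXCLUSIONS,
    labels: tuple[str, ...] = ("H", "M", "L"),
) -> list[CellLineInfo]:
    """Partition cell lines into radiosensitivity classes by CI overlap.

    Two lines are merged when their closed TCD50 confidence intervals
    intersect; classes are the connected components of this overlap
    relation (so a chain A-B-C merges even if A and C are disjoint).
    Components are ordered by ascending mean TCD50 of their members and
    labelled with ``labels`` (default H, M, L: low TCD50 means high
    radiosensitivity).

    Returns new :class:`CellLineInfo` objects with ``class_label`` set;
    excluded lines are omitted.

    Raises
    ------
    ValueError
        If the number of components differs from ``len(labels)``.
    """
    active = [ln for ln in lines if ln.name not in set(exclusions)]
    if len(active) < 2:
        raise ValueError("need at least two non-excluded cell lines")

    # connected components of the interval-overlap graph via union-find
    parent = list(range(len(active)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(active)):
        for j in range(i + 1, len(active)):
            a, b = active[i], active[j]
            if a.tcd50_lo <= b.tcd50_hi and b.tcd50_lo <= a.tcd50_hi:
                parent[find(i)] = find(j)

    comps: dict[int, list[CellLineInfo]] = {}
    for i, ln in enumerate(active):
        comps.setdefault(find(i), []).append(ln)

    groups = sorted(
        comps.values(),
        key=lambda g: sum(ln.tcd50_mean for ln in g) / len(g),
    )
    if len(groups) != len(labels):
        raise ValueError(
            f"TCD50 CI overlap yields {len(groups)} classes, expected"
            f" {len(labels)}; pass explicit labels"
        )
    out = []
    for label, group in zip(labels, groups):
        for ln in group:
            out.append(
                CellLineInfo(
                    ln.name,
                    ln.tcd50_mean,
                    ln.tcd50_lo,
                    ln.tcd50_hi,
                    class_label=label,
                    n_baseline=ln.n_baseline,
                    n_week2=ln.n_week2,
                )
            )
    return out


def class_of_cell_line(name: str, classed=None) -> str:
    """Look up the radiosensitivity class of a cell line by name."""
    classed = group_by_tcd50(CELL_LINES) if classed is None else classed
    for ln in classed:
        if ln.name == name:
            assert ln.class_label is not None
            return ln.class_label
    raise KeyError(f"cell line {name!r} not in classed table")
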