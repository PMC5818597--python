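"""Control-quintile cell/nuclear morphology statistics.

High-content imaging yields one area measurement (µm²) per cell and per
nucleus.  The statistic works entirely on occupancy of five equal-frequency
categories defined on matched vehicle-control cells: the smallest 20% of the
control population is "Lowest", the next 20% "Low", then "Medium", "High"
and "Highest".  Treatment shifts are read as changes in the percentage of
cells falling in each category, which are then tested dose-wise like any
other endpoint.

Controls are stratified by experimental condition (vehicle x cell line x
exposure duration); thresholds are derived only from controls of the
matching stratum, after equalising the number of cells drawn from each
control replicate (seeded subsampling without replacement down to the
smallest replicate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_response import DoseResponseSeries, NoelLoel, analyse_series

__all__ = [
    "QuintileThresholds",
    "QuintileOccupancy",
    "CATEGORIES",
    "derive_thresholds",
    "classify",
    "occupancy_dose_response",
    "median_fold",
    "thresholds_table",
]

CATEGORIES = ("Lowest", "Low", "Medium", "High", "Highest")
MEASURES = ("cell_area", "nuclear_area")
MIN_CONTROL_CELLS = 100


@dataclass
class QuintileThresholds:
    """Control 20/40/60/80th-percentile cut points for one measure/stratum."""

    measure: str
    stratum: str
    cuts: np.ndarray  # 4 ascending thresholds, µm²
    n_control: int

    def __post_init__(self) -> None:
        self.cuts = np.asarray(self.cuts, dtype=float)
        if self.cuts.size != 4:
            raise ValueError("exactly 4 cut points expected")
        if np.any(np.diff(self.cuts) <= 0):
            raise ValueError("cut points must be strictly ascending")


@dataclass
class QuintileOccupancy:
    """Percent of a population in each of the five categories."""

    condition: str
    measure: str
    proportions: np.ndarray  # percent, ordered as CATEGORIES
    n: int

    def as_dict(self) -> dict[str, float]:
        return dict(zip(CATEGORIES, map(float, self.proportions)))


def _stable_label_seed(seed: int, label: object) -> list[int]:
    import zlib

    return [int(seed) & 0x7FFFFFFF, zlib.crc32(str(label).encode()) & 0x7FFFFFFF]


def derive_thresholds(
    controls: pd.DataFrame,
    measure: str,
    stratum: str,
    seed: int = 0,
) -> QuintileThresholds:
    """Derive quintile cut points from stratum-matched control cells.

    ``controls`` is a per-cell table with at least ``replicate`` and the
    measure column (``cell_area_um2`` / ``nuclear_area_um2``).  Each control
    replicate is subsampled (without replacement, seeded per replicate label)
    to the smallest replicate's cell count so every replicate contributes
    equally, then the 20/40/60/80th percentiles of the pooled sample become
    the cuts (linear interpolation between closest order statistics).
    """
    col = f"{measure}_um2"
    if col not in controls.columns:
        raise ValueError(f"controls table lacks column {col!r}")
    if "replicate" not in controls.columns:
        raise ValueError("controls table lacks a replicate column")
    reps = controls.groupby("replicate")[col]
    if reps.ngroups < 2:
        raise ValueError("at least 2 control replicates are required")
    n_min = int(reps.size().min())
    pooled = []
    for label, vals in reps:
        v = np.sort(vals.to_numpy(dtype=float))
        if v.size > n_min:
            rng = np.random.default_rng(_stable_label_seed(seed, label))
            v = v[rng.choice(v.size, size=n_min, replace=False)]
        pooled.append(v)
    sample = np.concatenate(pooled)
    if sample.size < MIN_CONTROL_CELLS:
        raise ValueError(f"only {sample.size} control cells after equalisation; "
                         f"need at least {MIN_CONTROL_CELLS}")
    if np.any(sample <= 0):
        raise ValueError("areas must be positive")
    cuts = np.percentile(sample, [20, 40, 60, 80], method="linear")
    if np.any(np.diff(cuts) <= 0):
        raise ValueError("tied control values collapse a quintile boundary")
    return QuintileThresholds(measure=measure, stratum=stratum, cuts=cuts,
                              n_control=sample.size)


def classify(
    values: np.ndarray | pd.Series,
    thresholds: QuintileThresholds,
    condition: str = "",
) -> QuintileOccupancy:
    """Assign cells to the five categories and report percent occupancy.

    Intervals are half-open, lower-closed: a cell exactly at a cut belongs
    to the upper category.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no cells to classify")
    idx = np.searchsorted(thresholds.cuts, values, side="right")
    counts = np.bincount(idx, minlength=5)
    return QuintileOccupancy(
        condition=condition,
        measure=thresholds.measure,
        proportions=100.0 * counts / values.size,
        n=values.size,
    )


def category_index(values: np.ndarray, thresholds: QuintileThresholds) -> np.ndarray:
    """Category index (0=Lowest .. 4=Highest) per cell; monotone in value."""
    return np.searchsorted(thresholds.cuts, np.asarray(values, dtype=float),
                           side="right")


def occupancy_dose_response(
    cells: pd.DataFrame,
    thresholds: QuintileThresholds,
    category: str,
    chemical: str = "",
    alpha: float = 0.05,
    n_resamples: int = 2000,
    seed: int | None = None,
) -> NoelLoel:
    """NOEL/LOEL for one category's occupancy across the dose ladder.

    Per-replicate occupancies of ``category`` are computed at every dose
    (dose 0 = vehicle) and handed to the dose-response stage.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    col = f"{thresholds.measure}_um2"
    cat = CATEGORIES.index(category)
    doses, groups = [], []
    for dose, ddf in cells.groupby("dose_uM", sort=True):
        occ = []
        for _, rdf in ddf.groupby("replicate"):
            idx = category_index(rdf[col].to_numpy(), thresholds)
            occ.append(100.0 * float(np.mean(idx == cat)))
        doses.append(float(dose))
        groups.append(np.asarray(occ))
    series = DoseResponseSeries(
        endpoint=f"{thresholds.measure}:{category}",
        chemical=chemical,
        doses=np.asarray(doses),
        responses=groups,
    )
    result, _ = analyse_series(series, alpha=alpha, n_resamples=n_resamples, seed=seed)
    return result


def thresholds_table(thresholds: list[QuintileThresholds]) -> pd.DataFrame:
    """Flatten threshold sets into one exportable table: one row per
    stratum x measure with the four cut points (µm²) and the control cell
    count."""
    rows = []
    for t in thresholds:
        rows.append({
            "stratum": t.stratum, "measure": t.measure,
            "cut_20pct_um2": t.cuts[0], "cut_40pct_um2": t.cuts[1],
            "cut_60pct_um2": t.cuts[2], "cut_80pct_um2": t.cuts[3],
            "n_control": t.n_control,
        })
    return pd.DataFrame(rows)


def median_fold(treated: np.ndarray, control: np.ndarray) -> float:
    """Median-area ratio treated : control (the morphology slice fold)."""
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.size == 0 or control.size == 0:
        raise ValueError("empty cell set")
    m = float(np.median(control))
    if m <= 0:
        raise ValueError("non-positive control median area")
    return float(np.median(treated)) / m
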