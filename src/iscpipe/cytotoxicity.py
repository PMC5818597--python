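"""Relative Population Doubling and reference-concentration selection.

RPD expresses the doublings of a treated culture as a percentage of the
vehicle-control doublings over the same period:

    RPD = 100 * log2(post_t / pre_t) / log2(post_c / pre_c)

The reference concentration for fold-change extraction is the dose at which
RPD falls to 50% of control (interpolated on the log-dose axis between the
bracketing tested doses), or the top tested dose when cytotoxicity never
reaches 50%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RPDCurve", "compute_rpd", "select_reference_concentration"]

CELL_COUNT_COLUMNS = ["dose_uM", "replicate", "pre_count", "post_count"]


@dataclass
class RPDCurve:
    """Mean RPD per dose with per-replicate values retained.

    ``per_replicate[i]`` holds the replicate RPD values behind ``rpd[i]``.
    The vehicle (dose 0) is pinned at 100% by construction.
    """

    doses: np.ndarray
    rpd: np.ndarray
    per_replicate: list[np.ndarray]

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.rpd = np.asarray(self.rpd, dtype=float)


def _doublings(pre: np.ndarray, post: np.ndarray) -> np.ndarray:
    return np.log2(np.asarray(post, dtype=float) / np.asarray(pre, dtype=float))


def compute_rpd(treated: pd.DataFrame, vehicle: pd.DataFrame) -> RPDCurve:
    """Compute the RPD curve from treated and vehicle cell-count tables.

    Both tables need columns ``dose_uM, replicate, pre_count, post_count``.
    Replicates are paired by index with the vehicle when the replicate labels
    match; otherwise each treated replicate is normalised by the mean vehicle
    doubling.  Treated cultures that fail to double give RPD <= 0.
    """
    for df, name in ((treated, "treated"), (vehicle, "vehicle")):
        missing = [c for c in CELL_COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{name} cell counts missing columns {missing}")
        if (df["pre_count"] <= 0).any() or (df["post_count"] <= 0).any():
            raise ValueError(f"{name} cell counts must be positive")

    veh = vehicle.copy()
    veh["doublings"] = _doublings(veh["pre_count"], veh["post_count"])
    if (veh["doublings"] <= 0).any():
        raise ValueError("vehicle control failed to grow: post_count <= pre_count "
                         "makes the RPD denominator undefined")
    veh_by_rep = veh.set_index("replicate")["doublings"]
    veh_mean = float(veh["doublings"].mean())

    doses, means, per_rep = [], [], []
    for dose, grp in treated.groupby("dose_uM", sort=True):
        d_t = _doublings(grp["pre_count"], grp["post_count"])
        reps = grp["replicate"].to_numpy()
        if set(reps) <= set(veh_by_rep.index):
            denom = veh_by_rep.loc[reps].to_numpy()
        else:
            denom = np.full(len(grp), veh_mean)
        vals = 100.0 * np.asarray(d_t) / denom
        doses.append(float(dose))
        means.append(float(vals.mean()))
        per_rep.append(vals)

    doses = np.asarray(doses)
    means = np.asarray(means)
    if 0.0 not in doses:
        doses = np.concatenate([[0.0], doses])
        means = np.concatenate([[100.0], means])
        per_rep = [np.array([100.0] * len(veh))] + per_rep
    else:
        i = int(np.nonzero(doses == 0.0)[0][0])
        means[i] = 100.0
        per_rep[i] = np.full_like(per_rep[i], 100.0)
    return RPDCurve(doses=doses, rpd=means, per_replicate=per_rep)


def select_reference_concentration(
    curve: RPDCurve, rule: str = "interpolated"
) -> tuple[float, str]:
    """Pick the fold-change reference dose from an RPD curve.

    If any tested dose brings mean RPD to 50% or below, return the dose where
    the curve crosses 50%, linearly interpolated in log10(dose) between the
    bracketing tested doses (``rule="interpolated"``, the default) or the
    lowest tested dose with RPD <= 50% (``rule="nearest"``); basis is
    ``"interpolated_50pct"``.  Otherwise return the top tested dose with
    basis ``"top_dose"``.  Non-monotone curves crossing 50% more than once
    use the lowest crossing, with a warning.
    """
    if rule not in ("interpolated", "nearest"):
        raise ValueError(f"unknown rule {rule!r}")
    nz = curve.doses > 0
    doses = curve.doses[nz]
    rpd = curve.rpd[nz]
    if doses.size < 2:
        raise ValueError("RPD curve needs at least 2 non-zero doses")

    below = rpd <= 50.0
    if not below.any():
        return float(doses[-1]), "top_dose"

    crossings = [i for i in range(doses.size)
                 if below[i] and (i == 0 or not below[i - 1])]
    if len(crossings) > 1:
        warnings.warn("RPD curve crosses 50% more than once; using the lowest "
                      "crossing", stacklevel=2)
    i = crossings[0]
    if rpd[i] == 50.0 or i == 0 or rule == "nearest":
        return float(doses[i]), "interpolated_50pct"
    # log-dose linear interpolation between the bracketing tested doses
    x0, x1 = np.log10(doses[i - 1]), np.log10(doses[i])
    y0, y1 = rpd[i - 1], rpd[i]
    frac = (y0 - 50.0) / (y0 - y1)
    return float(10 ** (x0 + frac * (x1 - x0))), "interpolated_50pct"
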