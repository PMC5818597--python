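"""Fold changes for immunoblot densitometry and qRT-PCR expression.

Densitometry: band intensities of the target protein (p53, phospho-p53) are
normalised to the loading control (beta-actin) lane-wise; the fold change is
the treated target/loading ratio divided by the mean vehicle ratio.

qRT-PCR: relative expression by the comparative-Cq method,
    dCq  = Cq_target - Cq_reference        (per well)
    ddCq = dCq_treated - mean dCq_vehicle
    fold = E^(-ddCq)
with amplification efficiency E = 2 (perfect doubling) by default.

Before dose-response testing, log2 fold values are mean-centered per
replicate across each chemical's series, removing replicate-level batch
offsets (separate culture days) that otherwise inflate between-replicate
variance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["densitometry_fold", "relative_expression", "mean_center"]


def densitometry_fold(treated: pd.DataFrame, vehicle: pd.DataFrame) -> pd.DataFrame:
    """Loading-normalised fold change of band intensity vs the vehicle mean.

    Both tables need ``target_intensity`` and ``loading_intensity`` columns;
    the treated table keeps its other columns (dose, replicate, ...) and
    gains a ``fold`` column.
    """
    for df, name in ((treated, "treated"), (vehicle, "vehicle")):
        for col in ("target_intensity", "loading_intensity"):
            if col not in df.columns:
                raise ValueError(f"{name} densitometry table lacks {col!r}")
        if (df["loading_intensity"] <= 0).any():
            raise ValueError(f"{name} table has a non-positive loading intensity")
        if (df["target_intensity"] <= 0).any():
            raise ValueError(f"{name} table has a non-positive target intensity")
    veh_ratio = (vehicle["target_intensity"] / vehicle["loading_intensity"]).mean()
    out = treated.copy()
    out["fold"] = (treated["target_intensity"] / treated["loading_intensity"]) / veh_ratio
    return out


def relative_expression(
    records: pd.DataFrame,
    vehicle_dose: float = 0.0,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Comparative-Cq fold change per well relative to the vehicle group.

    ``records`` needs ``dose_uM, cq_target, cq_reference`` (one gene per
    call, or a ``gene`` column over which the computation is grouped).
    Returns the table with ``dcq, ddcq, fold`` columns.
    """
    for col in ("dose_uM", "cq_target", "cq_reference"):
        if col not in records.columns:
            raise ValueError(f"expression table lacks column {col!r}")
    if records[["cq_target", "cq_reference"]].isna().any().any():
        raise ValueError("missing Cq value (reference must be present for every well)")
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")

    def _one(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        df["dcq"] = df["cq_target"] - df["cq_reference"]
        veh = df.loc[df["dose_uM"] == vehicle_dose, "dcq"]
        if veh.empty:
            raise ValueError("no vehicle (dose 0) wells in expression table")
        df["ddcq"] = df["dcq"] - veh.mean()
        df["fold"] = efficiency ** (-df["ddcq"])
        return df

    if "gene" in records.columns:
        return pd.concat([_one(g) for _, g in records.groupby("gene", sort=False)],
                         ignore_index=True)
    return _one(records)


def mean_center(folds: pd.DataFrame, value: str = "fold") -> pd.DataFrame:
    """Mean-center log2 fold values per replicate across a chemical's series.

    Each replicate's log2 folds (all doses of one gene/chemical series) are
    shifted so that the replicate mean is exactly zero.  Purely additive
    replicate offsets in log space (separate-day batch effects) are removed
    exactly while within-replicate dose contrasts are preserved.  The output
    gains ``centered_log2`` and ``centered_fold`` (= 2**centered_log2)
    columns.
    """
    if "replicate" not in folds.columns:
        raise ValueError("fold table lacks a replicate column")
    if (folds[value] <= 0).any():
        raise ValueError("fold changes must be strictly positive")
    out = folds.copy()
    log2f = np.log2(out[value].to_numpy(dtype=float))
    rep_means = pd.Series(log2f).groupby(out["replicate"].to_numpy()).transform("mean")
    out["centered_log2"] = log2f - rep_means.to_numpy()
    out["centered_fold"] = 2.0 ** out["centered_log2"]
    return out
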