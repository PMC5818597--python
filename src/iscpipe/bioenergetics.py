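"""Basal bioenergetic phenotyping from OCR/ECAR flux and profile clustering.

Extracellular-flux analysis measures oxygen consumption rate (OCR, a proxy
for oxidative phosphorylation) and extracellular acidification rate (ECAR,
a glycolysis proxy) simultaneously.  Joint shifts relative to the vehicle
centroid place a condition in one of four energy-phenotype quadrants —
energetic (both up), quiescent (both down), aerobic (OCR up, ECAR down),
glycolytic (OCR down, ECAR up) — or "unchanged" when both folds sit within
a tolerance band around 1.

Chemical profiles are additionally grouped by agglomerative hierarchical
clustering on the standardized (OCR, ECAR) plane (Ward linkage, Euclidean
distance by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = [
    "EnergyPhenotype",
    "flux_folds",
    "classify_phenotype",
    "seahorse_magnitude",
    "cluster_profiles",
    "ClusterResult",
]

DEFAULT_TOLERANCE = 0.10


@dataclass
class EnergyPhenotype:
    label: str  # quiescent | aerobic | glycolytic | energetic | unchanged
    ocr_fold: float
    ecar_fold: float


def flux_folds(treated: pd.DataFrame, vehicle: pd.DataFrame) -> tuple[float, float]:
    """Mean treated / mean vehicle fold on each axis.

    Both tables need ``ocr_pmol_min`` and ``ecar_mph_min`` columns.
    """
    for df, name in ((treated, "treated"), (vehicle, "vehicle")):
        for col in ("ocr_pmol_min", "ecar_mph_min"):
            if col not in df.columns:
                raise ValueError(f"{name} flux table lacks {col!r}")
    v_ocr = float(vehicle["ocr_pmol_min"].mean())
    v_ecar = float(vehicle["ecar_mph_min"].mean())
    if v_ocr <= 0 or v_ecar <= 0:
        raise ValueError("vehicle mean flux must be positive")
    return (float(treated["ocr_pmol_min"].mean()) / v_ocr,
            float(treated["ecar_mph_min"].mean()) / v_ecar)


def classify_phenotype(
    ocr_fold: float,
    ecar_fold: float,
    tolerance: float = DEFAULT_TOLERANCE,
) -> EnergyPhenotype:
    """Quadrant classification of a joint OCR/ECAR shift.

    The tolerance band is the only route to "unchanged": if either axis
    departs from 1 by more than ``tolerance`` the condition is assigned a
    quadrant by the sign of each fold relative to 1 (a fold of exactly 1 on
    one axis counts as up).
    """
    if ocr_fold <= 0 or ecar_fold <= 0:
        raise ValueError("flux folds must be positive")
    if not (0 <= tolerance < 1):
        raise ValueError("tolerance must lie in [0, 1)")
    within = (abs(ocr_fold - 1) <= tolerance) and (abs(ecar_fold - 1) <= tolerance)
    if within:
        label = "unchanged"
    else:
        ocr_up = ocr_fold >= 1
        ecar_up = ecar_fold >= 1
        label = {(True, True): "energetic", (False, False): "quiescent",
                 (True, False): "aerobic", (False, True): "glycolytic"}[(ocr_up, ecar_up)]
    return EnergyPhenotype(label=label, ocr_fold=float(ocr_fold),
                           ecar_fold=float(ecar_fold))


def seahorse_magnitude(ocr_fold: float, ecar_fold: float, mode: str = "geometric") -> float:
    """Single magnitude-of-shift fold for the composite-score flux slice.

    ``geometric`` (default): exp(mean(|ln ocr_fold|, |ln ecar_fold|)) — the
    geometric mean of the inversion-adjusted folds, always >= 1.
    ``ocr_only``: inversion-adjusted OCR fold alone.
    """
    if ocr_fold <= 0 or ecar_fold <= 0:
        raise ValueError("flux folds must be positive")
    if mode == "geometric":
        return float(np.exp((abs(np.log(ocr_fold)) + abs(np.log(ecar_fold))) / 2.0))
    if mode == "ocr_only":
        return float(max(ocr_fold, 1.0 / ocr_fold))
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class ClusterResult:
    """Hierarchical clustering of per-condition flux profiles."""

    conditions: list[str]
    linkage: np.ndarray
    labels: np.ndarray
    newick: str


def _to_newick(node: hierarchy.ClusterNode, names: list[str]) -> str:
    if node.is_leaf():
        return names[node.id]
    left = _to_newick(node.get_left(), names)
    right = _to_newick(node.get_right(), names)
    return f"({left},{right}):{node.dist:.6g}"


def cluster_profiles(
    points: pd.DataFrame,
    method: str = "ward",
    metric: str = "euclidean",
    n_clusters: int = 2,
    standardize: bool = True,
) -> ClusterResult:
    """Agglomerative clustering of (OCR, ECAR) condition profiles.

    ``points`` needs ``condition, ocr_pmol_min, ecar_mph_min`` (one row per
    condition, e.g. chemical x dose means).  Axes are z-scored before
    clustering by default so neither unit dominates; flat labels are cut at
    ``n_clusters``; the dendrogram is serialized as a newick string.
    """
    if len(points) < 2:
        raise ValueError("clustering needs at least 2 conditions")
    X = points[["ocr_pmol_min", "ecar_mph_min"]].to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    Z = hierarchy.linkage(X, method=method, metric=metric)
    labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    names = [str(c) for c in points["condition"]]
    newick = _to_newick(hierarchy.to_tree(Z), names) + ";"
    return ClusterResult(conditions=names, linkage=Z, labels=labels, newick=newick)
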