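"""Integrated Signature of Carcinogenicity (ISC) composite scoring.

Twelve endpoint fold changes — measured at each chemical's reference
concentration (the 50%-RPD dose, or the top dose when cytotoxicity never
reached 50%) — are combined into a single prioritization score in the
ToxPi style:

* folds below 1 are inverted (down-regulation counts like up-regulation);
* all values are square-rooted except the two area endpoints;
* each endpoint is weighted so that every *technique* carries equal total
  weight: a technique measuring k endpoints gives each of them weight
  max_count / k.  For the standard panel (CBMN 1, Seahorse 1, morphology 2,
  western 2, qRT-PCR 3, cell cycle 3) this yields weights 3 / 1.5 / 1;
* slice values may be multiplied by per-group display scales (defaults 1);
* the ISC score is the weighted sum of slice values, and chemicals are
  ranked by descending score.

The radial "pie" rendering draws one slice per endpoint with radius
proportional to the slice value and angular width proportional to weight.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bioenergetics, morphology, signalling
from .cell_cycle import PHASES, phase_proportions
from .cytotoxicity import compute_rpd, select_reference_concentration
from .dose_response import mn_frequency

__all__ = [
    "ENDPOINT_TECHNIQUES",
    "ENDPOINTS",
    "SQRT_EXEMPT",
    "DEFAULT_SCALING_GROUPS",
    "EndpointFoldChange",
    "ISCProfile",
    "assign_weights",
    "transform_fold",
    "compute_isc",
    "rank_chemicals",
    "extract_fold_changes",
    "fold_at_dose",
    "render_profile",
    "build_profile",
]

# endpoint -> measuring technique; fixed for the standard 12-endpoint panel
ENDPOINT_TECHNIQUES: dict[str, str] = {
    "MN": "CBMN",
    "cell_area": "morphology",
    "nuclear_area": "morphology",
    "p53": "western",
    "phospho_p53": "western",
    "CDKN1A": "qpcr",
    "CHKA": "qpcr",
    "SGK1": "qpcr",
    "G1": "cellcycle",
    "S": "cellcycle",
    "G2": "cellcycle",
    "seahorse": "seahorse",
}
ENDPOINTS = tuple(ENDPOINT_TECHNIQUES)

# area endpoints enter the score untransformed (no square root)
SQRT_EXEMPT = frozenset({"cell_area", "nuclear_area"})

# display-scale groups: one "one-fold" magnitude per group of endpoints
DEFAULT_SCALING_GROUPS: dict[str, str] = {
    "MN": "major", "seahorse": "major",
    "cell_area": "cellular", "nuclear_area": "cellular",
    "p53": "cellular", "phospho_p53": "cellular",
    "CDKN1A": "molecular", "CHKA": "molecular", "SGK1": "molecular",
    "G1": "molecular", "S": "molecular", "G2": "molecular",
}
DEFAULT_GROUP_SCALES: dict[str, float] = {"major": 1.0, "cellular": 1.0, "molecular": 1.0}


@dataclass
class EndpointFoldChange:
    """One chemical x endpoint fold change at the reference concentration."""

    chemical: str
    endpoint: str
    fold: float
    reference_dose: float
    basis: str  # interpolated_50pct | top_dose
    missing: bool = False

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINT_TECHNIQUES:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if self.fold <= 0:
            raise ValueError("fold change must be strictly positive")

    @property
    def technique(self) -> str:
        return ENDPOINT_TECHNIQUES[self.endpoint]


def assign_weights(technique_map: dict[str, str] | None = None) -> dict[str, float]:
    """Equal-technique endpoint weights.

    Every technique's endpoints share that technique's total weight, and all
    techniques carry equal totals; with unit weight given to each endpoint
    of the largest technique, weight(e) = max endpoint count over techniques
    / endpoint count of e's technique.
    """
    tm = dict(technique_map) if technique_map is not None else dict(ENDPOINT_TECHNIQUES)
    if not tm:
        raise ValueError("empty technique map")
    counts: dict[str, int] = {}
    for t in tm.values():
        counts[t] = counts.get(t, 0) + 1
    max_count = max(counts.values())
    return {e: max_count / counts[t] for e, t in tm.items()}


def transform_fold(
    fold: float,
    endpoint: str,
    group_scales: dict[str, float] | None = None,
    scaling_groups: dict[str, str] | None = None,
    sqrt_exempt: frozenset[str] | set[str] = SQRT_EXEMPT,
) -> float:
    """Fold change -> slice value: invert below-1 folds, square-root unless
    exempt, multiply by the endpoint's group scale."""
    if fold <= 0:
        raise ValueError("fold change must be strictly positive")
    groups = scaling_groups if scaling_groups is not None else DEFAULT_SCALING_GROUPS
    scales = group_scales if group_scales is not None else DEFAULT_GROUP_SCALES
    f = fold if fold >= 1.0 else 1.0 / fold
    s = f if endpoint in sqrt_exempt else math.sqrt(f)
    scale = scales.get(groups.get(endpoint, ""), 1.0)
    if scale <= 0:
        raise ValueError("group scales must be positive")
    return scale * s


def compute_isc(slices: dict[str, float], weights: dict[str, float] | None = None) -> float:
    """Weighted sum of slice values: the ISC score."""
    w = weights if weights is not None else assign_weights()
    missing = set(w) - set(slices)
    if missing:
        raise ValueError(f"incomplete slice set, missing {sorted(missing)}")
    return float(sum(w[e] * slices[e] for e in w))


def rank_chemicals(scores: dict[str, float]) -> pd.DataFrame:
    """Rank chemicals by descending ISC score.

    Ties share a dense rank and are listed lexicographically within the tie.
    """
    if not scores:
        raise ValueError("no chemicals to rank")
    items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    ranks, prev, r = [], None, 0
    for _, s in items:
        if prev is None or s != prev:
            r += 1
            prev = s
        ranks.append(r)
    return pd.DataFrame({
        "chemical": [c for c, _ in items],
        "score": [s for _, s in items],
        "rank": ranks,
    })


def fold_at_dose(doses: np.ndarray, folds: np.ndarray, reference_dose: float) -> float:
    """Fold at the reference dose, log-dose linearly interpolated between the
    bracketing tested doses when the reference is not itself tested."""
    doses = np.asarray(doses, dtype=float)
    folds = np.asarray(folds, dtype=float)
    nz = doses > 0
    doses, folds = doses[nz], folds[nz]
    if doses.size == 0:
        raise ValueError("no non-zero doses")
    exact = np.isclose(doses, reference_dose)
    if exact.any():
        return float(folds[exact][0])
    if reference_dose <= doses[0]:
        return float(folds[0])
    if reference_dose >= doses[-1]:
        return float(folds[-1])
    i = int(np.searchsorted(doses, reference_dose))
    x0, x1 = np.log10(doses[i - 1]), np.log10(doses[i])
    frac = (np.log10(reference_dose) - x0) / (x1 - x0)
    return float(folds[i - 1] + frac * (folds[i] - folds[i - 1]))


def _per_dose_fold(df: pd.DataFrame, value_fn) -> tuple[np.ndarray, np.ndarray]:
    doses = np.array(sorted(df["dose_uM"].unique()))
    vals = np.array([value_fn(df[df["dose_uM"] == d]) for d in doses])
    base = vals[doses == 0]
    if base.size == 0:
        raise ValueError("table lacks a vehicle (dose 0) group")
    if base[0] <= 0:
        raise ValueError("vehicle-level value is non-positive; fold undefined")
    return doses, vals / base[0]


def extract_fold_changes(
    chemical: str,
    reference_dose: float,
    basis: str,
    cbmn: pd.DataFrame | None = None,
    morphology_cells: pd.DataFrame | None = None,
    cellcycle: pd.DataFrame | None = None,
    densitometry: pd.DataFrame | None = None,
    expression: pd.DataFrame | None = None,
    flux: pd.DataFrame | None = None,
    seahorse_mode: str = "geometric",
) -> list[EndpointFoldChange]:
    """Assemble the 12 endpoint fold changes of one chemical at its
    reference dose.

    Each assay table is reduced to a per-dose fold-vs-vehicle profile and
    evaluated at the reference dose (log-dose interpolation between
    bracketing tested doses).  A missing table contributes fold 1 flagged
    ``missing`` for each of its endpoints, with a warning — the slice then
    sits at baseline and can never raise the score.
    """
    out: list[EndpointFoldChange] = []

    def add(endpoint: str, fold: float, missing: bool = False) -> None:
        out.append(EndpointFoldChange(chemical=chemical, endpoint=endpoint,
                                      fold=fold, reference_dose=reference_dose,
                                      basis=basis, missing=missing))

    def add_missing(endpoints: list[str], table: str) -> None:
        warnings.warn(f"{chemical}: no {table} table; endpoint(s) {endpoints} "
                      "recorded at baseline fold 1", stacklevel=2)
        for e in endpoints:
            add(e, 1.0, missing=True)

    # micronucleus frequency ratio
    if cbmn is not None:
        doses, folds = _per_dose_fold(
            cbmn, lambda g: float(np.mean(mn_frequency(
                g["micronucleated"].to_numpy(), g["binucleates_scored"].to_numpy()))))
        add("MN", fold_at_dose(doses, folds, reference_dose))
    else:
        add_missing(["MN"], "CBMN")

    # median-area ratios
    if morphology_cells is not None:
        for endpoint, col in (("cell_area", "cell_area_um2"),
                              ("nuclear_area", "nuclear_area_um2")):
            doses, folds = _per_dose_fold(
                morphology_cells, lambda g, c=col: float(np.median(g[c])))
            add(endpoint, fold_at_dose(doses, folds, reference_dose))
    else:
        add_missing(["cell_area", "nuclear_area"], "morphology")

    # densitometry folds (target/loading vs vehicle mean ratio)
    if densitometry is not None:
        for endpoint in ("p53", "phospho_p53"):
            sub = densitometry[densitometry["target"] == endpoint]
            if sub.empty:
                add_missing([endpoint], "densitometry")
                continue
            veh = sub[sub["dose_uM"] == 0]
            folded = signalling.densitometry_fold(sub, veh)
            doses = np.array(sorted(folded["dose_uM"].unique()))
            folds = np.array([
                float(np.exp(np.mean(np.log(folded.loc[folded["dose_uM"] == d, "fold"]))))
                for d in doses])
            add(endpoint, fold_at_dose(doses, folds, reference_dose))
    else:
        add_missing(["p53", "phospho_p53"], "densitometry")

    # qRT-PCR relative expression (geometric mean fold per dose)
    if expression is not None:
        for gene in ("CDKN1A", "CHKA", "SGK1"):
            sub = expression[expression["gene"] == gene]
            if sub.empty:
                add_missing([gene], "expression")
                continue
            folded = signalling.relative_expression(sub)
            doses = np.array(sorted(folded["dose_uM"].unique()))
            folds = np.array([
                float(np.exp(np.mean(np.log(folded.loc[folded["dose_uM"] == d, "fold"]))))
                for d in doses])
            add(gene, fold_at_dose(doses, folds, reference_dose))
    else:
        add_missing(["CDKN1A", "CHKA", "SGK1"], "expression")

    # phase-percentage ratios
    if cellcycle is not None:
        props = phase_proportions(cellcycle)
        for phase in PHASES:
            doses, folds = _per_dose_fold(props, lambda g, p=phase: float(g[p].mean()))
            add(phase, fold_at_dose(doses, folds, reference_dose))
    else:
        add_missing(list(PHASES), "cell-cycle")

    # flux magnitude-of-shift
    if flux is not None:
        veh = flux[flux["dose_uM"] == 0]
        if veh.empty:
            raise ValueError("flux table lacks a vehicle (dose 0) group")
        doses = np.array(sorted(d for d in flux["dose_uM"].unique() if d > 0))
        mags = []
        for d in doses:
            ocr_f, ecar_f = bioenergetics.flux_folds(flux[flux["dose_uM"] == d], veh)
            mags.append(bioenergetics.seahorse_magnitude(ocr_f, ecar_f, seahorse_mode))
        add("seahorse", fold_at_dose(doses, np.asarray(mags), reference_dose))
    else:
        add_missing(["seahorse"], "flux")

    return out


@dataclass
class ISCProfile:
    """Weighted, transformed slice values and the total score for one chemical."""

    chemical: str
    folds: dict[str, float]
    slices: dict[str, float]
    weights: dict[str, float]
    scaling_groups: dict[str, str]
    total: float
    reference_dose: float
    basis: str
    rank: int | None = None
    missing: list[str] = field(default_factory=list)
    group_scales: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GROUP_SCALES))

    def to_dict(self) -> dict:
        return {
            "chemical": self.chemical,
            "folds": self.folds,
            "slices": self.slices,
            "weights": self.weights,
            "scaling_groups": self.scaling_groups,
            "total": self.total,
            "reference_dose": self.reference_dose,
            "basis": self.basis,
            "rank": self.rank,
            "missing": self.missing,
            "group_scales": self.group_scales,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ISCProfile":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ISCProfile":
        return cls.from_dict(json.loads(s))


def build_profile(
    fold_changes: list[EndpointFoldChange],
    weights: dict[str, float] | None = None,
    group_scales: dict[str, float] | None = None,
    scaling_groups: dict[str, str] | None = None,
) -> ISCProfile:
    """Transform a chemical's fold changes into its ISC profile and score."""
    if not fold_changes:
        raise ValueError("no fold changes supplied")
    chem = fold_changes[0].chemical
    w = weights if weights is not None else assign_weights()
    groups = scaling_groups if scaling_groups is not None else DEFAULT_SCALING_GROUPS
    folds = {fc.endpoint: fc.fold for fc in fold_changes}
    slices = {
        fc.endpoint: transform_fold(fc.fold, fc.endpoint, group_scales, groups)
        for fc in fold_changes
    }
    total = compute_isc(slices, w)
    scales = dict(group_scales) if group_scales is not None else dict(DEFAULT_GROUP_SCALES)
    return ISCProfile(
        chemical=chem,
        folds=folds,
        slices=slices,
        weights=dict(w),
        scaling_groups={e: groups.get(e, "") for e in folds},
        total=total,
        reference_dose=fold_changes[0].reference_dose,
        basis=fold_changes[0].basis,
        missing=[fc.endpoint for fc in fold_changes if fc.missing],
        group_scales=scales,
    )


def render_profile(profile: ISCProfile, path: str | None = None):
    """Radial pie-slice rendering of one ISC profile (SVG).

    One slice per endpoint: radius proportional to the slice value, angular
    width proportional to the endpoint weight; a dashed circle marks the
    one-fold baseline of each scaling group.  Returns the matplotlib figure;
    saves to ``path`` (SVG) when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    endpoints = list(profile.slices)
    weights = np.array([profile.weights[e] for e in endpoints])
    values = np.array([profile.slices[e] for e in endpoints])
    widths = 2 * np.pi * weights / weights.sum()
    lefts = np.concatenate([[0.0], np.cumsum(widths)[:-1]])

    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(111, projection="polar")
    cmap = plt.get_cmap("tab20")
    ax.bar(lefts, values, width=widths, align="edge",
           color=[cmap(i % 20) for i in range(len(endpoints))],
           edgecolor="white", linewidth=0.8)
    # dashed one-fold baseline per scaling group: a fold of 1 maps to a
    # slice value equal to the group's display scale
    theta = np.linspace(0, 2 * np.pi, 200)
    for scale in sorted({profile.group_scales.get(g, 1.0)
                         for g in profile.scaling_groups.values()}):
        ax.plot(theta, np.full_like(theta, scale), ls="--", lw=0.8, color="0.3")
    for left, width, e in zip(lefts, widths, endpoints):
        ax.text(left + width / 2, values.max() * 1.08, e, ha="center",
                va="center", fontsize=7)
    ax.set_xticks([])
    ax.set_yticklabels([])
    ax.set_title(f"{profile.chemical}  ISC = {profile.total:.1f}", fontsize=10)
    if path is not None:
        fig.savefig(path, format="svg", bbox_inches="tight")
        plt.close(fig)
    return fig
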