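"""Cell-cycle phase proportions and G2-arrest detection.

Flow-cytometry gating (upstream) yields event counts per phase {G1, S, G2}
per dose and replicate.  Counts are converted to phase percentages; each
phase's percentage-vs-dose series is tested like any other endpoint.  A
chemical is flagged as inducing G2 arrest when a statistically significant
G2 increase is accompanied by a significant decrease in at least one of the
other two phases.

Vehicle proportions may come from a concurrent dose-0 group or, when the
study used a historical vehicle bank, from per-vehicle historical replicate
percentages; concurrent controls take priority when both exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import DoseResponseSeries, NoelLoel, analyse_series

__all__ = ["PHASES", "ArrestResult", "phase_proportions", "detect_arrest",
           "arrest_decision"]

PHASES = ("G1", "S", "G2")
_COUNT_COLS = {"G1": "g1_events", "S": "s_events", "G2": "g2_events"}


def phase_proportions(counts: pd.DataFrame) -> pd.DataFrame:
    """Percent of events in each phase per row of a gated-count table.

    Requires columns ``g1_events, s_events, g2_events``; an optional
    ``other_events`` gate (sub-G1/debris) is excluded from the three-phase
    simplex.  Returns the input plus ``G1, S, G2`` percentage columns.
    """
    for col in _COUNT_COLS.values():
        if col not in counts.columns:
            raise ValueError(f"phase-count table lacks column {col!r}")
    ev = counts[list(_COUNT_COLS.values())].to_numpy(dtype=float)
    if (ev < 0).any():
        raise ValueError("negative event counts")
    total = ev.sum(axis=1)
    if (total <= 0).any():
        raise ValueError("zero total events in at least one row")
    out = counts.copy()
    for j, phase in enumerate(PHASES):
        out[phase] = 100.0 * ev[:, j] / total
    return out


@dataclass
class ArrestResult:
    """Per-phase NOEL/LOEL plus the G2-arrest decision for one chemical."""

    per_phase: dict[str, NoelLoel]
    arrest: bool
    g2_loel: float | None = field(init=False)

    def __post_init__(self) -> None:
        self.g2_loel = self.per_phase["G2"].loel


def detect_arrest(
    counts: pd.DataFrame,
    chemical: str = "",
    historical_vehicle: pd.DataFrame | None = None,
    alpha: float = 0.05,
    n_resamples: int = 2000,
    seed: int | None = None,
) -> ArrestResult:
    """Test each phase's percentage against the vehicle and flag G2 arrest.

    ``counts`` holds gated events per ``dose_uM`` and ``replicate``.  If no
    dose-0 rows are present, ``historical_vehicle`` must supply replicate
    rows of the same schema (dose 0) from the historical control bank.
    Arrest = significant G2 *increase* at some dose together with a
    significant *decrease* in G1 or S at some dose.
    """
    has_concurrent = (counts["dose_uM"] == 0).any()
    if not has_concurrent:
        if historical_vehicle is None:
            raise ValueError("no concurrent vehicle (dose 0) rows and no "
                             "historical vehicle bank supplied")
        veh = historical_vehicle.copy()
        veh["dose_uM"] = 0.0
        counts = pd.concat([veh, counts], ignore_index=True)

    props = phase_proportions(counts)
    per_phase: dict[str, NoelLoel] = {}
    for phase in PHASES:
        doses, groups = [], []
        for dose, grp in props.groupby("dose_uM", sort=True):
            doses.append(float(dose))
            groups.append(grp[phase].to_numpy(dtype=float))
        series = DoseResponseSeries(
            endpoint=f"cellcycle:{phase}", chemical=chemical,
            doses=np.asarray(doses), responses=groups,
            direction="increase" if phase == "G2" else "two_sided",
        )
        per_phase[phase], _ = analyse_series(series, alpha=alpha,
                                             n_resamples=n_resamples, seed=seed)

    return ArrestResult(per_phase=per_phase,
                        arrest=arrest_decision(per_phase, alpha))


def arrest_decision(per_phase: dict[str, NoelLoel], alpha: float = 0.05) -> bool:
    """The G2-arrest rule on per-phase dose-response results: a significant
    G2 *increase* at some dose together with a significant *decrease* in G1
    or S at some dose."""
    g2 = per_phase["G2"]
    g2_up = bool(np.any((g2.per_dose_p <= alpha) & (g2.effect > 0)))
    complement_down = any(
        bool(np.any((per_phase[ph].per_dose_p <= alpha) & (per_phase[ph].effect < 0)))
        for ph in ("G1", "S")
    )
    return g2_up and complement_down
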