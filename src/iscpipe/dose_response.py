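"""Spline dose-response modelling with per-dose departure tests (NOEL/LOEL).

Every endpoint in the pipeline — micronucleus frequency, quintile occupancy,
phase percentages, expression and densitometry fold changes — is reduced to a
:class:`DoseResponseSeries`: replicate responses on an ascending dose ladder
with the vehicle control at dose 0.  The analysis has three stages:

1. a cubic smoothing spline over log10(dose + pseudo-dose), with the penalty
   chosen by generalized cross-validation, summarising the mean trend;
2. a two-sided bootstrap departure test of each non-zero dose against the
   vehicle (studentized Welch statistic, resampling pooled centered
   residuals under the null of no difference);
3. the NOEL/LOEL decision rule: the LOEL is the lowest dose with p <= alpha,
   the NOEL the highest tested dose strictly below it.

No multiplicity correction is applied across doses by default; a Holm
adjustment is available via ``holm=True``.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline, make_smoothing_spline

__all__ = [
    "DoseResponseSeries",
    "NoelLoel",
    "SplineFit",
    "fit_spline",
    "test_departures",
    "determine_noel_loel",
    "analyse_series",
    "mn_frequency",
    "bootstrap_departure_p",
    "derive_test_seed",
]

DEFAULT_ALPHA = 0.05
DEFAULT_RESAMPLES = 2000


@dataclass
class DoseResponseSeries:
    """Replicate responses for one endpoint of one chemical across a dose ladder.

    ``responses[i]`` holds the replicate values observed at ``doses[i]``;
    dose 0 is the vehicle control.  ``direction`` records the biologically
    expected direction of departure and is carried through to reporting;
    the departure test itself is two-sided.
    """

    endpoint: str
    chemical: str
    doses: np.ndarray
    responses: list[np.ndarray]
    direction: str = "two_sided"

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = [np.asarray(r, dtype=float) for r in self.responses]
        if len(self.doses) != len(self.responses):
            raise ValueError("doses and responses must have equal length")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be sorted strictly ascending")
        if self.direction not in ("increase", "decrease", "two_sided"):
            raise ValueError(f"unknown direction {self.direction!r}")
        for d, r in zip(self.doses, self.responses):
            if r.size < 2:
                raise ValueError(f"dose {d} has fewer than 2 replicate values")

    @property
    def vehicle(self) -> np.ndarray:
        if self.doses[0] != 0.0:
            raise ValueError("series has no vehicle (dose 0) group")
        return self.responses[0]

    @property
    def treated_doses(self) -> np.ndarray:
        return self.doses[self.doses > 0]


@dataclass
class NoelLoel:
    """NOEL/LOEL decision for one series.

    ``loel`` is the lowest tested dose with p <= alpha (None if no dose is
    significant); ``noel`` the highest tested dose strictly below the LOEL,
    or the top dose when nothing is significant, or None when the LOEL is
    already the lowest tested dose.  ``effect`` holds the signed mean
    departure from the vehicle at each non-zero dose.
    """

    loel: float | None
    noel: float | None
    doses: np.ndarray
    per_dose_p: np.ndarray
    effect: np.ndarray
    alpha: float = DEFAULT_ALPHA

    def significant_doses(self) -> np.ndarray:
        return self.doses[self.per_dose_p <= self.alpha]

    def to_dict(self) -> dict:
        return {
            "loel": self.loel,
            "noel": self.noel,
            "alpha": self.alpha,
            "per_dose_p": {float(d): float(p) for d, p in zip(self.doses, self.per_dose_p)},
            "effect": {float(d): float(e) for d, e in zip(self.doses, self.effect)},
        }


@dataclass
class SplineFit:
    """A GCV smoothing-spline fit over log-dose.

    ``fitted`` are the fitted mean responses at the tested doses (vehicle
    included, anchored via the pseudo-dose); ``spline`` is None when fewer
    than 4 distinct doses were available and the stage fell back to per-dose
    comparison only.
    """

    doses: np.ndarray
    fitted: np.ndarray
    pseudo_dose: float
    spline: BSpline | None = None
    lam: float | None = None

    def predict(self, dose: np.ndarray) -> np.ndarray:
        if self.spline is None:
            raise ValueError("no spline available (fewer than 4 doses)")
        x = np.log10(np.asarray(dose, dtype=float) + self.pseudo_dose)
        return self.spline(x)


def _pseudo_dose(doses: np.ndarray) -> float:
    """Offset added before the log transform so the vehicle (dose 0) sits one
    decade below the lowest tested dose."""
    nonzero = doses[doses > 0]
    if nonzero.size == 0:
        raise ValueError("dose ladder has no non-zero dose")
    return float(nonzero.min()) / 10.0


def fit_spline(series: DoseResponseSeries, lam: float | None = None) -> SplineFit:
    """Fit a cubic smoothing spline to per-dose means on the log-dose axis.

    The penalty is chosen by generalized cross-validation unless ``lam`` is
    given explicitly (larger values smooth harder; in the heavy-smoothing
    limit the fit is a straight line in log-dose).  Doses with more
    replicates receive proportionally larger weights.  With fewer than 4
    distinct doses no spline is fitted and the per-dose means are returned
    unchanged.
    """
    pseudo = _pseudo_dose(series.doses)
    means = np.array([r.mean() for r in series.responses])
    if len(series.doses) < 4:
        return SplineFit(doses=series.doses, fitted=means, pseudo_dose=pseudo)
    x = np.log10(series.doses + pseudo)
    w = np.array([float(r.size) for r in series.responses])
    if np.allclose(means, means[0]):
        # degenerate flat data: GCV is indeterminate, return the flat fit
        return SplineFit(doses=series.doses, fitted=np.full_like(means, means[0]),
                         pseudo_dose=pseudo)
    spl = make_smoothing_spline(x, means, w=w, lam=lam)
    return SplineFit(doses=series.doses, fitted=spl(x), pseudo_dose=pseudo,
                     spline=spl, lam=lam)


def derive_test_seed(chemical: str, endpoint: str, global_seed: int = 0) -> int:
    """Stable bootstrap seed from (chemical, endpoint) XOR the global seed.

    Uses CRC32 of the labels so the seed depends only on configuration, never
    on the data or on replicate ordering; result is kept below 2**31.
    """
    h = zlib.crc32(f"{chemical}|{endpoint}".encode())
    return (h ^ (int(global_seed) & 0xFFFFFFFF)) & 0x7FFFFFFF


def _welch_t(a: np.ndarray, b: np.ndarray, ridge=0.0) -> np.ndarray:
    ma, mb = a.mean(axis=-1), b.mean(axis=-1)
    va, vb = a.var(axis=-1, ddof=1), b.var(axis=-1, ddof=1)
    se = np.sqrt(va / a.shape[-1] + vb / b.shape[-1] + ridge)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (ma - mb) / np.where(se > 0, se, 1.0),
                     np.where(ma == mb, 0.0, np.inf * np.sign(ma - mb)))
    return t


def bootstrap_departure_p(
    treated: np.ndarray,
    vehicle: np.ndarray,
    n_resamples: int = DEFAULT_RESAMPLES,
    rng: np.random.Generator | None = None,
    chunk: int = 500,
    variance_ridge: float = 0.01,
) -> np.ndarray:
    """Two-sided bootstrap p-values for mean departure of treated from vehicle.

    Vectorised over series: ``treated`` has shape (S, n_t) and ``vehicle``
    (S, n_v) or (n_v,) broadcast to all series.  The reference distribution
    of the Welch t statistic is built by resampling, with replacement, the
    pooled within-group-centered residuals of both groups — valid under the
    null that both groups share one distribution, and sharper-tailed at
    small n than within-group resampling.  p = (1 + #{|t*| >= |t|}) / (B+1),
    so the smallest achievable p is 1/(B+1).

    Residuals are sorted before resampling, so the result is invariant to
    replicate ordering.  A small variance ridge (``variance_ridge`` x the
    pooled residual variance) is added to the resampled standard error:
    with replacement and tiny groups a resample can draw near-identical
    residuals, and without the ridge its t statistic explodes, corrupting
    the tail of the reference distribution.

    Degenerate zero-variance groups: when both groups have zero variance the
    comparison is exact and p is 1/(B+1) (means differ) or 1 (means equal).
    """
    rng = rng if rng is not None else np.random.default_rng()
    treated = np.atleast_2d(np.asarray(treated, dtype=float))
    vehicle = np.asarray(vehicle, dtype=float)
    if vehicle.ndim == 1:
        vehicle = np.broadcast_to(vehicle, (treated.shape[0], vehicle.size))
    S, nt = treated.shape
    nv = vehicle.shape[1]
    n = nt + nv

    t_obs = _welch_t(treated, vehicle)
    resid = np.sort(np.concatenate(
        [treated - treated.mean(axis=1, keepdims=True),
         vehicle - vehicle.mean(axis=1, keepdims=True)], axis=1), axis=1)
    ridge = (variance_ridge * resid.var(axis=1, ddof=1)
             * (1.0 / nt + 1.0 / nv))[:, None]

    degenerate = np.all(resid == 0, axis=1)
    count = np.zeros(S)
    for start in range(0, n_resamples, chunk):
        b = min(chunk, n_resamples - start)
        idx_t = rng.integers(0, n, size=(S, b, nt))
        idx_v = rng.integers(0, n, size=(S, b, nv))
        rt = np.take_along_axis(resid[:, None, :], idx_t, axis=2)
        rv = np.take_along_axis(resid[:, None, :], idx_v, axis=2)
        tb = _welch_t(rt, rv, ridge)
        with np.errstate(invalid="ignore"):
            count += np.nansum(np.abs(tb) >= np.abs(t_obs)[:, None], axis=1)
    p = (1.0 + count) / (n_resamples + 1.0)

    if degenerate.any():
        means_differ = treated.mean(axis=1) != vehicle.mean(axis=1)
        p = np.where(degenerate, np.where(means_differ, 1.0 / (n_resamples + 1.0), 1.0), p)
    return p


def test_departures(
    series: DoseResponseSeries,
    fit: SplineFit | None = None,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-dose two-sided departure p-values against the vehicle group.

    Returns ``(p, effect)`` over the non-zero doses in ladder order, where
    ``effect`` is the signed difference of replicate means.  The bootstrap
    seed defaults to :func:`derive_test_seed` of the series labels, so the
    result is invariant to replicate ordering and reproducible across runs.
    """
    vehicle = series.vehicle
    treated_idx = np.nonzero(series.doses > 0)[0]
    if treated_idx.size == 0:
        raise ValueError("series has no non-zero dose to test")
    if seed is None:
        seed = derive_test_seed(series.chemical, series.endpoint)
    rng = np.random.default_rng(seed)

    effects = np.array([series.responses[i].mean() - vehicle.mean() for i in treated_idx])
    sizes = {series.responses[i].size for i in treated_idx}
    if len(sizes) == 1:
        block = np.stack([series.responses[i] for i in treated_idx])
        p = bootstrap_departure_p(block, vehicle, n_resamples, rng)
    else:  # ragged replicate counts: test dose by dose
        p = np.concatenate([
            bootstrap_departure_p(series.responses[i][None, :], vehicle, n_resamples, rng)
            for i in treated_idx
        ])
    return p, effects


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty_like(p)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def determine_noel_loel(
    doses: np.ndarray,
    p_values: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    effect: np.ndarray | None = None,
    holm: bool = False,
) -> NoelLoel:
    """Apply the NOEL/LOEL decision rule to per-dose p-values ordered by dose.

    LOEL = lowest dose with p <= alpha; NOEL = highest tested dose strictly
    below the LOEL (None when the LOEL is the lowest tested dose).  When no
    dose is significant the LOEL is None and the NOEL is the top dose.
    """
    doses = np.asarray(doses, dtype=float)
    p_values = np.asarray(p_values, dtype=float)
    if doses.shape != p_values.shape:
        raise ValueError("doses and p_values must align")
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p-values outside [0, 1]")
    if effect is None:
        effect = np.full_like(p_values, np.nan)
    p_used = _holm(p_values) if holm else p_values
    sig = np.nonzero(p_used <= alpha)[0]
    if sig.size == 0:
        return NoelLoel(loel=None, noel=float(doses[-1]), doses=doses,
                        per_dose_p=p_values, effect=effect, alpha=alpha)
    i = sig[0]
    loel = float(doses[i])
    noel = float(doses[i - 1]) if i > 0 else None
    return NoelLoel(loel=loel, noel=noel, doses=doses, per_dose_p=p_values,
                    effect=effect, alpha=alpha)


def analyse_series(
    series: DoseResponseSeries,
    alpha: float = DEFAULT_ALPHA,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int | None = None,
    holm: bool = False,
    lam: float | None = None,
) -> tuple[NoelLoel, SplineFit]:
    """Full dose-response analysis of one series: spline fit, departure
    tests, NOEL/LOEL decision."""
    fit = fit_spline(series, lam=lam)
    p, eff = test_departures(series, fit, n_resamples=n_resamples, seed=seed)
    result = determine_noel_loel(series.treated_doses, p, alpha=alpha,
                                 effect=eff, holm=holm)
    return result, fit


def mn_frequency(micronucleated: int | np.ndarray, scored: int | np.ndarray) -> np.ndarray | float:
    """Percent micronucleated binucleate cells: 100 * MN / scored."""
    micronucleated = np.asarray(micronucleated, dtype=float)
    scored = np.asarray(scored, dtype=float)
    if np.any(scored <= 0):
        raise ValueError("scored cell count must be positive")
    if np.any(micronucleated > scored):
        raise ValueError("micronucleated count exceeds cells scored")
    if np.any(micronucleated < 0):
        raise ValueError("negative micronucleated count")
    out = 100.0 * micronucleated / scored
    return float(out) if out.ndim == 0 else out
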