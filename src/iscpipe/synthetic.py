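"""Synthetic multi-endpoint carcinogenicity studies.

Generates complete per-chemical study bundles — CBMN counts with cell
counts for RPD, per-cell morphology areas, gated cell-cycle events,
qRT-PCR Cq values, densitometry band intensities and OCR/ECAR flux — with
the statistical structure the analysis stages assume, so the whole pipeline
is testable without laboratory data.

Effect curves are four-parameter Hill functions of dose (the simplest
monotone saturating family); an optional second Hill term with negative
sign supports biphasic responses (off by default).  Noise respects each
measurement's support: binomial for micronucleus counts,
Dirichlet-multinomial for phase counts, lognormal for areas, intensities
and flux.  One global seed expands into per-table child seeds by fixed
offsets, so each table can be regenerated independently and two runs with
the same seed are identical.

Chemical archetypes stand in for study compounds: ``GC``-class archetypes
carry a genotoxic fingerprint (micronucleus induction, G2 arrest, p53 and
p21 activation, nuclear-area increase), ``NGC``-class archetypes a
non-genotoxic one (no micronucleus induction, expression and cell-area
changes, quiescent flux shift), and ``inert`` archetypes are flat on every
endpoint.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "HillCurve",
    "ChemicalArchetype",
    "AssayDesign",
    "StudyBundle",
    "generate_cbmn",
    "generate_morphology",
    "generate_cellcycle",
    "generate_expression_and_densitometry",
    "generate_flux",
    "generate_study",
    "default_panel",
    "inert_archetype",
    "gc_archetype",
    "ngc_archetype",
]

# fixed child-seed offsets, one per generated table
_OFFSETS = {"cbmn": 11, "morphology": 12, "cellcycle": 13,
            "expression": 14, "densitometry": 15, "flux": 16}

ENDPOINT_EFFECT_KEYS = (
    "mn_percent", "cell_area_shift", "nuclear_area_shift", "g2_percent",
    "p53_fold", "phospho_p53_fold", "CDKN1A_fold", "CHKA_fold", "SGK1_fold",
    "ocr_fold", "ecar_fold",
)

# control centroids: basal OCR (pmol O2/min) and ECAR (mpH/min) of an
# untreated lymphoblastoid culture at assay density
CONTROL_OCR = 459.0
CONTROL_ECAR = 30.0
CONTROL_CELL_AREA_UM2 = 180.0     # median cell area, µm²
CONTROL_NUCLEAR_AREA_UM2 = 90.0   # median nuclear area, µm²
BASELINE_SIMPLEX = {"G1": 0.55, "S": 0.25, "G2": 0.20}
VEHICLE_DOUBLINGS = 2.0           # control doublings over treatment+recovery
SEED_PRE_COUNT = 1.0e5            # cells/ml at dosing
CQ_REFERENCE = 18.0               # ACTB quantification cycle
DCQ_BASELINE = 6.0                # target - reference Cq at vehicle
CQ_SD = 0.15                      # well-level Cq noise
BATCH_DCQ_SD = 0.30               # replicate-level (separate-day) dCq offset
DIRICHLET_CONCENTRATION = 300.0   # between-replicate tightness of phase props


@dataclass
class HillCurve:
    """Monotone saturating effect curve: value(d) = baseline +
    (max_effect - baseline) * d^h / (d^h + ec50^h), optionally minus a
    second (biphasic) Hill term."""

    baseline: float
    max_effect: float
    ec50: float
    hill_slope: float = 1.0
    biphasic_ec50: float | None = None
    biphasic_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.hill_slope <= 0:
            raise ValueError("hill_slope must be positive")

    @property
    def flat(self) -> bool:
        return self.max_effect == self.baseline and self.biphasic_amplitude == 0.0

    def value(self, dose: np.ndarray | float) -> np.ndarray | float:
        d = np.asarray(dose, dtype=float)
        h = self.hill_slope
        frac = np.where(d > 0, d ** h / (d ** h + self.ec50 ** h), 0.0)
        v = self.baseline + (self.max_effect - self.baseline) * frac
        if self.biphasic_ec50 is not None and self.biphasic_amplitude != 0.0:
            frac2 = np.where(d > 0, d ** h / (d ** h + self.biphasic_ec50 ** h), 0.0)
            v = v - self.biphasic_amplitude * frac2
        return float(v) if np.ndim(dose) == 0 else v


def flat_curve(level: float) -> HillCurve:
    return HillCurve(baseline=level, max_effect=level, ec50=1.0)


@dataclass
class ChemicalArchetype:
    """Synthetic stand-in for one test chemical.

    ``effects`` maps endpoint effect keys to Hill curves; ``cytotox_ec50``
    is the dose (µM) at which RPD falls to 50%.  ``replicate_cv`` is the
    between-replicate coefficient of variation applied multiplicatively;
    ``cell_level_sigma`` the log-scale SD of per-cell areas.
    """

    name: str
    mechanism_class: str  # GC | NGC | inert
    effects: dict[str, HillCurve]
    cytotox_ec50: float
    cytotox_slope: float = 1.5
    replicate_cv: float = 0.05
    cell_level_sigma: float = 0.35
    nuclear_level_sigma: float = 0.30

    def __post_init__(self) -> None:
        if self.mechanism_class not in ("GC", "NGC", "inert"):
            raise ValueError(f"unknown mechanism class {self.mechanism_class!r}")
        if self.cytotox_ec50 <= 0:
            raise ValueError("cytotox_ec50 must be positive")
        if not (0 <= self.replicate_cv < 1):
            raise ValueError("replicate_cv must lie in [0, 1)")
        if self.cell_level_sigma <= 0 or self.nuclear_level_sigma <= 0:
            raise ValueError("area sigmas must be positive")
        missing = set(ENDPOINT_EFFECT_KEYS) - set(self.effects)
        if missing:
            raise ValueError(f"archetype {self.name!r} lacks effect curves for {sorted(missing)}")
        if self.mechanism_class == "inert":
            for key, curve in self.effects.items():
                if not curve.flat:
                    raise ValueError(f"inert archetype has a non-flat {key} curve")

    def rpd_fraction(self, dose: np.ndarray | float) -> np.ndarray | float:
        """Expected RPD / 100 at a dose; 0.5 at cytotox_ec50 by construction."""
        d = np.asarray(dose, dtype=float)
        v = 1.0 / (1.0 + (d / self.cytotox_ec50) ** self.cytotox_slope)
        return float(v) if np.ndim(dose) == 0 else v


@dataclass
class AssayDesign:
    """Dose ladder and scoring depths shared by all generated tables."""

    doses: tuple[float, ...] = (0.0, 1.0, 3.16, 10.0, 31.6, 100.0)
    replicates: int = 3
    binucleates_per_replicate: int = 9000
    cellcycle_events_total: int = 36000
    cells_imaged_per_condition: int = 3000
    exposure_h: int = 23
    vehicle: str = "H2O"
    seed: int = 0

    def __post_init__(self) -> None:
        doses = tuple(float(d) for d in self.doses)
        if len(doses) == 0:
            raise ValueError("dose ladder is empty")
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError("doses must be strictly increasing")
        if 0.0 not in doses:
            raise ValueError("dose ladder must include 0 for the vehicle")
        self.doses = doses
        if self.replicates < 2:
            raise ValueError("at least 2 replicates required")
        for f in ("binucleates_per_replicate", "cellcycle_events_total",
                  "cells_imaged_per_condition"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if self.exposure_h not in (4, 23):
            raise ValueError("exposure_h must be 4 or 23")
        if self.vehicle not in ("H2O", "DMSO"):
            raise ValueError("vehicle must be H2O or DMSO")

    @property
    def stratum(self) -> str:
        return f"{self.vehicle}_TK6_{self.exposure_h}h"


def _child_rng(seed: int, table: str, name: str) -> np.random.Generator:
    return np.random.default_rng([
        int(seed) & 0x7FFFFFFF,
        _OFFSETS[table],
        zlib.crc32(name.encode()) & 0x7FFFFFFF,
    ])


def _rep_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray | float:
    """Multiplicative lognormal replicate noise with unit median and the
    requested coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = float(np.sqrt(np.log1p(cv ** 2)))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def generate_cbmn(archetype: ChemicalArchetype, design: AssayDesign,
                  seed: int | None = None) -> pd.DataFrame:
    """CBMN scoring table: micronucleated counts over binucleates scored,
    plus pre/post cell counts for the parallel RPD measurement.

    The micronucleated count at each dose/replicate is binomial over
    ``binucleates_per_replicate`` cells with probability given by the MN
    Hill curve (with multiplicative replicate noise, clamped to [0, 1] with
    a warning if noise pushes it outside); post-treatment cell counts
    decline so that expected RPD is 50% at ``cytotox_ec50``.
    """
    seed = design.seed if seed is None else seed
    rng = _child_rng(seed, "cbmn", archetype.name)
    mn_curve = archetype.effects["mn_percent"]
    rows = []
    for dose in design.doses:
        p_mean = float(mn_curve.value(dose)) / 100.0
        for rep in range(1, design.replicates + 1):
            p = p_mean * _rep_factor(rng, archetype.replicate_cv)
            if p > 1.0 or p < 0.0:
                warnings.warn("MN probability outside [0, 1] after noise; clamped",
                              stacklevel=2)
                p = min(max(p, 0.0), 1.0)
            mn = int(rng.binomial(design.binucleates_per_replicate, p))
            pre = SEED_PRE_COUNT
            doublings = VEHICLE_DOUBLINGS * float(archetype.rpd_fraction(dose))
            post = pre * 2.0 ** doublings * _rep_factor(rng, archetype.replicate_cv)
            rows.append({
                "chemical": archetype.name, "dose_uM": dose, "replicate": rep,
                "binucleates_scored": design.binucleates_per_replicate,
                "micronucleated": mn,
                "pre_count": pre, "post_count": post,
            })
    return pd.DataFrame(rows)


def generate_morphology(archetype: ChemicalArchetype, design: AssayDesign,
                        seed: int | None = None) -> pd.DataFrame:
    """Per-cell area table: lognormal cell and nuclear areas whose log-scale
    location is shifted by the archetype's Hill term (sign per archetype:
    alkylator-like up, most NGC-like down); nuclear < cell area is enforced
    per cell by resampling offending pairs."""
    seed = design.seed if seed is None else seed
    rng = _child_rng(seed, "morphology", archetype.name)
    cshift = archetype.effects["cell_area_shift"]
    nshift = archetype.effects["nuclear_area_shift"]
    n_per_rep = design.cells_imaged_per_condition // design.replicates
    frames = []
    for dose in design.doses:
        mu_c = np.log(CONTROL_CELL_AREA_UM2) + float(cshift.value(dose))
        mu_n = np.log(CONTROL_NUCLEAR_AREA_UM2) + float(nshift.value(dose))
        for rep in range(1, design.replicates + 1):
            cell = rng.lognormal(mu_c, archetype.cell_level_sigma, size=n_per_rep)
            nuc = rng.lognormal(mu_n, archetype.nuclear_level_sigma, size=n_per_rep)
            for _ in range(100):
                bad = nuc >= cell
                if not bad.any():
                    break
                cell[bad] = rng.lognormal(mu_c, archetype.cell_level_sigma, size=bad.sum())
                nuc[bad] = rng.lognormal(mu_n, archetype.nuclear_level_sigma, size=bad.sum())
            else:
                nuc = np.minimum(nuc, 0.95 * cell)
            frames.append(pd.DataFrame({
                "chemical": archetype.name, "dose_uM": dose, "replicate": rep,
                "stratum": design.stratum,
                "cell_area_um2": cell, "nuclear_area_um2": nuc,
            }))
    return pd.concat(frames, ignore_index=True)


def generate_cellcycle(archetype: ChemicalArchetype, design: AssayDesign,
                       seed: int | None = None) -> pd.DataFrame:
    """Gated event counts over {G1, S, G2}: Dirichlet-multinomial draws whose
    mean G2 proportion follows the archetype's G2 Hill curve, with G1 and S
    depleted proportionally; totals match the design."""
    seed = design.seed if seed is None else seed
    rng = _child_rng(seed, "cellcycle", archetype.name)
    g2_curve = archetype.effects["g2_percent"]
    events_per_rep = design.cellcycle_events_total // design.replicates
    base_g1, base_s = BASELINE_SIMPLEX["G1"], BASELINE_SIMPLEX["S"]
    rows = []
    for dose in design.doses:
        g2 = float(g2_curve.value(dose)) / 100.0
        if not (0.0 < g2 < 1.0):
            raise ValueError("G2 target proportion outside (0, 1)")
        rest = 1.0 - g2
        props = np.array([rest * base_g1 / (base_g1 + base_s),
                          rest * base_s / (base_g1 + base_s), g2])
        conc = DIRICHLET_CONCENTRATION * props
        if np.any(conc <= 0):
            raise ValueError("non-positive Dirichlet concentration")
        for rep in range(1, design.replicates + 1):
            theta = rng.dirichlet(conc)
            counts = rng.multinomial(events_per_rep, theta)
            rows.append({
                "chemical": archetype.name, "dose_uM": dose, "replicate": rep,
                "g1_events": int(counts[0]), "s_events": int(counts[1]),
                "g2_events": int(counts[2]),
            })
    return pd.DataFrame(rows)


def generate_expression_and_densitometry(
    archetype: ChemicalArchetype, design: AssayDesign, seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """qRT-PCR Cq table (CDKN1A, CHKA, SGK1 vs ACTB) and densitometry band
    intensities (p53, phospho-p53 vs beta-actin loading).

    Expression: the target Cq shifts by -log2(fold(dose)); wells carry
    Gaussian Cq noise and replicates carry a shared separate-day dCq offset
    (removed downstream by mean-centering).  Densitometry: target intensity
    = loading x fold(dose) with multiplicative lognormal noise.
    """
    seed = design.seed if seed is None else seed
    rng_e = _child_rng(seed, "expression", archetype.name)
    rng_d = _child_rng(seed, "densitometry", archetype.name)

    expr_rows = []
    for gene in ("CDKN1A", "CHKA", "SGK1"):
        curve = archetype.effects[f"{gene}_fold"]
        batch = rng_e.normal(0.0, BATCH_DCQ_SD, size=design.replicates)
        for dose in design.doses:
            fold = float(curve.value(dose))
            if fold <= 0:
                raise ValueError("expression fold curve must stay positive")
            for rep in range(1, design.replicates + 1):
                cq_ref = CQ_REFERENCE + rng_e.normal(0.0, CQ_SD)
                cq_tgt = (cq_ref + DCQ_BASELINE - np.log2(fold)
                          + batch[rep - 1] + rng_e.normal(0.0, CQ_SD))
                expr_rows.append({
                    "chemical": archetype.name, "gene": gene, "dose_uM": dose,
                    "replicate": rep, "cq_target": cq_tgt, "cq_reference": cq_ref,
                })

    dens_rows = []
    for target in ("p53", "phospho_p53"):
        curve = archetype.effects[f"{target}_fold"]
        for dose in design.doses:
            fold = float(curve.value(dose))
            if fold <= 0:
                raise ValueError("densitometry fold curve must stay positive")
            for rep in range(1, design.replicates + 1):
                loading = 1000.0 * _rep_factor(rng_d, max(archetype.replicate_cv, 1e-12))
                tgt = loading * fold * _rep_factor(rng_d, max(archetype.replicate_cv, 1e-12))
                dens_rows.append({
                    "chemical": archetype.name, "target": target, "dose_uM": dose,
                    "replicate": rep, "target_intensity": tgt,
                    "loading_intensity": loading,
                })
    return pd.DataFrame(expr_rows), pd.DataFrame(dens_rows)


def generate_flux(archetype: ChemicalArchetype, design: AssayDesign,
                  seed: int | None = None) -> pd.DataFrame:
    """Basal OCR/ECAR measurements around the control centroid, shifted along
    the archetype's energy-phenotype direction; zero noise and flat curves
    reproduce the centroid exactly."""
    seed = design.seed if seed is None else seed
    rng = _child_rng(seed, "flux", archetype.name)
    ocr_curve = archetype.effects["ocr_fold"]
    ecar_curve = archetype.effects["ecar_fold"]
    rows = []
    for dose in design.doses:
        ocr_mu = CONTROL_OCR * float(ocr_curve.value(dose))
        ecar_mu = CONTROL_ECAR * float(ecar_curve.value(dose))
        for rep in range(1, design.replicates + 1):
            rows.append({
                "chemical": archetype.name, "dose_uM": dose, "replicate": rep,
                "ocr_pmol_min": ocr_mu * _rep_factor(rng, archetype.replicate_cv),
                "ecar_mph_min": ecar_mu * _rep_factor(rng, archetype.replicate_cv),
            })
    return pd.DataFrame(rows)


@dataclass
class StudyBundle:
    """All generated tables of a multi-chemical study, plus a design echo."""

    cbmn: pd.DataFrame
    morphology: pd.DataFrame
    cellcycle: pd.DataFrame
    expression: pd.DataFrame
    densitometry: pd.DataFrame
    flux: pd.DataFrame
    archetypes: dict[str, str] = field(default_factory=dict)  # name -> class
    design: AssayDesign | None = None

    TABLE_NAMES = ("cbmn", "morphology", "cellcycle", "expression",
                   "densitometry", "flux")

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in self.TABLE_NAMES}

    def for_chemical(self, name: str) -> dict[str, pd.DataFrame]:
        return {t: df[df["chemical"] == name].reset_index(drop=True)
                for t, df in self.tables().items()}

    def to_csv(self, directory) -> dict[str, str]:
        """Write every table as ``<name>.csv``; byte-identical for a fixed
        (archetypes, design, seed)."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in self.tables().items():
            p = directory / f"{name}.csv"
            df.to_csv(p, index=False, float_format="%.10g", lineterminator="\n")
            paths[name] = str(p)
        return paths


def generate_study(archetypes: list[ChemicalArchetype], design: AssayDesign,
                   seed: int | None = None) -> StudyBundle:
    """One complete bundle per chemical, concatenated into tidy study tables."""
    if not archetypes:
        raise ValueError("at least one archetype required")
    names = [a.name for a in archetypes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate chemical names in archetype list")
    seed = design.seed if seed is None else seed
    parts: dict[str, list[pd.DataFrame]] = {t: [] for t in StudyBundle.TABLE_NAMES}
    for arch in archetypes:
        parts["cbmn"].append(generate_cbmn(arch, design, seed))
        parts["morphology"].append(generate_morphology(arch, design, seed))
        parts["cellcycle"].append(generate_cellcycle(arch, design, seed))
        expr, dens = generate_expression_and_densitometry(arch, design, seed)
        parts["expression"].append(expr)
        parts["densitometry"].append(dens)
        parts["flux"].append(generate_flux(arch, design, seed))
    return StudyBundle(
        **{t: pd.concat(v, ignore_index=True) for t, v in parts.items()},
        archetypes={a.name: a.mechanism_class for a in archetypes},
        design=design,
    )


# ---------------------------------------------------------------------------
# archetype factories and the default study panel


def _flat_effects() -> dict[str, HillCurve]:
    return {
        "mn_percent": flat_curve(0.8),
        "cell_area_shift": flat_curve(0.0),
        "nuclear_area_shift": flat_curve(0.0),
        "g2_percent": flat_curve(100.0 * BASELINE_SIMPLEX["G2"]),
        "p53_fold": flat_curve(1.0),
        "phospho_p53_fold": flat_curve(1.0),
        "CDKN1A_fold": flat_curve(1.0),
        "CHKA_fold": flat_curve(1.0),
        "SGK1_fold": flat_curve(1.0),
        "ocr_fold": flat_curve(1.0),
        "ecar_fold": flat_curve(1.0),
    }


def inert_archetype(name: str = "inert", cytotox_ec50: float = 1.0e6,
                    replicate_cv: float = 0.05) -> ChemicalArchetype:
    """A chemical with no effect on any endpoint (negative control)."""
    return ChemicalArchetype(name=name, mechanism_class="inert",
                             effects=_flat_effects(), cytotox_ec50=cytotox_ec50,
                             replicate_cv=replicate_cv)


def gc_archetype(
    name: str,
    mn_max: float = 3.5,
    mn_ec50: float = 20.0,
    g2_max: float = 40.0,
    p53_max: float = 2.5,
    phospho_max: float = 3.0,
    cdkn1a_max: float = 4.0,
    chka_max: float = 1.5,
    sgk1_max: float = 2.0,
    nuclear_shift: float = 0.25,
    cell_shift: float = 0.15,
    ocr_max: float = 1.4,
    ecar_max: float = 1.3,
    cytotox_ec50: float = 50.0,
    signalling_ec50: float = 25.0,
    expression_ec50: float = 10.0,
) -> ChemicalArchetype:
    """Genotoxic-carcinogen fingerprint: micronucleus induction, G2 arrest,
    p53/p21 activation, nuclear-area increase, mildly energetic flux.

    The expression half-maximum sits below the micronucleus half-maximum,
    emulating transcriptional responses emerging at sub-clastogenic doses.
    """
    eff = _flat_effects()
    eff["mn_percent"] = HillCurve(0.8, mn_max, mn_ec50, 1.5)
    eff["g2_percent"] = HillCurve(20.0, g2_max, signalling_ec50, 1.5)
    eff["p53_fold"] = HillCurve(1.0, p53_max, signalling_ec50, 1.5)
    eff["phospho_p53_fold"] = HillCurve(1.0, phospho_max, signalling_ec50, 1.5)
    eff["CDKN1A_fold"] = HillCurve(1.0, cdkn1a_max, expression_ec50, 1.5)
    eff["CHKA_fold"] = HillCurve(1.0, chka_max, expression_ec50, 1.5)
    eff["SGK1_fold"] = HillCurve(1.0, sgk1_max, expression_ec50, 1.5)
    eff["nuclear_area_shift"] = HillCurve(0.0, nuclear_shift, signalling_ec50, 1.5)
    eff["cell_area_shift"] = HillCurve(0.0, cell_shift, signalling_ec50, 1.5)
    eff["ocr_fold"] = HillCurve(1.0, ocr_max, signalling_ec50, 1.5)
    eff["ecar_fold"] = HillCurve(1.0, ecar_max, signalling_ec50, 1.5)
    return ChemicalArchetype(name=name, mechanism_class="GC", effects=eff,
                             cytotox_ec50=cytotox_ec50)


def ngc_archetype(
    name: str,
    cell_shift: float = -0.25,
    nuclear_shift: float = -0.10,
    chka_max: float = 1.8,
    cdkn1a_max: float = 1.0,
    sgk1_max: float = 1.0,
    p53_max: float = 1.0,
    g2_max: float = 20.0,
    ocr_max: float = 0.5,
    ecar_max: float = 0.6,
    cytotox_ec50: float = 60.0,
    effect_ec50: float = 25.0,
) -> ChemicalArchetype:
    """Non-genotoxic fingerprint: flat micronucleus response, moderate
    expression changes, cell-area reduction, quiescent flux shift."""
    eff = _flat_effects()
    eff["cell_area_shift"] = HillCurve(0.0, cell_shift, effect_ec50, 1.5)
    eff["nuclear_area_shift"] = HillCurve(0.0, nuclear_shift, effect_ec50, 1.5)
    eff["CHKA_fold"] = HillCurve(1.0, chka_max, effect_ec50, 1.5)
    eff["CDKN1A_fold"] = HillCurve(1.0, cdkn1a_max, effect_ec50, 1.5)
    eff["SGK1_fold"] = HillCurve(1.0, sgk1_max, effect_ec50, 1.5)
    eff["p53_fold"] = HillCurve(1.0, p53_max, effect_ec50, 1.5)
    eff["g2_percent"] = HillCurve(20.0, g2_max, effect_ec50, 1.5)
    eff["ocr_fold"] = HillCurve(1.0, ocr_max, effect_ec50, 1.5)
    eff["ecar_fold"] = HillCurve(1.0, ecar_max, effect_ec50, 1.5)
    return ChemicalArchetype(name=name, mechanism_class="NGC", effects=eff,
                             cytotox_ec50=cytotox_ec50)


def default_panel() -> list[ChemicalArchetype]:
    """The default eight-chemical study panel: four GC-like and four
    NGC-like archetypes with distinct fingerprints.

    The GC group spans two alkylator-like profiles (areas up), an
    oxidant-like profile (areas down, glycolytic flux) and a weaker
    adduct-forming profile; the NGC group spans phthalate-, metal-, dioxin-
    and carbamate-like profiles.  The metal-like archetype carries G2
    arrest and mild p53 activation without micronucleus induction; the
    carbamate-like archetype never reaches 50% cytotoxicity, so its
    reference dose is the top tested dose.
    """
    panel = [
        gc_archetype("gc_alkylator_a"),
        gc_archetype("gc_alkylator_b", mn_max=4.5, mn_ec50=30.0, cdkn1a_max=5.0,
                     nuclear_shift=0.30, cell_shift=0.20, cytotox_ec50=40.0),
        gc_archetype("gc_oxidant", mn_max=3.0, mn_ec50=15.0, phospho_max=2.5,
                     nuclear_shift=-0.30, cell_shift=-0.20,
                     ocr_max=0.85, ecar_max=1.5, sgk1_max=2.5),
        gc_archetype("gc_adduct", mn_max=2.5, mn_ec50=35.0, p53_max=2.0,
                     phospho_max=2.2, chka_max=1.8, g2_max=35.0,
                     ocr_max=1.3, ecar_max=1.25, cytotox_ec50=70.0),
        ngc_archetype("ngc_phthalate"),
        ngc_archetype("ngc_metal", p53_max=1.8, cdkn1a_max=2.0, g2_max=35.0,
                      ocr_max=0.34, ecar_max=0.56, cell_shift=-0.30),
        ngc_archetype("ngc_dioxin", cell_shift=-0.05, nuclear_shift=-0.02,
                      chka_max=2.2, sgk1_max=1.6, ocr_max=1.1, ecar_max=0.95,
                      cytotox_ec50=45.0),
        ngc_archetype("ngc_carbamate", sgk1_max=0.6, cdkn1a_max=0.7,
                      cytotox_ec50=5.0e5),
    ]
    return panel
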