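"""Study I/O, configuration and pipeline orchestration.

CSV is the single interchange format; units are embedded in column names
(``dose_uM``, ``cell_area_um2``, ``ocr_pmol_min``).  Readers validate each
table's schema and name the offending file and column on failure.

:func:`run_pipeline` executes the full analysis sequence on a study bundle:
RPD and reference-dose selection, per-endpoint dose-response NOEL/LOELs,
quintile morphology, G2-arrest detection, expression/densitometry folds,
bioenergetic phenotyping and clustering, and ISC scoring and ranking.  Every
stage is seeded from the study configuration, so outputs regenerate
byte-identically from (inputs, config, seed); a manifest records a hash of
each artifact.  Per-stage failures are isolated: a failing assay stage is
reported and its endpoints enter the score at baseline with a missing flag.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import bioenergetics, integration, morphology
from .cell_cycle import detect_arrest
from .cytotoxicity import compute_rpd, select_reference_concentration
from .dose_response import (DoseResponseSeries, analyse_series,
                            derive_test_seed, mn_frequency)
from .signalling import densitometry_fold, mean_center, relative_expression
from .synthetic import StudyBundle

__all__ = ["StudyConfig", "read_study", "write_study", "run_pipeline",
           "TABLE_SCHEMAS"]

logger = logging.getLogger("iscpipe")

TABLE_SCHEMAS: dict[str, list[str]] = {
    "cbmn": ["chemical", "dose_uM", "replicate", "binucleates_scored",
             "micronucleated", "pre_count", "post_count"],
    "morphology": ["chemical", "dose_uM", "replicate", "stratum",
                   "cell_area_um2", "nuclear_area_um2"],
    "cellcycle": ["chemical", "dose_uM", "replicate", "g1_events",
                  "s_events", "g2_events"],
    "expression": ["chemical", "gene", "dose_uM", "replicate", "cq_target",
                   "cq_reference"],
    "densitometry": ["chemical", "target", "dose_uM", "replicate",
                     "target_intensity", "loading_intensity"],
    "flux": ["chemical", "dose_uM", "replicate", "ocr_pmol_min",
             "ecar_mph_min"],
}


class StudyConfig(BaseModel):
    """Validated pipeline configuration."""

    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    n_resamples: int = Field(default=2000, ge=100)
    seed: int = 0
    holm: bool = False
    reference_rule: str = "interpolated"  # or "nearest"
    phenotype_tolerance: float = Field(default=0.10, ge=0.0, lt=1.0)
    seahorse_mode: str = "geometric"      # or "ocr_only"
    weights: dict[str, float] | None = None
    group_scales: dict[str, float] | None = None
    scaling_groups: dict[str, str] | None = None
    paths: dict[str, str] | None = None


def read_study(paths: dict[str, str] | str | Path,
               config: StudyConfig | None = None) -> StudyBundle:
    """Read and schema-validate study tables into a bundle.

    ``paths`` maps table names to CSV files, or is a directory containing
    ``<table>.csv`` for every table.  Numeric columns (doses, counts,
    intensities) are coerced to float — ``"1e2"`` parses as 100 µM — and a
    missing column raises an error naming the file and column.
    """
    if isinstance(paths, (str, Path)):
        directory = Path(paths)
        paths = {t: str(directory / f"{t}.csv") for t in TABLE_SCHEMAS}
    tables: dict[str, pd.DataFrame] = {}
    for name, schema in TABLE_SCHEMAS.items():
        if name not in paths:
            raise ValueError(f"no path supplied for the {name!r} table")
        df = pd.read_csv(paths[name])
        for col in schema:
            if col not in df.columns:
                raise ValueError(
                    f"{paths[name]}: missing required column {col!r}")
        for col in schema:
            if col in ("chemical", "gene", "target", "stratum"):
                continue
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
                row = int(bad[0]) if len(bad) else -1
                raise ValueError(
                    f"{paths[name]}: column {col!r}, row {row}: "
                    f"non-numeric value") from exc
        logger.info("read %s: %d rows", paths[name], len(df))
        tables[name] = df
    return StudyBundle(**tables)


def write_study(bundle: StudyBundle, directory: str | Path) -> dict[str, str]:
    """Export every bundle table as CSV (delegates to the bundle)."""
    return bundle.to_csv(directory)


def _sha256(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _json_safe(x):
    if isinstance(x, dict):
        return {str(k): _json_safe(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_json_safe(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return [_json_safe(v) for v in x.tolist()]
    return x


def _series_from_groups(df: pd.DataFrame, value_col: str, endpoint: str,
                        chemical: str) -> DoseResponseSeries:
    doses, groups = [], []
    for dose, grp in df.groupby("dose_uM", sort=True):
        doses.append(float(dose))
        groups.append(grp[value_col].to_numpy(dtype=float))
    return DoseResponseSeries(endpoint=endpoint, chemical=chemical,
                              doses=np.asarray(doses), responses=groups)


def _analyse(series: DoseResponseSeries, config: StudyConfig):
    seed = derive_test_seed(series.chemical, series.endpoint, config.seed)
    result, _fit = analyse_series(series, alpha=config.alpha,
                                  n_resamples=config.n_resamples, seed=seed,
                                  holm=config.holm)
    return result


def run_pipeline(bundle: StudyBundle, config: StudyConfig | None = None) -> dict:
    """Run the full multi-endpoint analysis on a study bundle.

    Returns a JSON-serialisable report: per chemical the RPD curve and
    reference dose, per-endpoint NOEL/LOELs, significant morphology
    quintiles, G2-arrest flag, energy phenotype per dose, the ISC profile;
    panel-wide the ranking, the flux cluster tree and a manifest of artifact
    hashes.
    """
    config = config or StudyConfig()
    chemicals = sorted(bundle.cbmn["chemical"].unique())
    report: dict = {"chemicals": {}, "config": config.model_dump()}
    profiles = []

    for chem in chemicals:
        tables = bundle.for_chemical(chem)
        entry: dict = {"errors": {}}

        # --- cytotoxicity: RPD curve and reference concentration
        cb = tables["cbmn"]
        curve = compute_rpd(cb[cb["dose_uM"] > 0], cb[cb["dose_uM"] == 0])
        ref_dose, basis = select_reference_concentration(
            curve, rule=config.reference_rule)
        entry["rpd"] = {"doses": curve.doses, "rpd": curve.rpd}
        entry["reference_dose"] = ref_dose
        entry["basis"] = basis

        # --- micronucleus dose-response
        try:
            cb = cb.assign(mn_pct=mn_frequency(
                cb["micronucleated"].to_numpy(), cb["binucleates_scored"].to_numpy()))
            mn_res = _analyse(_series_from_groups(cb, "mn_pct", "MN", chem), config)
            entry["mn"] = mn_res.to_dict()
        except Exception as exc:  # stage isolation
            logger.exception("%s: CBMN stage failed", chem)
            entry["errors"]["mn"] = str(exc)
            tables["cbmn"] = None

        # --- morphology quintiles
        try:
            cells = tables["morphology"]
            controls = cells[cells["dose_uM"] == 0]
            stratum = str(controls["stratum"].iloc[0])
            entry["morphology"] = {}
            for measure in morphology.MEASURES:
                thr = morphology.derive_thresholds(controls, measure, stratum,
                                                   seed=config.seed)
                cats = {}
                for cat in morphology.CATEGORIES:
                    seed = derive_test_seed(chem, f"{measure}:{cat}", config.seed)
                    res = morphology.occupancy_dose_response(
                        cells, thr, cat, chemical=chem, alpha=config.alpha,
                        n_resamples=config.n_resamples, seed=seed)
                    cats[cat] = res.to_dict()
                entry["morphology"][measure] = {
                    "thresholds": thr.cuts, "n_control": thr.n_control,
                    "categories": cats,
                    "n_significant": sum(1 for c in cats.values()
                                         if c["loel"] is not None),
                }
        except Exception as exc:
            logger.exception("%s: morphology stage failed", chem)
            entry["errors"]["morphology"] = str(exc)
            tables["morphology"] = None

        # --- cell cycle
        try:
            arrest = detect_arrest(
                tables["cellcycle"], chemical=chem, alpha=config.alpha,
                n_resamples=config.n_resamples,
                seed=derive_test_seed(chem, "cellcycle", config.seed))
            entry["cellcycle"] = {
                "arrest": arrest.arrest, "g2_loel": arrest.g2_loel,
                "per_phase": {ph: r.to_dict() for ph, r in arrest.per_phase.items()},
            }
        except Exception as exc:
            logger.exception("%s: cell-cycle stage failed", chem)
            entry["errors"]["cellcycle"] = str(exc)
            tables["cellcycle"] = None

        # --- expression (mean-centered) and densitometry dose-responses
        try:
            entry["expression"] = {}
            for gene, sub in tables["expression"].groupby("gene"):
                folded = mean_center(relative_expression(sub))
                series = _series_from_groups(folded, "centered_log2",
                                             f"expr:{gene}", chem)
                entry["expression"][gene] = _analyse(series, config).to_dict()
        except Exception as exc:
            logger.exception("%s: expression stage failed", chem)
            entry["errors"]["expression"] = str(exc)
            tables["expression"] = None
        try:
            entry["densitometry"] = {}
            for target, sub in tables["densitometry"].groupby("target"):
                folded = densitometry_fold(sub, sub[sub["dose_uM"] == 0])
                folded = folded.assign(log_fold=np.log(folded["fold"]))
                series = _series_from_groups(folded, "log_fold",
                                             f"dens:{target}", chem)
                entry["densitometry"][target] = _analyse(series, config).to_dict()
        except Exception as exc:
            logger.exception("%s: densitometry stage failed", chem)
            entry["errors"]["densitometry"] = str(exc)
            tables["densitometry"] = None

        # --- bioenergetics phenotype per dose
        try:
            fx = tables["flux"]
            veh = fx[fx["dose_uM"] == 0]
            entry["flux"] = {}
            for dose in sorted(d for d in fx["dose_uM"].unique() if d > 0):
                ocr_f, ecar_f = bioenergetics.flux_folds(
                    fx[fx["dose_uM"] == dose], veh)
                ph = bioenergetics.classify_phenotype(
                    ocr_f, ecar_f, tolerance=config.phenotype_tolerance)
                entry["flux"][float(dose)] = {
                    "label": ph.label, "ocr_fold": ph.ocr_fold,
                    "ecar_fold": ph.ecar_fold,
                }
        except Exception as exc:
            logger.exception("%s: flux stage failed", chem)
            entry["errors"]["flux"] = str(exc)
            tables["flux"] = None

        # --- ISC profile at the reference dose
        fcs = integration.extract_fold_changes(
            chem, ref_dose, basis,
            cbmn=tables["cbmn"], morphology_cells=tables["morphology"],
            cellcycle=tables["cellcycle"], densitometry=tables["densitometry"],
            expression=tables["expression"], flux=tables["flux"],
            seahorse_mode=config.seahorse_mode)
        profile = integration.build_profile(
            fcs, weights=config.weights, group_scales=config.group_scales,
            scaling_groups=config.scaling_groups)
        profiles.append(profile)
        entry["isc"] = profile.to_dict()
        report["chemicals"][chem] = entry

    # --- panel-wide: ranking and flux clustering
    ranking = integration.rank_chemicals({p.chemical: p.total for p in profiles})
    rank_of = dict(zip(ranking["chemical"], ranking["rank"]))
    for p in profiles:
        p.rank = int(rank_of[p.chemical])
        report["chemicals"][p.chemical]["isc"]["rank"] = p.rank
    report["ranking"] = ranking.to_dict(orient="records")

    points = (bundle.flux.groupby(["chemical", "dose_uM"], as_index=False)
              [["ocr_pmol_min", "ecar_mph_min"]].mean())
    points = points[points["dose_uM"] > 0]
    points["condition"] = (points["chemical"] + "@"
                           + points["dose_uM"].map("{:g}".format))
    if len(points) >= 2:
        clus = bioenergetics.cluster_profiles(points)
        report["flux_clustering"] = {
            "conditions": clus.conditions,
            "labels": clus.labels.tolist(),
            "newick": clus.newick,
        }

    report = _json_safe(report)
    report["manifest"] = {
        "report_hash": _sha256({k: v for k, v in report.items() if k != "manifest"}),
        "seed": config.seed,
    }
    return report
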