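"""End-to-end orchestration: plates or site table → summary → biomass report.

`run_pipeline` strings the stages together the way the survey analysis runs:
quantify plates (if given) → censored summary statistics → one outlier
screening pass with recomputation → basin comparison → covariate model table
→ mass-balance biomass estimate. Results are returned as a plain dict (JSON-
serialisable) and optionally written as CSV + JSON; a human-readable log of
each stage is collected in ``report['log']``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import censored as cs
from .biomass import estimate_biomass, lab_calibration
from .config import RunConfig
from .io import write_table
from .qpcr import quantify_plates

REGRESSION_COVARIATES = [
    "water_temperature",
    "secchi_depth",
    "water_depth",
    "tds",
    "tsm",
    "chl_a",
]


def summarize_sites(site_table: pd.DataFrame, config: RunConfig) -> dict:
    """Censored summary with a single outlier screen and recomputation."""
    conc = site_table["edna_concentration"].to_numpy(dtype=float)
    ids = site_table["site_id"].to_numpy()
    data = cs.CensoredData.from_concentrations(conc, config.lod)
    fit0 = cs.fit_censored_lognormal(data)
    screen = cs.detect_outliers(conc, ids, fit0, config.outlier_sd_multiplier)
    keep = ~screen["mask"]
    removed = screen["flagged_site_ids"]
    data1 = cs.CensoredData.from_concentrations(conc[keep], config.lod)
    fit = cs.fit_censored_lognormal(data1)
    ci = cs.mean_confidence_interval(data1, level=config.ci_level)
    return {
        "initial": {"mean": fit0.mean, "median": fit0.median, "sd": fit0.sd},
        "outliers_removed": removed,
        "outlier_bounds": [screen["lower"], screen["upper"]],
        "n_sites": int(keep.sum()),
        "n_nondetect": int(data1.n_censored),
        "mean": fit.mean,
        "median": fit.median,
        "sd": fit.sd,
        "mu": fit.mu,
        "sigma": fit.sigma,
        "lcl": ci.lcl,
        "ucl": ci.ucl,
        "ci_level": config.ci_level,
        "ci_method": ci.method,
        "keep_mask": keep,
    }


def compare_basins(site_table: pd.DataFrame, config: RunConfig) -> dict:
    sub = site_table.dropna(subset=["basin"])
    data = cs.CensoredData.from_concentrations(
        sub["edna_concentration"].to_numpy(dtype=float), config.lod
    )
    test = cs.compare_groups(data, sub["basin"].to_numpy())
    return {"chi2": test.chi2, "df": test.df, "p": test.p,
            "group_means_log": test.group_means_log}


def regression_model_table(
    site_table: pd.DataFrame,
    config: RunConfig,
    covariates: list[str] | None = None,
    transforms: dict[str, str] | None = None,
    explicit_models: list[list[str]] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Fit every admissible covariate model and rank by AICc.

    Collinear pairs (pairwise VIF above the configured threshold) are never
    combined. All models are fitted on the complete-case rows so AICc values
    are comparable.
    """
    covariates = [c for c in (covariates or REGRESSION_COVARIATES)
                  if c in site_table.columns]
    rows = site_table.dropna(subset=covariates)
    X = rows[covariates]
    vifs = cs.vif(X)
    forbidden = cs.collinear_pairs(X, threshold=config.vif_threshold)
    models = cs.enumerate_models(covariates, forbidden, explicit=explicit_models)
    data = cs.CensoredData.from_concentrations(
        rows["edna_concentration"].to_numpy(dtype=float), config.lod
    )
    fits = {}
    normality = {}
    for subset in models:
        label = cs.model_label(subset)
        covs = rows[list(subset)] if subset else None
        fit = cs.fit_censored_regression(data, covs, transforms)
        fits[label] = fit
        if fit.residuals.size >= 5 and np.std(fit.residuals) > 0:
            w, p = cs.shapiro_francia(fit.residuals)
            normality[label] = {"w_prime": w, "p": p}
    table = cs.aicc_table(fits)
    info = {
        "n_rows": int(len(rows)),
        "vif": {k: float(v) for k, v in vifs.items()},
        "collinear_pairs": [list(p) for p in forbidden],
        "normality": normality,
    }
    return table, info


def run_pipeline(
    config: RunConfig,
    site_table: pd.DataFrame | None = None,
    plate_tables: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run every stage available for the supplied inputs.

    Give ``plate_tables`` to start from raw qPCR wells, or ``site_table`` to
    start from per-site concentrations (a site table produced by
    quantification, or loaded from CSV). With both, the quantified
    concentrations replace the site table's eDNA column.
    """
    if site_table is None and plate_tables is None:
        raise ValueError("need a site table and/or plate tables")
    report: dict = {"log": []}
    log = report["log"].append
    if plate_tables is not None:
        try:
            sites_q, qc = quantify_plates(plate_tables, config)
        except ValueError as err:
            raise ValueError(f"quantification stage failed: {err}") from err
        report["quantification"] = qc
        log(f"quantified {len(sites_q)} sites from "
            f"{plate_tables['plate_id'].nunique()} plates")
        if site_table is None:
            site_table = sites_q.rename(
                columns={"site_concentration": "edna_concentration"}
            )
        else:
            site_table = site_table.drop(
                columns=["edna_concentration"], errors="ignore"
            ).merge(
                sites_q[["site_id", "site_concentration"]], on="site_id"
            ).rename(columns={"site_concentration": "edna_concentration"})

    conc = site_table["edna_concentration"].to_numpy(dtype=float)
    if not (conc > 0).any():
        warnings.warn("all sites are non-detects; biomass reported as 0",
                      stacklevel=2)
        report["summary"] = {"n_sites": len(conc), "n_nondetect": len(conc)}
        report["biomass"] = {"biomass_kg": [0.0, 0.0, 0.0],
                             "biomass_tonnes": [0.0, 0.0, 0.0],
                             "density_kg_per_ha": 0.0}
        log("degenerate input: every site censored")
        return report

    try:
        summary = summarize_sites(site_table, config)
    except ValueError as err:
        raise ValueError(f"summary stage failed: {err}") from err
    keep = summary.pop("keep_mask")
    kept = site_table.loc[keep]
    report["summary"] = summary
    log(f"summary on {summary['n_sites']} sites "
        f"({summary['n_nondetect']} non-detect, censored at {config.lod}); "
        f"removed outliers: {summary['outliers_removed'] or 'none'}")

    if "basin" in kept.columns and kept["basin"].notna().any():
        report["basin_comparison"] = compare_basins(kept, config)
        log(f"basin comparison: chi2={report['basin_comparison']['chi2']:.2f}, "
            f"df={report['basin_comparison']['df']}, "
            f"p={report['basin_comparison']['p']:.2f}")

    if any(c in kept.columns for c in REGRESSION_COVARIATES):
        table, info = regression_model_table(kept, config)
        report["model_table"] = table.to_dict(orient="records")
        report["regression_info"] = info
        log(f"model selection over {len(table)} models on {info['n_rows']} "
            f"complete rows; collinear pairs: {info['collinear_pairs']}")

    est = estimate_biomass(summary["mean"], summary["lcl"], summary["ucl"], config)
    report["biomass"] = {
        "total_shedding_copies_per_day": list(est.total_shedding),
        "biomass_kg": list(est.biomass_kg),
        "biomass_tonnes": list(est.biomass_tonnes),
        "density_kg_per_ha": est.density_kg_per_ha,
        "per_kg_rate": est.per_kg_rate,
        "lab_predicted_concentration": lab_calibration(config).predicted_concentration,
    }
    log(f"biomass {est.biomass_tonnes[0]:.0f} t "
        f"({est.biomass_tonnes[1]:.0f}–{est.biomass_tonnes[2]:.0f} t), "
        f"{est.density_kg_per_ha:.1f} kg/ha")

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary_rows = [
            {"statistic": k, "estimate": summary[k]}
            for k in ("mean", "median", "sd", "lcl", "ucl")
        ]
        write_table(pd.DataFrame(summary_rows), outdir / "summary.csv")
        if "model_table" in report:
            write_table(pd.DataFrame(report["model_table"]),
                        outdir / "model_table.csv")
        serialisable = {k: v for k, v in report.items()}
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(serialisable, fh, indent=2, default=str)
    return report
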