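"""qPCR plate quantification: standard curves, back-calculation, aggregation.

The quantification chain mirrors standard absolute qPCR practice:

1. fit a standard curve Cq = intercept + slope·log10(copies/reaction) across
   a tenfold dilution series (standards supplied in copies/µl are converted
   to copies/reaction through the template volume);
2. back-calculate each technical replicate's starting quantity
   SQ = 10^((Cq − intercept)/slope), with non-detects entering as zero;
3. convert to a water concentration C = (SQ / D) · E / V (copies/L) where
   D is µl template per reaction, E the extract eluate volume (µl) and V the
   water volume sampled (L);
4. average the three technical replicates per water sample and the four
   water samples per site, zeros included, so a site's value is the grand
   mean of its 12 reactions.

A sample counts as *detected* if at least one technical replicate amplified;
a run is *valid* only if every no-template control stayed negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig


@dataclass(frozen=True)
class StandardCurve:
    """OLS line of Cq on log10(copies/reaction) for a dilution series."""

    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    n_points: int
    warnings: tuple[str, ...] = ()

    def predict_cq(self, copies_per_reaction) -> np.ndarray:
        q = np.asarray(copies_per_reaction, dtype=float)
        return self.intercept + self.slope * np.log10(q)


@dataclass(frozen=True)
class SampleQuant:
    """One water-sample replicate quantified from its technical replicates."""

    site_id: str
    water_rep: str
    replicate_sq: tuple[float, ...]
    sample_concentration: float
    detected: bool


@dataclass(frozen=True)
class SiteQuant:
    """Site-level concentration: mean of the water replicates, zeros included."""

    site_id: str
    site_concentration: float
    n_water_reps: int
    detected: bool
    below_lod: bool


def fit_standard_curve(
    standards: pd.DataFrame,
    template_volume: float,
    efficiency_band: tuple[float, float] = (1.85, 2.05),
    r_squared_min: float = 0.98,
) -> StandardCurve:
    """Fit the standard curve from assay-channel standard wells.

    ``standards`` needs columns ``cq`` (NaN = non-detect) and
    ``nominal_copies_per_ul``. Non-detect standards are excluded with a
    warning; at least two distinct concentration levels must remain.
    """
    std = standards.loc[
        (standards.get("target", "assay") == "assay")
        if "target" in standards.columns
        else slice(None)
    ]
    std = std[np.isfinite(std["nominal_copies_per_ul"].astype(float))]
    nd = std["cq"].isna()
    if nd.any():
        warnings.warn(
            f"excluding {int(nd.sum())} non-detect standard well(s) from the curve",
            stacklevel=2,
        )
        std = std[~nd]
    copies_rxn = std["nominal_copies_per_ul"].astype(float) * template_volume
    if np.unique(copies_rxn).size < 2:
        raise ValueError("need at least 2 distinct standard concentrations with Cq")
    x = np.log10(copies_rxn.to_numpy())
    y = std["cq"].astype(float).to_numpy()
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    if slope >= 0:
        raise ValueError("standard-curve slope must be negative (Cq falls with copies)")
    efficiency = 10.0 ** (-1.0 / slope)
    r2 = float(res.rvalue**2)
    qc: list[str] = []
    if not efficiency_band[0] <= efficiency <= efficiency_band[1]:
        qc.append(f"efficiency {efficiency:.3f} outside band {efficiency_band}")
    if r2 < r_squared_min:
        qc.append(f"R^2 {r2:.4f} below {r_squared_min}")
    for msg in qc:
        warnings.warn("standard-curve QC: " + msg, stacklevel=2)
    return StandardCurve(slope, intercept, efficiency, r2, int(x.size), tuple(qc))


def back_calculate_sq(cq, curve: StandardCurve):
    """Starting quantity SQ = 10^((Cq − intercept)/slope), copies/reaction."""
    return 10.0 ** ((np.asarray(cq, dtype=float) - curve.intercept) / curve.slope)


def sq_to_concentration(sq, config: RunConfig):
    """C = (SQ/D)·E/V: copies/reaction → copies/L of the sampled water."""
    sq = np.asarray(sq, dtype=float)
    if np.any(sq < 0):
        raise ValueError("starting quantity must be non-negative")
    return (
        sq
        / config.template_volume_per_reaction
        * config.extract_volume
        / config.water_volume_sampled
    )


def aggregate_sample(
    site_id: str, water_rep: str, replicate_sq, config: RunConfig
) -> SampleQuant:
    """Mean of the technical-replicate concentrations, zeros included."""
    sq = np.asarray(replicate_sq, dtype=float)
    if sq.size == 0:
        raise ValueError("need at least one technical replicate")
    conc = float(np.mean(sq_to_concentration(sq, config)))
    return SampleQuant(
        site_id=str(site_id),
        water_rep=str(water_rep),
        replicate_sq=tuple(float(v) for v in sq),
        sample_concentration=conc,
        detected=bool(np.any(sq > 0)),
    )


def aggregate_site(samples: list[SampleQuant], config: RunConfig) -> SiteQuant:
    """Arithmetic mean of the water-sample replicate concentrations."""
    if not samples:
        raise ValueError("need at least one water replicate")
    site_ids = {s.site_id for s in samples}
    if len(site_ids) != 1:
        raise ValueError(f"mixed site_ids in one aggregation: {sorted(site_ids)}")
    conc = float(np.mean([s.sample_concentration for s in samples]))
    return SiteQuant(
        site_id=samples[0].site_id,
        site_concentration=conc,
        n_water_reps=len(samples),
        detected=any(s.detected for s in samples),
        below_lod=conc < config.lod,
    )


def validate_run(plate: pd.DataFrame) -> dict:
    """Run-validity per plate: every NTC assay well must be a non-detect.

    Field-blank amplifications do not invalidate the run but are reported as
    contamination warnings.
    """
    assay = plate[plate["target"] == "assay"]
    ntc = assay[assay["role"] == "ntc"]
    if ntc.empty:
        raise ValueError("plate has no NTC wells; cannot assess run validity")
    ntc_amplified = ntc["cq"].notna()
    blanks = assay[assay["role"] == "field_blank"]
    blank_hits = blanks.loc[blanks["cq"].notna(), "well"].astype(str).tolist()
    return {
        "valid": bool(~ntc_amplified.any()),
        "n_ntc": int(len(ntc)),
        "ntc_amplified_wells": ntc.loc[ntc_amplified, "well"].astype(str).tolist(),
        "field_blank_amplified_wells": blank_hits,
    }


def check_inhibition(
    ipc_wells: pd.DataFrame, reference_cq: float, shift: float = 1.0
) -> pd.DataFrame:
    """Flag wells whose IPC is delayed by more than ``shift`` cycles or absent.

    The internal positive control is spiked at a constant copy number, so a
    delayed or missing IPC signal marks PCR inhibition (a potential false
    negative on the assay channel).
    """
    ipc = ipc_wells[ipc_wells["target"] == "ipc"].copy()
    cq = ipc["cq"].astype(float)
    ipc["inhibited"] = cq.isna() | (cq > reference_cq + shift)
    return ipc[["plate_id", "well", "cq", "inhibited"]].reset_index(drop=True)


def quantify_plates(
    plates: pd.DataFrame, config: RunConfig, strict: bool = True
) -> tuple[pd.DataFrame, dict]:
    """Full plate → per-site quantification.

    Fits one standard curve per plate, checks run validity, back-calculates
    sample wells (non-detects as SQ = 0) and aggregates technical replicates
    into water samples and water samples into sites.

    Returns
    -------
    sites : DataFrame
        Columns site_id, site_concentration, n_water_reps, detected,
        below_lod (the per-site output dialect).
    report : dict
        Per-plate curves and validity plus field-blank and sample counts.
    """
    report: dict = {"plates": {}}
    per_sample: list[SampleQuant] = []
    blanks: list[SampleQuant] = []
    for plate_id, plate in plates.groupby("plate_id", sort=True):
        validity = validate_run(plate)
        if strict and not validity["valid"]:
            raise ValueError(
                f"plate {plate_id} invalid: NTC amplification in wells "
                f"{validity['ntc_amplified_wells']}"
            )
        assay = plate[plate["target"] == "assay"]
        curve = fit_standard_curve(
            assay[assay["role"] == "standard"],
            config.template_volume_per_reaction,
            config.efficiency_band,
            config.r_squared_min,
        )
        report["plates"][str(plate_id)] = {
            "validity": validity,
            "curve": {
                "slope": curve.slope,
                "intercept": curve.intercept,
                "efficiency": curve.efficiency,
                "r_squared": curve.r_squared,
                "qc_warnings": list(curve.warnings),
            },
        }
        for role, bucket in (("sample", per_sample), ("field_blank", blanks)):
            wells = assay[assay["role"] == role]
            for (site_id, water_rep), grp in wells.groupby(
                ["site_id", "water_rep"], sort=True, dropna=False
            ):
                cq = grp["cq"].astype(float).to_numpy()
                sq = np.where(np.isnan(cq), 0.0, back_calculate_sq(np.nan_to_num(cq, nan=1.0), curve))
                bucket.append(aggregate_sample(site_id, water_rep, sq, config))
    site_rows = []
    grouped: dict[str, list[SampleQuant]] = {}
    for s in per_sample:
        grouped.setdefault(s.site_id, []).append(s)
    for site_id in sorted(grouped):
        sq = aggregate_site(grouped[site_id], config)
        site_rows.append(
            {
                "site_id": sq.site_id,
                "site_concentration": sq.site_concentration,
                "n_water_reps": sq.n_water_reps,
                "detected": sq.detected,
                "below_lod": sq.below_lod,
            }
        )
    report["n_field_blanks"] = len(blanks)
    report["field_blank_detections"] = sorted(
        {b.site_id for b in blanks if b.detected}
    )
    sites = pd.DataFrame(
        site_rows,
        columns=["site_id", "site_concentration", "n_water_reps", "detected", "below_lod"],
    )
    return sites, report
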