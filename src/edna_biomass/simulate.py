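"""Synthetic eDNA surveys with known truth.

The generator emulates the statistical structure the analysis assumes: a
known total biomass sets the lake-wide mean concentration through the
mass-balance inverse; sites are patchy (zero-inflated lognormal: a fraction
of structurally fish-free sites, the rest lognormal with the grand mean
preserved); each site is sampled with four water replicates (lognormal
between-replicate noise) and three technical qPCR reactions per replicate.

Detection is mechanistic at the reaction level: expected template copies per
reaction follow from the concentration and the extraction volumes, realised
copies are Poisson, each copy amplifies with probability
``amplification_per_copy``, and a reaction with ≥1 amplifying copy yields a
Cq from the standard curve plus Gaussian instrument noise. Standards pass
through the same channel, so the fitted curve absorbs the per-copy
amplification probability and back-calculated quantities stay unbiased —
exactly how an empirical standard curve calibrates real plates.

Defaults reproduce the survey conditions this package targets: 70 sites ×
4 × 3 replicates, ≈24% non-detect sites, 95% site-level detection at the
220 copies/L LOD, site sd/mean ≈ 3.4, and a TSM–chl-a log-scale correlation
of 0.9.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .biomass import estimate_biomass, invert_biomass, lab_calibration
from .censored import CensoredData, fit_censored_lognormal, mean_confidence_interval
from .config import RunConfig
from .qpcr import quantify_plates

STANDARD_LEVELS = tuple(10.0**e for e in range(1, 7))  # copies/µl, tenfold


@dataclass(frozen=True)
class SimulationDesign:
    """Knobs of the synthetic survey; defaults are the study conditions."""

    n_sites: int = 70
    n_water_reps: int = 4
    n_tech_reps: int = 3
    true_biomass_kg: float = 4.83e6
    site_sigma: float = 1.525  # log-scale sd between occupied sites
    occupancy_zero_prob: float = 0.18  # structurally fish-free sites
    rep_cv: float = 0.30  # between-water-replicate CV
    tech_noise_sd: float = 0.15  # Cq instrument noise (cycles)
    curve_slope: float = -3.3219280948873626  # perfect doubling
    curve_intercept: float = 38.0
    amplification_per_copy: float = 0.45390  # ln(20)/(12 × 0.55): 95% at LOD
    covariate_correlation: float = 0.9  # TSM–chl-a, log scale
    covariate_beta: tuple[float, ...] = ()  # optional effects for power tests
    n_field_blanks: int = 15
    sites_per_plate: int = 6
    deterministic_copies: bool = False  # replace Poisson/binomial by expectation
    seed: int = 0

    def __post_init__(self):
        if min(self.n_sites, self.n_water_reps, self.n_tech_reps) < 1:
            raise ValueError("replicate counts must be >= 1")
        for p in (self.occupancy_zero_prob, self.amplification_per_copy):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.site_sigma <= 0:
            raise ValueError("site_sigma must be positive")


@dataclass(frozen=True)
class SyntheticSurvey:
    truth: dict
    plates: pd.DataFrame
    sites: pd.DataFrame  # site table incl. covariates and measured eDNA


# Environmental covariate envelopes (mean, sd, min, max) the generator
# respects; TSM and chl-a are jointly lognormal, the rest independent.
COVARIATE_RANGES = {
    "chl_a": (5.36, 4.44, 0.283, 15.3),
    "tsm": (16.5, 12.7, 0.59, 46.4),
    "water_temperature": (24.5, 1.1, 22.4, 27.8),
    "tds": (460.0, 10.5, 442.0, 478.0),
    "secchi_depth": (1.39, 0.70, 0.57, 3.20),
    "water_depth": (2.79, 1.08, 0.55, 4.49),
}

BASINS = ("Keszthelyi", "Szigligeti", "Szemesi", "Siofoki")
# site counts per basin for the default 70-site array (west → east)
BASIN_SIZES = (9, 21, 20, 20)


def simulate_site_concentrations(
    design: SimulationDesign, config: RunConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-site true concentrations (copies/L) with grand mean preserved.

    Mean c̄ comes from the true biomass via the mass-balance inverse; a site
    is 0 with probability ``occupancy_zero_prob``, otherwise lognormal with
    natural-scale mean c̄/(1 − p₀) so that E[site] = c̄.
    """
    c_bar = invert_biomass(design.true_biomass_kg, config)
    p0 = design.occupancy_zero_prob
    occupied = rng.random(design.n_sites) >= p0
    if p0 >= 1.0:
        return np.zeros(design.n_sites)
    m1 = c_bar / (1.0 - p0)
    mu1 = np.log(m1) - design.site_sigma**2 / 2.0
    conc = np.where(
        occupied,
        rng.lognormal(mean=mu1, sigma=design.site_sigma, size=design.n_sites),
        0.0,
    )
    return conc


def _simulate_cq(
    expected_copies: np.ndarray,
    design: SimulationDesign,
    rng: np.random.Generator,
) -> np.ndarray:
    """Reaction-level detection channel: Poisson → Binomial → Cq (NaN = ND)."""
    lam = np.clip(np.asarray(expected_copies, dtype=float), 0.0, None)
    if design.deterministic_copies:
        detected = lam * design.amplification_per_copy
    else:
        copies = rng.poisson(lam)
        detected = rng.binomial(copies, design.amplification_per_copy)
    cq = np.full(lam.shape, np.nan)
    hit = detected >= 1
    if hit.any():
        cq[hit] = (
            design.curve_intercept
            + design.curve_slope * np.log10(detected[hit])
            + rng.normal(0.0, design.tech_noise_sd, size=int(hit.sum()))
        )
    return cq


def simulate_plate(
    site_concentrations: np.ndarray,
    design: SimulationDesign,
    config: RunConfig,
    rng: np.random.Generator,
    site_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Emit plate tables for all sites: samples, standards, NTCs, blanks.

    Sites are chunked onto plates (``sites_per_plate`` each); every plate
    carries the tenfold standard series in triplicate, three NTCs and three
    positive controls. Field blanks are clean triplicates spread across
    plates. IPC-channel rows are emitted for sample wells at a constant
    reference Cq (no inhibition by default).
    """
    n_sites = len(site_concentrations)
    site_ids = site_ids or [f"S{i + 1:03d}" for i in range(n_sites)]
    f = config.copies_per_reaction_per_copy_per_litre
    lncv = np.sqrt(np.log1p(design.rep_cv**2))
    rows: list[dict] = []
    blanks_left = design.n_field_blanks
    n_plates = int(np.ceil(n_sites / design.sites_per_plate))
    ipc_ref = 30.0
    for p in range(n_plates):
        plate_id = f"P{p + 1:02d}"
        chunk = range(
            p * design.sites_per_plate, min((p + 1) * design.sites_per_plate, n_sites)
        )
        well = 0
        # Standards in triplicate. Dilution series are pipetted precisely, so
        # their expected detected copies a·q enter the forward model without
        # single-molecule noise; the fitted intercept thereby absorbs the
        # per-copy amplification probability a and sample back-calculation
        # stays calibrated, as with an empirical curve on a real plate.
        for level in STANDARD_LEVELS:
            nominal_rxn = level * config.template_volume_per_reaction
            eff_copies = design.amplification_per_copy * nominal_rxn
            cq = (
                design.curve_intercept
                + design.curve_slope * np.log10(eff_copies)
                + rng.normal(0.0, design.tech_noise_sd, size=design.n_tech_reps)
            )
            for c in cq:
                well += 1
                rows.append(
                    dict(plate_id=plate_id, well=f"W{well:03d}", role="standard",
                         target="assay", cq=c, nominal_copies_per_ul=level,
                         site_id=None, water_rep=None)
                )
        for _ in range(3):  # NTCs: clean water, never amplifies by default
            well += 1
            rows.append(dict(plate_id=plate_id, well=f"W{well:03d}", role="ntc",
                             target="assay", cq=np.nan, nominal_copies_per_ul=np.nan,
                             site_id=None, water_rep=None))
        pos_cq = _simulate_cq(np.full(3, 1e5), design, rng)
        for c in pos_cq:
            well += 1
            rows.append(dict(plate_id=plate_id, well=f"W{well:03d}", role="positive",
                             target="assay", cq=c, nominal_copies_per_ul=np.nan,
                             site_id=None, water_rep=None))
        for i in chunk:
            mult = rng.lognormal(-lncv**2 / 2.0, lncv, size=design.n_water_reps)
            for r in range(design.n_water_reps):
                lam = site_concentrations[i] * mult[r] * f
                cq = _simulate_cq(np.full(design.n_tech_reps, lam), design, rng)
                for c in cq:
                    well += 1
                    rows.append(
                        dict(plate_id=plate_id, well=f"W{well:03d}", role="sample",
                             target="assay", cq=c, nominal_copies_per_ul=np.nan,
                             site_id=site_ids[i], water_rep=f"R{r + 1}")
                    )
                    rows.append(
                        dict(plate_id=plate_id, well=f"W{well:03d}", role="sample",
                             target="ipc", cq=ipc_ref + rng.normal(0.0, 0.1),
                             nominal_copies_per_ul=np.nan,
                             site_id=site_ids[i], water_rep=f"R{r + 1}")
                    )
        if blanks_left > 0:
            blanks_left -= 1
            cq = _simulate_cq(np.zeros(design.n_tech_reps), design, rng)
            for c in cq:
                well += 1
                rows.append(
                    dict(plate_id=plate_id, well=f"W{well:03d}", role="field_blank",
                         target="assay", cq=c, nominal_copies_per_ul=np.nan,
                         site_id=f"FB{design.n_field_blanks - blanks_left:02d}",
                         water_rep="R1")
                )
    return pd.DataFrame(rows)


def simulate_covariates(
    design: SimulationDesign,
    site_concentrations: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Environmental covariates within the study envelopes.

    TSM and chl-a are bivariate normal on the log scale with the configured
    correlation; the others are independent truncated normals. Covariates
    are independent of concentration unless ``covariate_beta`` is set (used
    only for regression power tests). A few cells are blanked to emulate the
    incomplete satellite retrievals of the real survey.
    """
    n = len(site_concentrations)
    out = {}
    # correlated TSM / chl-a on log scale, range-clipped
    rho = design.covariate_correlation
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n)
    for j, name in enumerate(("chl_a", "tsm")):
        _, _, lo, hi = COVARIATE_RANGES[name]
        centre = 0.5 * (np.log(lo) + np.log(hi))
        spread = (np.log(hi) - centre) / 2.5
        out[name] = np.clip(np.exp(centre + spread * z[:, j]), lo, hi)
    for name in ("water_temperature", "tds", "secchi_depth", "water_depth"):
        mean, sd, lo, hi = COVARIATE_RANGES[name]
        out[name] = np.clip(rng.normal(mean, sd, size=n), lo, hi)
    df = pd.DataFrame(out)
    # emulate missing satellite/Secchi retrievals
    if n >= 10:
        miss = rng.choice(n, size=3, replace=False)
        df.loc[miss, ["chl_a", "tsm"]] = np.nan
        df.loc[rng.choice(n, size=2, replace=False), "secchi_depth"] = np.nan
    return df


def simulate_survey(
    design: SimulationDesign, config: RunConfig | None = None
) -> SyntheticSurvey:
    """Generate one complete survey: truth, plates, and a quantified site table."""
    config = config or RunConfig()
    rng = np.random.default_rng(design.seed)
    conc = simulate_site_concentrations(design, config, rng)
    covars = simulate_covariates(design, conc, rng)
    if design.covariate_beta:
        # power-test mode: multiplicative covariate effects on occupied sites
        beta = np.asarray(design.covariate_beta, dtype=float)
        X = covars.to_numpy(dtype=float)[:, : beta.size]
        X = np.nan_to_num((X - np.nanmean(X, axis=0)) / np.nanstd(X, axis=0))
        conc = conc * np.exp(X @ beta)
    site_ids = [f"S{i + 1:03d}" for i in range(design.n_sites)]
    plates = simulate_plate(conc, design, config, rng, site_ids)
    sites_q, _ = quantify_plates(plates, config)
    basins = np.repeat(
        BASINS, np.diff(np.round(np.cumsum((0,) + BASIN_SIZES)
                                 / sum(BASIN_SIZES) * design.n_sites)).astype(int))
    site_table = pd.DataFrame(
        {
            "site_id": site_ids,
            "latitude": 46.8 + 0.25 * rng.random(design.n_sites),
            "longitude": 17.25 + 0.9 * np.linspace(0, 1, design.n_sites),
            "basin": basins[: design.n_sites],
        }
    )
    site_table = pd.concat([site_table, covars], axis=1)
    site_table = site_table.merge(
        sites_q[["site_id", "site_concentration"]], on="site_id", how="left"
    ).rename(columns={"site_concentration": "edna_concentration"})
    truth = {
        "true_biomass_kg": design.true_biomass_kg,
        "true_mean_concentration": invert_biomass(design.true_biomass_kg, config),
        "site_concentrations": conc.tolist(),
        "seed": design.seed,
    }
    return SyntheticSurvey(truth=truth, plates=plates, sites=site_table)


def write_survey(survey: SyntheticSurvey, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    survey.plates.to_csv(outdir / "plates.csv", index=False)
    survey.sites.to_csv(outdir / "sites.csv", index=False)
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(survey.truth, fh, indent=2)


def end_to_end_recovery(
    design: SimulationDesign,
    n_replicate_surveys: int = 500,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Repeat the full pipeline on independent surveys; score biomass recovery.

    For each survey: simulate plates, quantify, censor non-detect sites at
    the LOD, fit the censored lognormal, take the profile CI on the mean, and
    convert to biomass. Reports CI coverage of the true biomass, the
    distribution of relative bias, and CI widths.
    """
    config = config or RunConfig()
    base = design.seed if seed is None else seed
    children = np.random.SeedSequence(base).spawn(n_replicate_surveys)
    estimates, covered, widths = [], [], []
    calib = lab_calibration(config)
    for child in children:
        d = replace(design, seed=int(child.generate_state(1)[0] % (2**31 - 1)))
        survey = simulate_survey(d, config)
        conc = survey.sites["edna_concentration"].to_numpy()
        data = CensoredData.from_concentrations(conc, config.lod)
        fit = fit_censored_lognormal(data)
        ci = mean_confidence_interval(data, level=config.ci_level)
        est = estimate_biomass(fit.mean, ci.lcl, ci.ucl, config, calib)
        point, lcl, ucl = est.biomass_kg
        estimates.append(point)
        covered.append(lcl <= design.true_biomass_kg <= ucl)
        widths.append(ucl - lcl)
    estimates = np.asarray(estimates)
    rel_bias = estimates / design.true_biomass_kg - 1.0
    return {
        "n_surveys": n_replicate_surveys,
        "coverage": float(np.mean(covered)),
        "median_bias": float(np.median(rel_bias)),
        "mean_bias": float(np.mean(rel_bias)),
        "ci_width_median_kg": float(np.median(widths)),
        "estimates_kg": estimates,
    }
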