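"""Run configuration: laboratory volumes, lake geometry, and analysis settings.

All concentrations are handled internally in copies/L; the qPCR volumes
(template per reaction, extract eluate, water sampled) convert between
copies/reaction and copies/L at the module boundary only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

SECONDS_PER_DAY = 86400.0
HA_PER_KM2 = 100.0


@dataclass(frozen=True)
class RunConfig:
    """Physical constants and analysis settings for one survey analysis.

    Defaults describe a large shallow lake survey calibrated against a
    flow-through tank experiment with known fish biomass.

    Parameters
    ----------
    template_volume_per_reaction : float
        Template volume D pipetted into each qPCR reaction (µl/reaction).
    extract_volume : float
        Total eluate volume E of the DNA extract from one water sample (µl).
    water_volume_sampled : float
        Water volume V collected per replicate sample (L).
    lod : float
        Limit of detection (copies/L); the lowest concentration detected in
        95% of replicates, used as the site-level left-censoring limit.
    decay_rate_k : float
        First-order eDNA decay rate under basal conditions (1/day).
    lake_volume, lake_area, lake_outflow : float
        Lake geometry: volume (L), surface area (km²), outflow (L/day).
    lab_raw_shedding : float
        Flow-corrected (but not decay-corrected) shedding rate measured in a
        tank holding a known biomass (copies/kg/s).
    lab_flow, lab_volume : float
        Flow (L/day) and volume (L) of the calibration tank.
    outlier_sd_multiplier : float
        Half-width of the outlier screen in natural-scale standard deviations.
    ci_level : float
        Confidence level for the mean-concentration interval.
    vif_threshold : float
        Variance-inflation-factor threshold above which a covariate pair is
        declared collinear and never combined in one model.
    efficiency_band : tuple of float
        Acceptable qPCR amplification-efficiency range before a QC warning.
    r_squared_min : float
        Minimum standard-curve R² before a QC warning.
    ipc_shift : float
        IPC Cq delay (cycles) beyond the reference that flags inhibition.
    rng_seed : int
        Seed for any stochastic step (bootstrap CIs, simulation drivers).
    """

    template_volume_per_reaction: float = 2.5
    extract_volume: float = 50.0
    water_volume_sampled: float = 0.05
    lod: float = 220.0
    decay_rate_k: float = 0.877
    lake_volume: float = 1.9e12
    lake_area: float = 596.0
    lake_outflow: float = 5.4e8
    lab_raw_shedding: float = 3900.0
    lab_flow: float = 456.0
    lab_volume: float = 379.0
    outlier_sd_multiplier: float = 3.0
    ci_level: float = 0.95
    vif_threshold: float = 5.0
    efficiency_band: tuple[float, float] = (1.85, 2.05)
    r_squared_min: float = 0.98
    ipc_shift: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "template_volume_per_reaction",
            "extract_volume",
            "water_volume_sampled",
            "lod",
            "decay_rate_k",
            "lake_volume",
            "lake_area",
            "lab_raw_shedding",
            "lab_flow",
            "lab_volume",
            "outlier_sd_multiplier",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.lake_outflow < 0:
            raise ValueError("lake_outflow must be non-negative")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.vif_threshold <= 1:
            raise ValueError("vif_threshold must exceed 1")

    @property
    def copies_per_reaction_per_copy_per_litre(self) -> float:
        """Conversion factor f such that SQ = f × C for one reaction.

        f = (V_water / E_extract) × D; with the default volumes
        f = 0.05/50 × 2.5 = 0.0025, so the 220 copies/L LOD corresponds to
        0.55 copies/reaction.
        """
        return (
            self.water_volume_sampled
            / self.extract_volume
            * self.template_volume_per_reaction
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["efficiency_band"] = list(self.efficiency_band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "efficiency_band" in d:
            d = {**d, "efficiency_band": tuple(d["efficiency_band"])}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
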