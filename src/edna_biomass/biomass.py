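"""Shedding/decay mass balance: mean eDNA concentration → relative biomass.

At steady state a water body of volume V (L) with outflow R (L/day) holding
fish that shed eDNA at total rate S (copies/day), with first-order decay at
rate k (1/day), carries concentration C = S / ((k + R/V)·V). Inverting,

    S = (k + R/V) · C · V.

The same balance applied to a flow-through tank with a known biomass turns a
laboratory shedding measurement into a per-kilogram rate, and the ratio of
the field total to the per-kg rate is the *relative* biomass: relative
because it assumes the laboratory shedding and decay rates transfer to the
field. The full equation is used everywhere — for the lake the R/V term is
negligible (~3e-4/day against k = 0.877/day) but it is never dropped.

All arithmetic is carried at full floating precision; rounding to the
3-significant-figure reporting convention happens only in `round_sig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import HA_PER_KM2, SECONDS_PER_DAY, RunConfig


@dataclass(frozen=True)
class SheddingParameters:
    """Mass-balance constants: decay k (1/day), flow R (L/day), volume V (L)."""

    k: float
    R: float
    V: float

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("decay rate k must be positive")
        if self.R < 0:
            raise ValueError("flow R must be non-negative")
        if self.V <= 0:
            raise ValueError("volume V must be positive")


@dataclass(frozen=True)
class LabCalibration:
    """Laboratory chain: raw tank shedding rate → per-kg shedding rate."""

    raw_rate: float  # copies/kg/s, flow-corrected but not decay-corrected
    flow: float  # L/day
    volume: float  # L
    k: float  # 1/day
    predicted_concentration: float  # copies/L in a 1-kg tank
    per_kg_rate: float  # copies/kg/day, flow- and decay-corrected


@dataclass(frozen=True)
class BiomassEstimate:
    """Relative biomass with bounds propagated from the concentration CI."""

    total_shedding: tuple[float, float, float]  # (point, lcl, ucl) copies/day
    biomass_kg: tuple[float, float, float]
    biomass_tonnes: tuple[float, float, float]
    density_kg_per_ha: float
    per_kg_rate: float


def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures (report-time convention)."""
    if x == 0 or not np.isfinite(x):
        return float(x)
    from math import floor, log10

    return float(round(x, -int(floor(log10(abs(x)))) + digits - 1))


def lab_predicted_concentration(raw_rate: float, flow: float) -> float:
    """Steady-state tank concentration implied by a flow-corrected rate.

    The raw rate (copies/kg/s) is converted to copies/kg/day and divided by
    the tank throughflow (L/day): a 1-kg fish shedding into a stream of
    ``flow`` litres per day sustains raw_rate·86400/flow copies/L before
    decay is accounted for.
    """
    if raw_rate < 0:
        raise ValueError("raw shedding rate must be non-negative")
    if flow <= 0:
        raise ValueError("flow must be strictly positive")
    return raw_rate * SECONDS_PER_DAY / flow


def shedding_rate(c: float, params: SheddingParameters) -> float:
    """S = (k + R/V)·C·V, copies/day; linear in the concentration C."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = (params.k + params.R / params.V) * c * params.V
    return float(out) if out.ndim == 0 else out


def lab_calibration(config: RunConfig) -> LabCalibration:
    """Run the laboratory chain from the configured tank constants."""
    c_tank = lab_predicted_concentration(config.lab_raw_shedding, config.lab_flow)
    tank = SheddingParameters(
        k=config.decay_rate_k, R=config.lab_flow, V=config.lab_volume
    )
    return LabCalibration(
        raw_rate=config.lab_raw_shedding,
        flow=config.lab_flow,
        volume=config.lab_volume,
        k=config.decay_rate_k,
        predicted_concentration=c_tank,
        per_kg_rate=shedding_rate(c_tank, tank),  # per kg: tank held 1 kg
    )


def estimate_biomass(
    mean: float,
    lcl: float,
    ucl: float,
    config: RunConfig,
    calibration: LabCalibration | None = None,
) -> BiomassEstimate:
    """Convert a mean concentration (with CI) into relative biomass.

    The lake mass balance is applied to the point estimate and both
    confidence limits; dividing by the per-kg laboratory rate gives kg,
    /1000 gives tonnes, and /(area·100) gives kg/ha.
    """
    if calibration is None:
        calibration = lab_calibration(config)
    if calibration.per_kg_rate <= 0:
        raise ValueError("per-kg shedding rate must be positive")
    if not lcl <= mean <= ucl:
        raise ValueError("confidence limits must bracket the mean")
    lake = SheddingParameters(
        k=config.decay_rate_k, R=config.lake_outflow, V=config.lake_volume
    )
    total = tuple(shedding_rate(c, lake) for c in (mean, lcl, ucl))
    kg = tuple(s / calibration.per_kg_rate for s in total)
    return BiomassEstimate(
        total_shedding=total,
        biomass_kg=kg,
        biomass_tonnes=tuple(v / 1000.0 for v in kg),
        density_kg_per_ha=kg[0] / (config.lake_area * HA_PER_KM2),
        per_kg_rate=calibration.per_kg_rate,
    )


def invert_biomass(
    biomass_kg: float,
    config: RunConfig,
    calibration: LabCalibration | None = None,
) -> float:
    """Mean concentration whose biomass estimate equals ``biomass_kg``.

    Exact inverse of the linear chain: C = B·r / ((k + R/V)·V) with r the
    per-kg laboratory rate. Used by the survey simulator to translate a true
    biomass into a true mean concentration.
    """
    if biomass_kg < 0:
        raise ValueError("biomass must be non-negative")
    if calibration is None:
        calibration = lab_calibration(config)
    factor = (
        config.decay_rate_k + config.lake_outflow / config.lake_volume
    ) * config.lake_volume
    return biomass_kg * calibration.per_kg_rate / factor
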