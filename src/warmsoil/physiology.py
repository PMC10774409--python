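"""Microbial physiology from ¹⁸O-H₂O incubations and root-exudation traps.

Growth is derived from ¹⁸O incorporation into DNA with a proportional-labeling
model: the fraction of DNA oxygen that is newly synthesized equals the DNA
atom% excess over the natural-abundance control divided by the soil-water
label excess. Converting new DNA-O to biomass C requires an explicit,
soil-specific factor ``f_co`` (µg biomass C per µg new DNA-O); there is no
hidden default. Respiration converts headspace CO₂ accumulation to carbon via
the ideal-gas law.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from warmsoil.datamodel import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

R_GAS = 8.314  # J mol-1 K-1
CARBON_MOLAR_MASS_UG = 12.01e6  # µg mol-1
STANDARD_PRESSURE_PA = 101325.0


@dataclass
class IsotopeIncubation:
    """Raw measurements for one paired (labeled + control) incubation."""

    sample_id: str
    soil_dry_mass: float  # g
    dna_total_o: float  # µg O in extracted DNA, labeled tube
    dna_atpct_labeled: float  # atom% 18O of DNA O, labeled tube
    dna_atpct_control: float  # atom% 18O of DNA O, natural-abundance tube
    co2_delta_ppm: float  # headspace CO2 accumulation, ppm v/v
    headspace_volume: float  # L
    headspace_temp: float  # K
    headspace_pressure: float = STANDARD_PRESSURE_PA  # Pa
    incubation_hours: float = 48.0
    water_label_atpct: float = 30.0
    f_co: Optional[float] = None  # µg biomass C per µg new DNA-O; no default

    def validate(self) -> None:
        if not (0 <= self.dna_atpct_control <= self.dna_atpct_labeled
                <= self.water_label_atpct):
            raise ValidationError(
                f"{self.sample_id}: atom% ordering violated "
                f"(0 <= control={self.dna_atpct_control} <= "
                f"labeled={self.dna_atpct_labeled} <= "
                f"water={self.water_label_atpct} required)"
            )
        for name in ("soil_dry_mass", "headspace_volume", "headspace_temp",
                     "headspace_pressure", "incubation_hours"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{self.sample_id}: {name} must be > 0")
        if self.dna_total_o < 0:
            raise ValidationError(f"{self.sample_id}: dna_total_o must be >= 0")


@dataclass(frozen=True)
class CueResult:
    c_growth: float  # µg C g-1 soil per incubation
    c_respiration: float  # µg C g-1 soil per incubation
    c_uptake: float  # µg C g-1 soil per incubation
    cue: float  # dimensionless fraction


def compute_growth(inc: IsotopeIncubation) -> float:
    """Microbial growth (µg C g⁻¹ soil per incubation) from label uptake.

    growth = dna_total_o x (at%_labeled - at%_control)
             / (at%_water - at%_control) x f_co / soil_dry_mass
    """
    inc.validate()
    if inc.f_co is None:
        raise ConfigurationError(
            f"{inc.sample_id}: f_co (µg biomass C per µg new DNA-O) must be "
            "supplied explicitly; it is soil-specific and has no default"
        )
    excess = inc.dna_atpct_labeled - inc.dna_atpct_control
    denom = inc.water_label_atpct - inc.dna_atpct_control
    new_dna_o = inc.dna_total_o * excess / denom
    return new_dna_o * inc.f_co / inc.soil_dry_mass


def compute_respiration(inc: IsotopeIncubation) -> float:
    """Respired C (µg C g⁻¹ soil per incubation) from headspace CO₂.

    Ideal gas: moles = P x (Δppm x 1e-6 x V[m³]) / (R x T); negative CO₂
    deltas (blank drift) are clamped to zero with a warning.
    """
    inc.validate()
    delta = inc.co2_delta_ppm
    if delta < 0:
        logger.warning(
            "%s: negative co2_delta_ppm %.3f clamped to 0 (blank drift)",
            inc.sample_id, delta,
        )
        delta = 0.0
    volume_m3 = inc.headspace_volume * 1e-3
    moles = inc.headspace_pressure * (delta * 1e-6 * volume_m3) / (
        R_GAS * inc.headspace_temp
    )
    return moles * CARBON_MOLAR_MASS_UG / inc.soil_dry_mass


def compute_cue(growth: float, respiration: float) -> CueResult:
    """CUE = growth / (growth + respiration); uptake = growth + respiration."""
    if growth < 0 or respiration < 0:
        raise ValidationError("growth and respiration must be non-negative")
    uptake = growth + respiration
    if uptake == 0:
        raise ValidationError("CUE undefined: growth and respiration both zero")
    return CueResult(
        c_growth=growth,
        c_respiration=respiration,
        c_uptake=uptake,
        cue=growth / uptake,
    )


def cue_from_incubation(inc: IsotopeIncubation) -> CueResult:
    return compute_cue(compute_growth(inc), compute_respiration(inc))


def cue_table(incubations: Iterable[IsotopeIncubation]) -> pd.DataFrame:
    """CueResult per incubation as a sample-indexed DataFrame."""
    rows = {}
    for inc in incubations:
        res = cue_from_incubation(inc)
        rows[inc.sample_id] = {
            "c_growth": res.c_growth,
            "c_respiration": res.c_respiration,
            "c_uptake": res.c_uptake,
            "cue": res.cue,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


@dataclass(frozen=True)
class ExudationMeasurement:
    """Cuvette-trap measurement for whole-growth-period root exudation."""

    delta_c: float  # mg C L-1, root cuvette TOC minus blank
    solution_volume: float  # L
    root_mass: float  # g
    collection_hours: float  # h
    root_biomass_areal: float  # g C m-2
    period_days: float  # days

    def validate(self) -> None:
        if self.root_mass <= 0:
            raise ValidationError("root_mass must be > 0")
        if self.collection_hours <= 0:
            raise ValidationError("collection_hours must be > 0")
        for name in ("delta_c", "solution_volume", "root_biomass_areal",
                     "period_days"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


def exudation_rate(
    delta_c: float,
    solution_volume: float,
    root_mass: float,
    collection_hours: float,
) -> float:
    """Exudation rate, mg C g⁻¹ root h⁻¹: (Δc x V) / (G x T)."""
    if root_mass <= 0:
        raise ValidationError("root_mass must be > 0")
    if collection_hours <= 0:
        raise ValidationError("collection_hours must be > 0")
    if delta_c < 0 or solution_volume < 0:
        raise ValidationError("delta_c and solution_volume must be >= 0")
    return (delta_c * solution_volume) / (root_mass * collection_hours)


def whole_period_exudation(m: ExudationMeasurement, to_grams: bool = False) -> float:
    """Whole-growth-period exudation: (Δc·V)/(G·T) x S x 24 x d.

    With Δc in mg C L⁻¹ and S in g C m⁻², the raw product carries
    mg C (g C root)⁻¹ x g C m⁻² = mg C m⁻² per period. ``to_grams=True``
    divides by 1000 once (logged) to report g C m⁻² per period.
    """
    m.validate()
    rate = exudation_rate(
        m.delta_c, m.solution_volume, m.root_mass, m.collection_hours
    )
    value = rate * m.root_biomass_areal * 24.0 * m.period_days
    if to_grams:
        logger.info("whole_period_exudation: converting mg -> g (x 1e-3)")
        value *= 1e-3
    return value
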