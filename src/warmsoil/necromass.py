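"""Amino-sugar biomarker accounting: bacterial, fungal and total necromass C.

Bacterial necromass works on muramic-acid mass (µg g⁻¹ soil x 45); fungal
necromass works on molar amounts ((mmol glucosamine − 2 x mmol muramic acid)
x 179.2 x 9, yielding mg g⁻¹ which is reported here in µg C g⁻¹ soil). The
muramic-acid mass <-> molar bridge uses a configurable molar mass of
251.2 g mol⁻¹.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

from warmsoil.datamodel import ValidationError

logger = logging.getLogger(__name__)

BACTERIAL_CONVERSION = 45.0  # µg C per µg muramic acid
GLUCOSAMINE_MOLAR_MASS = 179.2  # g mol-1
FUNGAL_CONVERSION = 9.0  # fungal glucosamine -> fungal residue C
MURAMIC_ACID_MOLAR_MASS = 251.2  # g mol-1, configurable bridge


def muramic_mass_to_mmol(
    mass_ug_per_g: float, molar_mass: float = MURAMIC_ACID_MOLAR_MASS
) -> float:
    """µg g⁻¹ soil -> mmol g⁻¹ soil (µg / (g mol⁻¹) = µmol; /1000 = mmol)."""
    return mass_ug_per_g / molar_mass / 1000.0


def muramic_mmol_to_mass(
    mmol_per_g: float, molar_mass: float = MURAMIC_ACID_MOLAR_MASS
) -> float:
    return mmol_per_g * molar_mass * 1000.0


@dataclass
class AminoSugarProfile:
    """Biomarker concentrations for one sample.

    Either muramic-acid representation may be omitted; the other is derived
    via the molar-mass bridge. Galactosamine is carried for QC only.
    """

    sample_id: str
    glucosamine: float  # mmol g-1 soil
    galactosamine: float  # mmol g-1 soil
    muramic_acid_mass: Optional[float] = None  # µg g-1 soil
    muramic_acid_mmol: Optional[float] = None  # mmol g-1 soil
    molar_mass_muramic: float = MURAMIC_ACID_MOLAR_MASS

    def __post_init__(self) -> None:
        if self.muramic_acid_mass is None and self.muramic_acid_mmol is None:
            raise ValidationError(
                f"{self.sample_id}: muramic acid required in at least one unit"
            )
        if self.muramic_acid_mmol is None:
            self.muramic_acid_mmol = muramic_mass_to_mmol(
                self.muramic_acid_mass, self.molar_mass_muramic
            )
        if self.muramic_acid_mass is None:
            self.muramic_acid_mass = muramic_mmol_to_mass(
                self.muramic_acid_mmol, self.molar_mass_muramic
            )
        for name in ("glucosamine", "galactosamine", "muramic_acid_mass",
                     "muramic_acid_mmol"):
            if getattr(self, name) < 0:
                raise ValidationError(
                    f"{self.sample_id}: {name} must be non-negative"
                )

    @property
    def fungal_conversion_valid(self) -> bool:
        return self.glucosamine >= 2.0 * self.muramic_acid_mmol


@dataclass(frozen=True)
class NecromassResult:
    sample_id: str
    bacterial_c: float  # µg C g-1 soil
    fungal_c: float  # µg C g-1 soil
    total_c: float  # µg C g-1 soil
    fungal_fraction: float  # % of total necromass (NaN when total is 0)
    contribution_to_soc: float  # % of SOC


def bacterial_residue_c(muramic_acid_mass: float) -> float:
    """Bacterial necromass C (µg C g⁻¹) = muramic acid (µg g⁻¹) x 45."""
    if muramic_acid_mass < 0:
        raise ValidationError("muramic acid mass must be non-negative")
    return muramic_acid_mass * BACTERIAL_CONVERSION


def fungal_residue_c(
    glucosamine_mmol: float,
    muramic_acid_mmol: float,
    strict: bool = True,
) -> float:
    """Fungal necromass C (µg C g⁻¹ soil).

    (mmol glucosamine − 2 x mmol muramic acid) x 179.2 x 9 yields mg g⁻¹
    when inputs are mmol g⁻¹ (mmol x g mol⁻¹ = mg); multiplied by 1000 once
    to report µg C g⁻¹. Negative fungal glucosamine errors in strict mode,
    otherwise clamps to zero with a warning.
    """
    if glucosamine_mmol < 0 or muramic_acid_mmol < 0:
        raise ValidationError("amino sugar concentrations must be non-negative")
    fungal_glucosamine = glucosamine_mmol - 2.0 * muramic_acid_mmol
    if fungal_glucosamine < 0:
        if strict:
            raise ValidationError(
                "glucosamine < 2 x muramic acid: negative fungal necromass "
                "is physically meaningless (use strict=False to clamp)"
            )
        logger.warning(
            "glucosamine %.6g < 2 x muramic %.6g: fungal necromass clamped to 0",
            glucosamine_mmol, muramic_acid_mmol,
        )
        fungal_glucosamine = 0.0
    mg_per_g = fungal_glucosamine * GLUCOSAMINE_MOLAR_MASS * FUNGAL_CONVERSION
    return mg_per_g * 1000.0  # mg g-1 -> µg g-1


def summarize_necromass(
    profile: AminoSugarProfile,
    soc: float,
    strict: bool = True,
) -> NecromassResult:
    """Full necromass accounting for one sample against its SOC.

    ``soc`` is mg C g⁻¹ soil; necromass (µg) is converted to mg before the
    ratio so contribution_to_soc is a percentage of SOC.
    """
    if soc <= 0:
        raise ValidationError(f"{profile.sample_id}: SOC must be > 0 (got {soc})")
    bacterial = bacterial_residue_c(profile.muramic_acid_mass)
    fungal = fungal_residue_c(
        profile.glucosamine, profile.muramic_acid_mmol, strict=strict
    )
    total = bacterial + fungal
    fungal_fraction = 100.0 * fungal / total if total > 0 else math.nan
    contribution = 100.0 * (total / 1000.0) / soc
    return NecromassResult(
        sample_id=profile.sample_id,
        bacterial_c=bacterial,
        fungal_c=fungal,
        total_c=total,
        fungal_fraction=fungal_fraction,
        contribution_to_soc=contribution,
    )
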