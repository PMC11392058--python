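"""Dose-metric conversions: gravimetric, surface-area and site-based doses.

In vitro doses are usually stated gravimetrically (ug mL^-1).  Once the
specific reactive-site content of a material is known (mmol g^-1, from
methanol chemisorption), any gravimetric dose converts exactly to a
reactive-site molarity:

    site molarity [umol L^-1] = mass conc [ug mL^-1] * sites [mmol g^-1]

(the unit product ug mL^-1 * mmol g^-1 is exactly umol L^-1).  The
surface-area dose is mass conc * BET * 1e-3 in m^2 L^-1.  The inverse
conversion recovers a material's site content from any printed
(gravimetric, site-molarity) dose pair.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core_io import SampleRecord

__all__ = [
    "DoseConversion",
    "site_molarity",
    "infer_specific_sites",
    "area_dose",
    "mix_dilution",
    "convert_dose",
]


@dataclass(frozen=True)
class DoseConversion:
    """The same exposure expressed on the three dose scales."""

    mass_concentration_ug_ml: float
    specific_sites_mmol_g: float
    site_molarity_umol_l: float
    area_dose_m2_l: float | None = None


def site_molarity(mass_concentration_ug_ml: float, specific_sites_mmol_g: float) -> float:
    """Reactive-site molarity (umol L^-1) of a suspension."""
    if mass_concentration_ug_ml < 0 or specific_sites_mmol_g < 0:
        raise ValueError("inputs must be >= 0")
    return mass_concentration_ug_ml * specific_sites_mmol_g


def infer_specific_sites(mass_dose_ug_ml: float, site_dose_umol_l: float) -> float:
    """Specific site content (mmol g^-1) implied by a printed dose pair."""
    if mass_dose_ug_ml <= 0:
        raise ValueError("mass dose must be > 0")
    return site_dose_umol_l / mass_dose_ug_ml


def area_dose(mass_concentration_ug_ml: float, bet_m2_per_g: float) -> float:
    """Surface-area dose (m^2 L^-1): ug mL^-1 = mg L^-1, times m^2 g^-1."""
    if bet_m2_per_g <= 0:
        raise ValueError("bet_m2_per_g must be > 0")
    return mass_concentration_ug_ml * bet_m2_per_g * 1e-3


def mix_dilution(components: Sequence[tuple[float, float]]) -> float:
    """Final concentration after mixing (concentration, volume) components.

    Volume-weighted mean; e.g. 3 mL of a 200 ug mL^-1 suspension plus 3 mL
    of DTT solution gives 100 ug mL^-1 of particles in the 6 mL reactor.
    """
    if not components:
        raise ValueError("empty component list")
    total_v = sum(v for _, v in components)
    if total_v <= 0:
        raise ValueError("total volume must be > 0")
    return sum(c * v for c, v in components) / total_v


def convert_dose(
    mass_concentration_ug_ml: float,
    specific_sites_mmol_g: float,
    sample: SampleRecord | None = None,
) -> DoseConversion:
    """Express one gravimetric dose on all three scales."""
    return DoseConversion(
        mass_concentration_ug_ml=mass_concentration_ug_ml,
        specific_sites_mmol_g=specific_sites_mmol_g,
        site_molarity_umol_l=site_molarity(mass_concentration_ug_ml, specific_sites_mmol_g),
        area_dose_m2_l=(
            area_dose(mass_concentration_ug_ml, sample.bet_m2_per_g)
            if sample is not None
            else None
        ),
    )
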