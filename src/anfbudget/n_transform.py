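"""Net N mineralization, nitrification and moisture targets for soil assays.

Paired KCl extractions bracket an aerobic incubation (default 28 d at 60%
water-filled pore space): inorganic N pools (NO3-, NH4+; ug N per g dry
soil) are measured at day 0 and at day 28, and the net rates are pool
differences over time,

    net mineralization = ((NO3_28 + NH4_28) - (NO3_0 + NH4_0)) / t
    net nitrification  = (NO3_28 - NO3_0) / t

Negative net mineralization means net microbial immobilization and is
reported as-is. Relative nitrification — the percent of net-mineralized N
that accumulated as nitrate — is the ratio of the two net rates and can
exceed 100% when the ammonium pool shrinks over the incubation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MineralizationAssay",
    "SoilPhysical",
    "WaterAddition",
    "net_mineralization",
    "net_nitrification",
    "relative_nitrification",
    "relative_nitrification_end_pool",
    "wfps",
    "water_to_target_wfps",
    "extract_to_soil_concentration",
]


@dataclass(frozen=True)
class MineralizationAssay:
    """Paired T0/T28 inorganic-N extractions for one soil sample.

    Concentrations are ug N per g dry soil, each the mean over extraction
    replicates (by protocol, three cups per timepoint).
    """

    nitrate_t0: float
    ammonium_t0: float
    nitrate_t28: float
    ammonium_t28: float
    duration: float = 28.0
    n_reps_t0: int = 3
    n_reps_t28: int = 3

    def __post_init__(self) -> None:
        for name in ("nitrate_t0", "ammonium_t0", "nitrate_t28", "ammonium_t28"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.duration > 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class SoilPhysical:
    """Bulk density (g cm-3), total porosity (fraction) and gravimetric
    moisture (g water per g dry soil) of a soil."""

    bulk_density: float
    porosity: float
    gravimetric_moisture: float

    def __post_init__(self) -> None:
        if not self.bulk_density > 0:
            raise ValueError("bulk_density must be positive")
        if not 0.0 < self.porosity < 1.0:
            raise ValueError("porosity must be in (0, 1)")
        if self.gravimetric_moisture < 0:
            raise ValueError("gravimetric_moisture must be >= 0")


@dataclass(frozen=True)
class WaterAddition:
    """Water volume (mL) needed to reach a target WFPS; ``over_wet`` marks a
    soil already wetter than the target (volume floored at 0)."""

    volume_ml: float
    over_wet: bool


def net_mineralization(assay: MineralizationAssay) -> float:
    """Net N mineralization, ug N g-1 d-1 (negative = net immobilization)."""
    t28 = assay.nitrate_t28 + assay.ammonium_t28
    t0 = assay.nitrate_t0 + assay.ammonium_t0
    return (t28 - t0) / assay.duration


def net_nitrification(assay: MineralizationAssay) -> float:
    """Net nitrification, ug N g-1 d-1."""
    return (assay.nitrate_t28 - assay.nitrate_t0) / assay.duration


def relative_nitrification(assay: MineralizationAssay) -> float:
    """Percent of net-mineralized N accumulating as NO3- (may exceed 100).

    Uses the ratio of net rates (delta-based reading). Returns NaN when net
    mineralization is exactly zero, where the ratio is undefined.
    """
    minz = net_mineralization(assay)
    if minz == 0.0:
        return math.nan
    return 100.0 * net_nitrification(assay) / minz


def relative_nitrification_end_pool(assay: MineralizationAssay) -> float:
    """Alternative reading: NO3- share of the total inorganic pool at T28."""
    total = assay.nitrate_t28 + assay.ammonium_t28
    if total == 0.0:
        return math.nan
    return 100.0 * assay.nitrate_t28 / total


def wfps(phys: SoilPhysical) -> float:
    """Current water-filled pore space as a fraction of pore volume."""
    return phys.gravimetric_moisture * phys.bulk_density / phys.porosity


def water_to_target_wfps(
    phys: SoilPhysical, dry_mass: float, target_wfps: float
) -> WaterAddition:
    """Water (mL) to bring ``dry_mass`` grams of soil to ``target_wfps``.

    Pore volume per gram is ``porosity / bulk_density`` (cm3 g-1); the
    deficit relative to current gravimetric moisture, times the dry mass,
    is the volume to add (1 g water = 1 mL).
    """
    if not 0.0 < target_wfps <= 1.0:
        raise ValueError("target_wfps must be in (0, 1]")
    if not dry_mass > 0:
        raise ValueError("dry_mass must be positive")
    per_gram = target_wfps * phys.porosity / phys.bulk_density - phys.gravimetric_moisture
    volume = dry_mass * per_gram
    if volume < 0:
        return WaterAddition(0.0, over_wet=True)
    return WaterAddition(volume, over_wet=False)


def extract_to_soil_concentration(
    mg_per_l: float, extract_volume_l: float, dry_mass_g: float
) -> float:
    """Convert an extract concentration (mg N L-1) to ug N per g dry soil,
    assuming complete extraction."""
    if not dry_mass_g > 0:
        raise ValueError("dry_mass_g must be positive")
    if extract_volume_l < 0:
        raise ValueError("extract_volume_l must be >= 0")
    return mg_per_l * extract_volume_l / dry_mass_g * 1000.0
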