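"""Annual, per-hectare N-fixation inputs from per-gram incubation rates.

Laboratory vial rates (ug N per g sample per day) are extrapolated to a
field year in three steps:

1. a growing-season partition assigns each sampling period a number of
   days (default 120 d total: pre-fertilization 20, post-fertilization 40,
   peak biomass 60; the post-senescence sampling is excluded by default);
2. soil rates are divided by the glucose stimulation factor (default 4.8),
   the mean factor by which the glucose amendment used to relieve carbon
   limitation in the soil assay inflates fixation — root assays show no
   glucose response, so root rates are used as measured;
3. per-gram rates become areal fluxes through the sampled soil mass
   (bulk density x core depth) for soils, or the areal root biomass for
   roots, then convert ug ha-1 to kg ha-1.

Period SEs propagate through the same linear map and combine in quadrature
across periods (separate samplings, assumed independent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_SEASON_DAYS",
    "GLUCOSE_FACTOR",
    "ScalingParams",
    "SeasonalRates",
    "ArealEstimate",
    "annual_soil_anf",
    "annual_root_anf",
    "period_means",
]

#: Default growing-season partition, days per sampling period.
DEFAULT_SEASON_DAYS: dict[str, float] = {
    "pre_fertilizer": 20.0,
    "post_fertilizer": 40.0,
    "peak_biomass": 60.0,
}

#: Mean factor by which glucose solution stimulates soil fixation.
GLUCOSE_FACTOR = 4.8

_UG_PER_CM2_TO_KG_PER_HA = 1e8 * 1e-9  # cm2 per ha x kg per ug = 0.1
_UG_PER_M2_TO_KG_PER_HA = 1e4 * 1e-9


@dataclass
class ScalingParams:
    """Site parameters for areal/annual scaling.

    ``bulk_density`` (g cm-3) and ``core_depth`` (cm) define the sampled
    soil mass; no extrapolation below the cored depth is attempted.
    ``root_biomass_areal`` is g root m-2 to the stated rooting depth.
    ``season_days`` may include an explicit ``senescence`` entry to extend
    the season beyond the default 120-d window (off by default).
    """

    bulk_density: float
    core_depth: float
    glucose_factor: float = GLUCOSE_FACTOR
    season_days: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEASON_DAYS)
    )
    root_biomass_areal: float | None = None
    apply_glucose_correction: Mapping[str, bool] = field(
        default_factory=lambda: {"soil": True, "root": False}
    )

    def __post_init__(self) -> None:
        if not self.bulk_density > 0 or not self.core_depth > 0:
            raise ValueError("bulk_density and core_depth must be positive")
        if not self.glucose_factor > 0:
            raise ValueError("glucose_factor must be positive")
        if any(d <= 0 for d in self.season_days.values()):
            raise ValueError("season_days must all be positive")
        if self.root_biomass_areal is not None and self.root_biomass_areal < 0:
            raise ValueError("root_biomass_areal must be >= 0")

    @property
    def season_length(self) -> float:
        return float(sum(self.season_days.values()))


@dataclass
class SeasonalRates:
    """Per-period mean fixation rates (ug N g-1 d-1) with SEs for one
    sample kind."""

    sample_kind: str
    rates: Mapping[str, tuple[float, float]]  # period -> (mean, se)

    def __post_init__(self) -> None:
        if self.sample_kind not in ("soil", "root"):
            raise ValueError("sample_kind must be 'soil' or 'root'")
        for period, (mean, se) in self.rates.items():
            if mean < 0 or se < 0:
                raise ValueError(f"negative rate or SE in period {period!r}")


@dataclass(frozen=True)
class ArealEstimate:
    """An annual areal flux, kg N ha-1 yr-1, with standard error."""

    value: float
    se: float


def _seasonal_sum(rates: SeasonalRates, p: ScalingParams, divisor: float) -> tuple[float, float]:
    """Sum rate x days / divisor over the season partition, with quadrature SE.

    Every period in the partition must have a measured rate; missing
    periods raise rather than silently extrapolating.
    """
    missing = [k for k in p.season_days if k not in rates.rates]
    if missing:
        raise ValueError(f"no rates for season periods: {missing}")
    total = 0.0
    var = 0.0
    for period, days in p.season_days.items():
        mean, se = rates.rates[period]
        total += mean * days / divisor
        var += (se * days / divisor) ** 2
    return total, math.sqrt(var)


def annual_soil_anf(rates: SeasonalRates, p: ScalingParams) -> ArealEstimate:
    """Annual soil fixation input, kg N ha-1 yr-1.

    Glucose-corrected per-gram rates, integrated over the season partition,
    times the areal mass of the cored soil layer.
    """
    if rates.sample_kind != "soil":
        raise ValueError("annual_soil_anf requires soil rates")
    divisor = p.glucose_factor if p.apply_glucose_correction.get("soil", True) else 1.0
    per_gram, per_gram_se = _seasonal_sum(rates, p, divisor)
    areal = p.bulk_density * p.core_depth * _UG_PER_CM2_TO_KG_PER_HA
    return ArealEstimate(per_gram * areal, per_gram_se * areal)


def annual_root_anf(rates: SeasonalRates, p: ScalingParams) -> ArealEstimate:
    """Annual root fixation input, kg N ha-1 yr-1.

    Rates as measured (no glucose correction), integrated over the season,
    times areal root biomass; fixation is assumed depth-invariant within
    the rooting zone the biomass estimate covers.
    """
    if rates.sample_kind != "root":
        raise ValueError("annual_root_anf requires root rates")
    if p.root_biomass_areal is None:
        raise ValueError("root_biomass_areal is required for root scaling")
    divisor = p.glucose_factor if p.apply_glucose_correction.get("root", False) else 1.0
    per_gram, per_gram_se = _seasonal_sum(rates, p, divisor)
    areal = p.root_biomass_areal * _UG_PER_M2_TO_KG_PER_HA
    return ArealEstimate(per_gram * areal, per_gram_se * areal)


def period_means(
    df: pd.DataFrame,
    value_col: str = "rate_per_gram",
    sample_kind: str = "soil",
    period_col: str = "period",
) -> SeasonalRates:
    """Aggregate a per-vial rate table to period means with SEs.

    SE is the standard error of the mean across vials within a period
    (ddof=1); a single-vial period gets SE 0.
    """
    if period_col not in df.columns or value_col not in df.columns:
        raise ValueError(f"table must have columns {period_col!r} and {value_col!r}")
    rates: dict[str, tuple[float, float]] = {}
    for period, grp in df.groupby(period_col):
        vals = grp[value_col].to_numpy(dtype=float)
        mean = float(np.mean(vals))
        se = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rates[str(period)] = (max(mean, 0.0), se)
    return SeasonalRates(sample_kind=sample_kind, rates=rates)
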