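"""Plot-level annual and cumulative nitrogen mass balance.

The balance for a plot-year is inputs minus outputs:

    balance = fertilizer + atmospheric deposition - harvest N removal

(optionally minus leaching and denitrification terms, which default to 0 so
a deficit estimated without them is conservative). A negative balance is a
deficit: N leaving in harvest exceeded known inputs, implying an unmeasured
source such as associative fixation.

Inputs are treated as exact; all uncertainty comes from the harvest N
output SE, so the annual-balance SE equals the N-output SE, cumulative SEs
combine in quadrature across years, and the SE of the mean is the
cumulative SE over the number of years. Arithmetic is carried at full
precision; rounding to 0.1 kg is left to reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlotYearRecord",
    "BalanceLedger",
    "n_output_from_yield",
    "annual_balance",
    "ledger",
    "records_from_dataframe",
]


def n_output_from_yield(yield_mg_ha: float, tissue_n_pct: float) -> float:
    """Harvest N removal, kg N ha-1, from dry yield (Mg ha-1) and tissue %N.

    1 Mg ha-1 at 1% N removes 10 kg N ha-1.
    """
    if yield_mg_ha < 0 or tissue_n_pct < 0:
        raise ValueError("yield and tissue N percent must be >= 0")
    return yield_mg_ha * tissue_n_pct * 10.0


@dataclass
class PlotYearRecord:
    """One plot-year of the N ledger (treatment means across field blocks).

    ``n_output_kg`` may be given directly (as published) or derived from
    ``yield_mg_ha`` and ``tissue_n_pct``. When both are given they must be
    mutually consistent to within 0.5 kg (printed-value rounding slack).
    """

    year: int
    treatment_kg_n: float
    deposition_kg_n: float
    yield_mg_ha: float = math.nan
    yield_se: float = math.nan
    tissue_n_pct: float | None = None
    n_output_kg: float = math.nan
    n_output_se: float = 0.0
    leaching_kg: float = 0.0
    denitrification_kg: float = 0.0
    deposition_borrowed: bool = False  # deposition filled from a multi-year mean

    def __post_init__(self) -> None:
        for name in ("treatment_kg_n", "deposition_kg_n", "n_output_se",
                     "leaching_kg", "denitrification_kg"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if math.isnan(self.n_output_kg):
            if self.tissue_n_pct is None or math.isnan(self.yield_mg_ha):
                raise ValueError(
                    "n_output_kg missing and not derivable from yield x tissue %N"
                )
            self.n_output_kg = n_output_from_yield(self.yield_mg_ha, self.tissue_n_pct)
        elif self.tissue_n_pct is not None and not math.isnan(self.yield_mg_ha):
            derived = n_output_from_yield(self.yield_mg_ha, self.tissue_n_pct)
            if abs(derived - self.n_output_kg) > 0.5:
                raise ValueError(
                    f"n_output_kg {self.n_output_kg} inconsistent with "
                    f"yield x tissue %N ({derived:.2f})"
                )


def annual_balance(rec: PlotYearRecord) -> tuple[float, float]:
    """(balance, SE) for one plot-year, kg N ha-1 yr-1.

    Negative = deficit. SE equals the harvest N-output SE (inputs exact).
    """
    bal = (
        rec.treatment_kg_n
        + rec.deposition_kg_n
        - rec.n_output_kg
        - rec.leaching_kg
        - rec.denitrification_kg
    )
    return bal, rec.n_output_se


@dataclass
class BalanceLedger:
    """Per-year and aggregate N balances with propagated SEs.

    Results container built by :func:`ledger`. ``per_year`` is a DataFrame
    indexed by year with columns ``balance`` and ``se``; aggregates satisfy
    cumulative = sum of annual balances, mean = cumulative / n_years,
    SE(cumulative) = quadrature of annual SEs, SE(mean) = SE(cumulative)/n.
    """

    per_year: pd.DataFrame
    cumulative: float
    cumulative_se: float
    mean: float
    mean_se: float
    n_years: int
    mean_deposition: float

    @property
    def cumulative_deficit(self) -> float:
        """Magnitude of the cumulative balance when it is negative, else 0."""
        return max(-self.cumulative, 0.0)

    @property
    def mean_deficit(self) -> float:
        return max(-self.mean, 0.0)

    def window(self, start: int, stop: int) -> tuple[float, float]:
        """(mean balance, SE of mean) over years in [start, stop] inclusive."""
        sub = self.per_year.loc[(self.per_year.index >= start) & (self.per_year.index <= stop)]
        if sub.empty:
            raise ValueError(f"no years in window [{start}, {stop}]")
        n = len(sub)
        mean = float(sub["balance"].sum()) / n
        se = float(np.sqrt(np.sum(sub["se"].to_numpy() ** 2))) / n
        return mean, se

    def summary(self) -> str:
        lines = [
            "N mass balance ledger (kg N ha-1; negative = deficit)",
            "-" * 54,
            f"{'year':>6} {'balance':>9} {'se':>7}",
        ]
        for year, row in self.per_year.iterrows():
            lines.append(f"{year:>6} {row['balance']:>9.1f} {row['se']:>7.1f}")
        lines += [
            "-" * 54,
            f"cumulative ({self.n_years} yr): {self.cumulative:.1f} "
            f"(SE {self.cumulative_se:.1f})",
            f"mean annual:        {self.mean:.1f} (SE {self.mean_se:.1f})",
            f"mean deposition:    {self.mean_deposition:.1f}",
        ]
        return "\n".join(lines)


def ledger(records: Iterable[PlotYearRecord]) -> BalanceLedger:
    """Build the multi-year ledger from plot-year records (unique years)."""
    recs = sorted(records, key=lambda r: r.year)
    if not recs:
        raise ValueError("need at least one record")
    years = [r.year for r in recs]
    if len(set(years)) != len(years):
        dupes = sorted({y for y in years if years.count(y) > 1})
        raise ValueError(f"duplicate years in ledger: {dupes}")
    rows = [annual_balance(r) for r in recs]
    per_year = pd.DataFrame(rows, columns=["balance", "se"], index=pd.Index(years, name="year"))
    n = len(recs)
    cumulative = float(per_year["balance"].sum())
    cumulative_se = float(np.sqrt(np.sum(per_year["se"].to_numpy() ** 2)))
    return BalanceLedger(
        per_year=per_year,
        cumulative=cumulative,
        cumulative_se=cumulative_se,
        mean=cumulative / n,
        mean_se=cumulative_se / n,
        n_years=n,
        mean_deposition=float(np.mean([r.deposition_kg_n for r in recs])),
    )


def records_from_dataframe(
    df: pd.DataFrame, treatment: float | None = None
) -> list[PlotYearRecord]:
    """Build records from a plot-years table (one row per year x treatment).

    Missing deposition cells are filled with the mean of the available
    years and flagged ``deposition_borrowed``.
    """
    sub = df if treatment is None else df[df["treatment_kg_n"] == treatment]
    if sub.empty:
        raise ValueError(f"no rows for treatment {treatment}")
    dep = sub["deposition_kg_n"]
    dep_mean = float(dep.dropna().mean()) if dep.notna().any() else math.nan
    records = []
    for _, row in sub.iterrows():
        borrowed = bool(pd.isna(row["deposition_kg_n"]))
        records.append(
            PlotYearRecord(
                year=int(row["year"]),
                treatment_kg_n=float(row["treatment_kg_n"]),
                deposition_kg_n=dep_mean if borrowed else float(row["deposition_kg_n"]),
                yield_mg_ha=float(row.get("yield_mg_ha", math.nan)),
                yield_se=float(row.get("yield_se", math.nan)),
                n_output_kg=float(row.get("n_output_kg", math.nan)),
                n_output_se=float(row.get("n_output_se", 0.0)),
                deposition_borrowed=borrowed,
            )
        )
    return records
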