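"""Shared fixtures: pipeline helpers over synthetic studies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from anfbudget.isotope_anf import IncubationVial, fixation_rate, headspace_atom_excess
from anfbudget.n_transform import (
    MineralizationAssay,
    net_mineralization,
    net_nitrification,
    relative_nitrification,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

VIAL_FIELDS = [
    "sample_kind", "dry_mass", "total_n", "atom_pct_treatment", "atom_pct_control",
    "vial_volume", "occupied_volume", "removed_volume", "tracer_volume",
    "tracer_enrichment", "duration",
]


def anf_rates_table(vials: pd.DataFrame) -> pd.DataFrame:
    """Run the vial table through the isotope rate pipeline."""
    rows = []
    for _, row in vials.iterrows():
        vial = IncubationVial(**{k: row[k] for k in VIAL_FIELDS})
        res = fixation_rate(vial, headspace_atom_excess(vial))
        rows.append({
            "site": row["site"], "treatment_kg_n": row["treatment_kg_n"],
            "period": row["period"], "block": row["block"],
            "sample_kind": row["sample_kind"],
            "rate_per_gram": res.rate_per_gram,
            "raw_rate_per_gram": res.raw_rate_per_gram,
            "below_detection": res.below_detection,
        })
    return pd.DataFrame(rows)


def minz_rates_table(assays: pd.DataFrame) -> pd.DataFrame:
    """Run the assay table through the mineralization calculus."""
    rows = []
    for _, row in assays.iterrows():
        assay = MineralizationAssay(
            row["nitrate_t0"], row["ammonium_t0"],
            row["nitrate_t28"], row["ammonium_t28"], duration=row["duration_d"],
        )
        rows.append({
            "site": row["site"], "treatment_kg_n": row["treatment_kg_n"],
            "period": row["period"], "block": row["block"],
            "net_mineralization": net_mineralization(assay),
            "net_nitrification": net_nitrification(assay),
            "relative_nitrification_pct": relative_nitrification(assay),
        })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def zero_noise_study():
    from anfbudget.synthetic_data import default_truth, simulate_study

    truth = default_truth(
        seed=7, atom_pct_sd=0.0, extract_cv=0.0, yield_cv=0.0, block_cv=0.0
    )
    return simulate_study(truth)


@pytest.fixture(scope="session")
def default_noise_study():
    from anfbudget.synthetic_data import default_truth, simulate_study

    return simulate_study(default_truth(seed=11))


@pytest.fixture(scope="session")
def table1():
    from anfbudget.synthetic_data import make_table1_fixture

    return make_table1_fixture()
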