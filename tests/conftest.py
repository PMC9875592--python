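"""Shared fixtures: synthetic reference tables and cohorts.

All tables used in tests are synthetic (round numbers), so nothing depends
on the transcription bundled as package data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

# reproducible property tests: no example database, fixed derivation
settings.register_profile("ci", derandomize=True, database=None)
settings.load_profile("ci")

from dii_retinopathy.reference import (
    PER_1000_KCAL,
    RAW,
    DIIComponent,
    DIIReferenceTable,
)
from dii_retinopathy.simulate import SimulationConfig, simulate_cohort
from dii_retinopathy.cohort import apply_exclusions, encode_covariates


@pytest.fixture(scope="session")
def density_table3() -> DIIReferenceTable:
    """Three components per 1,000 kcal, one pro- and two anti-inflammatory."""
    return DIIReferenceTable(
        components=(
            DIIComponent("fiber", 10.0, 2.0, -0.6, unit="g"),
            DIIComponent("saturated_fat", 14.0, 4.0, 0.4, unit="g"),
            DIIComponent("vitamin_c", 60.0, 20.0, -0.4, unit="mg"),
        ),
        mode=PER_1000_KCAL,
        source="synthetic test table",
    )


@pytest.fixture(scope="session")
def raw_table3() -> DIIReferenceTable:
    return DIIReferenceTable(
        components=(
            DIIComponent("fiber", 20.0, 4.0, -0.6, unit="g"),
            DIIComponent("saturated_fat", 28.0, 8.0, 0.4, unit="g"),
            DIIComponent("energy", 2000.0, 400.0, 0.18, unit="kcal"),
        ),
        mode=RAW,
        source="synthetic test table",
    )


def random_table(rng: np.random.Generator, n: int = 5, mode: str = RAW) -> DIIReferenceTable:
    comps = tuple(
        DIIComponent(
            name=f"c{i}",
            global_mean=float(rng.uniform(1, 100)),
            global_sd=float(rng.uniform(0.5, 20)),
            effect_score=float(rng.uniform(-1, 1)),
        )
        for i in range(n)
    )
    return DIIReferenceTable(components=comps, mode=mode, source="random")


@pytest.fixture(scope="session")
def study_cohort(density_table3):
    """Default-world cohort at the study size, scored and encoded."""
    df, truth = simulate_cohort(SimulationConfig(n=2403, seed=11), density_table3)
    kept, _ = apply_exclusions(df)
    return encode_covariates(kept), truth
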