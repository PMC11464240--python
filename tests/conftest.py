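"""Shared fixtures: small handcrafted record sets and synthetic datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vitalfit.records_io import ATTRIBUTES, INJURIES, REFLEXES, RecordSet
from vitalfit.synthetic_data import (  # noqa: F401 - re-exported for tests
    default_config,
    generate,
    single_attribute_config,
)


def make_recordset(
    attributes: np.ndarray,
    mortality: np.ndarray,
    trips: list | None = None,
    gears: list | None = None,
    vitality: list | None = None,
    **covariates,
) -> RecordSet:
    """Build a RecordSet directly from an (n, 10) attribute matrix."""
    attributes = np.asarray(attributes, dtype=int)
    n = len(attributes)
    trips = trips if trips is not None else ["T01"] * n
    df = pd.DataFrame({
        "fish_id": [f"F{i:04d}" for i in range(n)],
        "trip_id": trips,
        "deployment_id": [f"{t}_D1" for t in trips],
        "gear_type": gears if gears is not None else ["BT2"] * n,
    })
    defaults = {"sea_temp": 12.0, "depth": 30.0, "duration": 90.0,
                "total_catch": 800.0, "air_exposure": 10.0, "length": 23.0}
    for col, val in defaults.items():
        df[col] = covariates.get(col, val)
    for j, a in enumerate(ATTRIBUTES):
        df[a] = attributes[:, j]
    for inj in INJURIES:
        df[f"{inj}_raw"] = df[inj]
    n_reflex = attributes[:, : len(REFLEXES)].sum(axis=1)
    if vitality is None:
        vitality = np.select(
            [n_reflex == 0, n_reflex <= 2, n_reflex <= 5], ["A", "B", "C"], "D")
    df["vitality"] = vitality
    df["mortality"] = np.asarray(mortality, dtype=int)
    return RecordSet(df, provenance="fixture")


def random_recordset(rng: np.random.Generator, n: int = 100,
                     n_trips: int = 4) -> RecordSet:
    """Random attributes/outcomes over a few trips (no structure)."""
    attributes = rng.integers(0, 2, size=(n, 10))
    mortality = rng.integers(0, 2, size=n)
    trips = [f"T{1 + i % n_trips:02d}" for i in range(n)]
    return make_recordset(attributes, mortality, trips=trips)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def study_like():
    """Default synthetic dataset with study-shaped structure + truth."""
    rs, truth = generate(default_config(), seed=11)
    return rs, truth
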