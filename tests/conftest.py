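"""Shared fixtures: deterministic RNGs, a dealer, small private columns and
synthetic two-site cohorts (all generated at test time, nothing on disk)."""

from __future__ import annotations

import numpy as np
import pytest

from fedstats import ring as R
from fedstats.cohort import CohortConfig, generate_site
from fedstats.stats import SecureStats
from fedstats.table import CATEGORICAL, METRIC, ColumnSpec, PrivateColumn

# the 24-element age vector whose five-number summary matches the printed
# single-site session output {38.0, 62.5, 66.0, 72.25, 91.0}
CONFORMANCE_AGES = [38, 50, 50, 50, 50, 62.5, 62.5, 63, 64, 65, 65, 66,
                    66, 67, 68, 69, 70, 72, 73, 75, 80, 85, 90, 91]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def store() -> R.TripleStore:
    return R.TripleStore(seed=54321)


@pytest.fixture
def engine(store) -> SecureStats:
    return SecureStats(store, sdc_threshold=0)


def make_metric_column(values, rng, name="x", unit="", min_value=None
                       ) -> PrivateColumn:
    spec = ColumnSpec(name, METRIC, unit=unit, min_value=min_value)
    return PrivateColumn(spec=spec, values=R.share(values, rng, kind=R.FIXED))


def make_categorical_column(codes, categories, rng, name="k") -> PrivateColumn:
    spec = ColumnSpec(name, CATEGORICAL, tuple(categories))
    return PrivateColumn(spec=spec, values=R.share(codes, rng, kind=R.INT))


@pytest.fixture(scope="session")
def site_csvs() -> tuple[str, str]:
    """Two deterministic 24-patient synthetic site files."""
    cfg = CohortConfig()
    munich, _ = generate_site(cfg, 1001, "munich")
    rome, _ = generate_site(cfg, 1002, "rome")
    return munich, rome
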