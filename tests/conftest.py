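"""Shared fixtures: a small synthetic study system reused across tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from shortcutflux.config import PipelineConfig
from shortcutflux.pipeline import Dataset, build_synthetic_dataset, run_pipeline
from shortcutflux.synthetic import (
    CatchmentConfig,
    ObservationConfig,
    RainfallConfig,
    generate_applications,
    generate_catchment,
    generate_rainfall,
    simulate_observations,
)
from shortcutflux.substances import default_substances

SMALL = dict(grid_nrows=60, grid_ncols=100, n_inlets=40, n_substances=6)


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    return PipelineConfig(seed=1, **SMALL)


@pytest.fixture(scope="session")
def small_dataset(small_config) -> Dataset:
    return build_synthetic_dataset(small_config)


@pytest.fixture(scope="session")
def small_report(small_config, small_dataset):
    return run_pipeline(small_config, dataset=small_dataset)


@pytest.fixture(scope="session")
def small_catchment():
    return generate_catchment(CatchmentConfig(nrows=48, ncols=80, n_inlets=24), seed=3)


def minute_series(depths_mm, start="2019-05-01"):
    """Helper: a 1-min rainfall series from a list of depths."""
    idx = pd.date_range(start, periods=len(depths_mm), freq="1min")
    return pd.Series(np.asarray(depths_mm, dtype=float), index=idx, name="depth_mm")
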