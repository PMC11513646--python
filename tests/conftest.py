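"""Shared fixtures: small simulated datasets and helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from movesoc.simulate import GeneratorConfig, SimulatedData, simulate_dataset
from movesoc.trajectory import PathSegment


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(n_individuals=6, n_males=1, n_days=8, day_seconds=900)


@pytest.fixture(scope="session")
def small_sim(small_config) -> SimulatedData:
    return simulate_dataset(small_config, seed=2024)


@pytest.fixture(scope="session")
def default_sim() -> tuple[GeneratorConfig, SimulatedData]:
    cfg = GeneratorConfig(n_days=12)
    return cfg, simulate_dataset(cfg, seed=77)


def random_segment(rng: np.random.Generator, n: int = 30, interval: float = 60.0) -> PathSegment:
    """A random two-regime path segment for oracle comparisons."""
    t = np.arange(n, dtype=float) * interval
    steps = np.where(
        rng.random(n - 1) < 0.4,
        rng.exponential(2.0, n - 1),        # dwell-like
        rng.exponential(15.0, n - 1),       # transit-like
    )
    headings = np.cumsum(rng.normal(0.0, 1.2, n - 1))
    x = np.concatenate(([0.0], np.cumsum(steps * np.cos(headings))))
    y = np.concatenate(([0.0], np.cumsum(steps * np.sin(headings))))
    return PathSegment(t=t, x=x, y=y)
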