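"""Shared fixtures: small deterministic networks and signal sets."""

from __future__ import annotations

import numpy as np
import pytest

from iecflow import RegionTimeSeries, WeightedDigraph


def labels(n: int) -> list[str]:
    return [f"R{i:03d}" for i in range(n)]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def toy_digraph() -> WeightedDigraph:
    """The hand-worked 3-region signed toy (rows = targets)."""
    w = np.array([[0.0, 2.0, -1.0], [0.0, 0.0, 3.0], [-2.0, 0.0, 0.0]])
    return WeightedDigraph(w, labels(3), kind="EC")


@pytest.fixture
def random_ts(rng) -> RegionTimeSeries:
    return RegionTimeSeries(rng.standard_normal((6, 400)), labels(6), dt=0.72)


def make_ts(values: np.ndarray, dt: float = 1.0) -> RegionTimeSeries:
    return RegionTimeSeries(values, labels(values.shape[0]), dt=dt)


def random_digraph(n: int, seed: int, kind: str = "EC") -> WeightedDigraph:
    r = np.random.default_rng(seed)
    w = r.normal(0, 1, (n, n))
    np.fill_diagonal(w, 0.0)
    return WeightedDigraph(w, labels(n), kind=kind)
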