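"""Shared domain types, file I/O and run configuration.

Matrix orientation is fixed package-wide: **rows are targets, columns are
sources**, i.e. ``W[i, j]`` is the weight of the directed edge ``j -> i``.
Much of the graphical-model literature uses the transpose; every estimator
in this package emits the row=target convention and every consumer assumes
it.

Region ordering is authoritative from file order.  Cross-object operations
verify label-sequence equality and refuse silent reindexing.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RegionTimeSeries",
    "WeightedDigraph",
    "ModulePartition",
    "MATRIX_KINDS",
    "read_matrix",
    "write_matrix",
    "read_timeseries",
    "write_timeseries",
    "read_partition",
    "write_partition",
    "load_config",
    "get_logger",
    "check_same_regions",
]

#: matrix kinds with contract-level meaning.  ``EC`` and ``ground_truth``
#: must have a zero diagonal; ``SLN`` may contain NaN for unmeasured pairs.
MATRIX_KINDS = ("EC", "SC", "ground_truth", "SLN")

_LOG_FORMAT = "%(asctime)s %(name)s %(levelname)s: %(message)s"


def get_logger(name: str = "iecflow") -> logging.Logger:
    """Package logger writing to stderr."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(_LOG_FORMAT))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


logger = get_logger()


def _check_unique_labels(labels: Sequence[str]) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        raise ValueError("region_ids must be unique")
    if any(lab == "" for lab in labels):
        raise ValueError("empty region label")
    return labels


@dataclass
class RegionTimeSeries:
    """Region x time signal matrix with its sampling interval.

    Parameters
    ----------
    values : ndarray, shape (n_regions, n_timepoints)
        Real-valued activations; no missing values allowed.
    region_ids : sequence of str
        Ordered, unique region labels.
    dt : float
        Sampling interval in seconds.
    """

    values: np.ndarray
    region_ids: list[str]
    dt: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (regions x timepoints)")
        n, t = self.values.shape
        if n < 2:
            raise ValueError("need >=2 regions")
        if t < 3:
            raise ValueError("need >=3 timepoints")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains missing/non-finite values")
        self.region_ids = _check_unique_labels(self.region_ids)
        if len(self.region_ids) != n:
            raise ValueError("region_ids length does not match values")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class WeightedDigraph:
    """Square signed weighted matrix, rows = targets / columns = sources.

    ``kind`` carries the contract: EC and ground-truth matrices have a zero
    diagonal; SLN-like matrices may hold NaN for unmeasured pairs.
    ``meta`` carries sidecar information such as a planted hierarchy.
    """

    weights: np.ndarray
    region_ids: list[str]
    kind: str = "EC"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("weights must be a square matrix")
        self.region_ids = _check_unique_labels(self.region_ids)
        if len(self.region_ids) != self.weights.shape[0]:
            raise ValueError("region_ids length does not match matrix size")
        if self.kind != "SLN" and not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite weights (NaN only allowed for kind='SLN')")
        if self.kind in ("EC", "ground_truth") and np.any(np.diag(self.weights) != 0):
            raise ValueError(f"kind={self.kind!r} requires a zero diagonal")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def copy(self) -> "WeightedDigraph":
        return WeightedDigraph(
            self.weights.copy(), list(self.region_ids), self.kind, dict(self.meta)
        )


@dataclass
class ModulePartition:
    """Mapping region_id -> module label with an explicit module order."""

    assignment: dict[str, str]
    module_order: list[str]

    def __post_init__(self) -> None:
        self.assignment = {str(k): str(v) for k, v in self.assignment.items()}
        self.module_order = [str(m) for m in self.module_order]
        if len(set(self.module_order)) != len(self.module_order):
            raise ValueError("module_order has duplicates")
        used = set(self.assignment.values())
        missing = used - set(self.module_order)
        if missing:
            raise ValueError(f"module_order does not cover labels: {sorted(missing)}")

    def members(self, module: str) -> list[str]:
        return [r for r, m in self.assignment.items() if m == module]

    def module_of(self, region: str) -> str:
        return self.assignment[region]


# ---------------------------------------------------------------------------
# File I/O.  Dense labeled TSV is the canonical interchange format; HDF5 is
# supported for large time series (single dataset + label/dt attributes).
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path, kind: str = "EC") -> WeightedDigraph:
    """Read a labeled square TSV matrix.

    Header row and first column must hold identical ordered region labels.
    For ``kind='EC'`` a nonzero diagonal is forced to zero with a warning.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"non-square matrix body {df.shape} in {path}")
    rows = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if rows != cols:
        raise ValueError(f"row/column label mismatch in {path}")
    try:
        body = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if kind in ("EC", "ground_truth") and np.any(np.diag(body) != 0):
        logger.warning("forcing nonzero diagonal to zero for kind=%s (%s)", kind, path)
        np.fill_diagonal(body, 0.0)
    return WeightedDigraph(body, rows, kind=kind)


def write_matrix(g: WeightedDigraph, path: str | Path) -> Path:
    """Write a digraph as labeled TSV; round-trips losslessly."""
    path = Path(path)
    df = pd.DataFrame(g.weights, index=g.region_ids, columns=g.region_ids)
    df.to_csv(path, sep="\t", float_format="%.17g")
    return path


def read_timeseries(path: str | Path, dt: float) -> RegionTimeSeries:
    """Read a region x time TSV (rows = regions, leading label column) or HDF5."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            values = f["values"][()]
            labels = [
                x.decode() if isinstance(x, bytes) else str(x)
                for x in f["values"].attrs["region_ids"]
            ]
            dt = float(f["values"].attrs.get("dt", dt))
        return RegionTimeSeries(values, labels, dt)
    df = pd.read_csv(path, sep="\t", index_col=0, header=None)
    values = df.to_numpy(dtype=float)
    if np.any(pd.isna(values)):
        raise ValueError(f"missing values in time series {path}")
    return RegionTimeSeries(values, [str(x) for x in df.index], dt)


def write_timeseries(ts: RegionTimeSeries, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            d = f.create_dataset("values", data=ts.values)
            d.attrs["region_ids"] = [s.encode() for s in ts.region_ids]
            d.attrs["dt"] = ts.dt
        return path
    pd.DataFrame(ts.values, index=ts.region_ids).to_csv(
        path, sep="\t", header=False, float_format="%.17g"
    )
    return path


def read_partition(path: str | Path) -> ModulePartition:
    """Read a two-column TSV (region_id, module) into a ModulePartition.

    Module order follows first appearance in the file.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["region", "module"])
    assignment = dict(zip(df["region"].astype(str), df["module"].astype(str)))
    if len(assignment) != len(df):
        raise ValueError("duplicate region in partition file")
    order = list(dict.fromkeys(df["module"].astype(str)))
    return ModulePartition(assignment, order)


def write_partition(p: ModulePartition, path: str | Path) -> Path:
    path = Path(path)
    rows = sorted(p.assignment.items(), key=lambda kv: p.module_order.index(kv[1]))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
    return path


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, Mapping):
        raise ValueError("configuration must be a mapping")
    return dict(cfg)


def check_same_regions(*objs) -> list[str]:
    """Verify all objects carry the identical ordered region labels.

    Raises on any mismatch — silent reindexing is never performed.
    """
    ids = [list(o.region_ids) for o in objs]
    first = ids[0]
    for other in ids[1:]:
        if other != first:
            raise ValueError(
                "region label sequences differ between objects; "
                "reorder inputs explicitly before combining"
            )
    return first
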