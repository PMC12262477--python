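"""Scoring of EC estimates and simulated signals.

Static functional connectivity (FC), sliding-window functional connectivity
dynamics (FCD) with the Kolmogorov-Smirnov distance between FCD
distributions, the composite fit ``fit = r - KS``, the time-delay (TD)
projection of intrinsic lags, and the directionality F1 score against a
ground-truth graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import RegionTimeSeries, WeightedDigraph, check_same_regions, get_logger

__all__ = [
    "FitReport",
    "static_fc",
    "fcd_distribution",
    "ks_distance",
    "composite_fit",
    "time_delay_projection",
    "f1_directionality",
]

logger = get_logger(__name__)


@dataclass
class FitReport:
    """Composite fit between an empirical and a simulated signal set."""

    fc_correlation: float
    fcd_ks: float
    fit: float
    td_correlation: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fcd_ks <= 1.0:
            raise ValueError("KS statistic must lie in [0, 1]")
        if not -2.0 <= self.fit <= 1.0:
            raise ValueError("fit must lie in [-2, 1]")


def static_fc(ts: RegionTimeSeries) -> WeightedDigraph:
    """Pearson correlation matrix across regions (symmetric)."""
    if ts.n_timepoints < 3:
        raise ValueError("need >= 3 timepoints")
    sd = ts.values.std(axis=1)
    if np.any(sd == 0):
        bad = [ts.region_ids[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"zero-variance region(s): {bad}")
    fc = np.corrcoef(ts.values)
    return WeightedDigraph(fc, list(ts.region_ids), kind="SC", meta={"metric": "FC"})


def fcd_distribution(
    ts: RegionTimeSeries, window: int = 30, step: int = 3
) -> np.ndarray:
    """Upper-triangular entries of the FCD matrix.

    Sliding-window FC is computed per window; the FCD matrix is the Pearson
    correlation between the vectorized upper-triangular window-FCs for every
    pair of windows.  The returned vector has length w(w-1)/2 for w windows.
    """
    if window < 5:
        raise ValueError("window must be >= 5 samples")
    t = ts.n_timepoints
    if t < 2 * window:
        raise ValueError("duration must be >= 2x window")
    starts = range(0, t - window + 1, step)
    iu = np.triu_indices(ts.n_regions, k=1)
    vecs = []
    for s in starts:
        seg = ts.values[:, s : s + window]
        sd = seg.std(axis=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance region inside a window")
        vecs.append(np.corrcoef(seg)[iu])
    V = np.asarray(vecs)
    fcd = np.corrcoef(V)
    w = len(vecs)
    return fcd[np.triu_indices(w, k=1)]


def ks_distance(d1: np.ndarray, d2: np.ndarray) -> float:
    """Sup-norm distance between the empirical CDFs of two samples."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.size == 0 or d2.size == 0:
        raise ValueError("empty distribution")
    return float(stats.ks_2samp(d1, d2, method="asymp").statistic)


def composite_fit(
    empirical_ts: RegionTimeSeries,
    simulated_ts: RegionTimeSeries,
    window: int = 30,
    step: int = 3,
) -> FitReport:
    """fit = corr(off-diagonal static FCs) - KS(FCD distributions).

    Both components are invariant under any common positive affine
    rescaling of either signal set; a self-fit scores exactly 1.
    """
    check_same_regions(empirical_ts, simulated_ts)
    fc_e = static_fc(empirical_ts).weights
    fc_s = static_fc(simulated_ts).weights
    mask = ~np.eye(fc_e.shape[0], dtype=bool)
    r = float(np.corrcoef(fc_e[mask], fc_s[mask])[0, 1])
    ks = ks_distance(
        fcd_distribution(empirical_ts, window, step),
        fcd_distribution(simulated_ts, window, step),
    )
    return FitReport(fc_correlation=r, fcd_ks=ks, fit=r - ks)


def _xcov(a: np.ndarray, b: np.ndarray, max_lag: int) -> np.ndarray:
    """Cross-covariance c(l) = cov(a(t), b(t+l)) for l in [-max_lag, max_lag]."""
    a = a - a.mean()
    b = b - b.mean()
    t = len(a)
    full = np.correlate(b, a, mode="full")  # index t-1+l corresponds to lag l
    lags = np.arange(-max_lag, max_lag + 1)
    return full[t - 1 + lags] / t


def time_delay_projection(
    ts: RegionTimeSeries, max_lag: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Per-region mean intrinsic lag (seconds) and the pairwise lag matrix.

    For each pair the extremum of the lagged cross-covariance is refined by
    parabolic interpolation; ``L[i, j] > 0`` means region i precedes region
    j.  Extrema pinned at the lag-window edge are censored (NaN) and
    excluded from the row mean.  The projection is the row mean over all
    columns (diagonal zero included).
    """
    t = ts.n_timepoints
    if max_lag >= t / 4:
        raise ValueError("max_lag too large for the series duration")
    n = ts.n_regions
    L = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            c = _xcov(ts.values[i], ts.values[j], max_lag)
            k = int(np.argmax(np.abs(c)))
            if k == 0 or k == len(c) - 1:
                L[i, j] = L[j, i] = np.nan
                continue
            # parabolic refinement on the signed covariance around the peak
            y0, y1, y2 = c[k - 1], c[k], c[k + 1]
            denom = y0 - 2 * y1 + y2
            frac = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
            lag = (k - max_lag + frac) * ts.dt
            L[i, j] = lag
            L[j, i] = -lag
    # row mean over all N entries (zero diagonal included, censored excluded)
    counts = np.sum(~np.isnan(L), axis=1)
    proj = np.nansum(L, axis=1) / np.maximum(counts, 1)
    return proj, L


def f1_directionality(
    estimate: WeightedDigraph, truth: WeightedDigraph, sparsity: float
) -> float:
    """F1 of directed-edge recovery after binarizing at a sparsity level.

    The estimate keeps its top ``sparsity`` fraction of off-diagonal
    absolute weights; the truth is binarized as its nonzero entries
    (tract-tracing semantics: an absent projection is a structural zero).
    """
    if not 0 < sparsity < 1:
        raise ValueError("sparsity must be in (0, 1)")
    check_same_regions(estimate, truth)
    n = estimate.n_regions
    mask = ~np.eye(n, dtype=bool)
    true_edges = (truth.weights != 0) & mask
    if not np.any(true_edges):
        raise ValueError("truth has no edges")
    absw = np.abs(estimate.weights)[mask]
    k = int(np.ceil(sparsity * absw.size))
    cutoff = np.sort(absw)[::-1][k - 1]
    pred_edges = (np.abs(estimate.weights) >= cutoff) & mask & (estimate.weights != 0)
    tp = np.sum(pred_edges & true_edges)
    fp = np.sum(pred_edges & ~true_edges)
    fn = np.sum(~pred_edges & true_edges)
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return float(2 * precision * recall / (precision + recall))
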