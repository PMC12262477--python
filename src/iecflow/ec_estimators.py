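"""Native effective-connectivity estimators and the subsampling ensemble.

All estimators return an :class:`ECEstimate` whose matrix follows the
package convention (rows = targets, columns = sources) with a zero
diagonal.  Estimators fall into two families:

* dynamical-systems estimators (ridge VAR, pairwise-conditional Granger)
  consume the ordered time series;
* graphical estimators (DirectLiNGAM, the skewness-orientation graph,
  Patel's tau) treat timepoints as i.i.d. samples.

A registry maps estimator names to callables so the subsampling ensemble
and the CLI can address them uniformly, and externally computed EC matrices
can be injected from file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import stats

from .core import RegionTimeSeries, WeightedDigraph, get_logger, read_matrix

__all__ = [
    "ECEstimate",
    "EstimatorConfig",
    "estimate_var_l2",
    "estimate_mvgc",
    "estimate_patel_tau",
    "estimate_direct_lingam",
    "estimate_skew_graph",
    "ensemble_subsample",
    "register_external_ec",
    "register_estimator",
    "ESTIMATOR_REGISTRY",
]

logger = get_logger(__name__)


@dataclass
class ECEstimate:
    """One EC estimate: the weighted digraph plus estimator provenance."""

    graph: WeightedDigraph
    estimator_name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.graph.kind != "EC":
            raise ValueError("ECEstimate graph must have kind='EC'")
        if not np.all(np.isfinite(self.graph.weights)):
            raise ValueError("EC estimate has non-finite weights")

    @property
    def weights(self) -> np.ndarray:
        return self.graph.weights

    @property
    def region_ids(self) -> list[str]:
        return self.graph.region_ids


@dataclass
class EstimatorConfig:
    """Named estimator with its hyperparameters.

    Recognised hyperparameters: ``lam`` (ridge strength), ``lag`` (VAR lag,
    only 1 is supported/tested), ``quantile`` (Patel activation anchor),
    ``alpha`` (significance level), ``adjacency_threshold`` (skew graph),
    ``subsample_count`` and ``subsample_fraction`` (ensemble).
    """

    name: str
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        hp = self.hyperparams
        if hp.get("subsample_count", 1) < 1:
            raise ValueError("subsample_count must be >= 1")
        frac = hp.get("subsample_fraction", 0.5)
        if not 0 < frac <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")
        q = hp.get("quantile", 0.75)
        if not 0 < q < 1:
            raise ValueError("quantile must be in (0, 1)")


def _zero_diag_estimate(
    w: np.ndarray, ts: RegionTimeSeries, name: str, params: dict
) -> ECEstimate:
    w = np.asarray(w, dtype=float).copy()
    np.fill_diagonal(w, 0.0)
    g = WeightedDigraph(w, list(ts.region_ids), kind="EC")
    return ECEstimate(g, name, params)


# ---------------------------------------------------------------------------
# Dynamical-systems estimators
# ---------------------------------------------------------------------------


def estimate_var_l2(ts: RegionTimeSeries, lam: float = 0.01) -> ECEstimate:
    """Lag-1 vector autoregression with an L2 (ridge) penalty.

    Solves x(t+1) = A x(t) by the closed-form normal equations
    ``A' = (X'X + lam I)^-1 X'Y`` on mean-centred data, and returns A with
    rows = targets and a zeroed diagonal.  Signs are preserved.
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    n, t = ts.n_regions, ts.n_timepoints
    if t < n + 2:
        raise ValueError("need at least n_regions + 2 timepoints for lag-1 VAR")
    # centre predictors and responses by their own means (= fitting an
    # intercept); a shared global mean would break exact identification
    X = ts.values[:, :-1].T  # (T-1, n) predictors x(t)
    Y = ts.values[:, 1:].T   # (T-1, n) responses x(t+1)
    X = X - X.mean(axis=0, keepdims=True)
    Y = Y - Y.mean(axis=0, keepdims=True)
    gram = X.T @ X
    if lam == 0:
        if np.linalg.cond(gram) > 1e12:
            raise np.linalg.LinAlgError(
                "singular design with lam=0; use a positive ridge strength"
            )
        At = np.linalg.solve(gram, X.T @ Y)
    else:
        At = np.linalg.solve(gram + lam * np.eye(n), X.T @ Y)
    return _zero_diag_estimate(At.T, ts, "var", {"lam": lam, "lag": 1})


def estimate_mvgc(ts: RegionTimeSeries, alpha: float = 0.05) -> ECEstimate:
    """Pairwise-conditional Granger causality at lag 1.

    For every ordered pair (source j, target i) the full model predicts
    x_i(t+1) from x_i(t) and x_j(t); the restricted model uses only the
    target's own history.  The edge weight is the F statistic of the
    comparison, zeroed where p >= alpha.  Collinear (degenerate) designs
    yield a zero F statistic rather than an error.
    """
    n, t = ts.n_regions, ts.n_timepoints
    if t < n + 2:
        raise ValueError("need at least n_regions + 2 timepoints")
    X = ts.values[:, :-1]
    Y = ts.values[:, 1:]
    X = X - X.mean(axis=1, keepdims=True)
    Y = Y - Y.mean(axis=1, keepdims=True)
    m = t - 1
    dof = m - 3  # intercept (absorbed by centring), own lag, source lag
    if dof < 1:
        raise ValueError("too few timepoints for the full model")
    F = np.zeros((n, n))
    for i in range(n):
        yi = Y[i]
        xi = X[i]
        # restricted: yi ~ xi
        bi = xi @ yi / max(xi @ xi, 1e-300)
        rss_r = np.sum((yi - bi * xi) ** 2)
        for j in range(n):
            if j == i:
                continue
            D = np.column_stack([xi, X[j]])
            coef, _, rank, _ = np.linalg.lstsq(D, yi, rcond=None)
            rss_f = np.sum((yi - D @ coef) ** 2)
            if rank < 2 or rss_f <= 0 or rss_f >= rss_r:
                continue  # degenerate or no improvement -> no edge
            F[i, j] = (rss_r - rss_f) / (rss_f / dof)
    pvals = stats.f.sf(F, 1, dof)
    F[pvals >= alpha] = 0.0
    return _zero_diag_estimate(F, ts, "mvgc", {"alpha": alpha, "lag": 1})


# ---------------------------------------------------------------------------
# Graphical estimators
# ---------------------------------------------------------------------------


def _graded_activation(x: np.ndarray, q: float) -> np.ndarray:
    """Graded activation in [0, 1]: linear ramp from the q-quantile to the
    99th percentile, clipped.  Values at/below the anchor are inactive."""
    lo = np.quantile(x, q)
    hi = np.quantile(x, 0.99)
    if hi <= lo:
        raise ValueError("no activation variability (constant region signal)")
    return np.clip((x - lo) / (hi - lo), 0.0, 1.0)


def patel_tau_from_activations(fx: np.ndarray, fy: np.ndarray) -> float:
    """Patel's tau from two activation series in [0, 1].

    Joint activation theta1 = E[min(fx, fy)] (graded conjunction); the
    marginals are E[fx], E[fy].  tau = (P(x|y) - P(y|x)) / max(...), so
    tau > 0 marks x as ascendant (x -> y): x's activations form the broader
    set, and y's activation more strongly implies x's than vice versa.
    """
    theta1 = float(np.mean(np.minimum(fx, fy)))
    px, py = float(np.mean(fx)), float(np.mean(fy))
    if px <= 0 or py <= 0:
        raise ValueError("a region never activates above its anchor")
    p_x_given_y = theta1 / py
    p_y_given_x = theta1 / px
    m = max(p_x_given_y, p_y_given_x)
    if m == 0:
        return 0.0
    return (p_x_given_y - p_y_given_x) / m


def estimate_patel_tau(ts: RegionTimeSeries, q: float = 0.75) -> ECEstimate:
    """Patel's tau: pairwise directionality from conditional activation.

    Each region is mapped to a graded activation level above its q-quantile
    (original graded/fuzzy formulation; a hard cut at identical per-region
    quantiles would equalise the marginals and destroy the asymmetry the
    statistic measures).  For each pair, tau > 0 is stored as an X -> Y edge
    of weight tau, tau < 0 as Y -> X of weight |tau|.  Applied without
    subsampling.
    """
    if not 0 < q < 1:
        raise ValueError("quantile must be in (0, 1)")
    n = ts.n_regions
    acts = np.stack([_graded_activation(ts.values[i], q) for i in range(n)])
    w = np.zeros((n, n))
    for x in range(n):
        for y in range(x + 1, n):
            tau = patel_tau_from_activations(acts[x], acts[y])
            if tau > 0:
                w[y, x] = tau      # X -> Y
            elif tau < 0:
                w[x, y] = -tau     # Y -> X
    return _zero_diag_estimate(w, ts, "patel", {"quantile": q})


def _negentropy_H(u: np.ndarray) -> np.ndarray:
    """Differential entropy approximation of standardized rows (Hyvarinen's
    maximum-entropy approximation); ``u`` is (k, T), returns (k,)."""
    k1, k2, gamma = 79.047, 7.4129, 0.37457
    h_gauss = 0.5 * (1.0 + np.log(2.0 * np.pi))
    au = np.abs(u)
    logcosh = au + np.log1p(np.exp(-2.0 * au)) - np.log(2.0)
    t1 = logcosh.mean(axis=-1) - gamma
    t2 = (u * np.exp(-0.5 * u * u)).mean(axis=-1)
    return h_gauss - k1 * t1**2 - k2 * t2**2


def estimate_direct_lingam(ts: RegionTimeSeries) -> ECEstimate:
    """DirectLiNGAM: linear non-Gaussian acyclic causal discovery.

    Iteratively selects the most exogenous variable by the pairwise
    likelihood-ratio measure built from entropy approximations
    (root = argmin_j sum_i min(0, M_ji)^2 with
    M_ji = [H(x_j) + H(r_i|j)] - [H(x_i) + H(r_j|i)]), regresses it out of
    the remainder, and recurses.  Connection coefficients are then obtained
    by regressing each variable on its causal predecessors; rows = targets.
    Directions are unidentifiable for jointly Gaussian data (assignments
    near chance), a documented property of the model class.
    """
    n, t = ts.n_regions, ts.n_timepoints
    if t < n:
        raise ValueError("fewer samples than regions")
    data = ts.values
    U = (data - data.mean(axis=1, keepdims=True)) / data.std(axis=1, keepdims=True)
    remaining = list(range(n))
    Ucur = U.copy()
    order: list[int] = []
    while len(remaining) > 1:
        k = len(remaining)
        R = np.corrcoef(Ucur)
        H_self = _negentropy_H(Ucur)
        # Hres[j, i] = entropy of residual of var i regressed on var j
        Hres = np.empty((k, k))
        for j in range(k):
            rho = np.clip(R[j], -0.999999, 0.999999)
            res = (Ucur - rho[:, None] * Ucur[j][None, :]) / np.sqrt(1.0 - rho**2)[:, None]
            sd = res.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0
            Hres[j] = _negentropy_H(res / sd)
        # M[j, i] < 0 favours j -> i (lower total entropy); a true root has
        # no positive entries in its row, so violations are the positive part
        M = (H_self[:, None] + Hres) - (H_self[None, :] + Hres.T)
        np.fill_diagonal(M, 0.0)
        score = np.sum(np.maximum(0.0, M) ** 2, axis=1)
        root_local = int(np.argmin(score))
        order.append(remaining[root_local])
        rho = np.clip(R[root_local], -0.999999, 0.999999)
        Ucur = (Ucur - rho[:, None] * Ucur[root_local][None, :]) / np.sqrt(
            1.0 - rho**2
        )[:, None]
        sd = Ucur.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        Ucur = Ucur / sd
        Ucur = np.delete(Ucur, root_local, axis=0)
        remaining.pop(root_local)
    order.append(remaining[0])

    # coefficients on the identified acyclic order (original scale)
    B = np.zeros((n, n))
    centred = data - data.mean(axis=1, keepdims=True)
    for pos in range(1, n):
        target = order[pos]
        preds = order[:pos]
        D = centred[preds].T
        coef, *_ = np.linalg.lstsq(D, centred[target], rcond=None)
        B[target, preds] = coef
    return _zero_diag_estimate(B, ts, "lingam", {"order": [int(o) for o in order]})


def _conditional_corr(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    a, b = a[mask], b[mask]
    denom = np.sqrt(np.mean(a * a) * np.mean(b * b))
    if denom == 0:
        return 0.0
    return float(np.mean(a * b) / denom)


def estimate_skew_graph(
    ts: RegionTimeSeries,
    adjacency_threshold: float = 0.1,
    alpha: float = 0.05,
) -> ECEstimate:
    """Two-step skewness-orientation graph (adjacency + left-right rule).

    Step 1 finds an undirected adjacency as pairs whose partial correlation
    given all other regions exceeds ``adjacency_threshold`` in magnitude and
    is significant at ``alpha`` (Fisher z test).  Step 2 orients each
    adjacent pair by the left-right skewness rule: after flipping any
    negatively skewed region to positive skew, the pair correlation is
    computed conditional on the positivity of each member, and the variable
    whose conditioning yields the larger correlation is the source.  The
    stored weight is the signed Pearson correlation of the (unflipped) pair.
    """
    n, t = ts.n_regions, ts.n_timepoints
    if t <= n + 2:
        raise ValueError(
            "more regions than samples: partial correlation is ill-posed; "
            "use shrinkage or a smaller parcellation"
        )
    data = ts.values
    Z = (data - data.mean(axis=1, keepdims=True)) / data.std(axis=1, keepdims=True)
    corr = np.corrcoef(Z)
    prec = np.linalg.pinv(corr)
    d = np.sqrt(np.abs(np.diag(prec)))
    pcorr = -prec / np.outer(d, d)
    np.fill_diagonal(pcorr, 1.0)
    # Fisher z significance of the partial correlation (n-2 conditioning vars)
    dof = t - (n - 2) - 3
    if dof < 1:
        raise ValueError("too few samples for the partial-correlation test")
    z = np.arctanh(np.clip(pcorr, -0.999999, 0.999999)) * np.sqrt(dof)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    adj = (np.abs(pcorr) > adjacency_threshold) & (pvals < alpha)
    np.fill_diagonal(adj, False)

    skews = stats.skew(Z, axis=1)
    flipped = np.where(skews[:, None] < 0, -Z, Z)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if not adj[i, j]:
                continue
            a, b = flipped[i], flipped[j]
            c_i = _conditional_corr(a, b, a > 0)  # condition on i positive
            c_j = _conditional_corr(a, b, b > 0)  # condition on j positive
            weight = corr[i, j]
            if c_i >= c_j:
                w[j, i] = weight  # i is the source: i -> j
            else:
                w[i, j] = weight  # j -> i
    return _zero_diag_estimate(
        w, ts, "skew", {"adjacency_threshold": adjacency_threshold, "alpha": alpha}
    )


# ---------------------------------------------------------------------------
# Ensemble wrapper and plug-in registry
# ---------------------------------------------------------------------------

ESTIMATOR_REGISTRY: dict[str, Callable[..., ECEstimate]] = {
    "var": estimate_var_l2,
    "mvgc": estimate_mvgc,
    "patel": estimate_patel_tau,
    "lingam": estimate_direct_lingam,
    "skew": estimate_skew_graph,
}

#: estimators eligible for the subsampling ensemble: graphical models whose
#: i.i.d.-sample assumption survives timepoint subsampling.  Dynamical
#: estimators (var, mvgc) need the ordered series; Patel's tau is applied
#: without subsampling.
SUBSAMPLABLE = {"lingam", "skew"}


def register_estimator(
    name: str, fn: Callable[..., ECEstimate], subsamplable: bool = True
) -> None:
    """Register a custom estimator callable ``fn(ts, **hyperparams)``."""
    ESTIMATOR_REGISTRY[name] = fn
    if subsamplable:
        SUBSAMPLABLE.add(name)


def ensemble_subsample(
    ts: RegionTimeSeries, cfg: EstimatorConfig, seed: int = 0
) -> ECEstimate:
    """Subsampling ensemble: average signed edge indicators over subsamples.

    Runs the configured graphical estimator on ``subsample_count`` random
    timepoint subsamples of size ceil(fraction * T) drawn without
    replacement, and averages the signed adjacency indicators (+1 for a
    positive edge, -1 negative, 0 absent).  The result lies in [-1, 1] and
    reads as a signed empirical edge frequency.  Aborts if more than 20% of
    subsample fits fail.
    """
    if cfg.name not in ESTIMATOR_REGISTRY:
        raise KeyError(f"unknown estimator {cfg.name!r}")
    if cfg.name not in SUBSAMPLABLE:
        raise ValueError(
            f"estimator {cfg.name!r} is not eligible for the subsampling "
            "ensemble (dynamical estimators need the ordered series; "
            "Patel's tau is applied without subsampling)"
        )
    hp = dict(cfg.hyperparams)
    count = int(hp.pop("subsample_count", 100))
    fraction = float(hp.pop("subsample_fraction", 0.5))
    fn = ESTIMATOR_REGISTRY[cfg.name]
    rng = np.random.default_rng(seed)
    t = ts.n_timepoints
    size = int(np.ceil(fraction * t))
    n = ts.n_regions
    acc = np.zeros((n, n))
    failures: list[str] = []
    for rep in range(count):
        idx = np.sort(rng.choice(t, size=size, replace=False))
        sub = RegionTimeSeries(ts.values[:, idx], list(ts.region_ids), ts.dt)
        try:
            est = fn(sub, **hp)
        except Exception as exc:  # noqa: BLE001 - collected as diagnostics
            failures.append(f"subsample {rep}: {exc}")
            continue
        acc += np.sign(est.weights)
    if len(failures) > 0.2 * count:
        raise RuntimeError(
            f"estimator failed on {len(failures)}/{count} subsamples: "
            + "; ".join(failures[:5])
        )
    ok = count - len(failures)
    w = acc / max(ok, 1)
    params = {"base": cfg.name, "subsample_count": count,
              "subsample_fraction": fraction, "n_failed": len(failures), **hp}
    return _zero_diag_estimate(w, ts, f"{cfg.name}_ensemble", params)


def register_external_ec(
    path: str | Path,
    name: str,
    region_ids: list[str] | None = None,
    transposed: bool = False,
) -> ECEstimate:
    """Wrap an externally computed EC matrix file as an ECEstimate.

    ``transposed=True`` declares the file in the column=target convention
    (common in graphical-model tools); it is transposed on load.  If
    ``region_ids`` is given, the file's labels must match it exactly.
    """
    g = read_matrix(path, kind="EC")
    if transposed:
        g = WeightedDigraph(g.weights.T, list(g.region_ids), kind="EC")
    if region_ids is not None and list(g.region_ids) != [str(r) for r in region_ids]:
        raise ValueError(
            f"external EC {path} region labels do not match the session's "
            "region set (order-sensitive)"
        )
    return ECEstimate(g, name, {"source": str(path), "transposed": transposed})
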