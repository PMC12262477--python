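"""Integration of individual EC estimates into the integrated EC (iEC).

The integrated EC is a weighted sum of scale-standardized individual
estimates, iEC = sum_n beta_n EC_n, with the coefficient vector beta chosen
by Bayesian optimization (Gaussian-process surrogate with expected
improvement) to maximize an objective: either the Pearson correlation with
a target matrix (tracer data or a planted ground truth) or the composite
signal fit r - KS obtained by re-simulating whole-brain dynamics from the
candidate iEC.

Weights are bounded to [0, 1]: the estimators' sign semantics (positive =
excitatory influence) must not be inverted by the combination.  Each
estimate is standardized by the standard deviation of its off-diagonal
entries — no centering, so signs and structural zeros are preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern

from .core import WeightedDigraph, check_same_regions, get_logger
from .ec_estimators import ECEstimate
from .hopf_simulator import HopfParams, simulate_hopf

__all__ = [
    "IntegrationWeights",
    "ObjectiveSpec",
    "standardize_ec",
    "integrate_ec",
    "optimize_weights",
    "crossval_integration",
    "gp_maximize",
]

logger = get_logger(__name__)


@dataclass
class IntegrationWeights:
    """Per-estimator coefficients with the objective value achieved.

    ``beta`` is the elementwise median across restarts; ``restarts`` keeps
    the per-restart coefficient vectors for reporting.
    """

    beta: dict[str, float]
    objective_value: float
    objective_kind: str
    n_restarts: int
    restarts: list[dict[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.objective_value):
            raise ValueError("objective value must be finite")


@dataclass
class ObjectiveSpec:
    """What the integration weights are optimized against.

    ``kind='target_correlation'`` needs ``target`` (a WeightedDigraph; NaN
    entries are skipped; ``log_target=True`` applies log10 to its positive
    entries, customary for heavy-tailed tracer weights).
    ``kind='composite_fit'`` needs ``empirical_ts`` plus Hopf settings and
    scores a candidate iEC by simulating from it (fit = FC correlation minus
    the KS distance between FCD distributions).
    """

    kind: str
    target: WeightedDigraph | None = None
    log_target: bool = False
    empirical_ts: object = None
    hopf_params: HopfParams | None = None
    fcd_window: int = 30
    fcd_step: int = 3

    def __post_init__(self) -> None:
        if self.kind not in ("target_correlation", "composite_fit"):
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.kind == "target_correlation" and self.target is None:
            raise ValueError("target matrix required for target_correlation")
        if self.kind == "composite_fit" and self.empirical_ts is None:
            raise ValueError("empirical time series required for composite_fit")


def standardize_ec(e: ECEstimate) -> ECEstimate:
    """Divide off-diagonal entries by their standard deviation (no centering)."""
    w = e.weights.copy()
    off = w[~np.eye(w.shape[0], dtype=bool)]
    sd = off.std()
    if sd == 0:
        raise ValueError("all-zero (or constant) off-diagonal: cannot standardize")
    w = w / sd
    np.fill_diagonal(w, 0.0)
    g = WeightedDigraph(w, list(e.region_ids), kind="EC")
    return ECEstimate(g, e.estimator_name, dict(e.params, standardized=True))


def integrate_ec(
    estimates: Sequence[ECEstimate], w: IntegrationWeights | dict[str, float]
) -> WeightedDigraph:
    """Elementwise weighted sum of standardized estimates; linear in beta."""
    if not estimates:
        raise ValueError("no estimates to integrate")
    beta = w.beta if isinstance(w, IntegrationWeights) else dict(w)
    ids = check_same_regions(*[e.graph for e in estimates])
    acc = np.zeros((len(ids), len(ids)))
    for e in estimates:
        if e.estimator_name not in beta:
            raise KeyError(f"missing weight for estimator {e.estimator_name!r}")
        acc += beta[e.estimator_name] * standardize_ec(e).weights
    np.fill_diagonal(acc, 0.0)
    return WeightedDigraph(acc, ids, kind="EC")


def _offdiag(m: np.ndarray) -> np.ndarray:
    return m[~np.eye(m.shape[0], dtype=bool)]


def correlation_objective(
    estimates: Sequence[ECEstimate], target: WeightedDigraph, log_target: bool = False
) -> Callable[[np.ndarray], float]:
    """rho(iEC, T) over off-diagonal entries; NaN target entries skipped."""
    check_same_regions(*[e.graph for e in estimates], target)
    std = [standardize_ec(e).weights for e in estimates]
    tvec = _offdiag(target.weights.copy())
    if log_target:
        tvec = np.where(tvec > 0, np.log10(tvec), np.nan)
    valid = np.isfinite(tvec)
    if valid.sum() < 3:
        raise ValueError("too few defined target entries")
    tvec = tvec[valid]
    evecs = np.stack([_offdiag(s)[valid] for s in std])  # (n_est, n_valid)

    def f(beta: np.ndarray) -> float:
        ivec = beta @ evecs
        if ivec.std() == 0 or tvec.std() == 0:
            return 0.0
        return float(np.corrcoef(ivec, tvec)[0, 1])

    return f


def composite_fit_objective(
    estimates: Sequence[ECEstimate], spec: ObjectiveSpec, sim_seed: int
) -> Callable[[np.ndarray], float]:
    """fit = r - KS for a Hopf simulation driven by the candidate iEC.

    A fixed simulation seed per candidate keeps the objective deterministic
    so the surrogate model sees a smooth function.
    """
    from .validation_metrics import composite_fit  # local import, avoids cycle

    p = spec.hopf_params or HopfParams()

    def f(beta: np.ndarray) -> float:
        named = {e.estimator_name: b for e, b in zip(estimates, beta)}
        iec = integrate_ec(estimates, named)
        if np.all(iec.weights == 0):
            return -2.0
        sd = _offdiag(iec.weights).std()
        coupling = WeightedDigraph(iec.weights / sd, list(iec.region_ids), kind="EC")
        params = HopfParams(**{**p.__dict__, "seed": sim_seed})
        try:
            sim = simulate_hopf(coupling, params)
        except FloatingPointError:
            return -2.0
        rep = composite_fit(spec.empirical_ts, sim, spec.fcd_window, spec.fcd_step)
        return rep.fit

    return f


# ---------------------------------------------------------------------------
# Gaussian-process surrogate optimizer (expected improvement)
# ---------------------------------------------------------------------------


def gp_maximize(
    f: Callable[[np.ndarray], float],
    ndim: int,
    bounds: tuple[float, float] = (0.0, 1.0),
    n_calls: int = 40,
    seed: int = 0,
) -> tuple[np.ndarray, float, list[float]]:
    """Maximize ``f`` over a box with a GP surrogate and EI acquisition.

    Returns (best_x, best_y, trace of evaluated values).  The first
    ``max(8, 2*ndim)`` points are space-filling random draws; subsequent
    points maximize expected improvement over a random candidate set.
    """
    lo, hi = bounds
    rng = np.random.default_rng(seed)
    n_init = min(max(8, 2 * ndim), n_calls)
    X = list(rng.uniform(lo, hi, size=(n_init, ndim)))
    Y = [f(x) for x in X]
    if not all(np.isfinite(Y)):
        raise ValueError("objective returned a non-finite value")
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=0.3 * (hi - lo), length_scale_bounds=(1e-2, 1e1), nu=2.5
    )
    for _ in range(n_calls - n_init):
        gp = GaussianProcessRegressor(
            kernel=kernel, alpha=1e-8, normalize_y=True, n_restarts_optimizer=1,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        with warnings.catch_warnings():
            # kernel-hyperparameter refits routinely hit the lbfgs iteration
            # cap; the surrogate is still perfectly usable for acquisition
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(np.asarray(X), np.asarray(Y))
        cand = rng.uniform(lo, hi, size=(1024, ndim))
        mu, sigma = gp.predict(cand, return_std=True)
        best = max(Y)
        sigma = np.maximum(sigma, 1e-12)
        imp = mu - best - 1e-4
        zsc = imp / sigma
        ei = imp * stats.norm.cdf(zsc) + sigma * stats.norm.pdf(zsc)
        x_next = cand[int(np.argmax(ei))]
        y_next = f(x_next)
        if not np.isfinite(y_next):
            raise ValueError("objective returned a non-finite value")
        X.append(x_next)
        Y.append(y_next)
    k = int(np.argmax(Y))
    return np.asarray(X[k]), float(Y[k]), [float(v) for v in Y]


def optimize_weights(
    estimates: Sequence[ECEstimate],
    obj: ObjectiveSpec,
    bounds: tuple[float, float] = (0.0, 1.0),
    n_restarts: int = 50,
    n_calls: int = 40,
    seed: int = 0,
) -> IntegrationWeights:
    """Optimize beta over the box with ``n_restarts`` independent runs.

    Each restart uses a distinct seed; the returned ``beta`` is the
    elementwise median of the per-restart optima and ``objective_value`` is
    the objective evaluated at that median.
    """
    if not estimates:
        raise ValueError("at least one estimate required")
    names = [e.estimator_name for e in estimates]
    if len(set(names)) != len(names):
        raise ValueError("estimator names must be unique")
    if obj.kind == "target_correlation":
        f = correlation_objective(estimates, obj.target, obj.log_target)
    else:
        f = composite_fit_objective(estimates, obj, sim_seed=seed)
    rng = np.random.default_rng(seed)
    restarts: list[dict[str, float]] = []
    for r in range(n_restarts):
        sub = int(rng.integers(0, 2**31 - 1))
        x, y, _ = gp_maximize(f, len(names), bounds, n_calls=n_calls, seed=sub)
        restarts.append({n: float(v) for n, v in zip(names, x)})
    med = {n: float(np.median([r[n] for r in restarts])) for n in names}
    obj_at_median = f(np.array([med[n] for n in names]))
    return IntegrationWeights(
        beta=med,
        objective_value=float(obj_at_median),
        objective_kind=obj.kind,
        n_restarts=n_restarts,
        restarts=restarts,
    )


def crossval_integration(
    train_sessions: Sequence[dict],
    test_sessions: Sequence[dict],
    obj_kind: str = "target_correlation",
    n_restarts: int = 50,
    n_calls: int = 40,
    seed: int = 0,
    log_target: bool = False,
) -> dict:
    """Train/test protocol: optimize beta per training session, fix the
    elementwise median across sessions, evaluate on held-out sessions.

    Each session is a dict with ``estimates`` (list of ECEstimate) and the
    objective's target (``target`` digraph for correlation, or
    ``empirical_ts`` [+ ``hopf_params``] for the composite fit).  The report
    contains the per-session objective of every individual estimator and of
    the iEC under the fixed median beta.
    """
    if not train_sessions or not test_sessions:
        raise ValueError("need at least one training and one test session")
    name_sets = [
        tuple(e.estimator_name for e in s["estimates"])
        for s in list(train_sessions) + list(test_sessions)
    ]
    if len(set(name_sets)) != 1:
        raise ValueError("estimator sets differ across sessions")
    names = list(name_sets[0])

    def _spec(session: dict) -> ObjectiveSpec:
        if obj_kind == "target_correlation":
            return ObjectiveSpec(
                kind=obj_kind, target=session["target"], log_target=log_target
            )
        return ObjectiveSpec(
            kind=obj_kind,
            empirical_ts=session["empirical_ts"],
            hopf_params=session.get("hopf_params"),
        )

    rng = np.random.default_rng(seed)
    train_betas = []
    train_obj = []
    for s in train_sessions:
        w = optimize_weights(
            s["estimates"], _spec(s), n_restarts=n_restarts, n_calls=n_calls,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        train_betas.append(w.beta)
        train_obj.append(w.objective_value)
    median_beta = {n: float(np.median([b[n] for b in train_betas])) for n in names}

    def _eval(session: dict) -> dict:
        spec = _spec(session)
        if obj_kind == "target_correlation":
            f = correlation_objective(session["estimates"], spec.target, log_target)
        else:
            f = composite_fit_objective(
                session["estimates"], spec, sim_seed=int(rng.integers(0, 2**31 - 1))
            )
        scores = {"iec": f(np.array([median_beta[n] for n in names]))}
        for k, n in enumerate(names):
            unit = np.zeros(len(names))
            unit[k] = 1.0
            scores[n] = f(unit)
        return scores

    test_scores = [_eval(s) for s in test_sessions]
    report = {
        "estimators": names,
        "median_beta": median_beta,
        "train_betas": train_betas,
        "train_objectives": train_obj,
        "test_scores": test_scores,
        "test_median": {
            k: float(np.median([s[k] for s in test_scores]))
            for k in ["iec", *names]
        },
    }
    best_single = max(names, key=lambda n: report["test_median"][n])
    report["best_single"] = best_single
    report["iec_beats_best_single"] = bool(
        report["test_median"]["iec"] >= report["test_median"][best_single]
    )
    return report
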