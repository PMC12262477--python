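"""Whole-brain Stuart-Landau (Hopf) oscillator network simulator.

Each region is a Stuart-Landau oscillator near a Hopf bifurcation,

    dx_i = [(a_i - x_i^2 - y_i^2) x_i - w_i y_i + G sum_j C_ij (x_j - x_i)] dt
           + eps sqrt(dt) eta_i
    dy_i = [(a_i - x_i^2 - y_i^2) y_i + w_i x_i + G sum_j C_ij (y_j - y_i)] dt
           + eps sqrt(dt) eta'_i

integrated with the Euler-Maruyama scheme.  With a_i < 0 the uncoupled node
is a stable focus excited by noise; with a_i > 0 it settles on a limit cycle
of radius sqrt(a_i).  The coupling matrix C follows the package convention
(rows = targets), so row i collects the inputs of region i.

Sign conventions: the diffusive coupling difference is (x_j - x_i) and the
rotation is (-wy, +wx), the standard Hopf normal form; both are switchable
for sensitivity checks via ``coupling_sign`` / ``rotation_sign``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .core import RegionTimeSeries, WeightedDigraph, get_logger

__all__ = ["HopfParams", "simulate_hopf", "estimate_peak_frequencies"]

logger = get_logger(__name__)


@dataclass
class HopfParams:
    """Parameters of the Hopf network simulation.

    ``a`` is the bifurcation parameter (default -0.01, just below the
    bifurcation); ``omega`` the intrinsic angular frequency in rad/s (scalar
    or per-region); ``G`` the global coupling scale; ``epsilon`` the additive
    noise amplitude (default 0.02); ``dt`` the Euler-Maruyama step (default
    0.1 s of model time).  ``duration`` counts *output* timepoints after
    decimation to ``output_dt`` (default 0.72 s, a typical fMRI sampling
    interval; set to None to output every integration step).  ``burn_in``
    is the number of discarded initial integration steps; the default makes
    the burn-in 20% of all integrated steps.
    """

    a: float | np.ndarray = -0.01
    omega: float | np.ndarray = 2 * np.pi * 0.05
    G: float = 1.0
    epsilon: float = 0.02
    dt: float = 0.1
    duration: int = 1200
    burn_in: int | None = None
    output_dt: float | None = 0.72
    seed: int = 0
    coupling_sign: int = +1   # +1: (x_j - x_i); -1: (x_i - x_j)
    rotation_sign: int = +1   # +1: (-wy, +wx);  -1: (+wy, -wx)
    x0: np.ndarray | None = None  # initial state (default: small random)
    y0: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.duration < 3:
            raise ValueError("duration must be >= 3 output timepoints")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")

    def stride(self) -> int:
        if self.output_dt is None:
            return 1
        return max(1, int(round(self.output_dt / self.dt)))


def simulate_hopf(coupling: WeightedDigraph, p: HopfParams) -> RegionTimeSeries:
    """Integrate the coupled Stuart-Landau network; returns the x component.

    Deterministic under ``p.seed``; the burn-in is discarded and the output
    has exactly ``p.duration`` timepoints at sampling interval
    ``stride * dt`` seconds.
    """
    C = coupling.weights
    n = C.shape[0]
    a = np.broadcast_to(np.asarray(p.a, dtype=float), (n,)).copy()
    omega = np.broadcast_to(np.asarray(p.omega, dtype=float), (n,)).copy()
    stride = p.stride()
    n_steps = p.duration * stride
    burn = p.burn_in if p.burn_in is not None else int(round(0.25 * n_steps))
    total = burn + n_steps

    rng = np.random.default_rng(p.seed)
    s = p.coupling_sign
    row_sum = C.sum(axis=1)
    sqdt = np.sqrt(p.dt)
    rot = p.rotation_sign

    if p.x0 is not None:
        x = np.broadcast_to(np.asarray(p.x0, dtype=float), (n,)).copy()
    else:
        x = 0.1 * rng.standard_normal(n)
    if p.y0 is not None:
        y = np.broadcast_to(np.asarray(p.y0, dtype=float), (n,)).copy()
    else:
        y = 0.1 * rng.standard_normal(n)
    out = np.empty((n, p.duration))
    k_out = 0
    for step in range(total):
        r2 = x * x + y * y
        lin = a - r2
        cx = C @ x - row_sum * x
        cy = C @ y - row_sum * y
        dx = lin * x - rot * omega * y + p.G * s * cx
        dy = lin * y + rot * omega * x + p.G * s * cy
        x = x + p.dt * dx + p.epsilon * sqdt * rng.standard_normal(n)
        y = y + p.dt * dy + p.epsilon * sqdt * rng.standard_normal(n)
        if step % 200 == 0 and np.max(np.abs(x)) > 1e6:
            raise FloatingPointError(
                "numerical blow-up (|x| > 1e6); reduce dt or the coupling G"
            )
        idx = step - burn
        if idx >= 0 and idx % stride == stride - 1:
            out[:, k_out] = x
            k_out += 1
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite output; reduce dt or the coupling G")
    return RegionTimeSeries(out, list(coupling.region_ids), dt=stride * p.dt)


def estimate_peak_frequencies(
    ts: RegionTimeSeries, band: tuple[float, float] = (0.01, 0.1)
) -> np.ndarray:
    """Per-region peak angular frequency (rad/s) from a Welch periodogram.

    The peak is the in-band frequency of maximal power.  If the in-band
    spectrum is flat (no clear peak: max < 2x the in-band median power), the
    band midpoint is used with a warning.
    """
    low, high = band
    if ts.n_timepoints * ts.dt < 2.0 / low:
        raise ValueError("series too short to resolve the lower band edge")
    fs = 1.0 / ts.dt
    nperseg = min(256, ts.n_timepoints)
    freqs, pxx = welch(ts.values, fs=fs, nperseg=nperseg, axis=1)
    in_band = (freqs >= low) & (freqs <= high)
    if not np.any(in_band):
        raise ValueError("no spectral estimate inside the requested band")
    fb = freqs[in_band]
    pb = pxx[:, in_band]
    peaks = fb[np.argmax(pb, axis=1)]
    flat = np.max(pb, axis=1) < 2.0 * np.median(pb, axis=1)
    if np.any(flat):
        logger.warning(
            "flat spectrum in band for %d region(s); using band midpoint",
            int(np.sum(flat)),
        )
        peaks = np.where(flat, 0.5 * (low + high), peaks)
    return 2 * np.pi * peaks
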