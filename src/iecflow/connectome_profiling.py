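"""Descriptive profiling of a signed EC matrix.

Weighted in-/out-strengths, indicator-based positive/negative connection
ratios, a Hill tail-index of the positive weight distribution (heavy tails
are flagged by an index below 2), and feedforward/feedback sign profiles
against a tracer-style laminar matrix (SLN analogue: values in [0, 1],
feedforward above 0.5, feedback below).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import WeightedDigraph, check_same_regions

__all__ = [
    "DegreeProfile",
    "signed_degree_profile",
    "tail_index",
    "pathway_sign_profile",
]


@dataclass
class DegreeProfile:
    """Per-region weighted strengths and signed-connection ratios.

    Ratios use the matrix dimension N as the denominator, matching the
    indicator-sum formulation (the diagonal is zero so it never counts as
    positive or negative); pos + neg <= 1 per region.
    """

    region_ids: list[str]
    in_strength: np.ndarray
    out_strength: np.ndarray
    pos_in_ratio: np.ndarray
    neg_in_ratio: np.ndarray
    pos_out_ratio: np.ndarray
    neg_out_ratio: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "in_strength": self.in_strength,
                "out_strength": self.out_strength,
                "pos_in_ratio": self.pos_in_ratio,
                "neg_in_ratio": self.neg_in_ratio,
                "pos_out_ratio": self.pos_out_ratio,
                "neg_out_ratio": self.neg_out_ratio,
            },
            index=self.region_ids,
        )


def signed_degree_profile(g: WeightedDigraph) -> DegreeProfile:
    """Weighted in-/out-strength (row/column sums) and sign ratios.

    InStrength(i) = sum_j W_ij, OutStrength(j) = sum_i W_ij; the positive
    (negative) ratio of a row/column is the count of positive (negative)
    entries divided by N.
    """
    w = g.weights
    n = w.shape[0]
    return DegreeProfile(
        region_ids=list(g.region_ids),
        in_strength=w.sum(axis=1),
        out_strength=w.sum(axis=0),
        pos_in_ratio=(w > 0).sum(axis=1) / n,
        neg_in_ratio=(w < 0).sum(axis=1) / n,
        pos_out_ratio=(w > 0).sum(axis=0) / n,
        neg_out_ratio=(w < 0).sum(axis=0) / n,
    )


def tail_index(weights: np.ndarray, top_fraction: float = 0.1) -> float:
    """Hill estimator of the tail index over the top order statistics.

    alpha_hat = [ mean_{i<=k} log(x_(n-i+1) / x_(n-k)) ]^{-1} with
    k = ceil(top_fraction * n); an estimate below 2 marks a heavy tail.
    Requires >= 50 positive values.
    """
    w = np.asarray(weights, dtype=float)
    w = w[np.isfinite(w) & (w > 0)]
    if w.size < 50:
        raise ValueError("need >= 50 positive values for the tail index")
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    w = np.sort(w)
    k = int(np.ceil(top_fraction * w.size))
    k = max(k, 2)
    top = w[-k:]
    threshold = w[-k - 1] if w.size > k else w[0]
    return float(1.0 / np.mean(np.log(top / threshold)))


def pathway_sign_profile(
    ec: WeightedDigraph, sln_like: WeightedDigraph, threshold: float = 0.5
) -> pd.DataFrame:
    """Positive/negative EC proportions within FF and FB pathway classes.

    Edges with a defined tracer value are labelled feedforward if the value
    exceeds ``threshold`` and feedback if below; exact ties are dropped.
    Undefined (NaN) tracer entries are skipped.  Only off-diagonal EC
    entries with a defined class and a nonzero EC weight are profiled.
    """
    check_same_regions(ec, sln_like)
    n = ec.n_regions
    mask = ~np.eye(n, dtype=bool)
    sln = sln_like.weights
    defined = mask & np.isfinite(sln)
    if not np.any(defined):
        raise ValueError("no defined tracer edges")
    ff = defined & (sln > threshold)
    fb = defined & (sln < threshold)
    if not np.any(ff | fb):
        raise ValueError("all tracer values tie at the threshold; nothing to profile")
    rows = []
    for label, cls in (("FF", ff), ("FB", fb)):
        vals = ec.weights[cls]
        vals = vals[vals != 0]
        n_edges = vals.size
        rows.append(
            {
                "pathway": label,
                "n_edges": int(n_edges),
                "pos_proportion": float(np.mean(vals > 0)) if n_edges else np.nan,
                "neg_proportion": float(np.mean(vals < 0)) if n_edges else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("pathway")
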