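"""Separation of control vs disease networks and scale-free checks.

The control and AMI co-expression networks of a DEG set are compared by
their average clustering coefficient across the threshold grid.  At each
threshold the *gap* is avg_cc(AMI) − avg_cc(control); thresholds with a
positive gap are "separable" and the average separable width is the mean
gap over them.  Degree distributions are additionally checked against a
power law p(k) ∝ k^(−γ): biological networks are typically scale-free
with γ between 2 and 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .graph import (
    DEFAULT_GRID,
    CorrelationNetwork,
    average_clustering,
    count_clusters,
    pearson_matrix,
    threshold_network,
)


@dataclass
class SeparationProfile:
    """Per-threshold clustering gap between the AMI and control networks."""

    table: pd.DataFrame  # columns threshold, avg_cc_control, avg_cc_ami, gap
    separable_range: tuple[float, float] | None
    average_separable_width: float

    def to_dict(self) -> dict:
        return {
            "per_threshold": self.table.to_dict(orient="records"),
            "separable_range": list(self.separable_range) if self.separable_range else None,
            "average_separable_width": self.average_separable_width,
        }


def separation_profile(
    deg_set: Sequence[str],
    expr_control: pd.DataFrame,
    expr_ami: pd.DataFrame,
    grid: Sequence[float] = DEFAULT_GRID,
) -> SeparationProfile:
    """Average-clustering gap of a DEG set across the threshold grid.

    ``expr_control`` / ``expr_ami`` are genes × samples DataFrames of the
    two groups, restricted to (at least) the DEG set.
    """
    genes = list(deg_set)
    if not genes:
        raise ValueError("DEG set is empty")
    r_c = pearson_matrix(expr_control.loc[genes])
    r_a = pearson_matrix(expr_ami.loc[genes])
    rows = []
    for x in grid:
        cc_c = average_clustering(threshold_network(r_c, x), genes)
        cc_a = average_clustering(threshold_network(r_a, x), genes)
        rows.append((x, cc_c, cc_a, cc_a - cc_c))
    table = pd.DataFrame(rows, columns=["threshold", "avg_cc_control", "avg_cc_ami", "gap"])
    pos = table["gap"] > 0
    if pos.any():
        width = float(table.loc[pos, "gap"].mean())
        sep_range = _longest_run(table["threshold"].to_numpy(), pos.to_numpy())
    else:
        width = 0.0
        sep_range = None
    return SeparationProfile(table, sep_range, width)


def _longest_run(thresholds: np.ndarray, positive: np.ndarray) -> tuple[float, float]:
    """Maximal contiguous threshold interval with a positive gap."""
    best = (0, -1)  # (length, start)
    i = 0
    n = len(positive)
    while i < n:
        if positive[i]:
            j = i
            while j + 1 < n and positive[j + 1]:
                j += 1
            if j - i + 1 > best[0]:
                best = (j - i + 1, i)
            i = j + 1
        else:
            i += 1
    start = best[1]
    return (float(thresholds[start]), float(thresholds[start + best[0] - 1]))


def cluster_count_curve(
    deg_set: Sequence[str],
    expr: pd.DataFrame,
    grid: Sequence[float] = DEFAULT_GRID,
) -> pd.DataFrame:
    """Number of clustered genes (C_i > 0) per threshold for one group."""
    genes = list(deg_set)
    if genes:
        r = pearson_matrix(expr.loc[genes])
        counts = [count_clusters(threshold_network(r, x)) for x in grid]
    else:
        counts = [0 for _ in grid]
    return pd.DataFrame({"threshold": list(grid), "n_clusters": counts})


@dataclass
class PowerLawFit:
    """Result of a log–log least-squares fit of the degree histogram."""

    fittable: bool
    exponent: float | None = None
    min_degree: int | None = None
    n_points: int = 0

    @property
    def in_natural_range(self) -> bool | None:
        if not self.fittable:
            return None
        return 2.0 <= self.exponent <= 3.0

    def to_dict(self) -> dict:
        return {
            "fittable": self.fittable,
            "exponent": self.exponent,
            "min_degree": self.min_degree,
            "n_points": self.n_points,
            "in_natural_range": self.in_natural_range,
        }


def fit_power_law_histogram(
    degrees: Sequence[float], frequencies: Sequence[float]
) -> PowerLawFit:
    """Fit freq(k) ∝ k^(−γ) by least squares on log(freq) vs log(k).

    Bins with zero frequency or degree < 1 are dropped; at least three
    distinct positive degrees are required, otherwise the fit is refused
    (``fittable=False``) rather than extrapolated.
    """
    k = np.asarray(degrees, dtype=float)
    f = np.asarray(frequencies, dtype=float)
    keep = (k >= 1) & (f > 0)
    k, f = k[keep], f[keep]
    if np.unique(k).size < 3:
        return PowerLawFit(fittable=False)
    slope, _ = np.polyfit(np.log(k), np.log(f), 1)
    return PowerLawFit(
        fittable=True,
        exponent=float(-slope),
        min_degree=int(k.min()),
        n_points=int(k.size),
    )


def fit_power_law_mle(degrees: Sequence[int], k_min: int | None = None) -> PowerLawFit:
    """Discrete power-law exponent by maximum likelihood.

    Maximises the zeta-normalised likelihood p(k) = k^(−γ)/ζ(γ, k_min)
    over degrees ≥ k_min (default: the smallest positive degree).  Less
    biased than histogram regression on heavy-tailed data.
    """
    from scipy.optimize import minimize_scalar
    from scipy.special import zeta

    k = np.asarray(degrees, dtype=float)
    k = k[k >= 1]
    if k_min is None:
        k_min = int(k.min()) if k.size else 1
    k = k[k >= k_min]
    if np.unique(k).size < 3:
        return PowerLawFit(fittable=False)
    mean_log_k = float(np.log(k).mean())

    def neg_loglik(gamma: float) -> float:
        return gamma * mean_log_k + np.log(zeta(gamma, k_min))

    res = minimize_scalar(neg_loglik, bounds=(1.01, 8.0), method="bounded")
    return PowerLawFit(
        fittable=True,
        exponent=float(res.x),
        min_degree=k_min,
        n_points=int(k.size),
    )


def power_law_index(net: CorrelationNetwork, method: str = "regression") -> PowerLawFit:
    """Power-law exponent of a network's degree distribution.

    Isolated nodes are excluded; requires >=10 non-isolated nodes.
    ``method`` is ``"regression"`` (log–log least squares on the degree
    histogram, the default) or ``"mle"``.
    """
    degrees = np.array([d for _, d in net.graph.degree() if d >= 1])
    if degrees.size < 10:
        raise ValueError(f"need >=10 non-isolated nodes, got {degrees.size}")
    if method == "mle":
        return fit_power_law_mle(degrees)
    if method != "regression":
        raise ValueError(f"unknown method {method!r}")
    counts = np.bincount(degrees)
    ks = np.arange(len(counts))
    return fit_power_law_histogram(ks, counts)
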