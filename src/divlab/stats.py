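"""Summary statistics of simulated filaments.

Precision of coordination: across replicate filaments, the variance of the
helper count in a fixed 10-cell window is divided by the binomial variance
``10 h (1 - h)`` expected under independent random specialisation at the
observed mean helper fraction ``h``.  A ratio near 1 is indistinguishable
from random allocation; coordination drives it below 1, and its reciprocal
(the *precision*) above 1.

Clumping: a clump is a maximal contiguous run of helpers in the final
filament.  Spatially structured groups pay for large clumps — interior
helpers are far from any reproductive — which the cost-of-clumping
regression (least-squares slope of fitness on mean clump size) quantifies.
A non-growing control assigns phenotypes i.i.d. along a fixed-length
filament, isolating the clump growth that comes from coupling division
with differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats as sp_stats

__all__ = [
    "ReplicateSet",
    "RelativeVariance",
    "ClumpRegression",
    "window_helper_count",
    "relative_variance",
    "clump_metrics",
    "cost_of_clumping",
    "nongrowing_clump_sim",
]

WINDOW = 10  # cells in the fixed observation window


@dataclass
class ReplicateSet:
    """Final phenotype strings and fitness values of replicate filaments,
    with derived per-replicate summaries."""

    patterns: list[str]
    fitness: np.ndarray
    L: int
    completed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fitness = np.asarray(self.fitness, dtype=float)
        if len(self.patterns) != len(self.fitness):
            raise ValueError("patterns and fitness must have equal length")
        if self.completed is None:
            self.completed = np.array([len(p) == self.L for p in self.patterns])
        else:
            self.completed = np.asarray(self.completed, dtype=bool)

    def __len__(self) -> int:
        return len(self.patterns)

    @property
    def helper_totals(self) -> np.ndarray:
        """Total helpers H_i per replicate."""
        return np.array([p.count("H") for p in self.patterns])

    @property
    def window_counts(self) -> np.ndarray:
        """Helpers in the leftmost non-terminal 10 cells per replicate."""
        return np.array([window_helper_count(p) for p in self.patterns])

    @property
    def clump_means(self) -> np.ndarray:
        """Mean clump size m_i per replicate (NaN when a filament has no
        helpers, in which case m_i is undefined)."""
        return np.array([clump_metrics(p)[1] for p in self.patterns])


class RelativeVariance(NamedTuple):
    """Observed-to-binomial variance ratio and its reciprocal."""

    ratio: float
    precision: float


class ClumpRegression(NamedTuple):
    """Least-squares fit of fitness on mean clump size."""

    slope: float
    intercept: float
    mse: float


def window_helper_count(pattern: str) -> int:
    """Helpers among the leftmost non-terminal 10 cells — 1-based positions
    2-11, excluding the outside (terminal) cell, which is a helper under
    H-R-R-H initialisation."""
    if len(pattern) < WINDOW + 2:
        raise ValueError(
            f"filament of {len(pattern)} cells too short for a non-terminal "
            f"{WINDOW}-cell window (need >= {WINDOW + 2})"
        )
    return pattern[1 : WINDOW + 1].count("H")


def relative_variance(replicates: ReplicateSet, L: int | None = None) -> RelativeVariance:
    """Variance of the 10-cell window helper count across replicates,
    relative to the binomial variance ``10 h (1 - h)`` at the observed mean
    helper fraction ``h = mean_i(H_i / L)``."""
    if len(replicates) < 2:
        raise ValueError("need at least two replicates to estimate a variance")
    L = L if L is not None else replicates.L
    h_bar = float(np.mean(replicates.helper_totals / L))
    if h_bar <= 0.0 or h_bar >= 1.0:
        raise ValueError(
            f"mean helper fraction {h_bar} is degenerate: no binomial variance to compare with"
        )
    var = float(np.var(replicates.window_counts, ddof=1))
    ratio = var / (WINDOW * h_bar * (1.0 - h_bar))
    precision = np.inf if ratio == 0.0 else 1.0 / ratio
    return RelativeVariance(ratio=ratio, precision=precision)


def clump_metrics(pattern: str) -> tuple[list[int], float]:
    """Sizes of maximal contiguous helper runs and their mean.

    A filament with no helpers returns ``([], nan)`` — its mean clump size
    is undefined and such replicates are excluded from averages.
    """
    sizes: list[int] = []
    run = 0
    for c in pattern:
        if c == "H":
            run += 1
        else:
            if run:
                sizes.append(run)
            run = 0
    if run:
        sizes.append(run)
    mean = float(np.mean(sizes)) if sizes else float("nan")
    return sizes, mean


def cost_of_clumping(replicates: ReplicateSet) -> ClumpRegression:
    """Slope of the least-squares regression of filament fitness on mean
    clump size, ``Cov(w_i, m_i) / Var(m_i)``, with intercept and the mean
    squared error of the fit.

    Replicates with no helpers (undefined m_i) or that died before reaching
    L cells are excluded.
    """
    m = replicates.clump_means
    keep = ~np.isnan(m) & replicates.completed
    m, w = m[keep], replicates.fitness[keep]
    if len(m) < 2 or np.var(m) == 0.0:
        raise ValueError("mean clump sizes show no variance: slope undefined")
    fit = sp_stats.linregress(m, w)
    resid = w - (fit.intercept + fit.slope * m)
    return ClumpRegression(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        mse=float(np.mean(resid**2)),
    )


def nongrowing_clump_sim(
    q: float,
    L: int,
    T: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Mean clump sizes of ``T`` non-growing filaments of fixed length
    ``L`` whose cells are helpers i.i.d. with probability ``q``.

    This is the control for the clump-amplifying effect of growth: the
    returned per-replicate mean clump sizes (NaN where a replicate has no
    helpers) are compared against those of grown filaments at matched
    helper probability.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must lie in [0, 1], got {q}")
    if L < 1 or T < 1:
        raise ValueError("L and T must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    draws = rng.random((T, L)) < q
    out = np.empty(T)
    for i in range(T):
        pattern = "".join("H" if x else "R" for x in draws[i])
        out[i] = clump_metrics(pattern)[1]
    return out
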