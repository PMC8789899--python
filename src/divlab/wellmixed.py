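"""Well-mixed public-goods model of reproductive division of labour.

A clonal group of ``n`` cells contains ``k`` sterile helpers and ``n - k``
reproductives.  Helpers secrete a public good that raises the fecundity of
every reproductive linearly, ``f(k) = b + h k/n``, so average group fecundity
is ``g(k) = (1 - k/n) (b + h k/n)``.  Two mechanisms allocate the helper role:

* *coordinated specialisation* — the group always forms with the optimal
  helper number ``k*`` but pays a metabolic cost ``c_C``;
* *random specialisation* — each cell independently becomes a helper with
  probability ``q`` (so the helper count is binomial) and pays ``c_R``.

Coordination is favoured when its relative metabolic cost
``gamma = (c_C - c_R)/(1 - c_R)`` is below the *stochastic cost* of random
specialisation, ``(h - b) / (n (h + b))``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, NamedTuple

import numpy as np
from scipy import stats

__all__ = [
    "PublicGoodsParams",
    "LabourAllocation",
    "FavouredResult",
    "reproductive_fecundity",
    "group_fecundity",
    "optimal_allocation",
    "approx_optimum_phat",
    "fitness_coordinated",
    "fitness_random_exact",
    "fitness_random_closed",
    "stochastic_cost",
    "coordination_favoured",
    "boundary_map",
]

CoordinatedMode = Literal["exact-discrete", "phat-approx"]
FavouredMode = Literal["analytic", "exact"]


@dataclass(frozen=True)
class PublicGoodsParams:
    """Parameters of the well-mixed linear public-goods model.

    Parameters
    ----------
    n
        Group size (cells), ``n >= 1``.
    b
        Baseline fecundity of a reproductive without any helpers
        (offspring per cell).  ``b = 0`` means cooperation is essential.
    h
        Scale of the fecundity benefit from cooperation (offspring per
        cell); the ratio ``h/b`` measures how important cooperation is.
    c_C
        Metabolic cost of coordination, a fraction in ``[0, 1]``.
    c_R
        Metabolic cost of random specialisation, a fraction in ``[0, 1]``.
    cost_fn
        Optional hook: a callable ``cost_fn(n) -> c_C`` replacing the scalar
        coordination cost (the cost could in principle grow with group size).
    """

    n: int
    b: float
    h: float
    c_C: float = 0.0
    c_R: float = 0.0
    cost_fn: Callable[[int], float] | None = None

    def __post_init__(self) -> None:
        if self.n < 1 or int(self.n) != self.n:
            raise ValueError(f"group size n must be a positive integer, got {self.n}")
        if self.b < 0:
            raise ValueError(f"baseline fecundity b must be >= 0, got {self.b}")
        if self.h <= 0:
            raise ValueError(f"benefit scale h must be > 0, got {self.h}")
        for name in ("c_C", "c_R"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")

    @property
    def coordination_cost(self) -> float:
        """Effective coordination cost, honouring the ``cost_fn`` hook."""
        if self.cost_fn is not None:
            return float(self.cost_fn(self.n))
        return self.c_C

    @property
    def gamma(self) -> float:
        """Relative change in metabolic cost when switching to coordination,
        ``(c_C - c_R)/(1 - c_R)``."""
        if self.c_R >= 1.0:
            raise ValueError("gamma is undefined when c_R = 1")
        return (self.coordination_cost - self.c_R) / (1.0 - self.c_R)


class LabourAllocation(NamedTuple):
    """A helper allocation: count ``k``, proportion ``p = k/n`` and the
    average group fecundity ``g`` it achieves."""

    k: int
    p: float
    g: float


class FavouredResult(NamedTuple):
    """Outcome of the coordinated-vs-random comparison: the boolean verdict
    and the signed margin (positive iff coordination is favoured)."""

    favoured: bool
    margin: float


def _check_k(params: PublicGoodsParams, k: int) -> None:
    if not 0 <= k <= params.n:
        raise ValueError(f"helper count k={k} outside [0, {params.n}]")


def reproductive_fecundity(params: PublicGoodsParams, k: int) -> float:
    """Fecundity of one reproductive in a group with ``k`` helpers,
    ``b + h k/n`` (no mechanism costs)."""
    _check_k(params, k)
    return params.b + params.h * k / params.n


def group_fecundity(params: PublicGoodsParams, k: int) -> float:
    """Average group fecundity ``g(k) = (1 - k/n)(b + h k/n)``: offspring per
    cell that would disperse at the end of the group life cycle."""
    _check_k(params, k)
    return (1.0 - k / params.n) * reproductive_fecundity(params, k)


def _G(params: PublicGoodsParams, p: float) -> float:
    """Continuous group fecundity ``G(p) = (1 - p)(b + h p)``."""
    return (1.0 - p) * (params.b + params.h * p)


def optimal_allocation(params: PublicGoodsParams) -> LabourAllocation:
    """Exact discrete optimum ``k* = argmax_k g(k)``; ties break toward the
    smaller ``k`` (fewer sterile cells at equal group fecundity)."""
    ks = np.arange(params.n + 1)
    g = (1.0 - ks / params.n) * (params.b + params.h * ks / params.n)
    k_star = int(np.argmax(g))  # argmax returns the first (smallest) maximiser
    return LabourAllocation(k=k_star, p=k_star / params.n, g=float(g[k_star]))


def approx_optimum_phat(params: PublicGoodsParams) -> float:
    """Continuous-approximation optimum ``p-hat = (h - b)/(2h)``, clamped to
    ``[0, 1]``; 0 when ``h <= b`` (no division of labour), 1/2 when ``b = 0``."""
    if params.h <= params.b:
        return 0.0
    return (params.h - params.b) / (2.0 * params.h)


def fitness_coordinated(
    params: PublicGoodsParams, mode: CoordinatedMode = "exact-discrete"
) -> float:
    """Fitness of fully coordinated specialisers, ``(1 - c_C) G(p)``.

    ``mode="exact-discrete"`` evaluates at the discrete optimum ``p*``;
    ``mode="phat-approx"`` at the continuous root ``p-hat``.
    """
    if mode == "exact-discrete":
        g = optimal_allocation(params).g
    elif mode == "phat-approx":
        g = _G(params, approx_optimum_phat(params))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return (1.0 - params.coordination_cost) * g


def fitness_random_exact(params: PublicGoodsParams, q: float) -> float:
    """Expected fitness of random specialisers by explicit binomial summation,
    ``(1 - c_R) sum_k C(n,k) q^k (1-q)^(n-k) g(k)``."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"helper probability q={q} outside [0, 1]")
    ks = np.arange(params.n + 1)
    weights = stats.binom.pmf(ks, params.n, q)
    g = (1.0 - ks / params.n) * (params.b + params.h * ks / params.n)
    return (1.0 - params.c_R) * float(weights @ g)


def fitness_random_closed(params: PublicGoodsParams, q: float) -> float:
    """Closed form of :func:`fitness_random_exact` via the first two binomial
    moments: ``(1 - c_R)(b(1-q) + h q(1-q) - h q(1-q)/n)``."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"helper probability q={q} outside [0, 1]")
    n, b, h = params.n, params.b, params.h
    return (1.0 - params.c_R) * (
        b * (1.0 - q) + h * q * (1.0 - q) - h * q * (1.0 - q) / n
    )


def stochastic_cost(params: PublicGoodsParams) -> float:
    """Stochastic cost of random specialisation, ``(h - b)/(n (h + b))``;
    0 when ``h <= b`` (the model then has no division of labour)."""
    if params.h <= params.b:
        return 0.0
    return (params.h - params.b) / (params.n * (params.h + params.b))


def coordination_favoured(
    params: PublicGoodsParams, mode: FavouredMode = "analytic"
) -> FavouredResult:
    """Is coordinated specialisation favoured over random specialisation?

    ``mode="analytic"`` compares ``gamma`` with the stochastic cost;
    ``mode="exact"`` compares the fitnesses directly at ``p-hat``, i.e.
    ``w_C = (1 - c_C) G(p-hat)`` against
    ``w_R = (1 - c_R)(G(p-hat) - h Var(P*))`` with
    ``Var(P*) = p-hat (1 - p-hat)/n``.  The two are algebraically equivalent;
    both are exposed so the identity can be checked.  The comparison is a
    strict ``>`` with no tolerance; the signed margin is returned so callers
    can apply their own.
    """
    if params.c_R >= 1.0:
        raise ValueError("degenerate cost: c_R = 1 makes gamma undefined")
    if mode == "analytic":
        margin = stochastic_cost(params) - params.gamma
        return FavouredResult(margin > 0.0, margin)
    if mode == "exact":
        p_hat = approx_optimum_phat(params)
        var = p_hat * (1.0 - p_hat) / params.n
        w_c = (1.0 - params.coordination_cost) * _G(params, p_hat)
        w_r = (1.0 - params.c_R) * (_G(params, p_hat) - params.h * var)
        margin = w_c - w_r
        return FavouredResult(margin > 0.0, margin)
    raise ValueError(f"unknown mode {mode!r}")


def boundary_map(
    n_values,
    hb_values,
    gamma: float,
    b: float = 1.0,
    mode: FavouredMode = "analytic",
) -> np.ndarray:
    """Boolean matrix over a group-size x benefit-ratio grid.

    Entry ``[i, j]`` is True when coordination is favoured at
    ``n = n_values[i]`` and ``h/b = hb_values[j]`` for the given relative
    metabolic cost ``gamma`` (realised as ``c_R = 0``, ``c_C = gamma``).
    Coordination is favoured at small ``n``, large ``h/b`` and small
    ``gamma``, partitioning the plane along a monotone boundary.
    """
    n_values = np.asarray(n_values)
    hb_values = np.asarray(hb_values, dtype=float)
    if np.any(n_values < 1) or np.any(hb_values <= 0):
        raise ValueError("grid values must be positive (n >= 1, h/b > 0)")
    out = np.empty((len(n_values), len(hb_values)), dtype=bool)
    for i, n in enumerate(n_values):
        for j, hb in enumerate(hb_values):
            p = PublicGoodsParams(n=int(n), b=b, h=hb * b, c_C=gamma, c_R=0.0)
            out[i, j] = coordination_favoured(p, mode=mode).favoured
    return out
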