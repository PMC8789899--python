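"""Event-driven simulator of a growing clonal cyanobacteria filament.

A filament is an ordered row of cells, each irreversibly a *helper* (H,
fixes and secretes nitrogen — the public good) or a *reproductive* (R,
absorbs the good, grows, and divides).  Growth is exactly event-driven:
between divisions every reproductive grows linearly at its current rate, so
the next division time is computed analytically rather than by numerical
integration.

The public good received at position ``i`` is a background density ``phi``
plus each helper's production ``phibar (1 - s)^zeta`` spread along the
filament by a geometric kernel in the inter-cell distance, normalised so
that total production per helper is conserved regardless of the diffusion
factor ``eta``.  A newborn cell samples a helper-produced signal (geometric
kernel ``xi``, unnormalised, plus Gaussian detection noise) and adopts the
helper phenotype with a probability set by a logistic response norm around
the threshold ``d`` with sensitivity ``v``; ``v = 0`` or ``s = 0`` recovers
random specialisation with baseline probability ``q``.

Two engines produce identical trajectories from identical pre-drawn random
buffers: a step-by-step pure-Python reference built from the public
operations below, and a numba-compiled batch engine (:mod:`divlab._kernel`)
used for evolutionary runs and large replicate sets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "HELPER",
    "REPRODUCTIVE",
    "FilamentGenotype",
    "FilamentEnv",
    "FilamentState",
    "GrowthOutcome",
    "FilamentDead",
    "NoReproductives",
    "StalledGrowth",
    "public_good_density",
    "growth_rate",
    "growth_cap",
    "signal_level",
    "helper_probability",
    "next_replication",
    "apply_division",
    "grow_filament",
    "filament_fitness",
    "simulate_replicates",
]

HELPER = 1
REPRODUCTIVE = 0

Engine = Literal["fast", "reference"]


class FilamentDead(Exception):
    """Raised when a filament cannot continue growing."""


class NoReproductives(FilamentDead):
    """The filament contains no reproductive cells."""


class StalledGrowth(FilamentDead):
    """Every reproductive has zero growth rate (no public good anywhere)."""


@dataclass(frozen=True)
class FilamentGenotype:
    """The four co-evolving specialisation traits carried clonally.

    q : baseline helper probability in [0, 1].
    s : signalling level in [0, 1] — fraction of a helper's resources
        diverted from public-good production into signal production.
    d : response threshold (signal-density units), >= 0; held at 0 whenever
        s = 0 so the threshold cannot drift neutrally.
    v : response sensitivity (inverse signal-density units), >= 0; v = 0
        means newborns ignore the signal entirely.
    """

    q: float = 0.0
    s: float = 0.0
    d: float = 0.0
    v: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"q must lie in [0, 1], got {self.q}")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"s must lie in [0, 1], got {self.s}")
        if self.d < 0 or self.v < 0:
            raise ValueError("d and v must be >= 0")
        if self.s == 0.0 and self.d != 0.0:
            raise ValueError("d must be 0 whenever s = 0 (no signal to threshold)")


@dataclass(frozen=True)
class FilamentEnv:
    """Physical and physiological constants of filament growth.

    phi       : background public-good density (good/time); 0 makes
                cooperation essential.
    phibar    : maximum public-good production rate per helper (good/time).
    eta       : public-good diffusion factor in (0, 1]; small = only nearby
                reproductives benefit, 1 = shared equally along the filament.
    zeta      : exponent of the signalling trade-off (1 - s)^zeta.
    psi       : maximum growth rate of a reproductive (size/time).
    mu        : growth saturation shape (time/good) in 1 - exp(-mu * good).
    pibar0    : baseline critical size for division (size units).
    beta      : sensitivity-cost shape; critical size is
                pibar0 + exp(beta v) - 1.
    lam       : signal production scale (signal/time); per-helper maximum
                signal rate is lam * s.
    xi        : signal diffusion factor in (0, 1].
    sigma_eps : s.d. of Gaussian signal-detection noise (signal units).
    L         : filament length (cells) at which the life cycle ends.
    """

    phi: float = 0.0
    phibar: float = 1.0
    eta: float = 0.1
    zeta: float = 0.5
    psi: float = 1.0
    mu: float = 1.0
    pibar0: float = 1.0
    beta: float = 0.05
    lam: float = 50.0
    xi: float = 0.5
    sigma_eps: float = 0.05
    L: int = 100

    def __post_init__(self) -> None:
        for name in ("phi", "phibar", "zeta", "psi", "mu", "pibar0", "beta", "lam", "sigma_eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("eta", "xi"):
            val = getattr(self, name)
            if not 0.0 < val <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {val}")
        if self.L < 5:
            raise ValueError(f"L must exceed the 4-cell initial filament, got {self.L}")


@dataclass
class FilamentState:
    """Ordered cell array at one instant: phenotype labels, reproductive
    sizes (meaningful only at R positions) and elapsed time."""

    phenotypes: np.ndarray  # int8, HELPER/REPRODUCTIVE
    sizes: np.ndarray  # float64, aligned with phenotypes
    t: float = 0.0

    @classmethod
    def from_pattern(cls, pattern: str, sizes: Sequence[float] | None = None, t: float = 0.0) -> "FilamentState":
        """Build a state from a phenotype string over the alphabet {H, R}."""
        bad = set(pattern) - {"H", "R"}
        if bad:
            raise ValueError(f"invalid phenotype characters {sorted(bad)}; expected only H/R")
        phen = np.array([HELPER if c == "H" else REPRODUCTIVE for c in pattern], dtype=np.int8)
        sz = np.zeros(len(pattern), dtype=np.float64)
        if sizes is not None:
            r_idx = np.flatnonzero(phen == REPRODUCTIVE)
            if len(sizes) != len(r_idx):
                raise ValueError(
                    f"{len(sizes)} sizes given for {len(r_idx)} reproductives in {pattern!r}"
                )
            sz[r_idx] = np.asarray(sizes, dtype=np.float64)
        return cls(phenotypes=phen, sizes=sz, t=t)

    @property
    def pattern(self) -> str:
        return "".join("H" if c == HELPER else "R" for c in self.phenotypes)

    @property
    def n_cells(self) -> int:
        return len(self.phenotypes)

    def helpers(self) -> np.ndarray:
        """0-based indices of helper cells."""
        return np.flatnonzero(self.phenotypes == HELPER)

    def reproductives(self) -> np.ndarray:
        """0-based indices of reproductive cells."""
        return np.flatnonzero(self.phenotypes == REPRODUCTIVE)

    def copy(self) -> "FilamentState":
        return FilamentState(self.phenotypes.copy(), self.sizes.copy(), self.t)


@dataclass(frozen=True)
class GrowthOutcome:
    """Result of one filament life cycle: the final state, the time at which
    the L-th cell appeared, per-filament fitness (summed final growth rates
    of reproductives divided by tau_L) and a completed/dead status."""

    final_state: FilamentState
    tau_L: float
    fitness: float
    status: Literal["completed", "dead"]


# ---------------------------------------------------------------------------
# Elementary operations (pure-Python reference implementations)
# ---------------------------------------------------------------------------


def _check_index(state: FilamentState, i: int) -> None:
    if not 0 <= i < state.n_cells:
        raise IndexError(f"cell index {i} outside filament of {state.n_cells} cells")


def public_good_density(
    state: FilamentState, env: FilamentEnv, genotype: FilamentGenotype, i: int
) -> float:
    """Local public-good density at cell ``i``.

    ``phi`` plus, for each helper ``j``, its production
    ``phibar (1 - s)^zeta`` weighted by ``eta^|i-j|`` and normalised by
    ``sum_k eta^|k-j|`` over all filament positions ``k`` — so each helper's
    total contribution along the filament is conserved whatever ``eta``.
    """
    _check_index(state, i)
    helpers = state.helpers()
    if len(helpers) == 0:
        return env.phi
    idx = np.arange(state.n_cells)
    amp = env.phibar * (1.0 - genotype.s) ** env.zeta
    total = env.phi
    for j in helpers:
        denom = np.sum(env.eta ** np.abs(idx - j))
        total += amp * env.eta ** abs(i - j) / denom
    return float(total)


def growth_rate(good_density: float, env: FilamentEnv) -> float:
    """Instantaneous growth rate ``psi (1 - exp(-mu * density))`` — increasing
    and saturating in the local good density."""
    if good_density < 0:
        raise ValueError(f"good density must be >= 0, got {good_density}")
    return env.psi * (1.0 - np.exp(-env.mu * good_density))


def growth_cap(genotype: FilamentGenotype, env: FilamentEnv) -> float:
    """Critical size for division, ``pibar0 + exp(beta v) - 1``: higher
    sensitivity delays replication (the metabolic cost of attending to the
    signal)."""
    return env.pibar0 + np.exp(env.beta * genotype.v) - 1.0


def signal_level(
    state: FilamentState,
    genotype: FilamentGenotype,
    env: FilamentEnv,
    i: int,
    rng: np.random.Generator | None = None,
    *,
    noise: float | None = None,
) -> float:
    """Signal detected by the (newly inserted) cell at index ``i``:
    ``max(lam s sum_{j in H} xi^|i-j| + eps, 0)`` with
    ``eps ~ Normal(0, sigma_eps^2)`` drawn once per specialisation event.

    The signal kernel is deliberately *not* normalised, unlike the good
    kernel.  ``noise`` supplies the standard-normal draw explicitly (used by
    the engines); otherwise it is taken from ``rng``.
    """
    _check_index(state, i)
    helpers = state.helpers()
    helpers = helpers[helpers != i]
    raw = env.lam * genotype.s * float(np.sum(env.xi ** np.abs(helpers - i)))
    if noise is None:
        if rng is None:
            raise ValueError("signal_level needs either rng or an explicit noise draw")
        noise = float(rng.standard_normal())
    return max(raw + env.sigma_eps * noise, 0.0)


def helper_probability(genotype: FilamentGenotype, chi: float) -> float:
    """Probability that a newborn sensing signal ``chi`` becomes a helper:
    ``clamp(q + 1 - 2 / (1 + exp(-v (chi - d))), 0, 1)``.

    Equals ``q`` when ``v = 0`` or ``chi = d``; signal above threshold pushes
    the probability below ``q``, signal below threshold pushes it above.
    """
    if chi < 0:
        raise ValueError(f"detected signal must be >= 0, got {chi}")
    # q + 1 - 2/(1 + exp(-x)) == q - tanh(x/2): exact at x = 0, stable for large |x|
    p = genotype.q - float(np.tanh(0.5 * genotype.v * (chi - genotype.d)))
    return min(1.0, max(0.0, p))


def next_replication(
    state: FilamentState, env: FilamentEnv, genotype: FilamentGenotype
) -> tuple[int, float]:
    """The reproductive that divides next and its waiting time.

    Each reproductive's time-to-division is its remaining growth divided by
    its current growth rate (others held fixed); the minimum wins, ties going
    to the lowest index.  Raises :class:`NoReproductives` or
    :class:`StalledGrowth` when no division can ever occur.
    """
    repro = state.reproductives()
    if len(repro) == 0:
        raise NoReproductives("filament has no reproductive cells")
    pibar = growth_cap(genotype, env)
    best_i, best_tau = -1, np.inf
    for i in repro:
        psi_i = growth_rate(public_good_density(state, env, genotype, int(i)), env)
        if psi_i <= 0.0:
            continue  # tau would be infinite
        tau_i = (pibar - state.sizes[i]) / psi_i
        if tau_i < best_tau:
            best_i, best_tau = int(i), tau_i
    if best_i < 0:
        raise StalledGrowth("all reproductives have zero growth rate")
    return best_i, best_tau


def apply_division(
    state: FilamentState,
    env: FilamentEnv,
    genotype: FilamentGenotype,
    rng: np.random.Generator | None = None,
    *,
    draws: tuple[float, float, float] | None = None,
) -> FilamentState:
    """Advance the filament through its next division event.

    All reproductive sizes advance by their rate times the waiting time; the
    dividing parent buds a daughter before or after itself with equal
    probability; indices shift; the daughter's phenotype is drawn from the
    response norm evaluated at its post-insertion position (the parent still
    counted among the reproductives); parent size resets to zero, as does
    the daughter's if reproductive.

    ``draws`` supplies ``(side_uniform, noise_normal, phenotype_uniform)``
    explicitly; otherwise they come from ``rng`` in that order.
    """
    if draws is None:
        if rng is None:
            raise ValueError("apply_division needs either rng or explicit draws")
        draws = (float(rng.random()), float(rng.standard_normal()), float(rng.random()))
    side_u, noise_z, pheno_u = draws

    parent, tau = next_replication(state, env, genotype)

    new = state.copy()
    for i in new.reproductives():
        psi_i = growth_rate(public_good_density(state, env, genotype, int(i)), env)
        new.sizes[i] += psi_i * tau
    new.t += tau

    # daughter before (left of) the parent with probability 1/2, else after
    pos = parent if side_u < 0.5 else parent + 1
    parent_after = parent + 1 if side_u < 0.5 else parent
    new.phenotypes = np.insert(new.phenotypes, pos, REPRODUCTIVE)  # placeholder
    new.sizes = np.insert(new.sizes, pos, 0.0)

    chi = signal_level(new, genotype, env, pos, noise=noise_z)
    p = helper_probability(genotype, chi)
    new.phenotypes[pos] = HELPER if pheno_u < p else REPRODUCTIVE
    new.sizes[pos] = 0.0
    new.sizes[parent_after] = 0.0
    return new


def _draw_buffers(rng: np.random.Generator, reps: int, n_events: int):
    """Pre-draw the per-division randomness consumed identically by both
    engines: insertion side, signal noise, phenotype uniform."""
    side_u = rng.random((reps, n_events))
    noise_z = rng.standard_normal((reps, n_events))
    pheno_u = rng.random((reps, n_events))
    return side_u, noise_z, pheno_u


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def filament_fitness(
    outcome: GrowthOutcome, env: FilamentEnv, genotype: FilamentGenotype
) -> float:
    """Per-filament fitness: summed growth rates of the reproductives in the
    final L-cell configuration divided by ``tau_L``; 0 for dead filaments."""
    if outcome.status == "dead":
        return 0.0
    state = outcome.final_state
    total = 0.0
    for i in state.reproductives():
        total += growth_rate(public_good_density(state, env, genotype, int(i)), env)
    return total / outcome.tau_L


def _grow_reference(
    genotype: FilamentGenotype,
    env: FilamentEnv,
    init: str,
    side_u: np.ndarray,
    noise_z: np.ndarray,
    pheno_u: np.ndarray,
) -> GrowthOutcome:
    state = FilamentState.from_pattern(init)
    n_events = env.L - state.n_cells
    for ev in range(n_events):
        try:
            state = apply_division(
                state, env, genotype,
                draws=(float(side_u[ev]), float(noise_z[ev]), float(pheno_u[ev])),
            )
        except FilamentDead:
            return GrowthOutcome(state, np.inf, 0.0, "dead")
    outcome = GrowthOutcome(state, state.t, 0.0, "completed")
    return replace(outcome, fitness=filament_fitness(outcome, env, genotype))


def grow_filament(
    genotype: FilamentGenotype,
    env: FilamentEnv,
    rng: np.random.Generator | int | None = None,
    init: str = "HRRH",
    engine: Engine = "fast",
) -> GrowthOutcome:
    """Run one filament life cycle from the ``init`` pattern (default the
    four-cell propagule H-R-R-H; R-R-R-R is the no-initial-helper variant)
    until the filament reaches ``L`` cells or growth stalls.

    Both engines consume the same pre-drawn random buffers, so for a fixed
    seed they produce the same trajectory.
    """
    if len(init) >= env.L:
        raise ValueError(f"init pattern ({len(init)} cells) must be shorter than L={env.L}")
    rng = _as_rng(rng)
    n_events = env.L - len(init)
    side_u, noise_z, pheno_u = _draw_buffers(rng, 1, n_events)
    if engine == "reference":
        return _grow_reference(genotype, env, init, side_u[0], noise_z[0], pheno_u[0])
    if engine != "fast":
        raise ValueError(f"unknown engine {engine!r}")
    from . import _kernel

    res = _kernel.run_batch(genotype, env, init, side_u, noise_z, pheno_u)
    return _outcome_from_batch(res, 0, env)


def _outcome_from_batch(res: dict, r: int, env: FilamentEnv) -> GrowthOutcome:
    n = int(res["n_cells"][r])
    state = FilamentState(
        phenotypes=res["phenotypes"][r, :n].copy(),
        sizes=res["sizes"][r, :n].copy(),
        t=float(res["tau_L"][r]) if res["completed"][r] else float(res["t"][r]),
    )
    if res["completed"][r]:
        return GrowthOutcome(state, float(res["tau_L"][r]), float(res["fitness"][r]), "completed")
    return GrowthOutcome(state, np.inf, 0.0, "dead")


def simulate_replicates(
    genotype: FilamentGenotype,
    env: FilamentEnv,
    reps: int,
    rng: np.random.Generator | int | None = None,
    init: str = "HRRH",
) -> dict:
    """Simulate ``reps`` independent filament life cycles with the fast
    engine, returning arrays: ``fitness``, ``tau_L``, ``completed``,
    ``patterns`` (final phenotype strings), ``helper_counts``."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if len(init) >= env.L:
        raise ValueError(f"init pattern ({len(init)} cells) must be shorter than L={env.L}")
    rng = _as_rng(rng)
    n_events = env.L - len(init)
    side_u, noise_z, pheno_u = _draw_buffers(rng, reps, n_events)
    from . import _kernel

    res = _kernel.run_batch(genotype, env, init, side_u, noise_z, pheno_u)
    patterns = []
    for r in range(reps):
        n = int(res["n_cells"][r])
        patterns.append("".join("H" if c == HELPER else "R" for c in res["phenotypes"][r, :n]))
    return {
        "fitness": res["fitness"],
        "tau_L": res["tau_L"],
        "completed": res["completed"],
        "patterns": patterns,
        "helper_counts": np.array([p.count("H") for p in patterns]),
    }
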