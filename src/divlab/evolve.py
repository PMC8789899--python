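"""Two-phase mutation-selection search over the specialisation traits.

A monomorphic resident population starts at ``(q, s, d, v) = (0, 0, 0, 0)``.
Each generation a mutant is drawn from a diagonal multivariate normal
centred on the resident and replaces it iff its estimated mean fitness
(averaged over independent filament simulations) is strictly higher — a
sequential-invasion hill climb.  Phase 1 mutates only the baseline helper
probability ``q`` (random specialisation finds its optimum); at the phase
boundary ``q`` is frozen at its average over a mid-phase window, after which
only the coordination traits ``s``, ``d``, ``v`` mutate.  Evolved trait
values are trailing-window averages of the resident trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .filament import FilamentEnv, FilamentGenotype, simulate_replicates

__all__ = [
    "EvolutionConfig",
    "EvolutionResult",
    "propose_mutant",
    "estimate_fitness",
    "run_evolution",
]


@dataclass(frozen=True)
class EvolutionConfig:
    """Schedule and mutation parameters of the evolutionary search.

    Defaults follow the study design: 4000 generations of which the first
    500 mutate only ``q``; ``q`` then frozen at its mean over generations
    250-500; fitness estimated from 200 filaments per strategy; evolved
    values averaged over the last 2000 generations.  Mutation s.d. values
    are package choices (see docs/methods.md).
    """

    phase1_gens: int = 500
    total_gens: int = 4000
    reps: int = 200
    sigma_q: float = 0.02
    sigma_s: float = 0.02
    sigma_d: float = 0.2
    sigma_v: float = 0.2
    q_fix_window: tuple[int, int] = (250, 500)
    report_window: int = 2000
    init: str = "HRRH"

    def __post_init__(self) -> None:
        if not 1 <= self.phase1_gens < self.total_gens:
            raise ValueError("need 1 <= phase1_gens < total_gens")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        for name in ("sigma_q", "sigma_s", "sigma_d", "sigma_v"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.q_fix_window
        if not 1 <= lo <= hi <= self.phase1_gens:
            raise ValueError("q_fix_window must lie within [1, phase1_gens]")
        if not 1 <= self.report_window <= self.total_gens:
            raise ValueError("report_window must lie within [1, total_gens]")


@dataclass(frozen=True)
class EvolutionResult:
    """Evolved trait values (trailing-window averages) plus the full
    per-generation trace."""

    q: float
    s: float
    d: float
    v: float
    trace: pd.DataFrame

    @property
    def genotype(self) -> FilamentGenotype:
        """Evolved traits as a genotype (d forced to 0 if s rounds to 0)."""
        d = self.d if self.s > 0 else 0.0
        return FilamentGenotype(q=self.q, s=self.s, d=d, v=self.v)


def propose_mutant(
    resident: FilamentGenotype,
    config: EvolutionConfig,
    phase: int,
    rng: np.random.Generator,
) -> FilamentGenotype:
    """Draw a mutant genotype around the resident.

    Phase 1 perturbs only ``q``; phase 2 only ``s``, ``d``, ``v``.  Draws
    are truncated to the trait domains (``q, s`` to [0, 1]; ``d, v`` to
    [0, inf)), and ``d`` is reset to 0 whenever ``s = 0`` so the threshold
    cannot drift while no signal is produced.
    """
    if phase not in (1, 2):
        raise ValueError(f"phase must be 1 or 2, got {phase}")
    q, s, d, v = resident.q, resident.s, resident.d, resident.v
    if phase == 1:
        q = q + config.sigma_q * rng.standard_normal()
        q = min(1.0, max(0.0, q))
    else:
        s = min(1.0, max(0.0, s + config.sigma_s * rng.standard_normal()))
        d = max(0.0, d + config.sigma_d * rng.standard_normal())
        v = max(0.0, v + config.sigma_v * rng.standard_normal())
        if s == 0.0:
            d = 0.0
    return FilamentGenotype(q=q, s=s, d=d, v=v)


def estimate_fitness(
    genotype: FilamentGenotype,
    env: FilamentEnv,
    reps: int,
    rng: np.random.Generator | int | None = None,
    init: str = "HRRH",
) -> float:
    """Mean per-filament fitness over ``reps`` independent growth
    simulations (dead filaments contribute 0)."""
    res = simulate_replicates(genotype, env, reps, rng, init=init)
    return float(np.mean(res["fitness"]))


def run_evolution(
    env: FilamentEnv,
    config: EvolutionConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> EvolutionResult:
    """Run the two-phase hill climb and return evolved traits plus trace.

    Fitness of resident and mutant are both re-estimated every generation
    with fresh simulation randomness (no common-random-number pairing), so
    acceptance decisions are based on independent noisy estimates, as in a
    sequential invasion analysis.
    """
    config = config or EvolutionConfig()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    resident = FilamentGenotype(0.0, 0.0, 0.0, 0.0)
    records: list[dict] = []

    for gen in range(1, config.total_gens + 1):
        phase = 1 if gen <= config.phase1_gens else 2

        if gen == config.phase1_gens + 1:
            # freeze q at its mean over the fixing window before phase 2
            lo, hi = config.q_fix_window
            q_fixed = float(
                np.mean([rec["q"] for rec in records[lo - 1 : hi]])
            )
            resident = replace(resident, q=q_fixed)

        mutant = propose_mutant(resident, config, phase, rng)
        resident_fitness = estimate_fitness(resident, env, config.reps, rng, config.init)
        mutant_fitness = estimate_fitness(mutant, env, config.reps, rng, config.init)
        accepted = mutant_fitness > resident_fitness
        if accepted:
            resident = mutant

        records.append(
            {
                "generation": gen,
                "phase": phase,
                "q": resident.q,
                "s": resident.s,
                "d": resident.d,
                "v": resident.v,
                "mutant_q": mutant.q,
                "mutant_s": mutant.s,
                "mutant_d": mutant.d,
                "mutant_v": mutant.v,
                "resident_fitness": resident_fitness,
                "mutant_fitness": mutant_fitness,
                "accepted": accepted,
            }
        )

    trace = pd.DataFrame.from_records(records)
    tail = trace.iloc[-config.report_window :]
    return EvolutionResult(
        q=float(tail["q"].mean()),
        s=float(tail["s"].mean()),
        d=float(tail["d"].mean()),
        v=float(tail["v"].mean()),
        trace=trace,
    )
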