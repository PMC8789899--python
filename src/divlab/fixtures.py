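"""Synthetic inputs: toy filaments, seeded replicate sets, parameter sweeps.

The sweep drives the evolutionary search over a grid of background
public-good density (``phi``) and good diffusivity (``eta``) — the two
environmental axes along which coordination is expected to pay off (low
``phi``: cooperation essential; low ``eta``: small effective social
neighbourhood).  All randomness derives deterministically from a master
seed via ``numpy.random.SeedSequence`` so any single grid cell or replicate
can be recomputed in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .evolve import EvolutionConfig, run_evolution
from .filament import FilamentEnv, FilamentGenotype, FilamentState, simulate_replicates
from .stats import ReplicateSet, relative_variance

__all__ = [
    "make_fixture_filament",
    "replicate_set",
    "SweepGrid",
    "sweep",
    "cell_rng",
]


def make_fixture_filament(
    pattern: str, sizes: Sequence[float] | None = None
) -> FilamentState:
    """A deterministic filament state at t = 0 from a phenotype string.

    ``sizes`` assigns starting sizes to the reproductives in order (default
    all zero).  "HRRH" is the standard four-cell propagule; "RRRR" the
    no-initial-helper variant; helper-only strings are valid and useful for
    exercising dead-filament handling.
    """
    return FilamentState.from_pattern(pattern, sizes=sizes)


def replicate_set(
    genotype: FilamentGenotype,
    env: FilamentEnv,
    T: int,
    seed: np.random.Generator | int | None = None,
    init: str = "HRRH",
) -> ReplicateSet:
    """``T`` independent seeded filament life cycles packaged for the
    statistics layer."""
    res = simulate_replicates(genotype, env, T, seed, init=init)
    return ReplicateSet(
        patterns=res["patterns"],
        fitness=res["fitness"],
        L=env.L,
        completed=res["completed"],
    )


def cell_rng(master_seed: int, cell_index: int, replicate_index: int) -> np.random.Generator:
    """Generator for one (cell, replicate) of a sweep — a pure function of
    its arguments, so any cell can be re-run in isolation."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), int(cell_index), int(replicate_index)])
    )


@dataclass
class SweepGrid:
    """A phi x eta sweep: axes, per-cell evolutionary settings and, once
    run, a tidy results table (one row per cell) in ``results``."""

    phi_values: Sequence[float]
    eta_values: Sequence[float]
    runs_per_cell: int = 5
    precision_reps: int = 1000
    results: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi_values, dtype=float)
        eta = np.asarray(self.eta_values, dtype=float)
        if np.any(np.diff(phi) <= 0) or np.any(np.diff(eta) <= 0):
            raise ValueError("grid axes must be strictly increasing")
        if np.any(phi < 0) or np.any(eta <= 0) or np.any(eta > 1):
            raise ValueError("need phi >= 0 and eta in (0, 1]")


def sweep(
    grid: SweepGrid,
    env: FilamentEnv,
    config: EvolutionConfig,
    master_seed: int = 0,
) -> SweepGrid:
    """Fill a sweep grid: per cell, run ``runs_per_cell`` independent
    evolutionary searches, average the evolved traits, then measure the
    precision of coordination of the mean evolved strategy from a fresh
    replicate set.

    Returns the grid with ``results`` set; every row echoes its phi, eta
    and the seed material that regenerates it.
    """
    rows = []
    for ci, (phi, eta) in enumerate(
        (p, e) for p in grid.phi_values for e in grid.eta_values
    ):
        cell_env = replace(env, phi=float(phi), eta=float(eta))
        traits = np.zeros((grid.runs_per_cell, 4))
        for rep in range(grid.runs_per_cell):
            result = run_evolution(cell_env, config, cell_rng(master_seed, ci, rep))
            traits[rep] = (result.q, result.s, result.d, result.v)
        q, s, d, v = traits.mean(axis=0)
        evolved = FilamentGenotype(q=q, s=s, d=(d if s > 0 else 0.0), v=v)
        reps = replicate_set(
            evolved,
            cell_env,
            grid.precision_reps,
            cell_rng(master_seed, ci, grid.runs_per_cell),
            init=config.init,
        )
        rv = relative_variance(reps)
        rows.append(
            {
                "phi": float(phi),
                "eta": float(eta),
                "cell_index": ci,
                "master_seed": master_seed,
                "q_star": q,
                "s_star": s,
                "d_star": d,
                "v_star": v,
                "relative_variance": rv.ratio,
                "precision": rv.precision,
            }
        )
    grid.results = pd.DataFrame(rows)
    return grid
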