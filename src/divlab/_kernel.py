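"""Numba-compiled batch engine for filament growth.

Implements exactly the event loop of :mod:`divlab.filament` — analytic
advancement between divisions, geometric good/signal kernels, logistic
response norm — over many replicates per call.  Randomness is consumed from
pre-drawn buffers (one insertion-side uniform, one standard-normal noise
draw and one phenotype uniform per division event, in that order) so that
trajectories match the pure-Python reference engine draw for draw.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .filament import HELPER, REPRODUCTIVE, FilamentEnv, FilamentGenotype

__all__ = ["run_batch"]


@njit(cache=False)
def _grow_batch(
    init_phen,
    L,
    q, s, d, v,
    phi, phibar, eta, zeta, psi, mu, pibar0, beta, lam, xi, sigma_eps,
    side_u, noise_z, pheno_u,
):
    reps = side_u.shape[0]
    n0 = init_phen.size

    fitness = np.zeros(reps)
    tau_L = np.full(reps, np.inf)
    t_end = np.zeros(reps)
    completed = np.zeros(reps, np.bool_)
    out_phen = np.zeros((reps, L), np.int8)
    out_sizes = np.zeros((reps, L))
    n_cells = np.zeros(reps, np.int64)

    pibar = pibar0 + np.exp(beta * v) - 1.0
    good_amp = phibar * (1.0 - s) ** zeta

    # geometric kernels as lookup tables over inter-cell distance
    eta_pow = np.empty(L)
    xi_pow = np.empty(L)
    eta_pow[0] = 1.0
    xi_pow[0] = 1.0
    for m in range(1, L):
        eta_pow[m] = eta_pow[m - 1] * eta
        xi_pow[m] = xi_pow[m - 1] * xi

    phen = np.empty(L, np.int8)
    sizes = np.empty(L)
    psi_arr = np.empty(L)
    denom = np.empty(L)

    for r in range(reps):
        for i in range(n0):
            phen[i] = init_phen[i]
            sizes[i] = 0.0
        Lt = n0
        t = 0.0
        dead = False

        for ev in range(L - n0):
            # per-helper kernel normaliser over all current positions
            for j in range(Lt):
                if phen[j] == HELPER:
                    acc = 0.0
                    for k in range(Lt):
                        acc += eta_pow[abs(k - j)]
                    denom[j] = acc
            # growth rates and next division
            best_i = -1
            best_tau = np.inf
            for i in range(Lt):
                if phen[i] == REPRODUCTIVE:
                    good = phi
                    for j in range(Lt):
                        if phen[j] == HELPER:
                            good += good_amp * eta_pow[abs(i - j)] / denom[j]
                    rate = psi * (1.0 - np.exp(-mu * good))
                    psi_arr[i] = rate
                    if rate > 0.0:
                        tau_i = (pibar - sizes[i]) / rate
                        if tau_i < best_tau:
                            best_tau = tau_i
                            best_i = i
            if best_i < 0:
                dead = True  # no reproductives, or all rates zero
                break

            # advance sizes analytically and insert the daughter
            for i in range(Lt):
                if phen[i] == REPRODUCTIVE:
                    sizes[i] += psi_arr[i] * best_tau
            t += best_tau

            if side_u[r, ev] < 0.5:
                pos = best_i          # daughter before the parent
                parent_after = best_i + 1
            else:
                pos = best_i + 1      # daughter after the parent
                parent_after = best_i
            for m in range(Lt, pos, -1):
                phen[m] = phen[m - 1]
                sizes[m] = sizes[m - 1]
            Lt += 1
            phen[pos] = REPRODUCTIVE  # placeholder while sensing
            sizes[pos] = 0.0
            sizes[parent_after] = 0.0

            # response norm at the daughter's post-insertion index
            raw = 0.0
            for j in range(Lt):
                if j != pos and phen[j] == HELPER:
                    raw += xi_pow[abs(pos - j)]
            chi = lam * s * raw + sigma_eps * noise_z[r, ev]
            if chi < 0.0:
                chi = 0.0
            # identical to q + 1 - 2/(1 + exp(-x)); exact at x = 0
            p = q - np.tanh(0.5 * v * (chi - d))
            if p < 0.0:
                p = 0.0
            elif p > 1.0:
                p = 1.0
            if pheno_u[r, ev] < p:
                phen[pos] = HELPER

        n_cells[r] = Lt
        t_end[r] = t
        for i in range(Lt):
            out_phen[r, i] = phen[i]
            out_sizes[r, i] = sizes[i]
        if dead:
            continue

        # fitness: summed growth rates of reproductives in the final
        # configuration, divided by the time to reach L cells
        completed[r] = True
        tau_L[r] = t
        for j in range(Lt):
            if phen[j] == HELPER:
                acc = 0.0
                for k in range(Lt):
                    acc += eta_pow[abs(k - j)]
                denom[j] = acc
        total = 0.0
        for i in range(Lt):
            if phen[i] == REPRODUCTIVE:
                good = phi
                for j in range(Lt):
                    if phen[j] == HELPER:
                        good += good_amp * eta_pow[abs(i - j)] / denom[j]
                total += psi * (1.0 - np.exp(-mu * good))
        fitness[r] = total / t

    return fitness, tau_L, t_end, completed, out_phen, out_sizes, n_cells


def run_batch(
    genotype: FilamentGenotype,
    env: FilamentEnv,
    init: str,
    side_u: np.ndarray,
    noise_z: np.ndarray,
    pheno_u: np.ndarray,
) -> dict:
    """Run one life cycle per replicate row of the random buffers."""
    init_phen = np.array(
        [HELPER if c == "H" else REPRODUCTIVE for c in init], dtype=np.int8
    )
    fitness, tau_L, t, completed, phen, sizes, n_cells = _grow_batch(
        init_phen,
        env.L,
        genotype.q, genotype.s, genotype.d, genotype.v,
        env.phi, env.phibar, env.eta, env.zeta, env.psi, env.mu,
        env.pibar0, env.beta, env.lam, env.xi, env.sigma_eps,
        side_u, noise_z, pheno_u,
    )
    return {
        "fitness": fitness,
        "tau_L": tau_L,
        "t": t,
        "completed": completed,
        "phenotypes": phen,
        "sizes": sizes,
        "n_cells": n_cells,
    }
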