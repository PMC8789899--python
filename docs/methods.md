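# Methods

## Well-mixed model

A clonal group of `n` cells contains `k` sterile helpers and `n − k`
reproductives. Reproductive fecundity is linear in the helper proportion,
`f(k) = b + h k/n`; average group fecundity is
`g(k) = (1 − k/n) f(k)`. The model assumes a rivalrous public good shared
equally by all group members, a stable environment, and full clonality
(no within-group conflict). Coordinated specialisers realise the discrete
optimum `k* = argmax_k g(k)` and pay a fractional metabolic cost `c_C`;
random specialisers draw the helper count from `Binomial(n, q)` with
`q = p* = k*/n` and pay `c_R`.

Two optima are exposed and never silently interchanged: the discrete
argmax `p*` (ties broken toward fewer helpers, so equal group fecundity
never buys extra sterility) and the continuous root
`p̂ = (h − b)/(2h)` of the concave `G(p) = (1 − p)(b + hp)`, clamped to
`[0, 1]` and equal to `1/2` when cooperation is essential (`b = 0`).
`h ≤ b` is accepted and yields `k* = 0` and a zero stochastic cost rather
than an error: the model then simply has no division of labour. The
comparison `coordination_favoured` offers the analytic condition
`gamma < (h − b)/(n(h + b))` and the direct fitness comparison at `p̂`;
the two are algebraically identical (divide `w_C − w_R` by `1 − c_R`), and
the test suite checks the sign agreement across a parameter grid. The
comparison itself uses a strict `>` with no tolerance; the signed margin
is returned so callers can impose one. `c_C` may be supplied as a function
of `n` through the `cost_fn` hook; alternative goods (non-rivalrous, club
goods, non-sterile helpers, nonlinear fecundity) are out of scope.

## Filament model

The filament is an ordered array of cells with immutable phenotypes
(helper H / reproductive R), beginning as the four-cell propagule H-R-R-H
(an all-reproductive R-R-R-R variant is supported). Growth is exactly
event-driven: between divisions each reproductive's size advances linearly
at its current rate, so waiting times are computed analytically and there
is no integrator drift.

* **Public good.** Density at cell `i` is
  `phi + Σ_{j∈H} phibar (1−s)^zeta · eta^|i−j| / Σ_k eta^|k−j|`. The
  normaliser runs over *all* current positions, so each helper's summed
  contribution along the filament equals its production
  `phibar (1−s)^zeta` for every `eta` (a conservation principle, verified
  to 1e−12 in the tests); as `eta → 1` every cell receives an equal share.
  Good deposited at helper positions is wasted — this is what makes helper
  clumps costly when diffusion is local.
* **Growth and division.** A reproductive at good density `Φ` grows at
  `psi (1 − e^(−mu Φ))` and divides on reaching the cap
  `pibar = pibar0 + e^(beta v) − 1`. The next divider is the reproductive
  with the smallest `(pibar − size)/rate`, ties to the lowest index
  (determinism). The daughter is inserted before or after the parent with
  equal probability; the parent's size resets to zero.
* **Specialisation.** At the daughter's post-insertion index the detected
  signal is `chi = max(lam · s · Σ_{j∈H} xi^|i−j| + eps, 0)` with a single
  `eps ~ Normal(0, sigma_eps²)` per division; the signal kernel is
  deliberately *not* normalised, unlike the good kernel. The helper
  probability is `p = clamp(q + 1 − 2/(1 + e^(−v(chi−d))))`, implemented
  as `q − tanh(v(chi−d)/2)` so that `p = q` holds *exactly* at `v = 0` or
  `chi = d` in floating point. Signal above threshold suppresses the
  helper fate, below promotes it; `v → ∞` gives a step response.
* **Life cycle and fitness.** Growth stops when the filament reaches `L`
  cells at time `tau_L`; fitness is the summed growth rates of the final
  reproductives divided by `tau_L`. Filaments that stall (all rates zero,
  or no reproductives, possible only for degenerate inputs such as `phi=0`
  with no helpers or `s = 1`) are marked dead with fitness 0 — the model
  itself never removes reproductives, so death can only occur from such
  starting conditions.

Two engines share one contract. All per-division randomness (insertion
side, signal noise, phenotype uniform) is pre-drawn from a
`numpy.random.Generator` into buffers; a numba-compiled batch engine and a
pure-Python reference engine (built from the public step operations)
consume them in the same order and are tested to produce identical
phenotype strings and numerically identical times and fitness. Indices are
0-based in the library and 1-based in user-facing CLI output.

## Evolution

The search follows a strict sequential-invasion scheme: a monomorphic
resident starting at `(q, s, d, v) = (0, 0, 0, 0)`, one mutant per
generation drawn from a diagonal normal, acceptance iff the mutant's
estimated mean fitness (fresh, independently seeded simulations for both
strategies every generation — no common random numbers by default) is
strictly greater. Phase 1 mutates only `q`; at the phase boundary `q` is
frozen at its mean over the second half of phase 1; phase 2 mutates only
`s`, `d`, `v`, with `d` reset to 0 whenever `s = 0` so the threshold
cannot drift neutrally. Trait proposals are truncated at their domain
boundaries (simpler than rejection sampling; the boundary pile-up at 0 is
intended — it is the no-coordination state). Evolved values are
trailing-window averages of the resident trajectory. Population-genetic
detail (drift, polymorphism, recombination) is deliberately absent.

Full-scale defaults are 500 + 3500 generations, 200 filaments per fitness
estimate, `q` fixed over generations 250–500, evolved values averaged over
the last 2000 generations.

## Statistics

*Precision of coordination*: across `T` replicate final filaments, the
variance of the helper count in the leftmost non-terminal 10 cells
(1-based positions 2–11 — position 1 is excluded because under H-R-R-H
initialisation the outside cell is a helper by construction) divided by
`10 h̄ (1 − h̄)`, the binomial variance at the observed mean helper
fraction `h̄ = mean(H_i/L)`. Under i.i.d. specialisation the ratio is ≈ 1
(calibrated in the tests at T = 10⁴ within 3 Monte-Carlo s.e.); precision
is its reciprocal. Note the denominator uses the whole-filament helper
fraction, so for genotypes whose window and whole-filament helper rates
differ (e.g. tiny `q` with the two initial terminal helpers) the ratio is
biased below 1 even without coordination; corner comparisons in the tests
keep `q*` well away from this regime.

*Clumps*: maximal contiguous helper runs; per-filament mean clump size
`m_i` is undefined (NaN) for helper-free filaments, which are excluded
from averages and from the cost-of-clumping regression, as are dead
filaments. The cost of clumping is the least-squares slope
`Cov(w_i, m_i)/Var(m_i)` (computed via `scipy.stats.linregress`, checked
against a two-pass oracle). The non-growing control draws `L` i.i.d.
Bernoulli(q) phenotypes per replicate; comparing its clump-size
distribution with grown filaments isolates the amplification caused by
coupling division to differentiation. For i.i.d. strings the expected
clump count is `q(1−q)(L−1) + q`, used as a closed-form oracle.

## Parameter choices

The filament model has 15 environment/physiology constants; the package
ships documented defaults, every one overridable and echoed in run
sidecars:

| parameter | default | meaning / rationale |
|---|---|---|
| phi | 0.0 | background good density; 0 = essential cooperation (the focal regime) |
| phibar | 1.0 | helper production rate; sets the good scale |
| eta | 0.1 | good diffusion; 0.1 = very local sharing (focal regime) |
| zeta | 0.5 | signalling trade-off exponent; sub-linear so a small signalling investment costs ~s/2 of production, keeping the first evolutionary steps toward coordination selectable |
| psi, mu | 1.0 | growth scale and saturation; growth is near-linear at the good densities the defaults produce |
| pibar0 | 1.0 | baseline division size; with psi = 1 the time unit is one uncrowded division |
| beta | 0.05 | sensitivity cost; v = 1.5 delays division by ~8%, so sharp (v ≫ 10) responses are prohibitively costly |
| lam | 50.0 | signal scale; at s ≈ 0.02 a neighbouring helper already produces a signal of order 1, far above the detection noise, so useful sensitivities are v ~ 1–2 and useful thresholds d ~ 1–3 |
| xi | 0.5 | signal diffusion (fixed, distinct from eta) |
| sigma_eps | 0.05 | detection noise s.d. |
| L | 100 | filament size at dispersal |

Mutation s.d. defaults are `sigma_q = sigma_s = 0.02` and
`sigma_d = sigma_v = 0.2`: threshold and sensitivity live on the signal
scale (order 1), so their steps are an order of magnitude larger than
those of the probability-scaled traits; with 0.05 steps the threshold
cannot traverse its useful range within a scaled run.

These choices were fixed by pilot exploration of where the model expresses
its intended mechanism — coordination evolving under essential, local
cooperation and not under abundant, global cooperation — and are not
empirical estimates for any real cyanobacterium.

## Scaled problem sizes

The test suite and `scripts/acceptance.py` use desk-scale runs: filaments
of L = 50, two-phase searches of 100 + 200 generations with 50 filaments
per fitness estimate, 3 (tests) or 5 (acceptance script, matching the
sweep default) replicate evolutionary runs per environment corner, 2000
replicate filaments per precision estimate, and T = 10⁴ for the i.i.d.
calibrations. The high-φ corner is φ = 0.5: there the marginal value of a
helper is still positive (q* ≈ 0.1), which keeps the precision statistic
non-degenerate; for φ ≳ 1 helpers are worthless under the defaults and
window variance collapses. At these scales the corner contrast (s*, v*,
precision higher at φ = 0, η = 0.1 than at φ = 0.5, η = 1) is reproducible
across seeds, but evolved trait values carry substantial run-to-run spread
and individual 300-generation runs occasionally fail to leave the
random-specialisation state; full-scale runs converge much more tightly.

## What the synthetic data does and does not show

The generator *is* the study system — there is no external data. Passing
tests show the implementation honours the model's contracts (conservation,
calibration, determinism, the analytic condition) and that the model's
qualitative claims hold at desk scale under the shipped defaults. They do
not show that any real filament system occupies this parameter regime,
and the absolute evolved trait values and clump statistics are
parameterisation-dependent. Known limitations: single-filament fitness
(no population structure or frequency dependence), one-dimensional
geometry, fixed environment over a life cycle, and no regulatory detail
behind the response norm.
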