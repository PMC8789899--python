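"""Tests of the filament growth model: elementary operations, engine
cross-validation and stochastic contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sp_stats

from divlab.filament import (
    FilamentEnv,
    FilamentGenotype,
    FilamentState,
    NoReproductives,
    StalledGrowth,
    apply_division,
    filament_fitness,
    grow_filament,
    growth_cap,
    growth_rate,
    helper_probability,
    next_replication,
    public_good_density,
    signal_level,
    simulate_replicates,
)


def env(**kw) -> FilamentEnv:
    return FilamentEnv(**kw)


class TestPublicGood:
    def test_background_only_without_helpers(self):
        state = FilamentState.from_pattern("RRRR")
        assert public_good_density(state, env(phi=2.0), FilamentGenotype(), 1) == pytest.approx(2.0)

    def test_equal_shares_in_full_diffusion_limit(self):
        state = FilamentState.from_pattern("HRRRRR")
        e = env(phi=0.0, eta=1.0, phibar=1.0)
        dens = [public_good_density(state, e, FilamentGenotype(), i) for i in range(6)]
        assert dens == pytest.approx([1.0 / 6] * 6)

    def test_single_helper_contribution_sums_to_production(self):
        # conservation: the normalised kernel spreads exactly phibar (1-s)^zeta
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            j = int(rng.integers(0, n))
            pattern = "".join("H" if i == j else "R" for i in range(n))
            state = FilamentState.from_pattern(pattern)
            e = env(phi=0.3, eta=float(rng.uniform(0.05, 1.0)), phibar=2.0, zeta=0.5)
            g = FilamentGenotype(q=0.2, s=0.4, d=1.0, v=1.0)
            total = sum(
                public_good_density(state, e, g, i) - e.phi for i in range(n)
            )
            assert total == pytest.approx(2.0 * 0.6**0.5, rel=1e-12)

    def test_index_error(self):
        state = FilamentState.from_pattern("HRRH")
        with pytest.raises(IndexError):
            public_good_density(state, env(), FilamentGenotype(), 4)


class TestRatesAndCaps:
    def test_growth_rate_shape(self):
        e = env(psi=2.0, mu=1.0)
        assert growth_rate(0.0, e) == 0.0
        assert growth_rate(1e6, e) == pytest.approx(2.0)
        assert growth_rate(np.log(2), e) == pytest.approx(1.0)  # half-saturation

    def test_growth_cap(self):
        assert growth_cap(FilamentGenotype(), env(pibar0=1.5)) == pytest.approx(1.5)
        assert growth_cap(FilamentGenotype(v=3.0), env(beta=0.0)) == pytest.approx(1.0)
        e = env(beta=0.25, pibar0=1.0)
        assert growth_cap(FilamentGenotype(v=np.log(2) / 0.25), e) == pytest.approx(2.0)


class TestSignalAndResponse:
    def test_no_signal_without_signalling(self):
        state = FilamentState.from_pattern("HRRH")
        e = env(sigma_eps=0.0)
        assert signal_level(state, FilamentGenotype(s=0.0), e, 1, noise=0.0) == 0.0

    def test_single_adjacent_helper(self):
        state = FilamentState.from_pattern("HRR")
        e = env(lam=3.0, xi=0.25, sigma_eps=0.0)
        g = FilamentGenotype(q=0.0, s=0.5, d=1.0, v=1.0)
        assert signal_level(state, g, e, 1, noise=0.0) == pytest.approx(3.0 * 0.5 * 0.25)

    def test_negative_draw_clamps_to_zero(self):
        state = FilamentState.from_pattern("HRR")
        g = FilamentGenotype(q=0.0, s=0.01, d=1.0, v=1.0)
        assert signal_level(state, g, env(sigma_eps=1.0), 2, noise=-50.0) == 0.0

    @pytest.mark.parametrize(
        "genotype, chi, expected",
        [
            (FilamentGenotype(q=0.3, s=0.5, d=2.0, v=0.0), 7.0, 0.3),  # insensitive
            (FilamentGenotype(q=0.3, s=0.5, d=2.0, v=4.0), 2.0, 0.3),  # at threshold
            (FilamentGenotype(q=0.3, s=0.5, d=1.0, v=1e6), 0.0, 1.0),  # below -> helper
            (FilamentGenotype(q=0.3, s=0.5, d=1.0, v=1e6), 2.0, 0.0),  # above -> reproductive
        ],
    )
    def test_response_norm_limits(self, genotype, chi, expected):
        assert helper_probability(genotype, chi) == pytest.approx(expected)

    @given(
        q=st.floats(0, 1),
        d=st.floats(0, 10),
        v=st.floats(0, 100),
        chi=st.floats(0, 20),
    )
    @settings(derandomize=True, deadline=None, max_examples=200)
    def test_response_norm_bounded_and_directional(self, q, d, v, chi):
        g = FilamentGenotype(q=q, s=0.5, d=d, v=v)
        p = helper_probability(g, chi)
        assert 0.0 <= p <= 1.0
        if v > 0 and chi > d:
            assert p <= q
        if v > 0 and chi < d:
            assert p >= q


class TestEventLoop:
    def test_single_reproductive_waiting_time(self):
        # saturating good density makes the rate exactly psi
        state = FilamentState.from_pattern("HRH")
        e = env(phi=1e3, psi=2.0, pibar0=1.5)
        i, tau = next_replication(state, e, FilamentGenotype())
        assert i == 1
        assert tau == pytest.approx(1.5 / 2.0)

    def test_smaller_remaining_growth_divides_first(self):
        state = FilamentState.from_pattern("HRRH", sizes=[0.2, 0.6])
        i, tau = next_replication(state, env(phi=1e3), FilamentGenotype())
        assert i == 2

    def test_tie_breaks_to_lower_index(self):
        state = FilamentState.from_pattern("RRRR")
        i, _ = next_replication(state, env(phi=1.0), FilamentGenotype())
        assert i == 0

    def test_dead_signals(self):
        with pytest.raises(NoReproductives):
            next_replication(FilamentState.from_pattern("HH"), env(), FilamentGenotype())
        with pytest.raises(StalledGrowth):
            next_replication(FilamentState.from_pattern("RRR"), env(phi=0.0), FilamentGenotype())

    def test_division_reindexes_and_resets(self):
        state = FilamentState.from_pattern("HRRH", sizes=[0.9, 0.1])
        e = env(phi=1e3, sigma_eps=0.0)
        g = FilamentGenotype(q=0.0)  # daughter always reproductive
        new = apply_division(state, e, g, draws=(0.1, 0.0, 0.9))  # left insertion
        assert new.n_cells == 5
        assert new.pattern == "HRRRH"
        assert new.t > state.t
        # parent (old index 1, now index 2) reset to 0; daughter at index 1
        assert new.sizes[2] == 0.0
        assert new.sizes[1] == 0.0
        # the non-dividing reproductive advanced to the cap and is unchanged otherwise
        assert new.sizes[3] > 0.1
        # original cells keep their phenotypes
        assert state.pattern == "HRRH"

    @pytest.mark.parametrize("q, symbol", [(0.0, "R"), (1.0, "H")])
    def test_deterministic_daughter_phenotype(self, q, symbol):
        state = FilamentState.from_pattern("HRRH")
        new = apply_division(state, env(phi=1.0), FilamentGenotype(q=q), draws=(0.7, 0.0, 0.5))
        assert new.pattern.count(symbol) == state.pattern.count(symbol) + 1


class TestGrowth:
    def test_no_new_helpers_when_q_zero(self):
        out = grow_filament(FilamentGenotype(q=0.0), env(phi=0.5, L=40), rng=0)
        assert out.status == "completed"
        assert out.final_state.pattern.count("H") == 2
        # the initial helpers stay terminal: insertions are interior
        assert out.final_state.pattern[0] == "H" and out.final_state.pattern[-1] == "H"

    def test_starved_filament_dies(self):
        out = grow_filament(FilamentGenotype(q=0.0), env(phi=0.0, L=20), rng=0, init="RRRR")
        assert out.status == "dead"
        assert out.fitness == 0.0
        assert np.isinf(out.tau_L)

    def test_determinism_under_seed(self, small_env, random_genotype):
        a = grow_filament(random_genotype, small_env, rng=7)
        b = grow_filament(random_genotype, small_env, rng=7)
        assert a.final_state.pattern == b.final_state.pattern
        assert a.fitness == b.fitness and a.tau_L == b.tau_L

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize(
        "genotype",
        [
            FilamentGenotype(q=0.33),
            FilamentGenotype(q=0.4, s=0.1, d=1.5, v=1.5),
        ],
    )
    def test_engines_agree(self, seed, genotype):
        """The numba engine reproduces the step-by-step reference engine
        draw for draw: identical phenotype strings, matching times and
        fitness."""
        e = env(phi=0.1, eta=0.3, L=25)
        fast = grow_filament(genotype, e, rng=seed, engine="fast")
        ref = grow_filament(genotype, e, rng=seed, engine="reference")
        assert fast.final_state.pattern == ref.final_state.pattern
        assert fast.tau_L == pytest.approx(ref.tau_L, rel=1e-9)
        assert fast.fitness == pytest.approx(ref.fitness, rel=1e-9)
        np.testing.assert_allclose(fast.final_state.sizes, ref.final_state.sizes, rtol=1e-9)

    def test_fitness_matches_final_state_recomputation(self, small_env, random_genotype):
        """Engine fitness equals an independent evaluation of the rate sum
        on the final configuration."""
        out = grow_filament(random_genotype, small_env, rng=3)
        assert out.fitness == pytest.approx(
            filament_fitness(out, small_env, random_genotype), rel=1e-12
        )

    def test_daughters_are_bernoulli_under_random_specialisation(self):
        """With s=0, v=0 each daughter is an independent Bernoulli(q) draw."""
        q = 0.3
        res = simulate_replicates(FilamentGenotype(q=q), env(phi=0.5, L=54), 250, rng=11)
        # 250 replicates x 50 divisions; initial 2 helpers per filament excluded
        helpers_born = int(np.sum(res["helper_counts"]) - 2 * 250)
        n_divisions = 250 * 50
        p = sp_stats.binomtest(helpers_born, n_divisions, q).pvalue
        assert p > 0.01

    def test_replicate_sets_reproducible(self, small_env, random_genotype):
        a = simulate_replicates(random_genotype, small_env, 20, rng=5)
        b = simulate_replicates(random_genotype, small_env, 20, rng=5)
        assert a["patterns"] == b["patterns"]
        np.testing.assert_array_equal(a["fitness"], b["fitness"])

    def test_init_must_fit(self):
        with pytest.raises(ValueError):
            grow_filament(FilamentGenotype(), env(L=5), rng=0, init="HRRHR")


class TestTypes:
    def test_pattern_roundtrip(self):
        state = FilamentState.from_pattern("HRRH")
        assert state.pattern == "HRRH"
        assert list(state.helpers()) == [0, 3]
        assert list(state.reproductives()) == [1, 2]

    def test_invalid_genotype(self):
        with pytest.raises(ValueError):
            FilamentGenotype(q=1.5)
        with pytest.raises(ValueError):
            FilamentGenotype(s=0.0, d=1.0)  # threshold without a signal drifts

    def test_invalid_env(self):
        with pytest.raises(ValueError):
            FilamentEnv(eta=0.0)
        with pytest.raises(ValueError):
            FilamentEnv(eta=1.5)
        with pytest.raises(ValueError):
            FilamentEnv(L=3)
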