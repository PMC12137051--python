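"""Life-cycle primitives: dispersal, reproduction, transmission, mutation,
shuffling, and whole-generation stepping."""

import math

import numpy as np
import pytest

from conftest import random_state
from virunet.core import (
    AlleleCounter,
    InitSpec,
    MetapopState,
    ModelParams,
    ParasiteGenotype,
    PatchState,
    RngStreams,
    disperse,
    initialize,
    mutate_neutral,
    mutate_virulence,
    reproduce,
    run,
    shuffle_parasites,
    step,
    transmission_rate,
    transmit,
)
from virunet.landscapes import LandscapeGraph, generate_rgg


def bh_expectation(S, I, v, params):
    """Beverton-Holt expected newborn count (independent oracle)."""
    N = S + I
    f = params.lambda0 / (1 + params.alpha * N)
    return f * S + (1 - v) * f * I


def nb_expectation(newborns, I, v, params):
    """Nicholson-Bailey type-II expected infected count (independent
    oracle, monomorphic parasite population)."""
    beta = params.beta_max * v ** params.s
    return newborns * (1 - math.exp(-params.a * beta * I / (1 + params.a * newborns)))


class TestTransmissionRate:
    @pytest.mark.parametrize(
        "v, s, beta_max, expected",
        [(1.0, 0.5, 8.0, 8.0), (0.0, 0.5, 8.0, 0.0), (0.25, 0.5, 8.0, 4.0)],
    )
    def test_trade_off_values(self, v, s, beta_max, expected):
        params = ModelParams(beta_max=beta_max, s=s)
        assert transmission_rate(v, params) == pytest.approx(expected)

    @pytest.mark.parametrize("s", [0.3, 0.5, 1.0, 2.0])
    def test_monotone_in_v_and_saturates_at_beta_max(self, s):
        params = ModelParams(s=s, beta_max=8.0)
        v = np.linspace(0, 1, 101)
        beta = transmission_rate(v, params)
        assert (np.diff(beta) >= 0).all()
        assert beta[-1] == 8.0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            transmission_rate(1.2, ModelParams())
        with pytest.raises(ValueError):
            transmission_rate(-0.1, ModelParams())


class TestDisperse:
    def test_d_zero_is_identity(self, rgg100):
        rng = np.random.default_rng(0)
        state = random_state(rng, rgg100.n_patches)
        out = disperse(state, rgg100, 0.0, rng)
        assert (out.S == state.S).all()
        assert (out.inf_patch == state.inf_patch).all()

    def test_d_one_forces_move_to_only_neighbor(self, two_patch):
        rng = np.random.default_rng(1)
        state = MetapopState(
            S=np.array([10, 0]),
            inf_patch=np.empty(0, dtype=np.int64),
            inf_v=np.empty(0),
            inf_allele=np.empty(0, dtype=np.int64),
        )
        out = disperse(state, two_patch, 1.0, rng)
        assert list(out.S) == [0, 10]

    @pytest.mark.parametrize("d", [0.1, 0.5, 0.9])
    def test_conserves_totals(self, rgg100, d):
        rng = np.random.default_rng(2)
        state = random_state(rng, rgg100.n_patches)
        out = disperse(state, rgg100, d, rng)
        assert out.S.sum() == state.S.sum()
        assert len(out.inf_patch) == len(state.inf_patch)
        # genotypes ride along untouched
        assert (out.inf_v == state.inf_v).all()
        assert (out.inf_allele == state.inf_allele).all()

    def test_isolated_patch_raises(self):
        g = LandscapeGraph(1, ())
        state = MetapopState(
            S=np.array([5]),
            inf_patch=np.empty(0, dtype=np.int64),
            inf_v=np.empty(0),
            inf_allele=np.empty(0, dtype=np.int64),
        )
        with pytest.raises(ValueError, match="no neighbors"):
            disperse(state, g, 0.5, np.random.default_rng(0))


class TestReproduce:
    def test_monte_carlo_mean_matches_beverton_holt(self):
        """Sample mean over many draws agrees with the density-regulated
        expectation at the focal parameters (S=100, I=0)."""
        params = ModelParams(lambda0=4, alpha=0.01)
        rng = np.random.default_rng(3)
        patch = PatchState(susceptibles=100)
        expected = bh_expectation(100, 0, 0.0, params)  # = 200
        assert expected == pytest.approx(200.0)
        draws = np.array([reproduce(patch, params, rng) for _ in range(2000)])
        se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 3 * se

    def test_fully_virulent_infected_sterile(self):
        params = ModelParams()
        patch = PatchState(0, [ParasiteGenotype(1.0, k) for k in range(50)])
        rng = np.random.default_rng(4)
        assert all(reproduce(patch, params, rng) == 0 for _ in range(20))

    def test_empty_patch(self):
        assert reproduce(PatchState(0), ModelParams(), np.random.default_rng(0)) == 0

    def test_mixed_virulence_expectation(self):
        """Each infected parent's own v sets its fecundity."""
        params = ModelParams(lambda0=4, alpha=0.01)
        patch = PatchState(
            50, [ParasiteGenotype(0.2, 0)] * 25 + [ParasiteGenotype(0.8, 1)] * 25
        )
        # additive over parents at the shared patch density N = 100
        f = params.lambda0 / (1 + params.alpha * 100)
        expected = f * 50 + (1 - 0.2) * f * 25 + (1 - 0.8) * f * 25
        assert expected == pytest.approx(150.0)
        rng = np.random.default_rng(5)
        draws = np.array([reproduce(patch, params, rng) for _ in range(3000)])
        se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 3 * se


class TestTransmit:
    def test_no_parental_infected_no_infection(self):
        out = transmit(PatchState(0), 100, ModelParams(), np.random.default_rng(0))
        assert out == []

    def test_monte_carlo_mean_matches_nicholson_bailey(self):
        """Monomorphic v=1: infected-newborn mean matches the type-II
        escape expectation 100 * (1 - exp(-0.8/2)) ~ 32.97."""
        params = ModelParams(beta_max=8, s=0.5, a=0.01)
        parents = PatchState(0, [ParasiteGenotype(1.0, k) for k in range(10)])
        expected = nb_expectation(100, 10, 1.0, params)
        assert expected == pytest.approx(32.9679953964361, abs=1e-10)
        rng = np.random.default_rng(6)
        counts = np.array(
            [len(transmit(parents, 100, params, rng)) for _ in range(2000)]
        )
        se = counts.std(ddof=1) / math.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se

    def test_equal_strains_split_evenly(self):
        """Two strains with equal force win the within-host lottery
        equally often."""
        params = ModelParams()
        parents = PatchState(
            0, [ParasiteGenotype(0.9, 0)] * 20 + [ParasiteGenotype(0.9, 1)] * 20
        )
        rng = np.random.default_rng(7)
        alleles = [
            g.neutral_allele
            for _ in range(300)
            for g in transmit(parents, 100, params, rng)
        ]
        share = np.mean(np.array(alleles) == 0)
        n = len(alleles)
        assert abs(share - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_genotypes_are_parental_copies(self):
        params = ModelParams()
        parents = PatchState(0, [ParasiteGenotype(0.4, 17)] * 30)
        out = transmit(parents, 200, params, np.random.default_rng(8))
        assert out and all(g == ParasiteGenotype(0.4, 17) for g in out)


class TestMutation:
    def test_logit_shift_example(self):
        """A +ln(3) logit perturbation moves v = 0.5 to exactly 0.75."""
        from scipy.special import expit, logit

        assert expit(logit(0.5) + math.log(3)) == pytest.approx(0.75)

    def test_no_mutation_when_rate_zero(self):
        params = ModelParams(m_v=0.0)
        g = ParasiteGenotype(0.37, 5)
        rng = np.random.default_rng(9)
        assert all(mutate_virulence(g, params, rng) == g for _ in range(50))

    def test_output_strictly_inside_unit_interval(self):
        params = ModelParams(m_v=1.0, sigma_v=5.0)
        rng = np.random.default_rng(10)
        for v0 in (1e-7, 0.5, 1.0):
            for _ in range(50):
                v = mutate_virulence(ParasiteGenotype(v0, 0), params, rng).v
                assert 0.0 < v < 1.0

    def test_small_sigma_degenerates_to_identity(self):
        params = ModelParams(m_v=1.0, sigma_v=1e-12)
        rng = np.random.default_rng(11)
        v = mutate_virulence(ParasiteGenotype(0.6, 0), params, rng).v
        assert v == pytest.approx(0.6, abs=1e-9)

    def test_neutral_always_fresh_and_unique(self):
        params = ModelParams(m_v=1.0)
        counter = AlleleCounter(start=100)
        rng = np.random.default_rng(12)
        g = ParasiteGenotype(0.5, 3)
        a1 = mutate_neutral(g, params, rng, counter).neutral_allele
        a2 = mutate_neutral(g, params, rng, counter).neutral_allele
        assert a1 != a2 and a1 >= 100 and a2 >= 100

    def test_neutral_rate_zero_unchanged(self):
        params = ModelParams(m_v=0.5, m_n=0.0)
        counter = AlleleCounter()
        rng = np.random.default_rng(13)
        g = ParasiteGenotype(0.5, 3)
        assert all(
            mutate_neutral(g, params, rng, counter).neutral_allele == 3
            for _ in range(50)
        )


class TestShuffle:
    def test_per_patch_counts_and_global_multiset_invariant(self):
        rng = np.random.default_rng(14)
        for _ in range(100):
            state = random_state(rng)
            out = shuffle_parasites(state, rng)
            assert (out.S == state.S).all()
            assert (out.inf_patch == state.inf_patch).all()
            assert sorted(zip(out.inf_v, out.inf_allele)) == sorted(
                zip(state.inf_v, state.inf_allele)
            )

    def test_single_parasite_unchanged(self):
        state = MetapopState(
            S=np.array([3, 4]),
            inf_patch=np.array([1]),
            inf_v=np.array([0.5]),
            inf_allele=np.array([7]),
        )
        out = shuffle_parasites(state, np.random.default_rng(0))
        assert out.inf_v[0] == 0.5 and out.inf_allele[0] == 7


class TestStepAndRun:
    def test_extinct_parasite_stays_extinct(self, rgg100):
        params = ModelParams(T=5)
        state = initialize(rgg100, params, InitSpec(infected_fraction=0.0))
        streams = RngStreams.from_seed(1)
        for _ in range(5):
            state = step(state, rgg100, params, streams)
            assert state.n_infected == 0
            assert state.S.sum() > 0  # host-only Beverton-Holt persists

    def test_zero_growth_empties_landscape(self, rgg100):
        params = ModelParams(lambda0=0.0)
        state = initialize(rgg100, params, InitSpec())
        # carrying capacity 0 under lambda0=0: landscape starts empty
        state.S[:] = 10
        out = step(state, rgg100, params, RngStreams.from_seed(2))
        assert out.S.sum() == 0 and out.n_infected == 0

    def test_fixed_seed_reproduces_trajectory(self, rgg100):
        params = ModelParams(T=20)
        r1 = run(rgg100, params, seed=33)
        r2 = run(rgg100, params, seed=33)
        assert (r1.S == r2.S).all()
        assert (r1.I == r2.I).all()
        assert (r1.final_state.inf_v == r2.final_state.inf_v).all()

    def test_t_zero_returns_initial_state(self, rgg100):
        params = ModelParams(T=0)
        res = run(rgg100, params, seed=0)
        k = round((params.lambda0 - 1) / params.alpha)
        assert res.S.shape == (1, 100)
        assert res.final_state.t == 0
        assert (res.S[0] + res.I[0] == k).all()

    def test_fixed_virulence_never_drifts(self, rgg100):
        params = ModelParams(T=30, virulence_mode="fixed", fixed_v=0.94)
        res = run(rgg100, params, seed=5)
        st = res.final_state
        assert st.n_infected > 0
        assert (st.inf_v == 0.94).all()

    def test_fixed_mode_neutral_locus_still_mutates(self, rgg100):
        params = ModelParams(T=30, virulence_mode="fixed", fixed_v=0.94)
        res = run(rgg100, params, seed=5)
        # fresh alleles created beyond the initial assignment
        assert res.final_state.next_allele > 100 * 30

    def test_step_conserves_infected_identity_totals(self, rgg100):
        """One step's transmission only produces genotypes copied (possibly
        mutated) from parents: no infection appears if none existed."""
        params = ModelParams(T=1)
        state = initialize(rgg100, params, InitSpec(infected_fraction=0.0))
        out = step(state, rgg100, params, RngStreams.from_seed(6))
        assert out.n_infected == 0

    def test_initialize_densities(self, rgg100):
        params = ModelParams(lambda0=4, alpha=0.01)
        st = initialize(rgg100, params, InitSpec(infected_fraction=0.1))
        assert (st.S == 270).all()
        assert (st.I == 30).all()
        # maximal initial neutral diversity: all alleles distinct
        assert len(np.unique(st.inf_allele)) == st.n_infected

    def test_shuffled_run_same_epidemiology_as_marginal(self, rgg100):
        """Shuffling permutes genotypes only: per-step S and I totals stay
        valid and the run completes with parasites present."""
        params = ModelParams(T=50, shuffle=True)
        res = run(rgg100, params, seed=8)
        assert (res.S >= 0).all() and (res.I >= 0).all()


class TestTwoPatchOracle:
    """One full generation on a 2-patch landscape, tiny populations,
    compared against an independent brute-force simulation of the same
    rules (dispersal, density-regulated birth, escape infection)."""

    def brute_force(self, S0, I0, v, params, rng, n_rep):
        means = np.zeros(4)  # E[S_a], E[S_b], E[I_a], E[I_b]
        for _ in range(n_rep):
            # dispersal: each individual flips a coin, moves to other patch
            S = [0, 0]
            I = [0, 0]
            for p in range(2):
                for _ in range(S0[p]):
                    q = 1 - p if rng.random() < params.d else p
                    S[q] += 1
                for _ in range(I0[p]):
                    q = 1 - p if rng.random() < params.d else p
                    I[q] += 1
            newborn = [0, 0]
            for p in range(2):
                N = S[p] + I[p]
                f = params.lambda0 / (1 + params.alpha * N)
                for _ in range(S[p]):
                    newborn[p] += rng.poisson(f)
                for _ in range(I[p]):
                    newborn[p] += rng.poisson((1 - v) * f)
            Snew = [0, 0]
            Inew = [0, 0]
            for p in range(2):
                beta = params.beta_max * v ** params.s
                force = params.a * beta * I[p] / (1 + params.a * newborn[p])
                for _ in range(newborn[p]):
                    if rng.random() < 1 - math.exp(-force):
                        Inew[p] += 1
                    else:
                        Snew[p] += 1
            means += np.array([Snew[0], Snew[1], Inew[0], Inew[1]])
        return means / n_rep

    def test_step_matches_brute_force_means(self, two_patch):
        params = ModelParams(
            lambda0=3, alpha=0.05, beta_max=4, s=0.5, a=0.05, d=0.3, m_v=0.0, m_n=0.0
        )
        S0, I0, v = [8, 3], [2, 5], 0.6
        rng = np.random.default_rng(100)
        n_rep = 10_000
        oracle = self.brute_force(S0, I0, v, params, rng, n_rep)

        sim = np.zeros(4)
        for k in range(n_rep):
            state = MetapopState(
                S=np.array(S0, dtype=np.int64),
                inf_patch=np.repeat([0, 1], I0),
                inf_v=np.full(sum(I0), v),
                inf_allele=np.arange(sum(I0)),
                next_allele=sum(I0),
            )
            out = step(state, two_patch, params, np.random.default_rng(200 + k))
            I = out.I
            sim += np.array([out.S[0], out.S[1], I[0], I[1]])
        sim /= n_rep
        # agreement within 5 x Monte-Carlo standard error per component
        # (counts are small; se estimated from the oracle replicates scale)
        assert np.allclose(sim, oracle, atol=5 * np.sqrt(np.maximum(oracle, 1) / n_rep) + 0.05)
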