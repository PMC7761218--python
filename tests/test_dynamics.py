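"""Unit tests for the per-generation update rule, checked against
closed forms and the independent nested-loop reference in oracle.py."""

import math

import numpy as np
import pytest

import evometa as em
from evometa.state import MetacommunityState, PatchState, PopulationLineage

from conftest import random_patch
from oracle import assert_matches_oracle


class TestKernels:
    def test_capacity_maximum_at_optimum(self, params):
        assert em.carrying_capacity(0.3, 0.3, params) == params.K_max

    def test_capacity_closed_form(self):
        p = em.ModelParams(sigma_K=1.0, K_max=10_000)
        expected = 10_000 * math.exp(-0.5)  # 6065.306...
        assert em.carrying_capacity(1.0, 0.0, p) == pytest.approx(expected, rel=1e-12)

    def test_capacity_even_function(self, params):
        for a in (0.1, 0.7, 2.5):
            assert em.carrying_capacity(1.0 + a, 1.0, params) == pytest.approx(
                em.carrying_capacity(1.0 - a, 1.0, params), rel=1e-14
            )

    def test_capacity_rejects_nonfinite(self, params):
        with pytest.raises(ValueError):
            em.carrying_capacity(float("nan"), 0.0, params)

    def test_alpha_self_is_one(self, params):
        assert em.competition_coefficient(0.42, 0.42, params) == 1.0

    def test_alpha_closed_form(self):
        p = em.ModelParams(sigma_alpha=0.68)
        expected = 1.0 / (1.0 + 1.0 / (2 * 0.68**2))  # ~0.4805
        assert em.competition_coefficient(0.0, 1.0, p) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(0.4805, abs=5e-5)

    def test_alpha_vanishes_at_distance(self, params):
        assert em.competition_coefficient(0.0, 1e6, params) < 1e-9


class TestCompetitionLoad:
    def test_single_resident_at_focal_trait(self, params):
        res = [PopulationLineage(1, 0, x=0.5, N=100.0)]
        assert em.competition_load(0.5, res, params) == pytest.approx(100.0)

    def test_term_by_term_sum(self):
        p = em.ModelParams(sigma_alpha=0.68)
        res = [
            PopulationLineage(1, 0, x=0.0, N=100.0),
            PopulationLineage(1, 1, x=1.0, N=50.0),
        ]
        expected = 100.0 + 50.0 / (1.0 + 1.0 / (2 * 0.68**2))
        assert em.competition_load(0.0, res, p) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(124.03, abs=0.01)

    def test_empty_residents_give_zero(self, params):
        assert em.competition_load(1.0, [], params) == 0.0

    def test_monotone_decay_away_from_residents(self, params):
        res = [
            PopulationLineage(1, 0, x=0.0, N=100.0),
            PopulationLineage(1, 1, x=0.5, N=60.0),
        ]
        xs = np.linspace(0.5, 5.0, 50)
        loads = [em.competition_load(x, res, params) for x in xs]
        assert all(a >= b for a, b in zip(loads, loads[1:]))


class TestGrowthRate:
    def test_zero_at_capacity(self, params):
        res = [PopulationLineage(1, 0, x=0.0, N=params.K_max)]
        G = em.growth_rate(0.0, params.K_max, res, 0.0, params)
        assert G == pytest.approx(0.0, abs=1e-12)

    def test_half_capacity(self):
        p = em.ModelParams(r=1.9)
        res = [PopulationLineage(1, 0, x=0.0, N=p.K_max / 2)]
        assert em.growth_rate(0.0, p.K_max / 2, res, 0.0, p) == pytest.approx(0.95)

    def test_negative_when_overloaded(self, params):
        res = [PopulationLineage(1, 0, x=0.0, N=2 * params.K_max)]
        assert em.growth_rate(0.0, 2 * params.K_max, res, 0.0, params) < 0


class TestMutation:
    def test_no_mutation_when_mu_zero(self, rng):
        p = em.ModelParams(mu=0.0)
        lin = PopulationLineage(1, 0, x=0.0, N=10_000.0)
        for _ in range(50):
            mutants, removed = em.draw_mutants(lin, p, rng)
            assert mutants == [] and removed == 0

    def test_mean_mutant_count(self, rng):
        p = em.ModelParams(mu=1e-5, r=1.9)
        lin = PopulationLineage(1, 0, x=0.0, N=10_000.0)
        n = 100_000
        counts = [em.draw_mutants(lin, p, rng, next_lineage_id=1)[1] for _ in range(n)]
        mean = np.mean(counts)
        expected = p.mu * p.r * lin.N  # 0.19
        se = math.sqrt(expected / n)  # Poisson
        assert abs(mean - expected) < 3 * se

    def test_mutants_are_size_one_with_parent_species(self, rng):
        p = em.ModelParams(mu=0.5, sigma_mu=0.05)
        lin = PopulationLineage(7, 3, x=1.2, N=100.0, patch=2, born=0)
        mutants, removed = em.draw_mutants(lin, p, rng, t=5, next_lineage_id=50)
        assert removed == len(mutants) > 0
        for m in mutants:
            assert m.N == 1.0
            assert m.species_id == 7
            assert m.born == 5
            assert m.patch == 2
        assert len({m.lineage_id for m in mutants}) == len(mutants)

    def test_deterministic_mode_uses_expectation(self, rng):
        p = em.ModelParams(mu=0.01, r=1.9)
        lin = PopulationLineage(1, 0, x=0.0, N=1000.0)
        _, removed = em.draw_mutants(lin, p, rng, deterministic=True)
        assert removed == round(0.01 * 1.9 * 1000)


class TestStepPatch:
    def test_fixed_point_unchanged(self, rng):
        p = em.ModelParams(mu=0.0)
        patch = PatchState(0.0, [0.0], [p.K_max], [1], [0], [0])
        out = em.step_patch(patch, p, rng)
        assert out.N[0] == pytest.approx(p.K_max, rel=1e-12)
        assert len(out) == 1

    def test_logistic_convergence(self, rng):
        p = em.ModelParams(mu=0.0, r=1.9)
        patch = PatchState(0.0, [0.0], [500.0], [1], [0], [0])
        for _ in range(1000):
            patch = em.step_patch(patch, p, rng)
        assert abs(patch.N[0] - p.K_max) / p.K_max < 1e-6

    def test_negative_overshoot_clamped(self, rng):
        # hugely maladapted and overloaded lineage drives N below zero
        p = em.ModelParams(mu=0.0, r=1.9)
        patch = PatchState(
            0.0, [4.0, 0.0], [5000.0, 10_000.0], [1, 2], [0, 1], [0, 0]
        )
        out = em.step_patch(patch, p, rng)
        assert np.all(out.N >= 0.0)


class TestExtinction:
    def test_below_one_always_removed(self, params, rng):
        patch = PatchState(0.0, [0.0, 0.1], [0.5, 100.0], [1, 2], [0, 1], [0, 0])
        out = em.apply_extinction(patch, params, rng)
        assert list(out.lineage_id) == [1]

    def test_rho_zero_keeps_small_lineages(self, rng):
        p = em.ModelParams(rho=0.0, theta=2.0)
        patch = PatchState(0.0, [0.0], [1.5], [1], [0], [0])
        for _ in range(200):
            patch2 = em.apply_extinction(patch, p, rng)
            assert len(patch2) == 1

    def test_stochastic_removal_rate(self, rng):
        p = em.ModelParams(rho=0.025, theta=2.0)
        n = 10_000
        patch = PatchState(
            0.0,
            np.zeros(n),
            np.full(n, 1.5),
            np.ones(n, dtype=int),
            np.arange(n),
            np.zeros(n, dtype=int),
        )
        out = em.apply_extinction(patch, p, rng)
        removed_frac = 1.0 - len(out) / n
        se = math.sqrt(0.025 * 0.975 / n)
        assert abs(removed_frac - 0.025) < 3 * se


class TestDispersal:
    def test_d_zero_is_identity(self, two_species, rng):
        state, p = two_species
        out = em.disperse(state, p.replace(d=0.0), rng)
        for a, b in zip(out.patches, state.patches):
            np.testing.assert_array_equal(a.x, b.x)
            np.testing.assert_array_equal(a.N, b.N)

    def test_total_abundance_conserved(self, two_species, rng):
        state, p = two_species
        before = state.total_abundance
        out = em.disperse(state, p.replace(d=0.1), rng)
        assert out.total_abundance == before  # exact: integer moves only

    def test_d_positive_single_patch_errors(self, rng):
        state = MetacommunityState(
            [PatchState(0.0, [0.0], [100.0], [1], [0], [0])]
        )
        with pytest.raises(ValueError):
            em.disperse(state, em.ModelParams(k=2, d=0.1), rng)
        with pytest.raises(ValueError):
            em.ModelParams(k=1, d=0.1)

    def test_emigrant_mean_and_split(self):
        p = em.ModelParams(d=0.1, k=3)
        reps = 2000
        rng = np.random.default_rng(7)
        to_other = np.zeros(2)
        total = 0
        for _ in range(reps):
            state = MetacommunityState(
                [
                    PatchState(0.0, [0.0], [1000.0], [1], [0], [0], 0),
                    PatchState(0.0, [], [], [], [], [], 1),
                    PatchState(0.0, [], [], [], [], [], 2),
                ]
            )
            out = em.disperse(state, p, rng)
            total += 1000.0 - out.patches[0].N.sum()
            to_other[0] += out.patches[1].total_abundance
            to_other[1] += out.patches[2].total_abundance
        mean_em = total / reps
        se = math.sqrt(1000 * 0.1 * 0.9 / reps)
        assert abs(mean_em - 100.0) < 4 * se
        # equal split between the two destinations
        assert abs(to_other[0] - to_other[1]) / to_other.sum() < 0.02

    def test_immigrants_merge_with_identical_lineage(self, rng):
        p = em.ModelParams(d=0.5, k=2)
        state = MetacommunityState(
            [
                PatchState(0.0, [0.3], [1000.0], [1], [0], [0], 0),
                PatchState(0.5, [0.3], [50.0], [1], [1], [0], 1),
            ]
        )
        out = em.disperse(state, p, rng)
        # same species, same exact trait: no third lineage may appear
        assert len(out.patches[1]) == 1
        assert out.patches[1].N[0] > 50.0


class TestEnvironment:
    def test_zero_rate_is_identity(self, two_species):
        state, p = two_species
        out = em.advance_environment(state, p.replace(delta_env=0.0))
        assert [q.x_opt for q in out.patches] == [q.x_opt for q in state.patches]

    @pytest.mark.parametrize("rate,gens,shift", [(1e-5, 50_000, 0.5), (4e-4, 50_000, 20.0)])
    def test_cumulative_shift(self, two_species, rate, gens, shift):
        state, p = two_species
        # one increment per generation; apply the closed form, not a loop
        p = p.replace(delta_env=rate)
        out = state
        for _ in range(100):
            out = em.advance_environment(out, p)
        assert out.patches[0].x_opt - state.patches[0].x_opt == pytest.approx(
            100 * rate, rel=1e-9
        )
        assert gens * rate == pytest.approx(shift)


class TestStepGeneration:
    def test_fixed_point_idempotent(self, monomorphic, rng):
        state, p = monomorphic
        p = p.replace(mu=0.0, d=0.0, delta_env=0.0)
        out = em.step_generation(state, p, rng)
        for a, b in zip(out.patches, state.patches):
            np.testing.assert_allclose(a.N, b.N, rtol=1e-12)
            np.testing.assert_array_equal(a.x, b.x)

    def test_seeded_bit_reproducibility(self, two_species):
        state, p = two_species
        p = p.replace(mu=1e-3, d=0.05, delta_env=1e-4)
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            s = state.copy()
            for _ in range(50):
                s = em.step_generation(s, p, rng)
            runs.append(em.lineage_table(s))
        assert runs[0].equals(runs[1])

    @pytest.mark.parametrize("trial", range(100))
    def test_oracle_equivalence_random_states(self, trial):
        """One generation on random <=10-lineage states matches the
        nested-loop reference to 1e-12 relative tolerance."""
        rng = np.random.default_rng(1000 + trial)
        p = em.ModelParams(
            mu=float(rng.uniform(0, 0.01)),
            d=float(rng.choice([0.0, 0.05, 0.2])),
            delta_env=float(rng.choice([0.0, 1e-4])),
            rho=0.025,
        )
        patches = []
        lid = 0
        for i in range(2):
            n = int(rng.integers(1, 6))
            patches.append(random_patch(rng, n, x_opt=0.5 * i, index=i, lid_start=lid))
            lid += n
        state = MetacommunityState(patches, t=3)

        assert_matches_oracle(state, p, 555 + trial, em, pytest)
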