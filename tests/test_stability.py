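"""Reduced haplotype models, equilibria, stability and reversal feasibility."""

import numpy as np
import pytest

from udsim import FitnessParams, Simulator, genotype_from_label
from udsim.alleles import N_GENOTYPES
from udsim.stability import (
    NotAFixedPointError,
    ReducedModel,
    classify_stability,
    epsilon_star,
    find_equilibria,
    perturbation_ratios,
    reversal_feasible,
    _ud_introgression_pool,
)

WILD_EQ = {2: np.array([1.0, 0, 0, 0]), 3: np.r_[1.0, np.zeros(8)]}


def _introgression_report(model, refine=False):
    x = _ud_introgression_pool(model)
    return classify_stability(model, x, refine_marginal=refine)


class TestReducedStep:
    def test_monomorphic_states_are_fixed(self):
        m2 = ReducedModel.two_allele(0.95, 0.95)
        for x in (np.array([1.0, 0, 0, 0]), np.array([0.0, 0, 0, 1.0])):
            assert np.allclose(m2.step(x), x, atol=1e-15)

    def test_matches_full_genotype_model_at_m0(self, default_params):
        # two-allele reduced model vs full 2025-genotype model, 50:50 start
        sim = Simulator(default_params, m=0.0)
        G = np.zeros(N_GENOTYPES)
        G[0] = 0.5
        G[genotype_from_label("AABB").index] = 0.5
        m2 = ReducedModel.two_allele(0.95, 0.95)
        x = np.array([0.5, 0.0, 0.0, 0.5])
        for _ in range(80):
            G, _ = sim.step_frequencies(G)
            x = m2.step(x)
            fa, fb = sim.allele_frequency_vectors(G)
            ra, rb = m2.allele_frequencies(x)
            assert abs(fa[0] - ra[0]) < 1e-10
            assert abs(fa[1] - ra[1]) < 1e-10
            assert abs(fb[0] - rb[0]) < 1e-10

    def test_three_allele_matches_full_model_with_suppressor_release(self):
        # free-suppressor allele == A_LC with the mutated-construct fitness
        params = FitnessParams(0.95, 0.95, 0.96, 0.96)
        sim = Simulator(params, m=0.0)
        G = np.zeros(N_GENOTYPES)
        G[0] = 0.4
        G[genotype_from_label("AABB").index] = 0.4
        G[genotype_from_label("A_Rev A_Rev B_Rev B_Rev").index] = 0.2
        m3 = ReducedModel.three_allele(0.95, 0.95, 0.96)
        x = np.zeros(9)
        x[0] = 0.4  # (a, b)
        x[1 * 3 + 1] = 0.4  # (A, B)
        x[2 * 3 + 2] = 0.2  # (A_Rev, B_Rev)
        for _ in range(80):
            G, _ = sim.step_frequencies(G)
            x = m3.step(x)
            fa, _ = sim.allele_frequency_vectors(G)
            ra, _ = m3.allele_frequencies(x)
            assert abs(fa[0] - ra[0]) < 1e-10  # wild
            assert abs(fa[1] - ra[1]) < 1e-10  # intact construct
            assert abs(fa[6] - ra[2]) < 1e-10  # A_LC == free suppressor


class TestEquilibria:
    def test_two_allele_equilibria_found(self):
        reps = [r for r in find_equilibria(ReducedModel.two_allele(0.95, 0.95))
                if r.converged]
        points = [r.point for r in reps]
        assert any(np.allclose(p, WILD_EQ[2], atol=1e-8) for p in points)
        # a stable high-transgene equilibrium exists
        assert any(p[3] > 0.85 and r.classification == "stable"
                   for p, r in zip(points, reps))
        assert all(r.residual < 1e-10 for r in reps)

    def test_interior_threshold_point_at_eps_one(self):
        # brute-force scan of symmetric wild/construct mixtures finds an
        # interior fixed point separating the two basins
        m2 = ReducedModel.two_allele(1.0, 1.0)
        best_resid, best_x = np.inf, None
        for w in np.linspace(0.01, 0.98, 98):
            for u in np.linspace(0.005, 0.49, 98):
                v = 1.0 - w - 2 * u
                if v < 0:
                    continue
                x = np.array([w, u, u, v])
                r = np.abs(m2.step(x) - x).max()
                if r < best_resid:
                    best_resid, best_x = r, x
        assert best_resid < 0.01
        reps = [r for r in find_equilibria(m2) if r.converged]
        interior = [
            r for r in reps if 0.05 < r.point[0] < 0.95 and r.point[1] > 0.01
        ]
        assert interior, "interior threshold fixed point not located"
        saddle = interior[0]
        assert np.abs(saddle.point - best_x).max() < 0.02
        assert saddle.classification == "unstable"

    def test_wild_start_converges_to_wild_with_tiny_residual(self):
        m2 = ReducedModel.two_allele(0.95, 0.95)
        reps = find_equilibria(m2, starts=[WILD_EQ[2]])
        assert any(
            r.converged and np.allclose(r.point, WILD_EQ[2], atol=1e-8)
            and r.residual < 1e-10
            for r in reps
        )


class TestClassification:
    @pytest.mark.parametrize("eps", [0.5, 0.9, 0.95, 1.0])
    def test_wildtype_equilibrium_stable(self, eps):
        m2 = ReducedModel.two_allele(eps, eps)
        rep = classify_stability(m2, WILD_EQ[2])
        assert rep.classification == "stable"

    @pytest.mark.parametrize("eps", [0.95, 1.0])
    def test_introgression_equilibrium_stable(self, eps):
        m2 = ReducedModel.two_allele(eps, eps)
        rep = _introgression_report(m2, refine=True)
        assert rep.classification == "stable"

    @pytest.mark.parametrize("eps_rev", [0.95, 0.96])
    def test_three_allele_introgression_unstable(self, eps_rev):
        m3 = ReducedModel.three_allele(0.95, 0.95, eps_rev)
        rep = _introgression_report(m3)
        assert rep.classification == "unstable"

    def test_not_a_fixed_point_rejected(self):
        m2 = ReducedModel.two_allele(0.95, 0.95)
        with pytest.raises(NotAFixedPointError):
            classify_stability(m2, np.array([0.6, 0.0, 0.0, 0.4]))

    def test_classification_agrees_with_perturbation_simulation(self):
        # stable equilibria recapture small perturbations; unstable ones shed them
        m2 = ReducedModel.two_allele(0.95, 0.95)
        wild = classify_stability(m2, WILD_EQ[2])
        ratios = perturbation_ratios(m2, WILD_EQ[2], n=50, horizon=2000)
        assert wild.classification == "stable" and np.all(ratios < 1e-3)

        intro = _introgression_report(m2)
        ratios = perturbation_ratios(m2, intro.point, n=50, horizon=2000)
        assert intro.classification == "stable" and np.all(ratios < 1e-2)

        m3 = ReducedModel.three_allele(0.95, 0.95, 0.96)
        rep = _introgression_report(m3)
        ratios = perturbation_ratios(m3, rep.point, n=50, horizon=5000)
        assert rep.classification == "unstable" and np.all(ratios > 10)


class TestReversalFeasibility:
    def test_fitter_free_suppressor_succeeds_at_tiny_release(self):
        out = reversal_feasible(0.95, 0.96, 0.01)
        assert out.success

    def test_equal_fitness_succeeds_at_small_release(self):
        assert reversal_feasible(0.95, 0.95, 0.1).success

    def test_less_fit_suppressor_needs_large_release(self):
        assert not reversal_feasible(0.95, 0.94, 0.01).success
        assert reversal_feasible(0.95, 0.94, 8.0).success

    def test_recovery_time_insensitive_to_release_ratio(self):
        # successful releases differ enormously in size but little in the
        # time needed to return a fully wild-type population
        times = [
            reversal_feasible(0.95, 0.96, alpha).recovery_time
            for alpha in (0.01, 0.1, 1.0)
        ]
        assert all(t is not None for t in times)
        times = np.array(times, dtype=float)
        cv = times.std() / times.mean()
        assert cv < 0.5

    def test_epsilon_star_brackets_the_introgression_regime(self):
        es = epsilon_star(1.0)
        m2_lo = ReducedModel.two_allele(es - 0.01, es - 0.01)
        m2_hi = ReducedModel.two_allele(es + 0.01, es + 0.01)
        x_lo = _ud_introgression_pool(m2_lo)
        x_hi = _ud_introgression_pool(m2_hi)
        assert m2_lo.wild_frequency(x_lo) > 0.999  # below eps*: drive lost
        assert m2_hi.wild_frequency(x_hi) < 0.5  # above eps*: introgression
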