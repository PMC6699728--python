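"""The genotype-frequency recursion, releases and trajectory bookkeeping."""

import numpy as np
import pytest

from udsim import (
    DegeneratePopulationError,
    InvalidRatioError,
    PopulationState,
    ReleaseEvent,
    ScenarioConfig,
    Simulator,
    genotype_from_label,
    run,
    viability_mask,
)
from udsim.alleles import N_GENOTYPES
from udsim.simulate import allele_frequencies, initialize

from _oracles import canonical_genotype, step_oracle


def _state_to_dict(G):
    from udsim import enumerate_genotypes

    return {
        canonical_genotype(*(a.label for a in g.alleles)): float(G[g.index])
        for g in enumerate_genotypes()
        if G[g.index] > 0
    }


def _dict_to_vector(d):
    from udsim import enumerate_genotypes

    lookup = {
        canonical_genotype(*(a.label for a in g.alleles)): g.index
        for g in enumerate_genotypes()
    }
    G = np.zeros(N_GENOTYPES)
    for key, f in d.items():
        G[lookup[key]] = f
    return G


class TestInitialize:
    def test_one_to_one_release(self):
        s = initialize(1.0, genotype_from_label("AABB"))
        G = s.genotype_frequencies
        assert G[0] == 0.5
        assert G[genotype_from_label("AABB").index] == 0.5
        assert G.sum() == 1.0

    def test_no_release_is_pure_wild(self):
        G = initialize(0.0, genotype_from_label("AABB")).genotype_frequencies
        assert G[0] == 1.0 and np.count_nonzero(G) == 1

    def test_two_to_one_release(self):
        G = initialize(2.0, genotype_from_label("AABB")).genotype_frequencies
        assert G[genotype_from_label("AABB").index] == pytest.approx(2 / 3)

    def test_negative_ratio_rejected(self):
        with pytest.raises(InvalidRatioError):
            initialize(-0.5, genotype_from_label("AABB"))


class TestStep:
    def test_pure_wildtype_is_fixed_point(self, default_params):
        sim = Simulator(default_params, m=1e-4)
        G = np.zeros(N_GENOTYPES)
        G[0] = 1.0
        G2, omega_bar = sim.step_frequencies(G)
        assert np.array_equal(G2, G)
        assert omega_bar == 1.0

    def test_pure_AABB_fixed_point_without_mutation(self, default_params):
        sim = Simulator(default_params, m=0.0)
        G = np.zeros(N_GENOTYPES)
        idx = genotype_from_label("AABB").index
        G[idx] = 1.0
        G2, _ = sim.step_frequencies(G)
        assert G2[idx] == pytest.approx(1.0, abs=1e-15)

    def test_fifty_fifty_cross_matches_mating_pair_oracle(self, default_params):
        sim = Simulator(default_params, m=0.0)
        G = np.zeros(N_GENOTYPES)
        G[0] = 0.5
        G[genotype_from_label("AABB").index] = 0.5
        G2, _ = sim.step_frequencies(G)
        expected = _dict_to_vector(
            step_oracle(_state_to_dict(G), 0.0, 0.95, 0.96, 0.95, 0.96)
        )
        assert np.abs(G2 - expected).max() < 1e-12
        # closed form: the gamete pool is half ab, half AB, so random union
        # gives AABB 1/4, AaBb 1/2, aabb 1/4 before selection
        w_het = 0.95**2
        omega_bar = 0.25 * 0.95**4 + 0.5 * w_het + 0.25
        het = genotype_from_label("AaBb").index
        assert G2[het] == pytest.approx(0.5 * w_het / omega_bar, abs=1e-14)

    def test_step_matches_oracle_on_random_sparse_states(self, default_params, rng):
        viable_idx = np.nonzero(viability_mask())[0]
        from udsim import enumerate_genotypes

        genotypes = enumerate_genotypes()
        sim = Simulator(default_params, m=1e-3)
        for _ in range(25):
            support = rng.choice(viable_idx, size=5, replace=False)
            freqs = rng.dirichlet(np.ones(support.size))
            G = np.zeros(N_GENOTYPES)
            G[support] = freqs
            G2, _ = sim.step_frequencies(G)
            expected = _dict_to_vector(
                step_oracle(_state_to_dict(G), 1e-3, 0.95, 0.96, 0.95, 0.96)
            )
            assert np.abs(G2 - expected).max() < 1e-10

    def test_conservation_and_selection_each_generation(self, default_params, rng):
        sim = Simulator(default_params, m=1e-4)
        G = np.zeros(N_GENOTYPES)
        viable_idx = np.nonzero(viability_mask())[0]
        support = rng.choice(viable_idx, size=40, replace=False)
        G[support] = rng.dirichlet(np.ones(40))
        for _ in range(200):
            G, _ = sim.step_frequencies(G)
            assert abs(G.sum() - 1.0) < 1e-12
            assert np.all(G[~viability_mask()] == 0.0)
            assert np.all(G >= 0.0)

    def test_degenerate_population_raises(self, default_params):
        # all offspring of a (disallowed) non-viable-support state die
        sim = Simulator(default_params, m=0.0)
        G = np.zeros(N_GENOTYPES)
        G[genotype_from_label("AAbb").index] = 1.0
        with pytest.raises(DegeneratePopulationError):
            sim.step_frequencies(G)


class TestRelease:
    def test_release_scales_and_adds(self, default_params):
        sim = Simulator(default_params)
        state = initialize(1.0, genotype_from_label("AABB"))
        rev = genotype_from_label("A_Rev A_Rev B_Rev B_Rev")
        out = sim.apply_release(state, ReleaseEvent(0, rev, 2.0))
        G = out.genotype_frequencies
        assert G[rev.index] == pytest.approx(2 / 3)
        assert G.sum() == pytest.approx(1.0, abs=1e-15)

    def test_zero_release_is_identity(self, default_params):
        sim = Simulator(default_params)
        state = initialize(1.0, genotype_from_label("AABB"))
        out = sim.apply_release(state, ReleaseEvent(0, genotype_from_label("aabb"), 0.0))
        assert np.array_equal(out.genotype_frequencies, state.genotype_frequencies)

    def test_small_release_frequency(self, default_params):
        sim = Simulator(default_params)
        state = PopulationState(np.eye(N_GENOTYPES)[0])
        rev = genotype_from_label("A_LC A_LC B_LC B_LC")
        out = sim.apply_release(state, ReleaseEvent(0, rev, 0.01))
        assert out.genotype_frequencies[rev.index] == pytest.approx(0.01 / 1.01)

    def test_negative_ratio_and_nonviable_genotype_rejected(self):
        with pytest.raises(InvalidRatioError):
            ReleaseEvent(0, genotype_from_label("AABB"), -1.0)
        with pytest.raises(ValueError):
            ReleaseEvent(0, genotype_from_label("AAbb"), 1.0)


class TestAlleleFrequencies:
    @pytest.mark.parametrize("label,expected_A,expected_B", [
        ("AaBb", {"A": 0.5, "a": 0.5}, {"B": 0.5, "b": 0.5}),
        ("aabb", {"a": 1.0}, {"b": 1.0}),
    ])
    def test_single_genotype_counting(self, label, expected_A, expected_B):
        g = genotype_from_label(label)
        G = np.zeros(N_GENOTYPES)
        G[g.index] = 1.0
        fa, fb = allele_frequencies(PopulationState(G))
        from udsim import Locus, enumerate_alleles

        for lab, v in expected_A.items():
            k = [a.index for a in enumerate_alleles(Locus.A) if a.label == lab][0]
            assert fa[k] == pytest.approx(v)
        assert fa.sum() == pytest.approx(1.0) and fb.sum() == pytest.approx(1.0)

    def test_mixture_counting(self):
        G = np.zeros(N_GENOTYPES)
        G[0] = 0.5
        G[genotype_from_label("AABB").index] = 0.5
        fa, fb = allele_frequencies(PopulationState(G))
        assert fa[1] == pytest.approx(0.5) and fb[1] == pytest.approx(0.5)


class TestRun:
    def test_bit_identical_reproducibility(self):
        cfg = ScenarioConfig(m=1e-5, generations=300)
        tr1, tr2 = run(cfg), run(cfg)
        assert np.array_equal(tr1.allele_freq_A, tr2.allele_freq_A)
        assert np.array_equal(tr1.allele_freq_B, tr2.allele_freq_B)

    def test_allele_rows_normalised_and_releases_recorded(self):
        cfg = ScenarioConfig(
            m=0.0,
            generations=150,
            releases=[
                ReleaseEvent(0, genotype_from_label("AABB"), 1.0),
                ReleaseEvent(100, genotype_from_label("aabb"), 2.0),
            ],
        )
        tr = run(cfg)
        assert np.allclose(tr.allele_freq_A.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(tr.allele_freq_B.sum(axis=1), 1.0, atol=1e-12)
        assert [r.generation for r in tr.releases] == [0, 100]

    def test_m0_supra_threshold_release_reaches_introgression(self, default_params):
        # above the invasion threshold the drive persists with no decay
        cfg = ScenarioConfig(m=0.0, generations=2000, convergence_tol=1e-14)
        tr = run(cfg)
        assert tr.termination == "converged"
        final_transgene = tr.allele_freq_A[-1, 1]
        assert final_transgene > 0.9

    def test_m0_sub_threshold_release_is_eliminated(self):
        cfg = ScenarioConfig(
            m=0.0,
            generations=5000,
            releases=[ReleaseEvent(0, genotype_from_label("AABB"), 0.2)],
            stop_at_wild_freq=1 - 1e-6,
        )
        tr = run(cfg)
        assert tr.termination == "wild_threshold_reached"

    def test_mutant_alleles_stay_below_intact_when_mutants_less_fit(self):
        # a mutated construct less fit than the intact one never accumulates
        cfg = ScenarioConfig(eps_AM=0.90, eps_BM=0.90, m=1e-5, generations=2000)
        tr = run(cfg)
        intact = tr.allele_freq_A[:, 1]
        mutated = tr.allele_freq_A[:, 2:].sum(axis=1)
        assert np.all(mutated <= intact + 1e-9)
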