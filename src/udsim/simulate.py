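"""The discrete-generation deterministic recursion and release scheduling.

One generation proceeds as: (i) the post-selection adults contribute gametes
according to Mendelian segregation, pooled over the whole (panmictic, effectively
infinite) population; (ii) mutation acts on the gamete pool; (iii) offspring
genotype frequencies follow random union of two independent draws from the
mutated pool; (iv) each offspring class is weighted by its relative fitness
Omega_j (zero for non-viable genotypes) and the vector is normalised by the
population mean fitness Omega_bar so genotype frequencies again sum to one.

Working with the 81-dimensional gamete pool instead of the 2025 x 2025 mating
table is an O(81^2) per-generation computation; the test suite proves it
numerically identical to the explicit mating-pair-table formulation.

Releases scale the resident genotype frequencies by 1/(1 + alpha) and place
alpha/(1 + alpha) on the released genotype (released individuals carry no
mutations).  "Release at generation t" means the release is applied to the
state after t steps, before step t + 1; the post-release state at generation 0
therefore matches the textbook initial condition G_wild = 1/(1 + alpha),
G_released = alpha/(1 + alpha).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
import numpy as np
import pandas as pd

from .alleles import (
    FitnessParams,
    Genotype,
    Locus,
    N_ALLELES,
    N_GENOTYPES,
    N_PAIRS,
    PAIRS,
    WILD_INDEX,
    enumerate_alleles,
    enumerate_genotypes,
    fitness_vector,
    genotype_from_label,
    viability_mask,
)
from .mutation import MutationModel, N_HAPLOTYPES, build_mutation_matrix

__all__ = [
    "DegeneratePopulationError",
    "InvalidRatioError",
    "PopulationState",
    "ReleaseEvent",
    "ScenarioConfig",
    "Trajectory",
    "Simulator",
    "initialize",
    "step",
    "apply_release",
    "allele_frequencies",
    "run",
    "allele_labels",
]


class DegeneratePopulationError(RuntimeError):
    """Raised when the population mean fitness is zero (all offspring die)."""


class InvalidRatioError(ValueError):
    """Raised for a negative release ratio."""


@lru_cache(maxsize=None)
def allele_labels() -> tuple[str, ...]:
    """The 18 allele labels: the nine locus-A alleles, then the nine locus-B."""
    return tuple(
        a.label for locus in (Locus.A, Locus.B) for a in enumerate_alleles(locus)
    )


@dataclass(frozen=True)
class _Tables:
    """Precomputed index machinery for the gamete-pool recursion."""

    geno_to_gamete: np.ndarray  # (2025, 81) transmission probabilities
    pair_to_geno: np.ndarray  # (6561,) ordered haplotype pair -> genotype index
    count_A: np.ndarray  # (2025, 9) allele dosage / 2 at locus A
    count_B: np.ndarray  # (2025, 9)


@lru_cache(maxsize=None)
def _tables() -> _Tables:
    # Per-pair transmission: allele i of unordered pair k is transmitted w.p. 1/2.
    t_pair = np.zeros((N_PAIRS, N_ALLELES))
    for k, (i, j) in enumerate(PAIRS):
        t_pair[k, i] += 0.5
        t_pair[k, j] += 0.5
    geno_to_gamete = np.einsum("pa,qb->pqab", t_pair, t_pair).reshape(
        N_GENOTYPES, N_HAPLOTYPES
    )

    pair_idx = np.full((N_ALLELES, N_ALLELES), -1, dtype=np.int64)
    for k, (i, j) in enumerate(PAIRS):
        pair_idx[i, j] = pair_idx[j, i] = k
    a_of = np.arange(N_HAPLOTYPES) // N_ALLELES
    b_of = np.arange(N_HAPLOTYPES) % N_ALLELES
    h1 = np.repeat(np.arange(N_HAPLOTYPES), N_HAPLOTYPES)
    h2 = np.tile(np.arange(N_HAPLOTYPES), N_HAPLOTYPES)
    pair_to_geno = (
        pair_idx[a_of[h1], a_of[h2]] * N_PAIRS + pair_idx[b_of[h1], b_of[h2]]
    )

    count_A = t_pair[np.arange(N_GENOTYPES) // N_PAIRS]
    count_B = t_pair[np.arange(N_GENOTYPES) % N_PAIRS]
    for arr in (geno_to_gamete, pair_to_geno, count_A, count_B):
        arr.flags.writeable = False
    return _Tables(geno_to_gamete, pair_to_geno, count_A, count_B)


@dataclass(frozen=True)
class PopulationState:
    """Genotype-frequency vector (2025 entries summing to one) at a generation."""

    genotype_frequencies: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        G = np.asarray(self.genotype_frequencies, dtype=float)
        if G.shape != (N_GENOTYPES,):
            raise ValueError(f"expected {N_GENOTYPES} genotype frequencies, got {G.shape}")
        object.__setattr__(self, "genotype_frequencies", G)


@dataclass(frozen=True)
class ReleaseEvent:
    """Release of mutation-free individuals of one genotype at ratio alpha.

    ``alpha`` is the number of introduced individuals relative to the entire
    resident population at the moment of release.
    """

    generation: int
    genotype: Genotype
    alpha: float

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise InvalidRatioError(f"release ratio must be >= 0, got {self.alpha}")
        if isinstance(self.genotype, str):
            object.__setattr__(self, "genotype", genotype_from_label(self.genotype))
        if not viability_mask()[self.genotype.index]:
            raise ValueError(f"released genotype {self.genotype.label!r} is non-viable")


@dataclass
class ScenarioConfig:
    """Everything needed to run one deterministic scenario.

    Defaults mirror the canonical introduction experiment: a 1:1 release of
    intact double homozygotes (AABB) into a wild-type population with intact
    constructs costing 5% per copy and mutated constructs 4%.
    """

    eps_A: float = 0.95
    eps_B: float = 0.95
    eps_AM: float = 0.96
    eps_BM: float = 0.96
    m: float = 1e-6
    releases: list[ReleaseEvent] = field(
        default_factory=lambda: [ReleaseEvent(0, genotype_from_label("AABB"), 1.0)]
    )
    generations: int = 10_000
    record_genotypes: bool = False
    record_mean_fitness: bool = False
    thin: int = 1
    stop_at_wild_freq: float | None = None
    convergence_tol: float | None = None
    wild_threshold: float = 0.95
    cargo_threshold: float = 0.85

    @property
    def fitness_params(self) -> FitnessParams:
        return FitnessParams(self.eps_A, self.eps_B, self.eps_AM, self.eps_BM)

    def validate(self) -> None:
        errors: list[str] = []
        for name in ("eps_A", "eps_B", "eps_AM", "eps_BM"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                errors.append(f"{name}: must lie in [0, 1], got {v}")
        if self.m < 0 or 3 * self.m > 1:
            errors.append(f"m: must satisfy 0 <= m <= 1/3, got {self.m}")
        if self.generations < 1:
            errors.append(f"generations: must be >= 1, got {self.generations}")
        if self.thin < 1:
            errors.append(f"thin: must be >= 1, got {self.thin}")
        gens = [r.generation for r in self.releases]
        if any(g2 <= g1 for g1, g2 in zip(gens, gens[1:])):
            errors.append("releases: generations must be strictly increasing")
        if any(g < 0 for g in gens):
            errors.append("releases: generations must be >= 0")
        for name in ("stop_at_wild_freq", "wild_threshold", "cargo_threshold"):
            v = getattr(self, name)
            if v is not None and not (0.0 < v < 1.0):
                errors.append(f"{name}: must lie in (0, 1), got {v}")
        if errors:
            raise ValueError("; ".join(errors))


@dataclass
class Trajectory:
    """Per-generation record of a scenario run.

    ``allele_freq_A``/``allele_freq_B`` hold the nine per-locus allele
    frequencies (each row sums to one) for every recorded generation.
    """

    generations: np.ndarray
    allele_freq_A: np.ndarray
    allele_freq_B: np.ndarray
    genotype_freqs: np.ndarray | None = None
    mean_fitness: np.ndarray | None = None
    releases: list[ReleaseEvent] = field(default_factory=list)
    config: ScenarioConfig | None = None
    termination: str = "horizon"

    def __len__(self) -> int:
        return len(self.generations)

    @property
    def wild_freq_min(self) -> np.ndarray:
        """Per-generation minimum over loci of the wild-type allele frequency."""
        return np.minimum(
            self.allele_freq_A[:, WILD_INDEX], self.allele_freq_B[:, WILD_INDEX]
        )

    def to_dataframe(self, include_genotypes: bool = False) -> pd.DataFrame:
        labels = allele_labels()
        data = {"generation": self.generations}
        for k, lab in enumerate(labels[:N_ALLELES]):
            data[lab] = self.allele_freq_A[:, k]
        for k, lab in enumerate(labels[N_ALLELES:]):
            data[lab] = self.allele_freq_B[:, k]
        if self.mean_fitness is not None:
            data["mean_fitness"] = self.mean_fitness
        df = pd.DataFrame(data)
        if include_genotypes and self.genotype_freqs is not None:
            geno_labels = [g.label.replace(" ", "|") for g in enumerate_genotypes()]
            df = pd.concat(
                [df, pd.DataFrame(self.genotype_freqs, columns=geno_labels)], axis=1
            )
        return df


class Simulator:
    """Deterministic recursion engine for fixed fitness parameters and rate m."""

    def __init__(self, params: FitnessParams | None = None, m: float = 0.0):
        self.params = params if params is not None else FitnessParams()
        self.mutation: MutationModel = build_mutation_matrix(m)
        self.omega = fitness_vector(self.params)
        self._t = _tables()

    # -- core vector operations -------------------------------------------------

    def step_frequencies(self, G: np.ndarray) -> tuple[np.ndarray, float]:
        """Advance genotype frequencies one generation; return (G', Omega_bar)."""
        t = self._t
        pool = G @ t.geno_to_gamete
        M = self.mutation.matrix
        pool = (M.T @ pool.reshape(N_ALLELES, N_ALLELES) @ M).ravel()
        offspring = np.bincount(
            t.pair_to_geno, weights=np.outer(pool, pool).ravel(), minlength=N_GENOTYPES
        )
        weighted = offspring * self.omega
        omega_bar = float(weighted.sum())
        if omega_bar <= 0.0:
            raise DegeneratePopulationError(
                "population mean fitness is zero: every offspring genotype is non-viable"
            )
        G2 = weighted / omega_bar
        # round-off guard only; the recursion cannot produce real negatives
        G2[(G2 < 0.0) & (G2 > -1e-15)] = 0.0
        return G2, omega_bar

    def allele_frequency_vectors(self, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-locus allele-frequency 9-vectors (dosage / 2) of a genotype state."""
        return G @ self._t.count_A, G @ self._t.count_B

    # -- state-level API ---------------------------------------------------------

    def initialize(self, alpha: float, released_genotype: Genotype) -> PopulationState:
        """Initial state of a release at ratio alpha into a pure wild population."""
        if alpha < 0:
            raise InvalidRatioError(f"release ratio must be >= 0, got {alpha}")
        G = np.zeros(N_GENOTYPES)
        G[0] = 1.0 / (1.0 + alpha)  # index 0 is the all-wild genotype
        G[released_genotype.index] += alpha / (1.0 + alpha)
        return PopulationState(G, generation=0)

    def step(self, state: PopulationState) -> PopulationState:
        G2, _ = self.step_frequencies(state.genotype_frequencies)
        return PopulationState(G2, state.generation + 1)

    def apply_release(self, state: PopulationState, release: ReleaseEvent) -> PopulationState:
        G = state.genotype_frequencies / (1.0 + release.alpha)
        G = G.copy()
        G[release.genotype.index] += release.alpha / (1.0 + release.alpha)
        return PopulationState(G, state.generation)


# -- functional wrappers mirroring the operation-level interface ------------------


def initialize(alpha: float, released_genotype: Genotype) -> PopulationState:
    return Simulator().initialize(alpha, released_genotype)


def step(
    state: PopulationState, params: FitnessParams, mm: MutationModel
) -> PopulationState:
    sim = Simulator(params, mm.m)
    return sim.step(state)


def apply_release(state: PopulationState, release: ReleaseEvent) -> PopulationState:
    return Simulator().apply_release(state, release)


def allele_frequencies(state: PopulationState) -> tuple[np.ndarray, np.ndarray]:
    """freq(allele) = sum_i G_i * (copies of allele in genotype i) / 2, per locus."""
    return Simulator().allele_frequency_vectors(state.genotype_frequencies)


def run(cfg: ScenarioConfig) -> Trajectory:
    """Run a scenario: scheduled releases plus the deterministic recursion.

    Deterministic: identical configurations give bit-identical trajectories.
    Recording honours ``cfg.thin`` but always includes generation 0, release
    generations and the final generation.
    """
    cfg.validate()
    sim = Simulator(cfg.fitness_params, cfg.m)
    pending = {r.generation: r for r in cfg.releases}

    G = np.zeros(N_GENOTYPES)
    G[0] = 1.0
    applied: list[ReleaseEvent] = []
    if 0 in pending:
        r = pending.pop(0)
        G = sim.apply_release(PopulationState(G, 0), r).genotype_frequencies
        applied.append(r)

    gens: list[int] = []
    freq_A: list[np.ndarray] = []
    freq_B: list[np.ndarray] = []
    geno_rows: list[np.ndarray] = []
    omega_rows: list[float] = []
    termination = "horizon"

    def record(t: int, omega_bar: float, fa: np.ndarray, fb: np.ndarray) -> None:
        gens.append(t)
        freq_A.append(fa)
        freq_B.append(fb)
        if cfg.record_genotypes:
            geno_rows.append(G.copy())
        if cfg.record_mean_fitness:
            omega_rows.append(omega_bar)

    fa, fb = sim.allele_frequency_vectors(G)
    record(0, np.nan, fa, fb)

    for t in range(1, cfg.generations + 1):
        G_prev = G
        G, omega_bar = sim.step_frequencies(G)
        released_now = False
        if t in pending:
            r = pending.pop(t)
            G = sim.apply_release(PopulationState(G, t), r).genotype_frequencies
            applied.append(r)
            released_now = True
        fa, fb = sim.allele_frequency_vectors(G)
        last = t == cfg.generations
        stop = False
        if cfg.stop_at_wild_freq is not None and not pending:
            if min(fa[WILD_INDEX], fb[WILD_INDEX]) > cfg.stop_at_wild_freq:
                termination = "wild_threshold_reached"
                stop = True
        if not stop and cfg.convergence_tol is not None and not pending and not released_now:
            if np.abs(G - G_prev).sum() < cfg.convergence_tol:
                termination = "converged"
                stop = True
        if t % cfg.thin == 0 or released_now or last or stop:
            record(t, omega_bar, fa, fb)
        if stop:
            break

    return Trajectory(
        generations=np.asarray(gens, dtype=np.int64),
        allele_freq_A=np.vstack(freq_A),
        allele_freq_B=np.vstack(freq_B),
        genotype_freqs=np.vstack(geno_rows) if geno_rows else None,
        mean_fitness=np.asarray(omega_rows) if omega_rows else None,
        releases=applied,
        config=replace(cfg, releases=list(cfg.releases)),
        termination=termination,
    )
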