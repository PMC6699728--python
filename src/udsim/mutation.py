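"""Mendelian gamete production and the per-gene loss-of-function mutation step.

The two loci segregate independently, so a parent transmits each of its two
alleles at a locus with probability 1/2 and a gamete haplotype is an
(locus-A allele, locus-B allele) pair; there are 9 x 9 = 81 haplotypes.

Mutation acts during gamete production, one construct component at a time: a
construct with k still-functional components loses each of them independently
with probability m per generation, and the per-generation transition keeps only
the linear-in-m terms (multiple hits within one generation are neglected).  The
per-locus transition matrix therefore has off-diagonal entries m on the edges
of the knockout graph, diagonal entries 1 - k*m, an identity row for the
wild-type allele and an absorbing row for the fully mutated construct.  Rows
sum to one exactly, so the step conserves probability mass without any
renormalisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .alleles import Genotype, Locus, N_ALLELES, enumerate_alleles

__all__ = [
    "N_HAPLOTYPES",
    "InvalidRateError",
    "GameteDistribution",
    "MutationModel",
    "haplotype_labels",
    "gamete_distribution",
    "build_mutation_matrix",
    "apply_mutation",
]

N_HAPLOTYPES = N_ALLELES * N_ALLELES


class InvalidRateError(ValueError):
    """Raised for a per-gene mutation rate outside [0, 1/3]."""


@lru_cache(maxsize=None)
def haplotype_labels() -> tuple[str, ...]:
    """Labels of the 81 gamete haplotypes, row-major in (A allele, B allele)."""
    aA = enumerate_alleles(Locus.A)
    aB = enumerate_alleles(Locus.B)
    return tuple(f"{a.label}|{b.label}" for a in aA for b in aB)


@dataclass(frozen=True)
class GameteDistribution:
    """A probability distribution over the 81 gamete haplotypes.

    ``frequencies`` is indexed row-major: haplotype (A-allele i, B-allele j)
    sits at position ``i * 9 + j`` in the canonical allele ordering.
    """

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.shape != (N_HAPLOTYPES,):
            raise ValueError(f"expected {N_HAPLOTYPES} haplotype frequencies, got {f.shape}")
        object.__setattr__(self, "frequencies", f)

    @property
    def total(self) -> float:
        return float(self.frequencies.sum())

    def as_matrix(self) -> np.ndarray:
        """(9, 9) view: rows = locus-A allele, columns = locus-B allele."""
        return self.frequencies.reshape(N_ALLELES, N_ALLELES)


@dataclass(frozen=True)
class MutationModel:
    """Per-locus allele transition matrix for per-gene rate ``m``.

    The same 9 x 9 matrix applies at both loci because the allele orderings
    and knockout graphs are structurally identical.
    """

    m: float
    matrix: np.ndarray

    @property
    def joint_matrix(self) -> np.ndarray:
        """The 81 x 81 transition matrix on haplotypes (Kronecker product)."""
        return np.kron(self.matrix, self.matrix)


@lru_cache(maxsize=None)
def _knockout_targets() -> tuple[tuple[tuple[int, int], ...], ...]:
    """For each allele index, the (component, target-index) single-knockout edges."""
    alleles = enumerate_alleles(Locus.A)
    by_flags = {
        (a.functional_lethal, a.functional_suppressor, a.functional_cargo): a.index
        for a in alleles
        if a.is_transgenic
    }
    out: list[tuple[tuple[int, int], ...]] = []
    for a in alleles:
        if a.is_wild:
            out.append(())
            continue
        flags = [a.functional_lethal, a.functional_suppressor, a.functional_cargo]
        edges = []
        for comp in range(3):
            if flags[comp]:
                new = tuple(f if c != comp else False for c, f in enumerate(flags))
                edges.append((comp, by_flags[new]))
        out.append(tuple(edges))
    return tuple(out)


def build_mutation_matrix(m: float) -> MutationModel:
    """Build the per-locus mutation transition matrix for per-gene rate ``m``.

    Raises :class:`InvalidRateError` unless ``0 <= m <= 1/3`` (so that the
    diagonal entry 1 - 3m of the intact construct stays non-negative).
    """
    m = float(m)
    if m < 0.0 or 3.0 * m > 1.0:
        raise InvalidRateError(f"per-gene mutation rate must satisfy 0 <= m <= 1/3, got {m}")
    M = np.zeros((N_ALLELES, N_ALLELES))
    for src, edges in enumerate(_knockout_targets()):
        M[src, src] = 1.0 - len(edges) * m
        for _comp, dst in edges:
            M[src, dst] = m
    M.flags.writeable = False
    return MutationModel(m, M)


def gamete_distribution(g: Genotype) -> GameteDistribution:
    """Mendelian gamete haplotype distribution of one (viable) parent genotype.

    Free segregation: each of the two alleles at a locus is transmitted with
    probability 1/2, independently across loci.
    """
    f = np.zeros(N_HAPLOTYPES)
    for a in g.locusA_pair:
        for b in g.locusB_pair:
            f[a.index * N_ALLELES + b.index] += 0.25
    return GameteDistribution(f)


def apply_mutation(d: GameteDistribution, mm: MutationModel) -> GameteDistribution:
    """Push a gamete distribution through one generation of mutation.

    Equivalent to multiplying by the 81 x 81 Kronecker-product matrix, computed
    as two small per-locus matrix products.
    """
    P = d.as_matrix()
    out = mm.matrix.T @ P @ mm.matrix
    return GameteDistribution(out.ravel())
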