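"""Allele and genotype state space for a two-locus engineered underdominance (UD) drive.

The drive consists of two transgenic constructs inserted at unlinked genetic loci
(called A and B).  Each construct carries three components: a lethal effector, a
suppressor that neutralises the lethal carried at the *other* locus, and a cargo
gene conferring the desirable phenotype.  Loss-of-function mutation can knock out
any subset of the three components, so each locus has nine allele states: the
wild-type allele, the intact construct, and the seven mutated construct classes
(every non-empty subset of {lethal, suppressor, cargo} knocked out).  Allele
labels follow the field's convention: lower case for wild-type (``a``, ``b``),
upper case for the intact construct (``A``, ``B``), and subscripts naming the
knocked-out components (``A_L``, ``A_SC``, ``A_LSC``, ...).

With nine alleles per locus there are 45 unordered allele pairs per locus and
45 x 45 = 2025 two-locus genotypes.  A genotype is non-viable when it carries at
least one functional lethal at one locus and no functional suppressor at the
other locus (in either direction); suppression is all-or-nothing, so a single
functional suppressor copy rescues any number of lethal copies.  Relative fitness
is multiplicative per construct copy,

    Omega_i = eps_A**beta * eps_AM**phi * eps_B**mu * eps_BM**psi * (1 - gamma_i),

where beta/mu count intact construct copies at each locus, phi/psi count mutated
construct copies (all mutated classes share one fitness value per locus), and
gamma_i is the binary lethality indicator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, fields
from enum import Enum
from functools import lru_cache
from itertools import combinations_with_replacement

import numpy as np

__all__ = [
    "Locus",
    "Allele",
    "Genotype",
    "FitnessParams",
    "N_ALLELES",
    "N_PAIRS",
    "N_GENOTYPES",
    "PAIRS",
    "pair_index",
    "enumerate_alleles",
    "enumerate_genotypes",
    "genotype_from_alleles",
    "genotype_from_label",
    "is_viable",
    "copy_counts",
    "fitness",
    "viability_mask",
    "copy_count_arrays",
    "fitness_vector",
    "WILD_INDEX",
    "INTACT_INDEX",
    "MUTATED_INDICES",
    "TRANSGENIC_INDICES",
    "CARGO_FUNCTIONAL_INDICES",
]


class Locus(str, Enum):
    """The two unlinked genetic loci carrying the UD constructs."""

    A = "A"
    B = "B"


N_ALLELES = 9
N_PAIRS = 45
N_GENOTYPES = 2025

#: Canonical per-locus allele ordering: wild-type first, then the intact
#: construct, then knockouts by number of mutated components in L < S < C order.
_KNOCKOUTS = ("", "L", "S", "C", "LS", "LC", "SC", "LSC")

#: Position of the wild-type allele in the canonical ordering.
WILD_INDEX = 0
#: Position of the intact (non-mutated) construct.
INTACT_INDEX = 1
#: Mutated construct classes (>= 1 component knocked out).
MUTATED_INDICES = tuple(range(2, 9))
#: All transgenic alleles (intact or mutated).
TRANSGENIC_INDICES = tuple(range(1, 9))
#: Transgenic alleles with a functional cargo gene (no C in the knockout set).
CARGO_FUNCTIONAL_INDICES = (1, 2, 3, 5)


@dataclass(frozen=True)
class Allele:
    """One of the nine per-locus allele states.

    A knocked-out component is recorded by its subscript letter in ``label``;
    the corresponding ``functional_*`` flag is then False.  The wild-type
    allele carries no construct at all, so every functional flag is False.
    """

    locus: Locus
    is_wild: bool
    functional_lethal: bool
    functional_suppressor: bool
    functional_cargo: bool
    label: str
    index: int

    @property
    def is_transgenic(self) -> bool:
        return not self.is_wild

    @property
    def is_mutated(self) -> bool:
        """True for a construct with at least one loss-of-function mutation."""
        return self.is_transgenic and not (
            self.functional_lethal and self.functional_suppressor and self.functional_cargo
        )

    @property
    def n_functional(self) -> int:
        """Number of still-functional construct components (0 for wild-type)."""
        return (
            int(self.functional_lethal)
            + int(self.functional_suppressor)
            + int(self.functional_cargo)
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@lru_cache(maxsize=None)
def enumerate_alleles(locus: Locus | str) -> tuple[Allele, ...]:
    """Return the nine alleles at ``locus`` in canonical order.

    Order: wild-type, intact construct, single knockouts (L, S, C), double
    knockouts (LS, LC, SC), triple knockout (LSC).
    """
    locus = Locus(locus)
    base = locus.value
    out = [Allele(locus, True, False, False, False, base.lower(), 0)]
    for idx, ko in enumerate(_KNOCKOUTS, start=1):
        label = base if not ko else f"{base}_{ko}"
        out.append(
            Allele(
                locus,
                False,
                "L" not in ko,
                "S" not in ko,
                "C" not in ko,
                label,
                idx,
            )
        )
    return tuple(out)


#: The 45 unordered per-locus allele pairs (with repetition), lexicographic.
PAIRS: tuple[tuple[int, int], ...] = tuple(combinations_with_replacement(range(N_ALLELES), 2))

_PAIR_INDEX = np.full((N_ALLELES, N_ALLELES), -1, dtype=np.int64)
for _k, (_i, _j) in enumerate(PAIRS):
    _PAIR_INDEX[_i, _j] = _k
    _PAIR_INDEX[_j, _i] = _k
_PAIR_INDEX.flags.writeable = False


def pair_index(i: int, j: int) -> int:
    """Canonical index in ``PAIRS`` of the unordered allele pair {i, j}."""
    return int(_PAIR_INDEX[i, j])


@dataclass(frozen=True)
class Genotype:
    """A two-locus genotype: one unordered allele pair at each locus.

    ``index`` is the canonical position in ``enumerate_genotypes()``:
    ``index = pair_index(A-pair) * 45 + pair_index(B-pair)``.
    """

    locusA_pair: tuple[Allele, Allele]
    locusB_pair: tuple[Allele, Allele]
    index: int

    @property
    def label(self) -> str:
        return " ".join(a.label for a in self.locusA_pair + self.locusB_pair)

    @property
    def alleles(self) -> tuple[Allele, Allele, Allele, Allele]:
        return self.locusA_pair + self.locusB_pair

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@lru_cache(maxsize=None)
def enumerate_genotypes() -> tuple[Genotype, ...]:
    """All 2025 genotypes in canonical index order."""
    aA = enumerate_alleles(Locus.A)
    aB = enumerate_alleles(Locus.B)
    out = []
    for pa, (i, j) in enumerate(PAIRS):
        for pb, (k, l) in enumerate(PAIRS):
            out.append(Genotype((aA[i], aA[j]), (aB[k], aB[l]), pa * N_PAIRS + pb))
    return tuple(out)


def genotype_from_alleles(a1: Allele, a2: Allele, b1: Allele, b2: Allele) -> Genotype:
    """Canonical genotype holding the given alleles (order within a locus is free)."""
    pa = pair_index(a1.index, a2.index)
    pb = pair_index(b1.index, b2.index)
    return enumerate_genotypes()[pa * N_PAIRS + pb]


# Labels of engineered free-suppressor constructs map onto the suppressor-only
# mutated allele classes of the full model.
_LABEL_ALIASES = {
    "A_Rev": "A_LC",
    "B_Rev": "B_LC",
    "ARev": "A_LC",
    "BRev": "B_LC",
}

_TOKEN_RE = re.compile(r"[ABab](?:_(?:Rev|[LSC]{1,3}))?")


def genotype_from_label(text: str) -> Genotype:
    """Parse a genotype label such as ``"AABB"``, ``"aabb"`` or ``"A A_L B B_LC"``.

    Tokens may be separated by whitespace or ``/``, or concatenated when
    unambiguous (single-letter labels).  ``A_Rev``/``B_Rev`` are accepted as
    aliases for the suppressor-only alleles ``A_LC``/``B_LC``.
    """
    raw = [t for t in re.split(r"[\s/]+", text.strip()) if t]
    tokens: list[str] = []
    for chunk in raw:
        matched = _TOKEN_RE.findall(chunk)
        if "".join(matched) != chunk:
            raise ValueError(f"cannot parse genotype label {text!r}: bad token {chunk!r}")
        tokens.extend(matched)
    tokens = [_LABEL_ALIASES.get(t, t) for t in tokens]
    if len(tokens) != 4:
        raise ValueError(f"genotype label {text!r} must name exactly four alleles")
    by_label_A = {a.label: a for a in enumerate_alleles(Locus.A)}
    by_label_B = {a.label: a for a in enumerate_alleles(Locus.B)}
    a_alleles = [by_label_A[t] for t in tokens if t in by_label_A]
    b_alleles = [by_label_B[t] for t in tokens if t in by_label_B]
    if len(a_alleles) != 2 or len(b_alleles) != 2:
        raise ValueError(
            f"genotype label {text!r} must carry two locus-A and two locus-B alleles"
        )
    return genotype_from_alleles(a_alleles[0], a_alleles[1], b_alleles[0], b_alleles[1])


@dataclass(frozen=True)
class FitnessParams:
    """Per-construct-copy relative fitnesses.

    ``eps_A``/``eps_B`` apply per intact construct copy, ``eps_AM``/``eps_BM``
    per mutated construct copy (one shared value per locus, regardless of which
    or how many components are mutated).  ``eps_Rev`` is the per-copy fitness
    of a deliberately engineered free-suppressor construct; it is used only by
    the reduced three-allele model in :mod:`udsim.stability` (in the full
    genotype model a free suppressor is simply the ``A_LC``/``B_LC`` allele and
    carries the mutated-construct fitness).
    """

    eps_A: float = 0.95
    eps_B: float = 0.95
    eps_AM: float = 0.96
    eps_BM: float = 0.96
    eps_Rev: float = 0.96

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{f.name} must lie in [0, 1], got {v!r}")


def _pair_has(flag_getter) -> np.ndarray:
    alleles = enumerate_alleles(Locus.A)
    per_allele = np.array([bool(flag_getter(a)) for a in alleles])
    return np.array([per_allele[i] | per_allele[j] for i, j in PAIRS])


@lru_cache(maxsize=None)
def _pair_tables() -> dict[str, np.ndarray]:
    """Per-pair flag/count tables shared by both loci (identical structure)."""
    alleles = enumerate_alleles(Locus.A)
    has_lethal = _pair_has(lambda a: a.functional_lethal)
    has_supp = _pair_has(lambda a: a.functional_suppressor)
    intact = np.array([a.is_transgenic and not a.is_mutated for a in alleles], dtype=np.int64)
    mutated = np.array([a.is_mutated for a in alleles], dtype=np.int64)
    n_intact = np.array([intact[i] + intact[j] for i, j in PAIRS])
    n_mutated = np.array([mutated[i] + mutated[j] for i, j in PAIRS])
    tabs = {
        "has_lethal": has_lethal,
        "has_supp": has_supp,
        "n_intact": n_intact,
        "n_mutated": n_mutated,
    }
    for v in tabs.values():
        v.flags.writeable = False
    return tabs


@lru_cache(maxsize=None)
def viability_mask() -> np.ndarray:
    """Boolean (2025,) array: True where the genotype is viable.

    Non-viable iff a functional lethal at one locus meets zero functional
    suppressors at the other locus, in either direction.
    """
    t = _pair_tables()
    pa = np.arange(N_GENOTYPES) // N_PAIRS
    pb = np.arange(N_GENOTYPES) % N_PAIRS
    lethal_unsuppressed = (t["has_lethal"][pa] & ~t["has_supp"][pb]) | (
        t["has_lethal"][pb] & ~t["has_supp"][pa]
    )
    out = ~lethal_unsuppressed
    out.flags.writeable = False
    return out


@lru_cache(maxsize=None)
def copy_count_arrays() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectors (beta, phi, mu, psi) of construct copy counts for all genotypes."""
    t = _pair_tables()
    pa = np.arange(N_GENOTYPES) // N_PAIRS
    pb = np.arange(N_GENOTYPES) % N_PAIRS
    arrays = (
        t["n_intact"][pa],
        t["n_mutated"][pa],
        t["n_intact"][pb],
        t["n_mutated"][pb],
    )
    for a in arrays:
        a.flags.writeable = False
    return arrays


def fitness_vector(params: FitnessParams) -> np.ndarray:
    """Relative fitness Omega_i of every genotype, as a (2025,) array."""
    beta, phi, mu, psi = copy_count_arrays()
    omega = (
        params.eps_A**beta
        * params.eps_AM**phi
        * params.eps_B**mu
        * params.eps_BM**psi
    )
    return np.where(viability_mask(), omega, 0.0)


def is_viable(g: Genotype) -> bool:
    """Viability of a single genotype (gamma_i = 0)."""
    return bool(viability_mask()[g.index])


def copy_counts(g: Genotype) -> tuple[int, int, int, int]:
    """(beta, phi, mu, psi): intact/mutated construct copy counts per locus."""
    beta, phi, mu, psi = copy_count_arrays()
    i = g.index
    return int(beta[i]), int(phi[i]), int(mu[i]), int(psi[i])


def fitness(g: Genotype, params: FitnessParams) -> float:
    """Relative fitness Omega_i of a single genotype under ``params``."""
    return float(fitness_vector(params)[g.index])
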