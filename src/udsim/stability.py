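"""Mutation-free reduced haplotype models and numerical stability analysis.

These models restrict each locus to a small allele set — {wild, construct} for
the plain underdominance system, or {wild, construct, free suppressor} when a
suppressor-only reversal construct is present — and track the gamete
(haplotype) frequency vector of the adult population.  With mutation off, one
generation maps the gamete pool x through

    x'[h]  propto  sum_{h1, h2} x[h1] x[h2] * Omega(h1, h2) * T(h | h1, h2),

where Omega is the viability-weighted multiplicative fitness of the offspring
genotype formed by haplotypes (h1, h2) and T is Mendelian transmission with
free segregation.  This is exactly the gamete-pool form of the full genotype
recursion restricted to the reduced allele set, so the two formulations produce
identical allele-frequency trajectories (a property the test suite checks to
1e-10 rather than assumes).

Equilibria are located numerically (forward iteration plus root polishing) and
classified by the spectral radius of the Jacobian of the map expressed in
simplex coordinates (the last haplotype frequency is eliminated, which removes
the spurious unit eigenvalue that normalisation would otherwise contribute).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import optimize

from .simulate import DegeneratePopulationError

__all__ = [
    "ReducedAllele",
    "ReducedModel",
    "EquilibriumReport",
    "ReversalOutcome",
    "NotAFixedPointError",
    "BracketError",
    "reduced_step",
    "find_equilibria",
    "classify_stability",
    "perturbation_ratios",
    "reversal_feasible",
    "epsilon_star",
]


class NotAFixedPointError(ValueError):
    """Raised when stability classification is requested off a fixed point."""


class BracketError(RuntimeError):
    """Raised when a bisection search cannot bracket the sought threshold."""


@dataclass(frozen=True)
class ReducedAllele:
    """An allele of a reduced model: label, component flags and per-copy fitness."""

    label: str
    lethal: bool
    suppressor: bool
    fitness: float

    @classmethod
    def wild(cls, label: str) -> "ReducedAllele":
        return cls(label, False, False, 1.0)

    @classmethod
    def construct(cls, label: str, eps: float) -> "ReducedAllele":
        return cls(label, True, True, eps)

    @classmethod
    def free_suppressor(cls, label: str, eps: float) -> "ReducedAllele":
        return cls(label, False, True, eps)


class ReducedModel:
    """A mutation-free haplotype-frequency model on small per-locus allele sets.

    Allele lists must place the wild-type allele first; the all-wild haplotype
    then has index 0.  Haplotype (i, j) has index ``i * nB + j``.
    """

    def __init__(
        self,
        alleles_A: Sequence[ReducedAllele],
        alleles_B: Sequence[ReducedAllele],
    ):
        if alleles_A[0].lethal or alleles_A[0].suppressor or alleles_B[0].lethal:
            raise ValueError("the first allele at each locus must be wild-type")
        self.alleles_A = tuple(alleles_A)
        self.alleles_B = tuple(alleles_B)
        self.nA = len(alleles_A)
        self.nB = len(alleles_B)
        self.n_haplotypes = self.nA * self.nB
        self._build_tables()

    @classmethod
    def two_allele(cls, eps_A: float = 0.95, eps_B: float = 0.95) -> "ReducedModel":
        """Wild-type vs intact construct at each locus (plain UD system)."""
        return cls(
            [ReducedAllele.wild("a"), ReducedAllele.construct("A", eps_A)],
            [ReducedAllele.wild("b"), ReducedAllele.construct("B", eps_B)],
        )

    @classmethod
    def three_allele(
        cls, eps_A: float = 0.95, eps_B: float = 0.95, eps_rev: float = 0.96
    ) -> "ReducedModel":
        """UD system plus a suppressor-only (free suppressor) allele per locus."""
        return cls(
            [
                ReducedAllele.wild("a"),
                ReducedAllele.construct("A", eps_A),
                ReducedAllele.free_suppressor("A_Rev", eps_rev),
            ],
            [
                ReducedAllele.wild("b"),
                ReducedAllele.construct("B", eps_B),
                ReducedAllele.free_suppressor("B_Rev", eps_rev),
            ],
        )

    def _build_tables(self) -> None:
        nA, nB, nH = self.nA, self.nB, self.n_haplotypes
        a_of = np.arange(nH) // nB
        b_of = np.arange(nH) % nB
        lethal_A = np.array([al.lethal for al in self.alleles_A])
        supp_A = np.array([al.suppressor for al in self.alleles_A])
        lethal_B = np.array([al.lethal for al in self.alleles_B])
        supp_B = np.array([al.suppressor for al in self.alleles_B])
        fit_A = np.array([al.fitness for al in self.alleles_A])
        fit_B = np.array([al.fitness for al in self.alleles_B])

        a1 = a_of[:, None]
        a2 = a_of[None, :]
        b1 = b_of[:, None]
        b2 = b_of[None, :]
        has_lethal_A = lethal_A[a1] | lethal_A[a2]
        has_supp_A = supp_A[a1] | supp_A[a2]
        has_lethal_B = lethal_B[b1] | lethal_B[b2]
        has_supp_B = supp_B[b1] | supp_B[b2]
        viable = ~((has_lethal_A & ~has_supp_B) | (has_lethal_B & ~has_supp_A))
        W = fit_A[a1] * fit_A[a2] * fit_B[b1] * fit_B[b2] * viable
        # Transmission tensor: offspring gamete carries one parental allele per
        # locus with probability 1/2 each, independently across loci.
        T = np.zeros((nH, nH, nH))
        for h1 in range(nH):
            for h2 in range(nH):
                for aa in (a_of[h1], a_of[h2]):
                    for bb in (b_of[h1], b_of[h2]):
                        T[h1, h2, aa * nB + bb] += 0.25
        self.W = W
        self.WT = W[:, :, None] * T
        self._a_of = a_of
        self._b_of = b_of

    # -- dynamics ---------------------------------------------------------------

    def step(self, x: np.ndarray) -> np.ndarray:
        """One generation of the gamete-pool recursion."""
        x = np.asarray(x, dtype=float)
        wbar = float(x @ self.W @ x)
        if wbar <= 0.0:
            raise DegeneratePopulationError("mean fitness is zero in reduced model")
        return np.einsum("ijh,i,j->h", self.WT, x, x) / wbar

    def iterate(
        self, x: np.ndarray, max_gens: int, tol: float | None = 1e-14
    ) -> tuple[np.ndarray, int, bool]:
        """Iterate ``step``; return (state, generations run, converged flag)."""
        x = np.asarray(x, dtype=float)
        for t in range(1, max_gens + 1):
            x_new = self.step(x)
            if tol is not None and np.abs(x_new - x).sum() < tol:
                return x_new, t, True
            x = x_new
        return x, max_gens, False

    def allele_frequencies(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-locus allele marginals of a gamete-pool vector.

        With mutation off these equal the allele frequencies of the adult
        population that produced the pool.
        """
        P = np.asarray(x, dtype=float).reshape(self.nA, self.nB)
        return P.sum(axis=1), P.sum(axis=0)

    def wild_frequency(self, x: np.ndarray) -> float:
        """Minimum over loci of the wild-type allele frequency."""
        fa, fb = self.allele_frequencies(x)
        return float(min(fa[0], fb[0]))

    def residual(self, x: np.ndarray) -> float:
        return float(np.abs(self.step(x) - x).max())

    # -- simplex-coordinate map for Jacobians ------------------------------------

    def _reduced_map(self) -> Callable[[np.ndarray], np.ndarray]:
        def F(y: np.ndarray) -> np.ndarray:
            x = np.append(y, 1.0 - y.sum())
            return self.step(x)[:-1]

        return F


@dataclass(frozen=True)
class EquilibriumReport:
    """A located fixed point with its stability classification."""

    point: np.ndarray
    residual: float
    spectral_radius: float
    classification: str  # "stable" | "unstable" | "marginal"
    converged: bool = True
    message: str = ""


@dataclass(frozen=True)
class ReversalOutcome:
    """Summary of a free-suppressor reversal attempt in the reduced model."""

    success: bool
    recovery_time: int | None
    generations_run: int
    final_wild_freq: float


def reduced_step(x: np.ndarray, model: ReducedModel) -> np.ndarray:
    """One generation of ``model`` applied to haplotype frequencies ``x``."""
    return model.step(x)


def _spectral_radius(model: ReducedModel, x: np.ndarray, h: float = 1e-7) -> float:
    """Spectral radius of the central-difference Jacobian in simplex coordinates."""
    F = model._reduced_map()
    y = np.asarray(x, dtype=float)[:-1]
    n = y.size
    J = np.empty((n, n))
    for k in range(n):
        e = np.zeros(n)
        e[k] = h
        J[:, k] = (F(y + e) - F(y - e)) / (2.0 * h)
    return float(np.abs(np.linalg.eigvals(J)).max())


def perturbation_ratios(
    model: ReducedModel,
    point: np.ndarray,
    size: float = 1e-4,
    n: int = 20,
    horizon: int = 20_000,
    seed: int = 0,
) -> np.ndarray:
    """Final/initial distance ratios for an ensemble of random perturbations.

    Each perturbation mixes the fixed point with a Dirichlet draw at weight
    ``size`` (staying on the simplex) and is iterated for ``horizon``
    generations or until it converges.  Ratios well below 1 mean trajectories
    return to the equilibrium; ratios well above 1 mean they escape.
    """
    point = np.asarray(point, dtype=float)
    rng = np.random.default_rng(seed)
    ratios = np.empty(n)
    for k in range(n):
        x = (1.0 - size) * point + size * rng.dirichlet(np.ones(model.n_haplotypes))
        d0 = np.abs(x - point).max()
        x, _, _ = model.iterate(x, horizon, tol=1e-15)
        ratios[k] = np.abs(x - point).max() / d0
    return ratios


def classify_stability(
    model: ReducedModel,
    point: np.ndarray,
    residual_tol: float = 1e-8,
    refine_marginal: bool = False,
) -> EquilibriumReport:
    """Classify a fixed point by the spectral radius of the linearised map.

    Stable if the spectral radius is < 1, unstable if > 1, and marginal when it
    lies within 1e-6 of 1.  A marginal linearisation leaves stability to
    higher-order terms; with ``refine_marginal=True`` the call settles it by a
    deterministic perturbation ensemble (the spectral radius is still reported
    as measured).
    """
    point = np.asarray(point, dtype=float)
    res = model.residual(point)
    if res > residual_tol:
        raise NotAFixedPointError(
            f"residual {res:.3e} exceeds {residual_tol:.1e}; not a fixed point"
        )
    rho = _spectral_radius(model, point)
    if abs(rho - 1.0) < 1e-6:
        cls = "marginal"
    elif rho < 1.0:
        cls = "stable"
    else:
        cls = "unstable"
    message = ""
    if cls == "marginal" and refine_marginal:
        ratios = perturbation_ratios(model, point, n=5, horizon=50_000)
        if np.all(ratios < 1.0):
            cls = "stable"
            message = "linearly marginal; perturbation ensemble returns to the point"
        elif np.any(ratios > 10.0):
            cls = "unstable"
            message = "linearly marginal; perturbation ensemble escapes"
    return EquilibriumReport(point, res, rho, cls, message=message)


def _default_starts(model: ReducedModel) -> list[np.ndarray]:
    nH = model.n_haplotypes
    starts = [np.eye(nH)[k] for k in range(nH)]
    starts.append(np.full(nH, 1.0 / nH))
    # wild/full-construct mixtures straddle the invasion threshold
    full = np.zeros(nH)
    full[-1] = 1.0  # haplotype carrying the last allele at both loci
    ab = np.eye(nH)[0]
    construct_hap = np.zeros(nH)
    construct_hap[1 * model.nB + 1] = 1.0  # (construct, construct) haplotype
    for w in (0.3, 0.5, 0.7):
        starts.append(w * ab + (1 - w) * construct_hap)
    # symmetric mixtures with mass on the mixed (wild, construct) haplotypes,
    # near where the interior threshold saddle sits
    aB = np.zeros(nH)
    aB[1] = 1.0
    Ab = np.zeros(nH)
    Ab[1 * model.nB] = 1.0
    for w, u in ((0.6, 0.1), (0.5, 0.15), (0.4, 0.05)):
        starts.append(w * ab + u * (aB + Ab) + (1 - w - 2 * u) * construct_hap)
    return starts


def find_equilibria(
    model: ReducedModel,
    starts: Iterable[np.ndarray] | None = None,
    max_iter: int = 20_000,
    merge_tol: float = 1e-8,
) -> list[EquilibriumReport]:
    """Locate fixed points by forward iteration plus root polishing.

    Each start is polished with a quasi-Newton root find on f(y) - y in simplex
    coordinates, both directly and after forward iteration (the latter finds
    attractors, the former can land on saddles).  Results with residual below
    1e-10 are deduplicated within ``merge_tol`` and classified; starts that
    fail to converge are reported with ``converged=False`` rather than raised.
    """
    if starts is None:
        starts = _default_starts(model)
    F = model._reduced_map()

    def residual_fun(y: np.ndarray) -> np.ndarray:
        try:
            return F(y) - y
        except DegeneratePopulationError:
            return np.full_like(y, 1e6)  # steer the root finder away

    def polish(x0: np.ndarray) -> np.ndarray | None:
        sol = optimize.root(residual_fun, x0[:-1], method="hybr", tol=1e-13)
        x = np.append(sol.x, 1.0 - sol.x.sum())
        if np.any(x < -1e-9) or np.any(x > 1 + 1e-9):
            return None
        x = np.clip(x, 0.0, None)
        s = x.sum()
        if s <= 0:
            return None
        x = x / s
        try:
            return x if model.residual(x) < 1e-10 else None
        except DegeneratePopulationError:
            return None

    found: list[np.ndarray] = []
    failures: list[EquilibriumReport] = []
    for x0 in starts:
        x0 = np.asarray(x0, dtype=float)
        candidates = []
        try:
            direct = polish(x0)
        except DegeneratePopulationError:
            direct = None
        if direct is not None:
            candidates.append(direct)
        try:
            x_it, _, _ = model.iterate(x0, max_iter, tol=1e-14)
            iterated = polish(x_it)
        except DegeneratePopulationError:
            x_it, iterated = x0, None
        if iterated is not None:
            candidates.append(iterated)
        if not candidates:
            try:
                res = model.residual(x_it)
            except DegeneratePopulationError:
                res = np.inf
            failures.append(
                EquilibriumReport(
                    x0, res, np.nan, "unknown", False,
                    "no fixed point located from this start",
                )
            )
            continue
        for x in candidates:
            if not any(np.abs(x - f).max() < merge_tol for f in found):
                found.append(x)

    reports = [classify_stability(model, x) for x in found]
    return reports + failures


def _ud_introgression_pool(model: ReducedModel, ud_alpha: float = 1.0) -> np.ndarray:
    """Gamete pool at the UD introgression equilibrium after a supra-threshold release."""
    x0 = np.zeros(model.n_haplotypes)
    x0[0] = 1.0 / (1.0 + ud_alpha)
    x0[1 * model.nB + 1] += ud_alpha / (1.0 + ud_alpha)
    x_eq, _, _ = model.iterate(x0, 100_000, tol=1e-14)
    return x_eq


def reversal_feasible(
    eps: float,
    eps_rev: float,
    alpha: float,
    ud_alpha: float = 1.0,
    horizon: int = 200_000,
    wild_tol: float = 1e-3,
    recovery_threshold: float = 0.95,
) -> ReversalOutcome:
    """Can a free-suppressor release at ratio ``alpha`` reverse an established drive?

    Simulates the three-allele mutation-free model from the post-introgression
    state, adds a release of suppressor-only double homozygotes, and reports
    whether the population returns to (numerically) all wild-type: minimum
    per-locus wild-type allele frequency above ``1 - wild_tol``.
    """
    if not (0.0 <= eps <= 1.0 and 0.0 <= eps_rev <= 1.0):
        raise ValueError("fitness parameters must lie in [0, 1]")
    if alpha < 0:
        raise ValueError("release ratio must be >= 0")
    model = ReducedModel.three_allele(eps, eps, eps_rev)
    x = _ud_introgression_pool(model, ud_alpha)
    # release of suppressor-only double homozygotes: all their gametes carry
    # the (suppressor, suppressor) haplotype
    ss = np.zeros(model.n_haplotypes)
    ss[2 * model.nB + 2] = 1.0
    x = (x + alpha * ss) / (1.0 + alpha)

    recovery_time: int | None = None
    prev = x
    for t in range(1, horizon + 1):
        x = model.step(prev)
        wf = model.wild_frequency(x)
        if recovery_time is None and wf > recovery_threshold:
            recovery_time = t
        if wf > 1.0 - wild_tol:
            return ReversalOutcome(True, recovery_time, t, wf)
        if np.abs(x - prev).sum() < 1e-14:
            return ReversalOutcome(wf > 1.0 - wild_tol, recovery_time, t, wf)
        prev = x
    return ReversalOutcome(False, recovery_time, horizon, model.wild_frequency(x))


def epsilon_star(
    alpha: float, tol: float = 5e-4, introgression_freq: float = 1e-3
) -> float:
    """Smallest construct fitness eps at which a release ratio alpha introgresses.

    Operational definition: bisection (to ``tol``) on eps in the two-allele
    model; a release of construct double homozygotes at ratio alpha either
    converges to the transgene-free state (loss) or to an equilibrium with
    transgene allele frequency above ``introgression_freq`` (introgression).
    """

    def introgresses(eps: float) -> bool:
        model = ReducedModel.two_allele(eps, eps)
        x_eq = _ud_introgression_pool(model, alpha)
        fa, _ = model.allele_frequencies(x_eq)
        return float(1.0 - fa[0]) > introgression_freq

    lo, hi = 0.0, 1.0
    if not introgresses(hi):
        raise BracketError(f"release ratio {alpha} does not introgress even at eps = 1")
    if introgresses(lo):
        return lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if introgresses(mid):
            hi = mid
        else:
            lo = mid
    return hi
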