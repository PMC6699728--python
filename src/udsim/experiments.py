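"""Scenario drivers and summary statistics for drive persistence and reversal.

Covers the headline analyses of a mutating two-locus underdominance drive:

* trajectory metrics — per-allele maximum frequencies, generations until the
  wild-type allele frequency recovers past a threshold, and the efficacious
  period during which cargo-functional transgenes stay at high frequency;
* the minimal wild-type release ratio that reverses an established drive,
  found by bisection;
* a head-to-head comparison of the wild-type and free-suppressor reversal
  strategies.

"Return to wild-type" is always judged on the minimum of the two per-locus
wild-type allele frequencies, and transgene elimination means the total
non-wild allele frequency at both loci has fallen below 1e-3 and is
non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alleles import (
    FitnessParams,
    CARGO_FUNCTIONAL_INDICES,
    WILD_INDEX,
    genotype_from_label,
)
from .simulate import (
    ReleaseEvent,
    ScenarioConfig,
    Simulator,
    Trajectory,
    allele_labels,
    run,
)
from .stability import BracketError

__all__ = [
    "MetricsRecord",
    "StrategyComparison",
    "max_allele_frequencies",
    "time_to_wildtype",
    "efficacious_period",
    "compute_metrics",
    "reversal_threshold",
    "compare_strategies",
    "ELIMINATION_FREQ",
]

#: Transgene elimination: total non-wild allele frequency at both loci below
#: this value and non-increasing.
ELIMINATION_FREQ = 1e-3

NOT_REACHED = -1


@dataclass(frozen=True)
class MetricsRecord:
    """Summary metrics of one scenario trajectory.

    Generation counts are ``NOT_REACHED`` (-1) when the event never occurs
    within the recorded horizon.
    """

    max_allele_freq: dict[str, float]
    time_to_wild_095: int
    time_to_wild_090: int
    efficacious_period: int
    horizon: int
    wild_threshold: float = 0.95
    cargo_threshold: float = 0.85

    def to_dict(self) -> dict:
        return {
            "max_allele_freq": dict(self.max_allele_freq),
            "time_to_wild_095": self.time_to_wild_095,
            "time_to_wild_090": self.time_to_wild_090,
            "efficacious_period": self.efficacious_period,
            "horizon": self.horizon,
            "wild_threshold": self.wild_threshold,
            "cargo_threshold": self.cargo_threshold,
        }


def max_allele_frequencies(tr: Trajectory) -> dict[str, float]:
    """Maximum frequency attained by each of the 18 alleles over the trajectory."""
    if len(tr) == 0:
        raise ValueError("trajectory is empty")
    labels = allele_labels()
    maxima = np.concatenate(
        [tr.allele_freq_A.max(axis=0), tr.allele_freq_B.max(axis=0)]
    )
    return {lab: float(v) for lab, v in zip(labels, maxima)}


def time_to_wildtype(tr: Trajectory, threshold: float = 0.95) -> int:
    """First recorded generation at which both per-locus wild-type frequencies
    exceed ``threshold``; ``NOT_REACHED`` if never within the horizon."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    hits = np.nonzero(tr.wild_freq_min > threshold)[0]
    if hits.size == 0:
        return NOT_REACHED
    return int(tr.generations[hits[0]])


def efficacious_period(tr: Trajectory, threshold: float = 0.85) -> int:
    """Number of generations with cargo-functional transgenes above ``threshold``.

    Cargo-functional alleles are the transgenic classes whose cargo component
    is intact (the intact construct plus lethal- and/or suppressor-knockout
    alleles); their summed per-locus frequency must exceed the threshold at
    both loci for a generation to count.  With thinned recording each recorded
    generation stands for the interval since the previous record.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    idx = list(CARGO_FUNCTIONAL_INDICES)
    cargo_A = tr.allele_freq_A[:, idx].sum(axis=1)
    cargo_B = tr.allele_freq_B[:, idx].sum(axis=1)
    above = (cargo_A > threshold) & (cargo_B > threshold)
    gens = tr.generations
    spans = np.diff(gens, prepend=gens[0] - 1) if len(gens) else np.array([])
    return int(spans[above].sum())


def compute_metrics(
    tr: Trajectory, wild_threshold: float = 0.95, cargo_threshold: float = 0.85
) -> MetricsRecord:
    return MetricsRecord(
        max_allele_freq=max_allele_frequencies(tr),
        time_to_wild_095=time_to_wildtype(tr, wild_threshold),
        time_to_wild_090=time_to_wildtype(tr, 0.90),
        efficacious_period=efficacious_period(tr, cargo_threshold),
        horizon=int(tr.generations[-1]),
        wild_threshold=wild_threshold,
        cargo_threshold=cargo_threshold,
    )


# -- reversal experiments ---------------------------------------------------------

_RELEASED = {
    "wildtype": "aabb",
    "free_suppressor": "A_LC A_LC B_LC B_LC",
}


def _established_state(sim: Simulator, ud_alpha: float, release_generation: int) -> np.ndarray:
    """Genotype state ``release_generation`` steps after a 1:1-style UD release."""
    G = sim.initialize(ud_alpha, genotype_from_label("AABB")).genotype_frequencies
    for _ in range(release_generation):
        G, _ = sim.step_frequencies(G)
    return G


def _transgenes_eliminated(
    sim: Simulator,
    G: np.ndarray,
    horizon: int,
    threshold: float = ELIMINATION_FREQ,
) -> bool:
    """Run forward; True once the non-wild allele frequency at both loci drops
    below ``threshold`` while non-increasing, False if the dynamics converge
    (or the horizon expires) with transgenes still present."""
    prev_trans = np.inf
    for _ in range(horizon):
        G_prev = G
        G, _ = sim.step_frequencies(G)
        fa, fb = sim.allele_frequency_vectors(G)
        trans = max(1.0 - fa[WILD_INDEX], 1.0 - fb[WILD_INDEX])
        if trans < threshold and trans <= prev_trans:
            return True
        if np.abs(G - G_prev).sum() < 1e-13:
            return trans < threshold
        prev_trans = trans
    return False


def reversal_threshold(
    strategy: str,
    params: FitnessParams | None = None,
    m: float = 0.0,
    release_generation: int = 100,
    ud_alpha: float = 1.0,
    tol: float = 0.005,
    alpha_max: float = 16.0,
    horizon: int = 50_000,
) -> float:
    """Minimal release ratio of the reversal strategy that eliminates the drive.

    The drive is first established by a 1:1 AABB release and allowed to run for
    ``release_generation`` generations; bisection on the reversal release ratio
    alpha (to ``tol``) then separates releases that eliminate all transgenic
    alleles from those that leave the drive at its introgression equilibrium.
    For the wild-type strategy at eps = 0.95 this threshold is large (about
    1.75); for a free-suppressor strategy with a fitness advantage over the
    drive it collapses towards zero, i.e. the smallest ratio probed succeeds.
    """
    if strategy not in _RELEASED:
        raise ValueError(f"strategy must be one of {sorted(_RELEASED)}, got {strategy!r}")
    if params is None:
        params = FitnessParams()
    sim = Simulator(params, m)
    G_est = _established_state(sim, ud_alpha, release_generation)
    released = genotype_from_label(_RELEASED[strategy])

    def succeeds(alpha: float) -> bool:
        G = G_est / (1.0 + alpha)
        G = G.copy()
        G[released.index] += alpha / (1.0 + alpha)
        return _transgenes_eliminated(sim, G, horizon)

    lo, hi = 0.0, alpha_max
    if not succeeds(hi):
        raise BracketError(
            f"no successful {strategy} reversal found for any alpha <= {alpha_max}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if succeeds(mid):
            hi = mid
        else:
            lo = mid
    return hi


@dataclass
class StrategyComparison:
    """Paired trajectories and recovery times of the two reversal strategies."""

    wildtype: Trajectory
    free_suppressor: Trajectory
    recovery_time_wildtype: int
    recovery_time_free_suppressor: int
    wild_threshold: float = 0.95


def compare_strategies(
    params: FitnessParams | None = None,
    alpha: float = 2.0,
    release_generation: int = 100,
    m: float = 0.0,
    horizon: int = 50_000,
    wild_threshold: float = 0.95,
) -> StrategyComparison:
    """Run both reversal strategies at the same release ratio and compare.

    Each scenario is a 1:1 AABB introduction followed at ``release_generation``
    by either a wild-type or a free-suppressor (suppressor-only double
    homozygote) release at ratio ``alpha``; recovery time is the first
    generation with both per-locus wild-type frequencies above
    ``wild_threshold``.
    """
    if params is None:
        params = FitnessParams()
    out: dict[str, Trajectory] = {}
    for strategy, released in _RELEASED.items():
        cfg = ScenarioConfig(
            eps_A=params.eps_A,
            eps_B=params.eps_B,
            eps_AM=params.eps_AM,
            eps_BM=params.eps_BM,
            m=m,
            releases=[
                ReleaseEvent(0, genotype_from_label("AABB"), 1.0),
                ReleaseEvent(release_generation, genotype_from_label(released), alpha),
            ],
            generations=horizon,
            stop_at_wild_freq=1.0 - 1e-6,
        )
        out[strategy] = run(cfg)
    return StrategyComparison(
        wildtype=out["wildtype"],
        free_suppressor=out["free_suppressor"],
        recovery_time_wildtype=time_to_wildtype(out["wildtype"], wild_threshold),
        recovery_time_free_suppressor=time_to_wildtype(
            out["free_suppressor"], wild_threshold
        ),
        wild_threshold=wild_threshold,
    )
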