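"""Independent brute-force oracles used to cross-check the vectorised engine.

Everything here works on allele *labels* and Python dicts, deliberately sharing
no index machinery with the package: functional components are re-derived from
the label text, viability is re-evaluated from the lethal/suppressor rule, and
one generation of mating + mutation + selection is computed by looping over
every ordered genotype pair and every gamete combination.
"""

from __future__ import annotations

from collections import defaultdict
from itertools import product

ALLELE_ORDER = ["", "_L", "_S", "_C", "_LS", "_LC", "_SC", "_LSC"]


def locus_labels(base: str) -> list[str]:
    """The nine allele labels at a locus, canonical order (e.g. base='A')."""
    return [base.lower()] + [base + s for s in ALLELE_ORDER]


def functional_components(label: str) -> set[str]:
    """Which of {L, S, C} remain functional, read straight off the label."""
    if label.islower():
        return set()
    if "_" in label:
        _, subs = label.split("_")
        return set("LSC") - set(subs)
    return set("LSC")


GenoKey = tuple[tuple[str, str], tuple[str, str]]


def canonical_genotype(a1: str, a2: str, b1: str, b2: str) -> GenoKey:
    order_a = {lab: k for k, lab in enumerate(locus_labels("A"))}
    order_b = {lab: k for k, lab in enumerate(locus_labels("B"))}
    pa = tuple(sorted((a1, a2), key=order_a.__getitem__))
    pb = tuple(sorted((b1, b2), key=order_b.__getitem__))
    return (pa, pb)


def genotype_viable(key: GenoKey) -> bool:
    """Unsuppressed-lethal rule applied directly to the labels."""
    (a1, a2), (b1, b2) = key
    lethal_a = any("L" in functional_components(l) for l in (a1, a2))
    supp_a = any("S" in functional_components(l) for l in (a1, a2))
    lethal_b = any("L" in functional_components(l) for l in (b1, b2))
    supp_b = any("S" in functional_components(l) for l in (b1, b2))
    return not ((lethal_a and not supp_b) or (lethal_b and not supp_a))


def count_nonviable() -> int:
    """Brute-force double loop over all 45 x 45 locus-pair combinations."""
    labels_a = locus_labels("A")
    labels_b = locus_labels("B")
    pairs_a = [(labels_a[i], labels_a[j]) for i in range(9) for j in range(i, 9)]
    pairs_b = [(labels_b[i], labels_b[j]) for i in range(9) for j in range(i, 9)]
    return sum(
        not genotype_viable((pa, pb)) for pa in pairs_a for pb in pairs_b
    )


def genotype_fitness(key: GenoKey, eps_A: float, eps_AM: float,
                     eps_B: float, eps_BM: float) -> float:
    if not genotype_viable(key):
        return 0.0
    (a1, a2), (b1, b2) = key
    beta = sum(l == "A" for l in (a1, a2))
    phi = sum(l.startswith("A_") for l in (a1, a2))
    mu = sum(l == "B" for l in (b1, b2))
    psi = sum(l.startswith("B_") for l in (b1, b2))
    return eps_A**beta * eps_AM**phi * eps_B**mu * eps_BM**psi


def allele_mutation_targets(label: str, m: float) -> dict[str, float]:
    """Single-generation transitions of one transmitted allele (linear in m)."""
    comps = functional_components(label)
    if not comps:
        return {label: 1.0}
    base = label[0]
    out = {label: 1.0 - len(comps) * m}
    for c in comps:
        remaining = comps - {c}
        subs = "".join(x for x in "LSC" if x not in remaining)
        out[f"{base}_{subs}"] = out.get(f"{base}_{subs}", 0.0) + m
    return out


def mutated_gamete_dict(key: GenoKey, m: float) -> dict[tuple[str, str], float]:
    """Mendelian gametes of one parent, each transmitted allele then mutated."""
    (a1, a2), (b1, b2) = key
    out: dict[tuple[str, str], float] = defaultdict(float)
    for a in (a1, a2):
        for b in (b1, b2):
            for ta, pa in allele_mutation_targets(a, m).items():
                for tb, pb in allele_mutation_targets(b, m).items():
                    out[(ta, tb)] += 0.25 * pa * pb
    return dict(out)


def step_oracle(
    state: dict[GenoKey, float],
    m: float,
    eps_A: float,
    eps_AM: float,
    eps_B: float,
    eps_BM: float,
) -> dict[GenoKey, float]:
    """One generation via the explicit mating-pair table.

    Loops over every ordered pair of parental genotypes, forms offspring from
    every gamete combination, weights by offspring fitness and normalises by
    the population mean fitness.
    """
    gametes = {g: mutated_gamete_dict(g, m) for g in state}
    offspring: dict[GenoKey, float] = defaultdict(float)
    for (g1, f1), (g2, f2) in product(state.items(), repeat=2):
        w = f1 * f2
        if w == 0.0:
            continue
        for (ha, hb), p1 in gametes[g1].items():
            for (ka, kb), p2 in gametes[g2].items():
                offspring[canonical_genotype(ha, ka, hb, kb)] += w * p1 * p2
    weighted = {
        g: f * genotype_fitness(g, eps_A, eps_AM, eps_B, eps_BM)
        for g, f in offspring.items()
    }
    omega_bar = sum(weighted.values())
    return {g: f / omega_bar for g, f in weighted.items() if f != 0.0}
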