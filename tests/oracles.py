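"""Brute-force enumeration oracles, independent of the implementation.

Everything here works by summing probabilities over ordered allele
draws; none of it shares code with the LR formulas it is used to
verify.
"""

from __future__ import annotations

import itertools

from kinerr import Genotype, MarkerFrequencies


def genotype_prob_enum(g: Genotype, m: MarkerFrequencies) -> float:
    """P(G) by summing over ordered population draws."""
    p = dict(zip(m.alleles, m.freqs))
    total = 0.0
    for x, y in itertools.product(m.alleles, repeat=2):
        if Genotype(x, y) == g:
            total += p[x] * p[y]
    return total


def joint_prob_enum(
    g1: Genotype, g2: Genotype, n_ibd: int, m: MarkerFrequencies
) -> float:
    """P(G1, G2 | exactly n_ibd alleles shared IBD) by enumeration.

    Under 1 IBD allele the pair shares one ancestral population draw;
    the remaining alleles are independent population draws.
    """
    p = dict(zip(m.alleles, m.freqs))
    total = 0.0
    if n_ibd == 0:
        for x1, x2, y1, y2 in itertools.product(m.alleles, repeat=4):
            if Genotype(x1, x2) == g1 and Genotype(y1, y2) == g2:
                total += p[x1] * p[x2] * p[y1] * p[y2]
    elif n_ibd == 1:
        # shared ancestral allele a; private alleles u (person 1), v (person 2)
        for a, u, v in itertools.product(m.alleles, repeat=3):
            if Genotype(a, u) == g1 and Genotype(a, v) == g2:
                total += p[a] * p[u] * p[v]
    elif n_ibd == 2:
        for a, b in itertools.product(m.alleles, repeat=2):
            if Genotype(a, b) == g1 and Genotype(a, b) == g2:
                total += p[a] * p[b]
    else:
        raise ValueError(n_ibd)
    return total


def pairwise_lr_enum(
    g1: Genotype,
    g2: Genotype,
    k: tuple[float, float, float],
    m: MarkerFrequencies,
) -> float:
    """[sum_i k_i P(G1,G2 | i IBD)] / [P(G1) P(G2)] by enumeration."""
    num = sum(k[i] * joint_prob_enum(g1, g2, i, m) for i in range(3))
    return num / (genotype_prob_enum(g1, m) * genotype_prob_enum(g2, m))


def trio_pi_enum(
    gm: Genotype, gc: Genotype, gaf: Genotype, m: MarkerFrequencies
) -> float | None:
    """Paternity index by enumerating meioses.

    Numerator: mother and alleged father each transmit a uniformly
    chosen allele.  Denominator: mother transmits, the paternal allele
    is a population draw.  Returns None when the mother is incompatible
    with the child (both terms vanish).
    """
    p = dict(zip(m.alleles, m.freqs))
    num = 0.0
    for i in gm.alleles:
        for j in gaf.alleles:
            if Genotype(i, j) == gc:
                num += 0.25
    den = 0.0
    for i in gm.alleles:
        for z in m.alleles:
            if Genotype(i, z) == gc:
                den += 0.5 * p[z]
    if den == 0.0:
        return None
    return num / den


def all_genotypes(m: MarkerFrequencies) -> list[Genotype]:
    return [
        Genotype(a, b)
        for a, b in itertools.combinations_with_replacement(m.alleles, 2)
    ]
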