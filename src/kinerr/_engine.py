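"""Vectorised gene-dropping and LR evaluation for Monte-Carlo runs.

Implements the same model as :mod:`kinerr.pedigree` and
:mod:`kinerr.lr` — HWE founders, Mendelian transmission, IBD-state
pairwise LRs and the trio paternity index — on numpy arrays of allele
indices, one batch of cases at a time.  Tests assert numerical
equivalence of the array kernels with the scalar reference
implementations.
"""

from __future__ import annotations

import numpy as np

from .hypotheses import (
    HypothesisKind,
    MutationPolicy,
    Relationship,
    RelationshipHypothesis,
    STRICT_ZERO,
)
from .panels import FrequencySet

__all__ = ["simulate_log10_lr"]


def _pairwise_lr_vec(
    g1a: np.ndarray,
    g1b: np.ndarray,
    g2a: np.ndarray,
    g2b: np.ndarray,
    p: np.ndarray,
    k: tuple[float, float, float],
    floor: float,
) -> np.ndarray:
    """k0 + k1*L1 + k2*L2 for arrays of allele indices at one locus."""
    k0, k1, k2 = k
    pa2, pb2 = p[g2a], p[g2b]
    het2 = g2a != g2b
    p_g2 = np.where(het2, 2.0 * pa2 * pb2, pa2 * pa2)
    lr = np.full(g1a.shape, k0, dtype=float)
    if k1:
        def m(i, x):
            return np.where(i == x, 1.0, floor)

        def p_g2_given(i):
            hom = m(i, g2a) * pa2
            het = m(i, g2a) * pb2 + m(i, g2b) * pa2
            return np.where(het2, het, hom)

        lr += k1 * 0.5 * (p_g2_given(g1a) + p_g2_given(g1b)) / p_g2
    if k2:
        same = ((g1a == g2a) & (g1b == g2b)) | ((g1a == g2b) & (g1b == g2a))
        lr += np.where(same, k2 / p_g2, 0.0)
    return lr


def _trans_vec(
    ga: np.ndarray, gb: np.ndarray, x: np.ndarray, floor: float
) -> np.ndarray:
    t = 0.5 * (ga == x) + 0.5 * (gb == x)
    if floor:
        t = np.where(t == 0.0, floor, t)
    return t


def _trio_pi_vec(
    gma, gmb, gca, gcb, gfa, gfb, p: np.ndarray, floor: float
) -> np.ndarray:
    """Paternity index with motherless-duo fallback on maternal mismatch."""
    het_c = gca != gcb
    tm_a = _trans_vec(gma, gmb, gca, floor)
    tm_b = _trans_vec(gma, gmb, gcb, floor)
    tf_a = _trans_vec(gfa, gfb, gca, floor)
    tf_b = _trans_vec(gfa, gfb, gcb, floor)
    num = np.where(het_c, tm_a * tf_b + tm_b * tf_a, tm_a * tf_a)
    den = np.where(het_c, tm_a * p[gcb] + tm_b * p[gca], tm_a * p[gca])
    fallback = _pairwise_lr_vec(
        gfa, gfb, gca, gcb, p, (0.0, 1.0, 0.0), floor
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), fallback)
    return pi


class _Locus:
    """Sampling helpers for one marker within a batch."""

    def __init__(self, p: np.ndarray, rng: np.random.Generator, n: int,
                 mutation: MutationPolicy):
        self.p = p
        self.cum = np.cumsum(p)
        self.cum[-1] = 1.0
        self.rng = rng
        self.n = n
        self.mutation = mutation

    def draw(self) -> np.ndarray:
        return np.searchsorted(self.cum, self.rng.random(self.n))

    def founder(self) -> tuple[np.ndarray, np.ndarray]:
        return self.draw(), self.draw()

    def transmit(self, g: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
        a, b = g
        allele = np.where(self.rng.random(self.n) < 0.5, a, b)
        if self.mutation.simulate_mutations:
            mutate = self.rng.random(self.n) < self.mutation.mu
            step = np.where(self.rng.random(self.n) < 0.5, -1, 1)
            moved = allele + step
            moved = np.where(moved < 0, 1, moved)
            k = len(self.p)
            moved = np.where(moved >= k, k - 2, moved)
            allele = np.where(mutate, moved, allele)
        return allele


def simulate_log10_lr(
    relationship: Relationship,
    truth_related: bool,
    freqs: FrequencySet,
    n: int,
    rng: np.random.Generator,
    mutation: MutationPolicy = STRICT_ZERO,
    tested: RelationshipHypothesis | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n`` cases and return (log10 LR, LR-is-zero mask).

    ``tested`` defaults to the hypothesis matching the scenario (trio
    paternity for trios, the scenario's IBD coefficients otherwise);
    passing a different hypothesis evaluates e.g. unrelated pairs under
    a sibling claim.  Entries with a zero combined LR carry ``True`` in
    the mask and an unspecified value in the log10 array.
    """
    rel = Relationship(relationship)
    if rel in (Relationship.UNRELATED_TRIO, Relationship.UNRELATED_PAIR):
        if truth_related:
            raise ValueError(f"{rel.value} cannot be simulated as related")
        rel = Relationship.TRIO if rel.is_trio else Relationship.PARENT_CHILD
    if tested is None:
        tested = RelationshipHypothesis.for_relationship(rel)
    if rel.is_trio != (tested.kind is HypothesisKind.TRIO_PATERNITY):
        raise ValueError("tested hypothesis incompatible with scenario structure")

    floor = mutation.lr_floor
    log10 = np.zeros(n)
    zero = np.zeros(n, dtype=bool)
    for mf in freqs.markers():
        p = mf.freq_array
        if mutation.simulate_mutations:
            p = p[mf.numeric_ladder()]
        loc = _Locus(p, rng, n, mutation)
        if rel is Relationship.TRIO:
            mother, father = loc.founder(), loc.founder()
            child = (loc.transmit(mother), loc.transmit(father))
            af = father if truth_related else loc.founder()
            lr = _trio_pi_vec(*mother, *child, *af, p, floor)
        else:
            if not truth_related:
                pair1, pair2 = loc.founder(), loc.founder()
            elif rel is Relationship.PARENT_CHILD:
                parent, coparent = loc.founder(), loc.founder()
                pair1 = parent
                pair2 = (loc.transmit(parent), loc.transmit(coparent))
            elif rel is Relationship.FULL_SIB:
                f, m = loc.founder(), loc.founder()
                pair1 = (loc.transmit(f), loc.transmit(m))
                pair2 = (loc.transmit(f), loc.transmit(m))
            elif rel is Relationship.HALF_SIB:
                shared, a, b = loc.founder(), loc.founder(), loc.founder()
                pair1 = (loc.transmit(shared), loc.transmit(a))
                pair2 = (loc.transmit(shared), loc.transmit(b))
            elif rel is Relationship.FIRST_COUSIN:
                gf, gm = loc.founder(), loc.founder()
                sib1 = (loc.transmit(gf), loc.transmit(gm))
                sib2 = (loc.transmit(gf), loc.transmit(gm))
                pair1 = (loc.transmit(sib1), loc.transmit(loc.founder()))
                pair2 = (loc.transmit(sib2), loc.transmit(loc.founder()))
            else:  # pragma: no cover
                raise ValueError(f"invalid relationship {relationship!r}")
            lr = _pairwise_lr_vec(*pair1, *pair2, p, tested.k, floor)
        z = lr <= 0.0
        zero |= z
        log10 += np.where(z, 0.0, np.log10(np.where(z, 1.0, lr)))
    log10 = np.where(zero, -np.inf, log10)
    return log10, zero
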