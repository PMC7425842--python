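"""Kinship likelihood ratios for trio and pairwise hypotheses.

Each locus contributes a likelihood ratio comparing the probability of
the observed genotypes under the tested relationship against
unrelatedness; loci are unlinked, so the combined LR is the product
(accumulated in log10 space to avoid underflow).

Pairwise LRs condition on the IBD state::

    LR = k0 + k1 * L1 + k2 * L2

with ``L1 = P(G2 | G1, 1 allele IBD) / P(G2)`` (conditioning on which
allele of G1 is the IBD copy, each with probability 1/2) and
``L2 = [G1 = G2] / P(G2)``.  Trio cases use the paternity index
``PI = P(child | mother, alleged father) / P(child | mother, random
man)`` obtained by enumerating the maternal/paternal assignments of the
child's alleles consistent with the mother; if no assignment is
consistent (maternal mismatch), the locus falls back to the motherless
parent-child duo LR between child and alleged father.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .hypotheses import (
    HypothesisKind,
    MutationPolicy,
    PAIRWISE_PRESETS,
    RelationshipHypothesis,
    STRICT_ZERO,
)
from .panels import FrequencySet, MarkerFrequencies
from .pedigree import Genotype, SimulatedCase

__all__ = [
    "LRResult",
    "genotype_prob",
    "pairwise_lr_locus",
    "trio_lr_locus",
    "combined_lr",
    "write_lr_report",
]


@dataclass(frozen=True)
class LRResult:
    """Per-locus and combined likelihood ratios for one case."""

    per_locus: Mapping[str, float]
    combined: float
    log10_combined: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_locus", dict(self.per_locus))


def genotype_prob(g: Genotype, m: MarkerFrequencies) -> float:
    """HWE genotype probability: p^2 for aa, 2*p_a*p_b for ab."""
    pa = m.freq_of(g.allele1)
    if not g.is_het:
        return pa * pa
    return 2.0 * pa * m.freq_of(g.allele2)


def _p_g2_given_ibd(
    ibd_allele: str, g2: Genotype, m: MarkerFrequencies, floor: float
) -> float:
    """P(G2 | one allele of G2 is an IBD copy of ``ibd_allele``).

    The non-IBD allele is drawn from the population.  A mismatch of the
    IBD copy contributes ``floor`` (0 under strict exclusion, mu under
    the rate-floor mutation treatment).
    """
    match = lambda x: 1.0 if ibd_allele == x else floor  # noqa: E731
    if not g2.is_het:
        return match(g2.allele1) * m.freq_of(g2.allele1)
    return match(g2.allele1) * m.freq_of(g2.allele2) + match(
        g2.allele2
    ) * m.freq_of(g2.allele1)


def pairwise_lr_locus(
    g1: Genotype,
    g2: Genotype,
    hyp: RelationshipHypothesis,
    m: MarkerFrequencies,
    mutation: MutationPolicy = STRICT_ZERO,
) -> float:
    """Single-locus pairwise LR ``k0 + k1*L1 + k2*L2``.

    Mendelian-impossible sharing contributes 0 to L1/L2, so a wholly
    mismatched pair returns ``k0`` (0 for parent-child under strict
    exclusion).
    """
    if hyp.kind is not HypothesisKind.PAIRWISE:
        raise ValueError("pairwise_lr_locus requires a PAIRWISE hypothesis")
    k0, k1, k2 = hyp.k
    p_g2 = genotype_prob(g2, m)
    lr = k0
    if k1:
        floor = mutation.lr_floor
        l1 = 0.5 * (
            _p_g2_given_ibd(g1.allele1, g2, m, floor)
            + _p_g2_given_ibd(g1.allele2, g2, m, floor)
        ) / p_g2
        lr += k1 * l1
    if k2 and g1 == g2:
        lr += k2 / p_g2
    return lr


def _transmission_prob(
    parent: Genotype, allele: str, floor: float
) -> float:
    """P(parent transmits ``allele``): 1, 1/2, or ``floor`` on mismatch."""
    t = (0.5 if parent.allele1 == allele else 0.0) + (
        0.5 if parent.allele2 == allele else 0.0
    )
    return t if t > 0 else floor


def trio_lr_locus(
    gm: Genotype,
    gc: Genotype,
    gaf: Genotype,
    m: MarkerFrequencies,
    mutation: MutationPolicy = STRICT_ZERO,
) -> float:
    """Single-locus paternity index for a mother/child/alleged-father trio."""
    floor = mutation.lr_floor
    a, b = gc.alleles
    tm_a = _transmission_prob(gm, a, floor)
    tf_a = _transmission_prob(gaf, a, floor)
    if not gc.is_het:
        num = tm_a * tf_a
        den = tm_a * m.freq_of(a)
    else:
        tm_b = _transmission_prob(gm, b, floor)
        tf_b = _transmission_prob(gaf, b, floor)
        num = tm_a * tf_b + tm_b * tf_a
        den = tm_a * m.freq_of(b) + tm_b * m.freq_of(a)
    if den == 0.0:
        # mother incompatible with the child: untested maternal link,
        # treat the locus as a motherless duo
        return pairwise_lr_locus(
            gaf, gc, PAIRWISE_PRESETS["PARENT_CHILD"], m, mutation
        )
    return num / den


def combined_lr(
    case: SimulatedCase,
    hyp: RelationshipHypothesis,
    freqs: FrequencySet,
    mutation: MutationPolicy = STRICT_ZERO,
) -> LRResult:
    """Multiply per-locus LRs across the panel (log10 accumulation).

    The combined LR is 0 exactly when some locus LR is 0, in which case
    ``log10_combined`` is -inf.
    """
    if case.is_trio != (hyp.kind is HypothesisKind.TRIO_PATERNITY):
        raise ValueError(
            f"hypothesis {hyp.kind.value} incompatible with a "
            f"{'trio' if case.is_trio else 'pairwise'} case"
        )
    per_locus: dict[str, float] = {}
    log10_sum = 0.0
    any_zero = False
    for mf in freqs.markers():
        if case.is_trio:
            lr = trio_lr_locus(
                case.genotypes["mother"][mf.marker],
                case.genotypes["child"][mf.marker],
                case.genotypes["alleged_father"][mf.marker],
                mf,
                mutation,
            )
        else:
            lr = pairwise_lr_locus(
                case.genotypes["person1"][mf.marker],
                case.genotypes["person2"][mf.marker],
                hyp,
                mf,
                mutation,
            )
        per_locus[mf.marker] = lr
        if lr == 0.0:
            any_zero = True
        else:
            log10_sum += math.log10(lr)
    if any_zero:
        return LRResult(per_locus, 0.0, float("-inf"))
    return LRResult(per_locus, 10.0 ** log10_sum, log10_sum)


def write_lr_report(
    results: Mapping[str, tuple[str, LRResult]], path: str | Path
) -> None:
    """CSV report: case_id,hypothesis,marker,lr with a combined row per case."""
    rows = []
    for case_id, (hyp_label, res) in results.items():
        for marker, lr in res.per_locus.items():
            rows.append(
                {"case_id": case_id, "hypothesis": hyp_label, "marker": marker, "lr": lr}
            )
        rows.append(
            {
                "case_id": case_id,
                "hypothesis": hyp_label,
                "marker": "combined",
                "lr": res.combined,
            }
        )
    pd.DataFrame(rows, columns=["case_id", "hypothesis", "marker", "lr"]).to_csv(
        path, index=False
    )
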