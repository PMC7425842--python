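"""False negative / false positive / inconclusive rates under LR thresholds.

A decision policy turns a combined LR into INCLUSION, EXCLUSION or
INCONCLUSIVE.  The binary policy uses a single inclusion threshold
(everything below is an exclusion); the ternary policy adds an
exclusion threshold, leaving an open inconclusive interval
``t_excl < LR < t_incl`` (the convention matches an inconclusive range
stated with strict inequalities, e.g. 0.01 < LR < 100, so LRs exactly
on a threshold are decisions).

Rates are estimated by Monte-Carlo: simulate ``n_sims`` related and
``n_sims`` unrelated cases, compute each case's combined LR for the
tested hypothesis, classify, and tally.  The false negative rate is
the fraction of truly related cases not called inclusion (binary) or
called exclusion (ternary); the false positive rate is the fraction of
unrelated cases called inclusion.  An exact enumeration over all joint
genotype configurations serves as an oracle on small panels.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._engine import simulate_log10_lr
from .hypotheses import (
    MutationPolicy,
    Relationship,
    RelationshipHypothesis,
    STRICT_ZERO,
)
from .lr import pairwise_lr_locus
from .panels import FrequencySet, MarkerFrequencies
from .pedigree import Genotype

__all__ = [
    "Decision",
    "DecisionPolicy",
    "RateTable",
    "LRHistogram",
    "LRSample",
    "classify",
    "sample_log10_lrs",
    "rates_from_samples",
    "estimate_rates",
    "exact_rates_bruteforce",
    "write_rates_csv",
    "write_histograms_csv",
]


class Decision(str, enum.Enum):
    INCLUSION = "INCLUSION"
    EXCLUSION = "EXCLUSION"
    INCONCLUSIVE = "INCONCLUSIVE"


class PolicyMode(str, enum.Enum):
    BINARY = "BINARY"
    TERNARY = "TERNARY"


@dataclass(frozen=True)
class DecisionPolicy:
    """LR thresholds and binary/ternary mode.

    BINARY: inclusion iff LR >= t_incl, else exclusion.
    TERNARY: inclusion iff LR >= t_incl, exclusion iff LR <= t_excl,
    inconclusive in between.
    """

    mode: PolicyMode = PolicyMode.BINARY
    t_incl: float = 100.0
    t_excl: float | None = None

    def __post_init__(self) -> None:
        mode = PolicyMode(self.mode)
        object.__setattr__(self, "mode", mode)
        if not self.t_incl > 1:
            raise ValueError(f"t_incl must be > 1, got {self.t_incl}")
        if mode is PolicyMode.TERNARY:
            if self.t_excl is None or not (0 < self.t_excl < 1):
                raise ValueError(
                    f"TERNARY requires 0 < t_excl < 1, got {self.t_excl}"
                )
        elif self.t_excl is not None:
            raise ValueError("BINARY policy takes no t_excl")

    @staticmethod
    def binary(t_incl: float) -> "DecisionPolicy":
        return DecisionPolicy(PolicyMode.BINARY, t_incl)

    @staticmethod
    def ternary(t_excl: float, t_incl: float) -> "DecisionPolicy":
        return DecisionPolicy(PolicyMode.TERNARY, t_incl, t_excl)


def classify(lr: float, policy: DecisionPolicy) -> Decision:
    """Classify one combined LR under a policy."""
    if lr < 0:
        raise ValueError(f"LR must be >= 0, got {lr}")
    if lr >= policy.t_incl:
        return Decision.INCLUSION
    if policy.mode is PolicyMode.BINARY:
        return Decision.EXCLUSION
    if lr <= policy.t_excl:
        return Decision.EXCLUSION
    return Decision.INCONCLUSIVE


@dataclass
class LRSample:
    """Combined LRs of simulated cases, in log10 with a zero mask."""

    log10: np.ndarray
    is_zero: np.ndarray

    @property
    def n(self) -> int:
        return int(self.log10.size)

    def lr(self) -> np.ndarray:
        return np.where(self.is_zero, 0.0, 10.0 ** self.log10)

    def decision_counts(self, policy: DecisionPolicy) -> dict[Decision, int]:
        incl, excl, inc = _decision_counts(self.log10, self.is_zero, policy)
        return {
            Decision.INCLUSION: incl,
            Decision.EXCLUSION: excl,
            Decision.INCONCLUSIVE: inc,
        }


def _decision_counts(
    log10: np.ndarray, zero: np.ndarray, policy: DecisionPolicy
) -> tuple[int, int, int]:
    inclusion = (~zero) & (log10 >= math.log10(policy.t_incl))
    if policy.mode is PolicyMode.BINARY:
        exclusion = ~inclusion
    else:
        exclusion = zero | (log10 <= math.log10(policy.t_excl))
        exclusion &= ~inclusion
    n = log10.size
    n_incl = int(inclusion.sum())
    n_excl = int(exclusion.sum())
    return n_incl, n_excl, n - n_incl - n_excl


# log10-decade histogram: LR = 0 | (0, 1e-10) | decades | [1e10, inf)
_EDGES = np.arange(-10, 11)


@dataclass
class LRHistogram:
    """Counts of combined LRs per decade of LR (S-table style bins)."""

    relationship: str
    arm: str  # "related" or "unrelated"
    zero_count: int
    underflow: int          # 0 < LR < 1e-10
    decade_counts: np.ndarray  # 20 bins [10^e, 10^(e+1)), e = -10..9
    overflow: int           # LR >= 1e10

    @property
    def n_sims(self) -> int:
        return int(
            self.zero_count
            + self.underflow
            + self.decade_counts.sum()
            + self.overflow
        )

    @staticmethod
    def empty(relationship: str, arm: str) -> "LRHistogram":
        return LRHistogram(relationship, arm, 0, 0, np.zeros(20, dtype=np.int64), 0)

    def add_sample(self, log10: np.ndarray, zero: np.ndarray) -> None:
        self.zero_count += int(zero.sum())
        vals = log10[~zero]
        self.underflow += int((vals < -10).sum())
        self.overflow += int((vals >= 10).sum())
        counts, _ = np.histogram(vals, bins=_EDGES)
        self.decade_counts += counts

    def rows(self) -> list[dict]:
        rows = [
            {
                "relationship": self.relationship,
                "arm": self.arm,
                "bin_low_log10": "zero",
                "bin_high_log10": "zero",
                "count": self.zero_count,
            },
            {
                "relationship": self.relationship,
                "arm": self.arm,
                "bin_low_log10": "-inf",
                "bin_high_log10": -10,
                "count": self.underflow,
            },
        ]
        for lo, count in zip(_EDGES[:-1], self.decade_counts):
            rows.append(
                {
                    "relationship": self.relationship,
                    "arm": self.arm,
                    "bin_low_log10": int(lo),
                    "bin_high_log10": int(lo) + 1,
                    "count": int(count),
                }
            )
        rows.append(
            {
                "relationship": self.relationship,
                "arm": self.arm,
                "bin_low_log10": 10,
                "bin_high_log10": "inf",
                "count": self.overflow,
            }
        )
        return rows


def _binom_se(p: float, n: int | None) -> float:
    if not n:
        return 0.0
    return math.sqrt(p * (1.0 - p) / n)


@dataclass(frozen=True)
class RateTable:
    """Estimated error rates for one relationship/panel/policy cell.

    ``n_sims is None`` marks exact enumeration (zero Monte-Carlo SE).
    """

    relationship: str
    panel: str
    policy: DecisionPolicy
    n_sims: int | None
    fn_rate: float
    fp_rate: float
    inconclusive_related: float = 0.0
    inconclusive_unrelated: float = 0.0
    fn_se: float = 0.0
    fp_se: float = 0.0

    def __post_init__(self) -> None:
        for name in ("fn_rate", "fp_rate", "inconclusive_related",
                     "inconclusive_unrelated"):
            v = getattr(self, name)
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def to_row(self) -> dict:
        return {
            "relationship": self.relationship,
            "panel": self.panel,
            "mode": self.policy.mode.value,
            "t_incl": self.policy.t_incl,
            "t_excl": self.policy.t_excl,
            "n_sims": self.n_sims,
            "fn_rate": self.fn_rate,
            "fp_rate": self.fp_rate,
            "inconclusive_related": self.inconclusive_related,
            "inconclusive_unrelated": self.inconclusive_unrelated,
            "fn_se": self.fn_se,
            "fp_se": self.fp_se,
        }


def sample_log10_lrs(
    relationship: Relationship,
    truth_related: bool,
    freqs: FrequencySet,
    n: int,
    rng: np.random.Generator | int,
    mutation: MutationPolicy = STRICT_ZERO,
    tested: RelationshipHypothesis | None = None,
) -> LRSample:
    """Simulate ``n`` cases of one arm and return their combined LRs."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    log10, zero = simulate_log10_lr(
        relationship, truth_related, freqs, int(n), rng, mutation, tested
    )
    return LRSample(log10, zero)


def rates_from_samples(
    related: LRSample,
    unrelated: LRSample,
    policy: DecisionPolicy,
    relationship: str = "",
    panel: str = "",
) -> RateTable:
    """Classify two LR samples (related and unrelated arms) into rates."""
    incl_r, excl_r, inc_r = _decision_counts(
        related.log10, related.is_zero, policy
    )
    incl_u, _, inc_u = _decision_counts(
        unrelated.log10, unrelated.is_zero, policy
    )
    n_r, n_u = related.n, unrelated.n
    if policy.mode is PolicyMode.BINARY:
        fn = (n_r - incl_r) / n_r
    else:
        fn = excl_r / n_r
    fp = incl_u / n_u
    return RateTable(
        relationship=relationship,
        panel=panel,
        policy=policy,
        n_sims=n_r,
        fn_rate=fn,
        fp_rate=fp,
        inconclusive_related=inc_r / n_r,
        inconclusive_unrelated=inc_u / n_u,
        fn_se=_binom_se(fn, n_r),
        fp_se=_binom_se(fp, n_u),
    )


def estimate_rates(
    relationship: Relationship,
    freqs: FrequencySet,
    policy: DecisionPolicy,
    n_sims: int,
    seed: int,
    mutation: MutationPolicy = STRICT_ZERO,
    tested: RelationshipHypothesis | None = None,
    batch_size: int = 200_000,
) -> tuple[RateTable, LRHistogram, LRHistogram]:
    """Monte-Carlo error rates plus LR histograms for both arms.

    Streams in batches, so memory is independent of ``n_sims``.  The
    related and unrelated arms use independent seeded RNG streams (the
    arms are reproducible separately).  Deterministic given ``seed``.
    """
    if n_sims < 1:
        raise ValueError(f"n_sims must be >= 1, got {n_sims}")
    rel = Relationship(relationship)
    rngs = {
        "related": np.random.default_rng([int(seed), 1]),
        "unrelated": np.random.default_rng([int(seed), 2]),
    }
    hists = {
        arm: LRHistogram.empty(rel.value, arm) for arm in ("related", "unrelated")
    }
    counts = {arm: np.zeros(3, dtype=np.int64) for arm in ("related", "unrelated")}
    for arm in ("related", "unrelated"):
        remaining = int(n_sims)
        while remaining > 0:
            m = min(remaining, batch_size)
            log10, zero = simulate_log10_lr(
                rel, arm == "related", freqs, m, rngs[arm], mutation, tested
            )
            hists[arm].add_sample(log10, zero)
            counts[arm] += np.asarray(
                _decision_counts(log10, zero, policy), dtype=np.int64
            )
            remaining -= m
    incl_r, excl_r, inc_r = counts["related"]
    incl_u, _, inc_u = counts["unrelated"]
    if policy.mode is PolicyMode.BINARY:
        fn = (n_sims - incl_r) / n_sims
    else:
        fn = excl_r / n_sims
    fp = incl_u / n_sims
    table = RateTable(
        relationship=rel.value,
        panel=freqs.panel.name,
        policy=policy,
        n_sims=int(n_sims),
        fn_rate=float(fn),
        fp_rate=float(fp),
        inconclusive_related=float(inc_r / n_sims),
        inconclusive_unrelated=float(inc_u / n_sims),
        fn_se=_binom_se(float(fn), n_sims),
        fp_se=_binom_se(float(fp), n_sims),
    )
    return table, hists["related"], hists["unrelated"]


# ---------------------------------------------------------------------------
# exact enumeration oracle


def _joint_ibd_probs(
    mf: MarkerFrequencies,
) -> tuple[list[tuple[Genotype, Genotype]], np.ndarray, np.ndarray, np.ndarray]:
    """Joint P(G1, G2 | s alleles IBD) for s = 0, 1, 2 by enumeration.

    Sums over ordered allele draws: G1 = two population draws; for
    s = 1 one uniformly chosen allele of G1 is copied into G2 and the
    other G2 allele is a population draw; for s = 2 both are copied.
    Independent of the LR formulas it is used to check.
    """
    alleles = mf.alleles
    p = {a: f for a, f in zip(mf.alleles, mf.freqs)}
    pairs = [
        (Genotype(a, b), Genotype(c, d))
        for a, b in itertools.combinations_with_replacement(alleles, 2)
        for c, d in itertools.combinations_with_replacement(alleles, 2)
    ]
    index = {pair: i for i, pair in enumerate(pairs)}
    p0 = np.zeros(len(pairs))
    p1 = np.zeros(len(pairs))
    p2 = np.zeros(len(pairs))
    for x1 in alleles:
        for x2 in alleles:
            pg1 = p[x1] * p[x2]
            g1 = Genotype(x1, x2)
            p2[index[(g1, g1)]] += pg1
            for y1 in alleles:
                for y2 in alleles:
                    p0[index[(g1, Genotype(y1, y2))]] += pg1 * p[y1] * p[y2]
            for ibd in (x1, x2):
                for z in alleles:
                    p1[index[(g1, Genotype(ibd, z))]] += pg1 * 0.5 * p[z]
    return pairs, p0, p1, p2


def exact_rates_bruteforce(
    relationship: Relationship,
    freqs: FrequencySet,
    policy: DecisionPolicy,
    mutation: MutationPolicy = STRICT_ZERO,
    max_states: int = 10_000_000,
) -> RateTable:
    """Exact error rates for a pairwise relationship on a small panel.

    Enumerates every joint genotype configuration across the panel with
    its exact probability under the true relationship (IBD-state
    mixture) and under unrelatedness, evaluates the implementation's LR
    and decision for each, and integrates.  Errors out when the state
    space exceeds ``max_states`` joint outcomes.
    """
    rel = Relationship(relationship)
    if rel.is_trio:
        raise ValueError("exact enumeration supports pairwise relationships only")
    hyp = RelationshipHypothesis.for_relationship(rel)
    k0, k1, k2 = (1.0, 0.0, 0.0) if rel is Relationship.UNRELATED_PAIR else hyp.k

    n_states = 1
    for mf in freqs.markers():
        g = len(mf.alleles) * (len(mf.alleles) + 1) // 2
        n_states *= g * g
        if n_states > max_states:
            raise ValueError(
                f"joint state space exceeds {max_states:.0g} outcomes; "
                "use Monte-Carlo (estimate_rates) instead"
            )

    lr_total = np.ones(1)
    p_rel_total = np.ones(1)
    p_unrel_total = np.ones(1)
    for mf in freqs.markers():
        pairs, p0, p1, p2 = _joint_ibd_probs(mf)
        p_rel = k0 * p0 + k1 * p1 + k2 * p2
        lr = np.array(
            [pairwise_lr_locus(g1, g2, hyp, mf, mutation) for g1, g2 in pairs]
        )
        lr_total = np.multiply.outer(lr_total, lr).ravel()
        p_rel_total = np.multiply.outer(p_rel_total, p_rel).ravel()
        p_unrel_total = np.multiply.outer(p_unrel_total, p0).ravel()

    inclusion = lr_total >= policy.t_incl
    if policy.mode is PolicyMode.BINARY:
        exclusion = ~inclusion
        inconclusive = np.zeros_like(inclusion)
    else:
        exclusion = (lr_total <= policy.t_excl) & ~inclusion
        inconclusive = ~(inclusion | exclusion)
    fn = float(p_rel_total[exclusion].sum()) if policy.mode is PolicyMode.TERNARY \
        else float(p_rel_total[~inclusion].sum())
    fp = float(p_unrel_total[inclusion].sum())
    return RateTable(
        relationship=rel.value,
        panel=freqs.panel.name,
        policy=policy,
        n_sims=None,
        fn_rate=fn,
        fp_rate=fp,
        inconclusive_related=float(p_rel_total[inconclusive].sum()),
        inconclusive_unrelated=float(p_unrel_total[inconclusive].sum()),
    )


def write_rates_csv(tables: Iterable[RateTable], path: str | Path) -> None:
    pd.DataFrame([t.to_row() for t in tables]).to_csv(path, index=False)


def write_histograms_csv(hists: Iterable[LRHistogram], path: str | Path) -> None:
    rows: list[dict] = []
    for h in hists:
        rows.extend(h.rows())
    pd.DataFrame(rows).to_csv(path, index=False)
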