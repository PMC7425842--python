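"""Relationship scenarios, IBD-coefficient hypotheses, mutation policy.

A pairwise relationship is summarised by the probabilities
(k0, k1, k2) that the two individuals share 0, 1 or 2 alleles identical
by descent (IBD) at an autosomal locus: parent-child (0, 1, 0), full
siblings (1/4, 1/2, 1/4), half siblings (1/2, 1/2, 0), first cousins
(3/4, 1/4, 0), unrelated (1, 0, 0).  The standard trio (mother, child,
alleged father) is a structural hypothesis rather than a k-vector and
is evaluated with a paternity index.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "Relationship",
    "HypothesisKind",
    "RelationshipHypothesis",
    "MutationMode",
    "MutationPolicy",
    "PAIRWISE_PRESETS",
]


class Relationship(str, enum.Enum):
    """True relationship scenarios available to the simulator."""

    TRIO = "TRIO"
    PARENT_CHILD = "PARENT_CHILD"
    FULL_SIB = "FULL_SIB"
    HALF_SIB = "HALF_SIB"
    FIRST_COUSIN = "FIRST_COUSIN"
    UNRELATED_TRIO = "UNRELATED_TRIO"
    UNRELATED_PAIR = "UNRELATED_PAIR"

    @property
    def is_trio(self) -> bool:
        return self in (Relationship.TRIO, Relationship.UNRELATED_TRIO)


class HypothesisKind(str, enum.Enum):
    TRIO_PATERNITY = "TRIO_PATERNITY"
    PAIRWISE = "PAIRWISE"


@dataclass(frozen=True)
class RelationshipHypothesis:
    """Tested hypothesis: trio paternity, or a pairwise (k0, k1, k2)."""

    kind: HypothesisKind
    k: tuple[float, float, float] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind is HypothesisKind.PAIRWISE:
            if self.k is None:
                raise ValueError("PAIRWISE hypothesis requires k=(k0,k1,k2)")
            k = tuple(float(x) for x in self.k)
            if len(k) != 3 or any(not 0 <= x <= 1 for x in k):
                raise ValueError(f"invalid IBD coefficients {k}")
            if abs(sum(k) - 1.0) > 1e-9:
                raise ValueError(f"IBD coefficients must sum to 1, got {k}")
            object.__setattr__(self, "k", k)
        elif self.k is not None:
            raise ValueError("TRIO_PATERNITY hypothesis takes no k")

    @staticmethod
    def trio() -> "RelationshipHypothesis":
        return RelationshipHypothesis(HypothesisKind.TRIO_PATERNITY, label="TRIO")

    @staticmethod
    def pairwise(k0: float, k1: float, k2: float, label: str = "") -> "RelationshipHypothesis":
        return RelationshipHypothesis(HypothesisKind.PAIRWISE, (k0, k1, k2), label)

    @staticmethod
    def for_relationship(rel: Relationship) -> "RelationshipHypothesis":
        """The hypothesis testing a scenario as itself (trio as paternity,
        pairwise scenarios as their k-vector)."""
        if rel.is_trio:
            return RelationshipHypothesis.trio()
        if rel is Relationship.UNRELATED_PAIR:
            return PAIRWISE_PRESETS["UNRELATED"]
        return PAIRWISE_PRESETS[rel.value]


PAIRWISE_PRESETS: dict[str, RelationshipHypothesis] = {
    "PARENT_CHILD": RelationshipHypothesis.pairwise(0.0, 1.0, 0.0, "PARENT_CHILD"),
    "FULL_SIB": RelationshipHypothesis.pairwise(0.25, 0.5, 0.25, "FULL_SIB"),
    "HALF_SIB": RelationshipHypothesis.pairwise(0.5, 0.5, 0.0, "HALF_SIB"),
    "FIRST_COUSIN": RelationshipHypothesis.pairwise(0.75, 0.25, 0.0, "FIRST_COUSIN"),
    "UNRELATED": RelationshipHypothesis.pairwise(1.0, 0.0, 0.0, "UNRELATED"),
}


class MutationMode(str, enum.Enum):
    STRICT_ZERO = "STRICT_ZERO"  # Mendelian exclusion gives locus LR 0
    RATE_FLOOR = "RATE_FLOOR"    # zero transmission probabilities -> mu


@dataclass(frozen=True)
class MutationPolicy:
    """How mutation enters the likelihood ratio and the simulator.

    ``mode`` controls the LR side: STRICT_ZERO treats any Mendelian
    incompatibility as a hard exclusion (locus LR 0); RATE_FLOOR
    replaces zero transmission probabilities with the aggregate
    per-meiosis mutation rate ``mu``.  ``simulate_mutations`` controls
    the simulation side: when on, each transmitted allele mutates with
    probability ``mu`` by one step on the marker's numeric allele
    ladder (equal probability up/down, reflecting at the ends).
    """

    mode: MutationMode = MutationMode.STRICT_ZERO
    mu: float = 0.002
    simulate_mutations: bool = False

    def __post_init__(self) -> None:
        if self.mode is MutationMode.RATE_FLOOR and not (0 < self.mu < 0.01):
            raise ValueError(f"mu must be in (0, 0.01), got {self.mu}")
        if self.simulate_mutations and not (0 < self.mu < 0.01):
            raise ValueError(f"mu must be in (0, 0.01), got {self.mu}")

    @property
    def lr_floor(self) -> float:
        """Value substituted for a zero transmission probability."""
        return self.mu if self.mode is MutationMode.RATE_FLOOR else 0.0


STRICT_ZERO = MutationPolicy()
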