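"""Mendelian gene-dropping simulation of relationship scenarios.

Founders are drawn under Hardy-Weinberg equilibrium from a frequency
set; children receive one allele from each parent, chosen uniformly.
Loci are treated as unlinked and independent.  Each scenario keeps only
the individuals that would be tested in casework (trio: mother, child,
alleged father; pairwise scenarios: the two tested individuals) and
discards hidden founders.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .hypotheses import MutationPolicy, Relationship, STRICT_ZERO
from .panels import FrequencySet, MarkerFrequencies

__all__ = [
    "Genotype",
    "MultilocusGenotype",
    "SimulatedCase",
    "sample_founder",
    "transmit",
    "simulate_case",
    "cases_to_csv",
]


def _label_key(label: str):
    try:
        return (0, float(label), "")
    except ValueError:
        return (1, 0.0, label)


@dataclass(frozen=True)
class Genotype:
    """An unordered pair of allele labels, stored in canonical order."""

    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        a, b = str(self.allele1), str(self.allele2)
        if _label_key(b) < _label_key(a):
            a, b = b, a
        object.__setattr__(self, "allele1", a)
        object.__setattr__(self, "allele2", b)

    @property
    def is_het(self) -> bool:
        return self.allele1 != self.allele2

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele1, self.allele2)

    def shares_allele(self, other: "Genotype") -> bool:
        return bool(set(self.alleles) & set(other.alleles))


@dataclass(frozen=True)
class MultilocusGenotype:
    """One individual's genotype at every marker of a panel."""

    per_marker: Mapping[str, Genotype]

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_marker", dict(self.per_marker))

    def __getitem__(self, marker: str) -> Genotype:
        return self.per_marker[marker]


@dataclass(frozen=True)
class SimulatedCase:
    """The tested individuals of one simulated relationship case.

    Trio scenarios carry ``mother``, ``child``, ``alleged_father``;
    pairwise scenarios carry ``person1``, ``person2``.  ``truth_related``
    records which arm (related or unrelated) the case was simulated
    under.
    """

    relationship: Relationship
    genotypes: Mapping[str, MultilocusGenotype]
    truth_related: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "genotypes", dict(self.genotypes))
        expected = (
            {"mother", "child", "alleged_father"}
            if self.relationship.is_trio
            else {"person1", "person2"}
        )
        if set(self.genotypes) != expected:
            raise ValueError(
                f"{self.relationship.value} case requires individuals "
                f"{sorted(expected)}, got {sorted(self.genotypes)}"
            )

    @property
    def is_trio(self) -> bool:
        return self.relationship.is_trio


def _sample_allele(mf: MarkerFrequencies, rng: np.random.Generator) -> str:
    return mf.alleles[rng.choice(len(mf.alleles), p=mf.freq_array)]


def sample_founder(
    freqs: FrequencySet, rng: np.random.Generator
) -> MultilocusGenotype:
    """Draw an unrelated individual under HWE, independent across loci."""
    return MultilocusGenotype(
        {
            mf.marker: Genotype(_sample_allele(mf, rng), _sample_allele(mf, rng))
            for mf in freqs.markers()
        }
    )


def transmit(
    parent: Genotype,
    rng: np.random.Generator,
    mutation: MutationPolicy = STRICT_ZERO,
    marker: MarkerFrequencies | None = None,
) -> str:
    """One meiosis: a uniformly chosen parental allele, optionally mutated.

    With ``mutation.simulate_mutations`` on, the transmitted allele
    moves one step up or down the marker's numerically sorted allele
    ladder with probability ``mu`` (reflecting at the ends); the marker
    frequencies must then be supplied and carry numeric labels.
    """
    allele = parent.allele1 if rng.random() < 0.5 else parent.allele2
    if mutation.simulate_mutations:
        if marker is None:
            raise ValueError("stepwise mutation requires the marker frequencies")
        if rng.random() < mutation.mu:
            order = marker.numeric_ladder()
            ladder = [marker.alleles[i] for i in order]
            pos = ladder.index(allele)
            step = -1 if rng.random() < 0.5 else 1
            new = pos + step
            if new < 0:
                new = 1
            elif new >= len(ladder):
                new = len(ladder) - 2
            allele = ladder[new]
    return allele


def _child(
    p1: MultilocusGenotype,
    p2: MultilocusGenotype,
    freqs: FrequencySet,
    rng: np.random.Generator,
    mutation: MutationPolicy,
) -> MultilocusGenotype:
    return MultilocusGenotype(
        {
            mf.marker: Genotype(
                transmit(p1[mf.marker], rng, mutation, mf),
                transmit(p2[mf.marker], rng, mutation, mf),
            )
            for mf in freqs.markers()
        }
    )


def simulate_case(
    relationship: Relationship,
    truth_related: bool,
    freqs: FrequencySet,
    rng: np.random.Generator,
    mutation: MutationPolicy = STRICT_ZERO,
) -> SimulatedCase:
    """Gene-drop one case of the given scenario.

    ``truth_related=False`` simulates the unrelated counterpart of the
    scenario: for a trio the alleged father is an independent founder;
    for pairwise scenarios the two tested individuals are independent
    founders (the tested hypothesis is what varies downstream).
    """
    rel = Relationship(relationship)
    if rel in (Relationship.UNRELATED_TRIO, Relationship.UNRELATED_PAIR):
        if truth_related:
            raise ValueError(f"{rel.value} cannot be simulated as related")
        rel = Relationship.TRIO if rel.is_trio else Relationship.PARENT_CHILD

    founder = lambda: sample_founder(freqs, rng)  # noqa: E731
    child = lambda a, b: _child(a, b, freqs, rng, mutation)  # noqa: E731

    if rel is Relationship.TRIO:
        mother, father = founder(), founder()
        kid = child(mother, father)
        af = father if truth_related else founder()
        return SimulatedCase(
            Relationship.TRIO if truth_related else Relationship.UNRELATED_TRIO,
            {"mother": mother, "child": kid, "alleged_father": af},
            truth_related,
        )

    if not truth_related:
        return SimulatedCase(
            Relationship.UNRELATED_PAIR,
            {"person1": founder(), "person2": founder()},
            truth_related,
        )

    if rel is Relationship.PARENT_CHILD:
        parent, coparent = founder(), founder()
        p1, p2 = parent, child(parent, coparent)
    elif rel is Relationship.FULL_SIB:
        f, m = founder(), founder()
        p1, p2 = child(f, m), child(f, m)
    elif rel is Relationship.HALF_SIB:
        shared, a, b = founder(), founder(), founder()
        p1, p2 = child(shared, a), child(shared, b)
    elif rel is Relationship.FIRST_COUSIN:
        gf, gm = founder(), founder()
        sib1, sib2 = child(gf, gm), child(gf, gm)
        p1, p2 = child(sib1, founder()), child(sib2, founder())
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"invalid relationship {relationship!r}")

    return SimulatedCase(rel, {"person1": p1, "person2": p2}, truth_related)


def cases_to_csv(cases: list[SimulatedCase], path: str | Path) -> None:
    """Export genotypes as CSV: case_id,individual,marker,allele1,allele2."""
    rows = [
        {
            "case_id": i,
            "individual": who,
            "marker": marker,
            "allele1": g.allele1,
            "allele2": g.allele2,
        }
        for i, case in enumerate(cases)
        for who, mlg in sorted(case.genotypes.items())
        for marker, g in mlg.per_marker.items()
    ]
    pd.DataFrame(
        rows, columns=["case_id", "individual", "marker", "allele1", "allele2"]
    ).to_csv(path, index=False)
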