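"""STR panels and population allele frequencies.

A *panel* is an ordered list of autosomal STR marker names (the loci a
commercial typing kit amplifies).  A *frequency set* attaches to every
marker of a panel a population allele-frequency distribution, which is
the entire population model used downstream: founders are drawn from it
under Hardy-Weinberg equilibrium and likelihood ratios are evaluated
against it.

Published forensic frequency tables are an input, not a deliverable, so
this module also generates synthetic frequency sets with realistic STR
structure (5-15 alleles per marker, expected heterozygosity mostly in
0.6-0.95) from a seeded symmetric Dirichlet, and round-trips frequency
sets through a plain CSV format (``marker,allele,frequency``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "STRPanel",
    "MarkerFrequencies",
    "FrequencySet",
    "builtin_panel",
    "generate_frequency_set",
    "read_frequencies",
    "write_frequencies",
    "read_panel",
    "write_panel",
]

_SUM_TOL = 1e-9

# CODIS-era marker names; the counts (15 / 21 autosomal STRs) are the
# contractual part, the labels are cosmetic.
_IDENTIFILER_15 = [
    "CSF1PO", "D2S1338", "D3S1358", "D5S818", "D7S820", "D8S1179",
    "D13S317", "D16S539", "D18S51", "D19S433", "D21S11", "FGA",
    "TH01", "TPOX", "vWA",
]
_GLOBALFILER_21 = _IDENTIFILER_15 + [
    "D1S1656", "D2S441", "D10S1248", "D12S391", "D22S1045", "SE33",
]

_BUILTIN = {
    "identifiler15": ("identifiler15", _IDENTIFILER_15),
    "globalfiler21": ("globalfiler21", _GLOBALFILER_21),
}


@dataclass(frozen=True)
class STRPanel:
    """An ordered set of autosomal STR markers."""

    name: str
    markers: tuple[str, ...]

    def __post_init__(self) -> None:
        markers = tuple(self.markers)
        object.__setattr__(self, "markers", markers)
        if len(markers) < 1:
            raise ValueError("panel must contain at least one marker")
        if len(set(markers)) != len(markers):
            raise ValueError("panel marker names must be unique")

    def __len__(self) -> int:
        return len(self.markers)


def builtin_panel(name: str) -> STRPanel:
    """Return one of the built-in kit-like panels.

    ``"identifiler15"`` is a 15-marker second-generation panel,
    ``"globalfiler21"`` a 21-marker third-generation panel.
    """
    try:
        label, markers = _BUILTIN[name]
    except KeyError:
        raise ValueError(
            f"unknown panel {name!r}; valid options: {sorted(_BUILTIN)}"
        ) from None
    return STRPanel(label, tuple(markers))


@dataclass(frozen=True)
class MarkerFrequencies:
    """Allele labels and frequencies for one marker.

    Allele labels are text (repeat counts, including intermediate
    alleles such as ``"9.3"``); they only need to parse as numbers when
    stepwise mutation simulation is enabled.
    """

    marker: str
    alleles: tuple[str, ...]
    freqs: tuple[float, ...]

    def __post_init__(self) -> None:
        alleles = tuple(str(a) for a in self.alleles)
        freqs = tuple(float(f) for f in self.freqs)
        object.__setattr__(self, "alleles", alleles)
        object.__setattr__(self, "freqs", freqs)
        if len(alleles) != len(freqs):
            raise ValueError(f"{self.marker}: alleles/freqs length mismatch")
        if len(alleles) < 2:
            raise ValueError(f"{self.marker}: at least 2 alleles required")
        if len(set(alleles)) != len(alleles):
            raise ValueError(f"{self.marker}: duplicate allele labels")
        if any(f <= 0 for f in freqs):
            raise ValueError(f"{self.marker}: all frequencies must be > 0")
        total = sum(freqs)
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(
                f"{self.marker}: frequencies sum to {total}, expected 1"
            )

    @property
    def freq_array(self) -> np.ndarray:
        return np.asarray(self.freqs, dtype=float)

    def freq_of(self, allele: str) -> float:
        try:
            return self.freqs[self.alleles.index(str(allele))]
        except ValueError:
            raise KeyError(
                f"allele {allele!r} not in marker {self.marker}"
            ) from None

    @property
    def heterozygosity(self) -> float:
        """Expected heterozygosity 1 - sum(p_i^2) under HWE."""
        p = self.freq_array
        return float(1.0 - np.sum(p * p))

    def numeric_ladder(self) -> np.ndarray:
        """Allele indices sorted by numeric label value.

        Required by stepwise mutation; raises if any label is not a
        decimal repeat count.
        """
        try:
            vals = [float(a) for a in self.alleles]
        except ValueError as exc:
            raise ValueError(
                f"{self.marker}: stepwise mutation requires numeric allele "
                f"labels ({exc})"
            ) from None
        return np.argsort(np.asarray(vals))


@dataclass(frozen=True)
class FrequencySet:
    """Per-marker allele frequencies covering a whole panel."""

    population: str
    panel: STRPanel
    per_marker: Mapping[str, MarkerFrequencies] = field(default_factory=dict)

    def __post_init__(self) -> None:
        per_marker = dict(self.per_marker)
        object.__setattr__(self, "per_marker", per_marker)
        missing = [m for m in self.panel.markers if m not in per_marker]
        if missing:
            raise ValueError(f"missing frequencies for marker(s): {missing}")
        extra = [m for m in per_marker if m not in self.panel.markers]
        if extra:
            raise ValueError(f"frequencies for non-panel marker(s): {extra}")
        for name, mf in per_marker.items():
            if mf.marker != name:
                raise ValueError(
                    f"per_marker key {name!r} does not match entry "
                    f"marker {mf.marker!r}"
                )

    def __getitem__(self, marker: str) -> MarkerFrequencies:
        return self.per_marker[marker]

    def markers(self) -> Iterable[MarkerFrequencies]:
        for m in self.panel.markers:
            yield self.per_marker[m]

    def mean_heterozygosity(self) -> float:
        return float(np.mean([mf.heterozygosity for mf in self.markers()]))


def generate_frequency_set(
    panel: STRPanel,
    alleles_per_marker: tuple[int, int] = (5, 15),
    concentration: float = 1.0,
    seed: int = 0,
    population: str = "synthetic",
) -> FrequencySet:
    """Draw a synthetic frequency set with realistic STR structure.

    For each marker the allele count is drawn uniformly from the
    inclusive range ``alleles_per_marker`` and frequencies from a
    symmetric Dirichlet with parameter ``concentration``.  Allele
    labels are consecutive integer repeat counts starting at a
    marker-specific offset, so stepwise mutation works out of the box.
    With the defaults (range [5, 15], concentration 1.0) the expected
    heterozygosity 1 - sum(p^2) lies in roughly [0.6, 0.95] for most
    markers, matching published forensic STR tables.

    Deterministic given ``seed``.
    """
    lo, hi = int(alleles_per_marker[0]), int(alleles_per_marker[1])
    if not (2 <= lo <= hi <= 30):
        raise ValueError(
            f"alleles_per_marker range must lie within [2, 30], got {(lo, hi)}"
        )
    if not concentration > 0:
        raise ValueError(f"concentration must be > 0, got {concentration}")
    rng = np.random.default_rng(seed)
    per_marker: dict[str, MarkerFrequencies] = {}
    for marker in panel.markers:
        k = int(rng.integers(lo, hi + 1))
        freqs = rng.dirichlet(np.full(k, float(concentration)))
        # guard against Dirichlet draws below representable mass
        freqs = np.maximum(freqs, 1e-8)
        freqs = freqs / freqs.sum()
        start = int(rng.integers(5, 21))  # typical STR repeat-count range
        alleles = tuple(str(start + i) for i in range(k))
        per_marker[marker] = MarkerFrequencies(marker, alleles, tuple(freqs))
    return FrequencySet(population, panel, per_marker)


def write_frequencies(freq_set: FrequencySet, path: str | Path) -> None:
    """Write a frequency set as CSV with columns marker,allele,frequency."""
    rows = [
        {"marker": mf.marker, "allele": a, "frequency": repr(f)}
        for mf in freq_set.markers()
        for a, f in zip(mf.alleles, mf.freqs)
    ]
    pd.DataFrame(rows, columns=["marker", "allele", "frequency"]).to_csv(
        path, index=False
    )


def read_frequencies(
    path: str | Path, panel: STRPanel, population: str | None = None
) -> FrequencySet:
    """Read a ``marker,allele,frequency`` CSV into a FrequencySet.

    Per-marker frequency sums are renormalized to 1 when they fall in
    [0.99, 1.01] (published tables are rounded to 3-4 decimals);
    anything outside that band is an error, as are duplicate
    (marker, allele) rows, non-positive frequencies, and markers of the
    panel absent from the file.
    """
    df = pd.read_csv(path, dtype={"marker": str, "allele": str})
    required = {"marker", "allele", "frequency"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: expected columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    dupes = df.duplicated(subset=["marker", "allele"])
    if dupes.any():
        bad = df.loc[dupes, ["marker", "allele"]].iloc[0]
        raise ValueError(
            f"{path}: duplicate row for marker {bad['marker']!r} "
            f"allele {bad['allele']!r}"
        )
    per_marker: dict[str, MarkerFrequencies] = {}
    for marker, grp in df.groupby("marker", sort=False):
        freqs = grp["frequency"].to_numpy(dtype=float)
        if np.any(freqs <= 0):
            raise ValueError(f"{path}: non-positive frequency at {marker}")
        total = float(freqs.sum())
        if not (0.99 <= total <= 1.01):
            raise ValueError(
                f"{path}: frequencies for {marker} sum to {total:.6g}, "
                f"outside [0.99, 1.01]"
            )
        freqs = freqs / total
        per_marker[str(marker)] = MarkerFrequencies(
            str(marker), tuple(grp["allele"].astype(str)), tuple(freqs)
        )
    missing = [m for m in panel.markers if m not in per_marker]
    if missing:
        raise ValueError(f"{path}: missing panel marker(s): {missing}")
    extra = [m for m in per_marker if m not in panel.markers]
    if extra:
        raise ValueError(f"{path}: non-panel marker(s): {extra}")
    return FrequencySet(population or "file", panel, per_marker)


def write_panel(panel: STRPanel, path: str | Path) -> None:
    """Write a panel as JSON or YAML ({name, markers}) by extension."""
    doc = {"name": panel.name, "markers": list(panel.markers)}
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(doc))
    else:
        path.write_text(json.dumps(doc, indent=2))


def read_panel(path: str | Path) -> STRPanel:
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
    return STRPanel(str(doc["name"]), tuple(str(m) for m in doc["markers"]))
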