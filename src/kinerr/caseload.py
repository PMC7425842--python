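"""Projection of expected numbers of falsely interpreted cases.

The model multiplies, for each (case type, decision arm, threshold)
cell: total caseload x case-type share x related (or unrelated) share
x fraction of laboratories using that LR threshold x the corresponding
false negative (related arm) or false positive (unrelated arm) rate.
The related/unrelated split is applied uniformly across case types, a
deliberate simplification.  Expected counts are rounded half away from
zero; laboratories without a threshold (most full-sibling reporting)
render no decision and contribute no cells.

``table1_identifiler()`` encodes the published worldwide model for a
15-marker second-generation panel: 10 million cases, 72% truly
related, a 75/20/5% trio / parent-child / full-sibling mix, AABB-style
threshold adoption (trio 65% at LR 100 and 35% at LR 1,000;
parent-child 75%/25%; full-sibling 20% at LR 100) and the published
per-cell false rates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .rates import RateTable

__all__ = [
    "RELATED",
    "UNRELATED",
    "CaseloadModel",
    "FalseCountRow",
    "FalseCountTable",
    "expected_false_count",
    "project",
    "project_from_simulation",
    "table1_identifiler",
    "read_model",
    "write_model",
]

RELATED = "related"
UNRELATED = "unrelated"

RateKey = tuple[str, float, str]  # (case type, threshold, arm)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class CaseloadModel:
    """Inputs of the false-interpretation projection."""

    total_cases: int
    related_fraction: float
    casetype_mix: Mapping[str, float]
    lab_threshold_mix: Mapping[str, Mapping[float, float]]
    rates: Mapping[RateKey, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "casetype_mix", dict(self.casetype_mix))
        object.__setattr__(
            self,
            "lab_threshold_mix",
            {ct: dict(mix) for ct, mix in self.lab_threshold_mix.items()},
        )
        object.__setattr__(self, "rates", dict(self.rates))
        if self.total_cases < 0:
            raise ValueError("total_cases must be >= 0")
        if not 0 <= self.related_fraction <= 1:
            raise ValueError(
                f"related_fraction must be in [0, 1], got {self.related_fraction}"
            )
        mix_sum = sum(self.casetype_mix.values())
        if self.casetype_mix and abs(mix_sum - 1.0) > 1e-9:
            raise ValueError(f"casetype_mix sums to {mix_sum}, expected 1")
        for ct, mix in self.lab_threshold_mix.items():
            if ct not in self.casetype_mix:
                raise ValueError(f"lab_threshold_mix for unknown case type {ct!r}")
            if sum(mix.values()) > 1 + 1e-9:
                # labs reporting LR only (no threshold) make up the remainder
                raise ValueError(f"lab fractions for {ct!r} sum above 1")

    def with_rates(self, rates: Mapping[RateKey, float]) -> "CaseloadModel":
        return CaseloadModel(
            self.total_cases,
            self.related_fraction,
            self.casetype_mix,
            self.lab_threshold_mix,
            rates,
        )


@dataclass(frozen=True)
class FalseCountRow:
    case_type: str
    arm: str
    threshold: float
    lab_fraction: float
    false_rate: float
    unrounded: float
    count: int


@dataclass(frozen=True)
class FalseCountTable:
    """Projected false-interpretation counts, one row per model cell."""

    rows: tuple[FalseCountRow, ...]

    @property
    def total_unrounded(self) -> float:
        return sum(r.unrounded for r in self.rows)

    @property
    def grand_total(self) -> int:
        """Sum of unrounded cell values, rounded once at the end."""
        return _round_half_away(self.total_unrounded)

    @property
    def sum_of_rounded_rows(self) -> int:
        """Sum of the per-row rounded counts (what a printed table adds to)."""
        return sum(r.count for r in self.rows)

    def counts(self) -> list[int]:
        return [r.count for r in self.rows]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "case_type": r.case_type,
                    "arm": r.arm,
                    "threshold": r.threshold,
                    "lab_fraction": r.lab_fraction,
                    "false_rate": r.false_rate,
                    "expected_count": r.count,
                    "unrounded": r.unrounded,
                }
                for r in self.rows
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def expected_false_count(
    n_type: float, arm_fraction: float, lab_fraction: float, false_rate: float
) -> tuple[float, int]:
    """One projection cell: n_type x arm x lab share x rate.

    Returns (unrounded value, count rounded half away from zero).
    """
    for name, v in (
        ("n_type", n_type),
        ("arm_fraction", arm_fraction),
        ("lab_fraction", lab_fraction),
        ("false_rate", false_rate),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    for name, v in (
        ("arm_fraction", arm_fraction),
        ("lab_fraction", lab_fraction),
        ("false_rate", false_rate),
    ):
        if v > 1:
            raise ValueError(f"{name} must be <= 1, got {v}")
    unrounded = n_type * arm_fraction * lab_fraction * false_rate
    return unrounded, _round_half_away(unrounded)


def project(model: CaseloadModel) -> FalseCountTable:
    """Expected false-interpretation counts for every model cell.

    Rows are ordered related arm first (false negatives), then the
    unrelated arm (false positives), case types in mix order,
    thresholds ascending within a case type.
    """
    rows: list[FalseCountRow] = []
    for arm in (RELATED, UNRELATED):
        arm_fraction = (
            model.related_fraction if arm == RELATED else 1.0 - model.related_fraction
        )
        for case_type, type_share in model.casetype_mix.items():
            n_type = model.total_cases * type_share
            mix = model.lab_threshold_mix.get(case_type, {})
            for threshold in sorted(mix):
                key = (case_type, threshold, arm)
                if key not in model.rates:
                    raise KeyError(
                        f"no false rate for case type {case_type!r} at "
                        f"threshold {threshold:g} ({arm} arm)"
                    )
                rate = model.rates[key]
                unrounded, count = expected_false_count(
                    n_type, arm_fraction, mix[threshold], rate
                )
                rows.append(
                    FalseCountRow(
                        case_type, arm, threshold, mix[threshold], rate,
                        unrounded, count,
                    )
                )
    return FalseCountTable(tuple(rows))


def project_from_simulation(
    model: CaseloadModel, rate_tables: Iterable[RateTable]
) -> FalseCountTable:
    """Run the projection with rates taken from simulation output.

    Each RateTable supplies the (relationship, t_incl) cell: its
    fn_rate feeds the related arm and its fp_rate the unrelated arm.
    Missing (case type, threshold) coverage is an error.
    """
    rates: dict[RateKey, float] = {}
    for t in rate_tables:
        rates[(t.relationship, t.policy.t_incl, RELATED)] = t.fn_rate
        rates[(t.relationship, t.policy.t_incl, UNRELATED)] = t.fp_rate
    needed = {
        (ct, thr, arm)
        for ct, mix in model.lab_threshold_mix.items()
        for thr in mix
        for arm in (RELATED, UNRELATED)
    }
    missing = sorted(k for k in needed if k not in rates)
    if missing:
        raise KeyError(f"rate tables do not cover model cell(s): {missing}")
    return project(model.with_rates(rates))


def table1_identifiler() -> CaseloadModel:
    """The published worldwide projection model for the 15-marker panel."""
    return CaseloadModel(
        total_cases=10_000_000,
        related_fraction=0.72,
        casetype_mix={"TRIO": 0.75, "PARENT_CHILD": 0.20, "FULL_SIB": 0.05},
        lab_threshold_mix={
            "TRIO": {100.0: 0.65, 1000.0: 0.35},
            "PARENT_CHILD": {100.0: 0.75, 1000.0: 0.25},
            "FULL_SIB": {100.0: 0.20},
        },
        rates={
            # related arm: false negative rates
            ("TRIO", 100.0, RELATED): 0.00058,
            ("TRIO", 1000.0, RELATED): 0.00284,
            ("PARENT_CHILD", 100.0, RELATED): 0.0114,
            ("PARENT_CHILD", 1000.0, RELATED): 0.0767,
            ("FULL_SIB", 100.0, RELATED): 0.2082,
            # unrelated arm: false positive rates
            ("TRIO", 100.0, UNRELATED): 0.000007,
            ("TRIO", 1000.0, UNRELATED): 0.000002,
            ("PARENT_CHILD", 100.0, UNRELATED): 0.00015,
            ("PARENT_CHILD", 1000.0, UNRELATED): 0.000055,
            ("FULL_SIB", 100.0, UNRELATED): 0.00032,
        },
    )


PRESETS = {"table1_identifiler": table1_identifiler}


def _model_to_doc(model: CaseloadModel) -> dict:
    return {
        "total_cases": model.total_cases,
        "related_fraction": model.related_fraction,
        "casetype_mix": dict(model.casetype_mix),
        "lab_threshold_mix": {
            ct: {float(t): f for t, f in mix.items()}
            for ct, mix in model.lab_threshold_mix.items()
        },
        "rates": [
            {"case_type": ct, "threshold": thr, "arm": arm, "rate": rate}
            for (ct, thr, arm), rate in model.rates.items()
        ],
    }


def write_model(model: CaseloadModel, path: str | Path) -> None:
    """Serialize a model as YAML or JSON (by extension)."""
    doc = _model_to_doc(model)
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(doc))
    else:
        path.write_text(json.dumps(doc, indent=2))


def read_model(path: str | Path) -> CaseloadModel:
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
    rates = {
        (r["case_type"], float(r["threshold"]), r["arm"]): float(r["rate"])
        for r in doc.get("rates", [])
    }
    return CaseloadModel(
        total_cases=int(doc["total_cases"]),
        related_fraction=float(doc["related_fraction"]),
        casetype_mix={k: float(v) for k, v in doc["casetype_mix"].items()},
        lab_threshold_mix={
            ct: {float(t): float(f) for t, f in mix.items()}
            for ct, mix in doc["lab_threshold_mix"].items()
        },
        rates=rates,
    )
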