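"""Multi-indicator model validation.

A calibrated motion-segment model is judged against in-vitro reference
values for several biomechanical indicators — range of motion (RoM),
intradiscal pressure (IDP), facet contact force (FCF) and disc compression
(DC) — each under its own load case.  For every computed entry the report
carries the percent accuracy (same statistic as calibration) and, when the
reference supplies a standard deviation, whether the computed value lies
strictly within one SD of the reference mean.

The overall verdict accepts an indicator that misses the accuracy floor as
long as it stays within one SD of the in-vitro mean — a sub-floor accuracy
inside the experimental scatter is evidence of agreement, not failure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .calibration import accuracy
from .exceptions import MappingError

__all__ = [
    "ReferenceValue",
    "ComputedValue",
    "ValidationReport",
    "validate",
    "load_references",
    "write_references",
    "DEFAULT_ACCURACY_FLOOR",
]

#: Default accuracy floor (percent): validation aims for >90% per indicator.
DEFAULT_ACCURACY_FLOOR = 90.0

INDICATORS = {"RoM", "IDP", "FCF", "DC"}


@dataclass(frozen=True)
class ReferenceValue:
    """One in-vitro reference: indicator mean (and optional SD) for a
    direction and load case."""

    indicator: str
    direction: str  # flexion, extension, left/right bending or axial rotation, n/a
    load_case: str
    mean: float
    sd: float | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.indicator not in INDICATORS:
            raise ValueError(f"unknown indicator {self.indicator!r}")
        if self.sd is not None and self.sd < 0:
            raise ValueError("SD must be nonnegative")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.indicator, self.direction, self.load_case)


@dataclass(frozen=True)
class ComputedValue:
    indicator: str
    direction: str
    load_case: str
    value: float

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.indicator, self.direction, self.load_case)


@dataclass(frozen=True)
class ValidationReport:
    entries: pd.DataFrame  # indicator, direction, load_case, computed, reference_mean,
    #          reference_sd, accuracy_percent, within_one_sd, acceptable
    accuracy_floor: float
    overall_pass: bool

    def to_dict(self) -> dict:
        entries = self.entries.copy()
        entries["within_one_sd"] = entries["within_one_sd"].astype(object).where(
            entries["within_one_sd"].notna(), None
        )
        return {
            "accuracy_floor": self.accuracy_floor,
            "overall_pass": bool(self.overall_pass),
            "entries": entries.to_dict(orient="records"),
        }


def validate(
    computed: Sequence[ComputedValue | tuple],
    references: Sequence[ReferenceValue],
    accuracy_floor: float = DEFAULT_ACCURACY_FLOOR,
) -> ValidationReport:
    """Score computed indicator values against in-vitro references.

    Every computed entry must have a reference with the same
    (indicator, direction, load case) key; an orphan raises
    :class:`MappingError` naming it.  An entry is acceptable when its
    accuracy reaches the floor, or — failing that — when it lies strictly
    within one SD of the reference mean; the report passes overall iff every
    entry is acceptable.
    """
    comp = [c if isinstance(c, ComputedValue) else ComputedValue(*c) for c in computed]
    ref_map = {r.key: r for r in references}
    orphans = [c.key for c in comp if c.key not in ref_map]
    if orphans:
        raise MappingError(f"computed entries without a matching reference: {orphans}")
    rows = []
    for c in comp:
        ref = ref_map[c.key]
        acc = accuracy(c.value, ref.mean)
        within = None if ref.sd is None else bool(abs(c.value - ref.mean) < ref.sd)
        acceptable = acc >= accuracy_floor or within is True
        rows.append(
            {
                "indicator": c.indicator,
                "direction": c.direction,
                "load_case": c.load_case,
                "computed": c.value,
                "reference_mean": ref.mean,
                "reference_sd": ref.sd,
                "units": ref.units,
                "accuracy_percent": acc,
                "within_one_sd": within,
                "acceptable": acceptable,
            }
        )
    entries = pd.DataFrame(rows)
    overall = bool(entries["acceptable"].all()) if len(entries) else True
    return ValidationReport(entries=entries, accuracy_floor=accuracy_floor, overall_pass=overall)


def load_references(path: str | Path) -> list[ReferenceValue]:
    """Read a reference table from JSON: a list of objects with keys
    indicator, direction, load_case, mean, and optional sd, units."""
    with open(path) as fh:
        raw = json.load(fh)
    return [
        ReferenceValue(
            indicator=r["indicator"],
            direction=r.get("direction", "n/a"),
            load_case=r["load_case"],
            mean=float(r["mean"]),
            sd=None if r.get("sd") is None else float(r["sd"]),
            units=r.get("units", ""),
        )
        for r in raw
    ]


def write_references(references: Sequence[ReferenceValue], path: str | Path) -> None:
    payload = [
        {
            "indicator": r.indicator,
            "direction": r.direction,
            "load_case": r.load_case,
            "mean": r.mean,
            "sd": r.sd,
            "units": r.units,
        }
        for r in references
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
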