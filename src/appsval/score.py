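"""Cutoff-table point scores over the three APPS predictors.

The APPS sums 1–3 points for each of age (years), PaO2/FiO2 ratio (mmHg)
and maximal airway pressure Pmax (cmH2O, standing in for plateau pressure
under pressure-controlled ventilation), for a total of 3–9.  This module
represents such scores as explicit band tables so that both the original
cutoffs and recalibrated variants are instances of one mechanism, and so
that cutoff conventions at the printed band boundaries stay configurable.

Boundary convention for the builtin definitions: a printed dash range such
as "47–66" is the closed interval [47, 66]; "<47" is (-inf, 47) and ">66"
is (66, inf).  Raw (non-integer) predictor values are banded directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "SCORE_VARIABLES",
    "RISK_DIRECTION",
    "VariableBand",
    "ScoreDefinition",
    "ScoredRecord",
    "ScoreError",
    "ScoringError",
    "builtin_definition",
    "three_band_definition",
    "score_record",
    "score_cohort",
]

#: Predictor columns a score definition bands, in canonical order.
SCORE_VARIABLES = ("age", "pf_ratio", "pmax")

#: +1 when higher values carry more risk (age, Pmax); -1 when lower values
#: do (PaO2/FiO2).
RISK_DIRECTION = {"age": +1, "pf_ratio": -1, "pmax": +1}

_MIN_TOTAL = 3
_MAX_TOTAL = 9


class ScoreError(ValueError):
    """Invalid score definition or unknown builtin key."""


class ScoringError(ValueError):
    """One or more records could not be scored.

    Attributes
    ----------
    failures : list of (record_id, message)
        Every offending record, so callers can report them all at once.
    """

    def __init__(self, failures: Sequence[tuple[str, str]]):
        self.failures = list(failures)
        detail = "; ".join(f"{rid}: {msg}" for rid, msg in self.failures)
        super().__init__(f"{len(self.failures)} record(s) failed scoring: {detail}")


@dataclass(frozen=True)
class VariableBand:
    """Half-open-or-closed interval of one predictor mapped to a point value."""

    variable: str
    lower: float
    upper: float
    lower_closed: bool
    upper_closed: bool
    points: int

    def __post_init__(self) -> None:
        if self.variable not in SCORE_VARIABLES:
            raise ScoreError(
                f"unknown score variable {self.variable!r}; expected one of {SCORE_VARIABLES}"
            )
        if self.points not in (1, 2, 3):
            raise ScoreError(f"band points must be 1, 2 or 3, got {self.points}")
        if not self.lower < self.upper:
            raise ScoreError(
                f"band for {self.variable} has empty interval ({self.lower}, {self.upper})"
            )

    def contains(self, value: float) -> bool:
        above = value >= self.lower if self.lower_closed else value > self.lower
        below = value <= self.upper if self.upper_closed else value < self.upper
        return above and below


@dataclass(frozen=True)
class ScoreDefinition:
    """A named 3-variable cutoff-table score with three bands per variable."""

    name: str
    bands: tuple[VariableBand, ...]

    def __post_init__(self) -> None:
        per_var: dict[str, list[VariableBand]] = {v: [] for v in SCORE_VARIABLES}
        for band in self.bands:
            per_var[band.variable].append(band)
        for var, var_bands in per_var.items():
            if len(var_bands) != 3:
                raise ScoreError(
                    f"definition {self.name!r}: variable {var} has {len(var_bands)} bands, expected 3"
                )
            _check_partition(self.name, var, var_bands)
            _check_monotone(self.name, var, var_bands)

    def bands_for(self, variable: str) -> tuple[VariableBand, ...]:
        """Bands of one variable ordered by increasing points."""
        return tuple(
            sorted((b for b in self.bands if b.variable == variable), key=lambda b: b.points)
        )

    def points_for(self, variable: str, value: float) -> int:
        if not math.isfinite(value):
            raise ScoreError(f"non-finite {variable} value {value!r}")
        for band in self.bands_for(variable):
            if band.contains(value):
                return band.points
        raise ScoreError(  # pragma: no cover - partition check makes this unreachable
            f"definition {self.name!r}: no band of {variable} contains {value}"
        )

    # -- serialization -----------------------------------------------------

    def to_mapping(self) -> dict:
        out: dict = {"name": self.name, "variables": {}}
        for var in SCORE_VARIABLES:
            rows = []
            for b in self.bands_for(var):
                row: dict = {"points": int(b.points)}
                if math.isfinite(b.lower):
                    row["lower"] = float(b.lower)
                    row["lower_closed"] = bool(b.lower_closed)
                if math.isfinite(b.upper):
                    row["upper"] = float(b.upper)
                    row["upper_closed"] = bool(b.upper_closed)
                rows.append(row)
            out["variables"][var] = rows
        return out

    @classmethod
    def from_mapping(cls, data: Mapping) -> "ScoreDefinition":
        bands = []
        for var, rows in data["variables"].items():
            for row in rows:
                bands.append(
                    VariableBand(
                        variable=var,
                        lower=float(row.get("lower", -math.inf)),
                        upper=float(row.get("upper", math.inf)),
                        lower_closed=bool(row.get("lower_closed", False)),
                        upper_closed=bool(row.get("upper_closed", False)),
                        points=int(row["points"]),
                    )
                )
        return cls(name=str(data["name"]), bands=tuple(bands))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_mapping(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScoreDefinition":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))


def _check_partition(name: str, var: str, bands: Iterable[VariableBand]) -> None:
    """Bands must tile the real line: ordered, non-overlapping, exhaustive."""
    ordered = sorted(bands, key=lambda b: (b.lower, b.upper))
    if not math.isinf(ordered[0].lower) or not math.isinf(ordered[-1].upper):
        raise ScoreError(f"definition {name!r}: {var} bands do not cover the real line")
    for left, right in zip(ordered, ordered[1:]):
        if left.upper != right.lower:
            raise ScoreError(
                f"definition {name!r}: {var} bands leave a gap or overlap between "
                f"{left.upper} and {right.lower}"
            )
        if left.upper_closed == right.lower_closed:
            raise ScoreError(
                f"definition {name!r}: {var} boundary {left.upper} is "
                f"{'claimed by both' if left.upper_closed else 'claimed by neither'} adjacent band"
            )


def _check_monotone(name: str, var: str, bands: Iterable[VariableBand]) -> None:
    """Points must increase in the variable's risk direction."""
    ordered = sorted(bands, key=lambda b: (b.lower, b.upper))
    pts = [b.points for b in ordered]
    expected = sorted(pts) if RISK_DIRECTION[var] > 0 else sorted(pts, reverse=True)
    if pts != expected:
        raise ScoreError(
            f"definition {name!r}: {var} points {pts} are not monotone in the risk direction"
        )


def three_band_definition(
    name: str,
    age_cutoffs: tuple[float, float],
    pf_cutoffs: tuple[float, float],
    pmax_cutoffs: tuple[float, float],
) -> ScoreDefinition:
    """Build a definition from one (low, high) cutoff pair per variable.

    For age and Pmax the bands are ``< low`` (1 pt), ``[low, high]`` (2 pts),
    ``> high`` (3 pts); for PaO2/FiO2 the risk direction flips, so
    ``> high`` scores 1 and ``< low`` scores 3.
    """
    bands: list[VariableBand] = []
    for var, (low, high) in (
        ("age", age_cutoffs),
        ("pf_ratio", pf_cutoffs),
        ("pmax", pmax_cutoffs),
    ):
        if not low < high:
            raise ScoreError(f"{var} cutoffs must satisfy low < high, got {low}, {high}")
        if RISK_DIRECTION[var] > 0:
            pts = (1, 2, 3)
        else:
            pts = (3, 2, 1)
        bands.append(VariableBand(var, -math.inf, low, False, False, pts[0]))
        bands.append(VariableBand(var, low, high, True, True, pts[1]))
        bands.append(VariableBand(var, high, math.inf, False, False, pts[2]))
    return ScoreDefinition(name=name, bands=tuple(bands))


#: Cutoff pairs of the two builtin definitions.  "original" is the score as
#: first published (age 47/66, P/F 105/158, Pmax 27/30); "recalibrated"
#: moves the age cutoffs to 47/59 and the Pmax cutoffs to 30/33, leaving
#: P/F untouched.
BUILTIN_CUTOFFS = {
    "original": {"age": (47.0, 66.0), "pf_ratio": (105.0, 158.0), "pmax": (27.0, 30.0)},
    "recalibrated": {"age": (47.0, 59.0), "pf_ratio": (105.0, 158.0), "pmax": (30.0, 33.0)},
}


def builtin_definition(which: str) -> ScoreDefinition:
    """Load a packaged score definition ("original" or "recalibrated")."""
    if which not in BUILTIN_CUTOFFS:
        raise ScoreError(
            f"unknown builtin definition {which!r}; valid keys: {sorted(BUILTIN_CUTOFFS)}"
        )
    ref = resources.files("appsval") / "definitions" / f"{which}.yaml"
    with ref.open("r", encoding="utf-8") as fh:
        return ScoreDefinition.from_mapping(yaml.safe_load(fh))


@dataclass(frozen=True)
class ScoredRecord:
    """A patient record with its per-variable points and 3–9 total."""

    record: "PatientRecord"  # noqa: F821 - forward ref to cohort module
    component_points: tuple[int, int, int]  # (age, pf_ratio, pmax)
    total: int

    def __post_init__(self) -> None:
        if self.total != sum(self.component_points):
            raise ScoreError("total does not equal the sum of component points")
        if not _MIN_TOTAL <= self.total <= _MAX_TOTAL:
            raise ScoreError(f"total {self.total} outside {_MIN_TOTAL}–{_MAX_TOTAL}")


def score_record(record, definition: ScoreDefinition) -> ScoredRecord:
    values = {}
    for var in SCORE_VARIABLES:
        value = getattr(record, var)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise ScoringError([(record.id, f"missing required predictor {var!r}")])
        values[var] = float(value)
    pts = tuple(definition.points_for(var, values[var]) for var in SCORE_VARIABLES)
    return ScoredRecord(record=record, component_points=pts, total=sum(pts))


def score_cohort(cohort: Sequence, definition: ScoreDefinition) -> list[ScoredRecord]:
    """Score every record, preserving order; abort listing all failures."""
    scored: list[ScoredRecord] = []
    failures: list[tuple[str, str]] = []
    for record in cohort:
        try:
            scored.append(score_record(record, definition))
        except ScoringError as exc:
            failures.extend(exc.failures)
    if failures:
        raise ScoringError(failures)
    return scored
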