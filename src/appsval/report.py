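"""Full validation report: cohort summary, discrimination, calibration,
stratum tables and stratified survival per score definition.

``run_validation`` is deterministic for a given cohort and options, and
every number in the report is taken verbatim from the module that
computed it.  The machine-readable form is canonical JSON (sorted keys),
so identical inputs produce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from typing import Mapping, Optional, Sequence

from .association import stratify_cohort
from .calibration import SeparationError, calibration_table
from .cohort import PatientRecord, read_cohort  # noqa: F401  (re-exported cohort I/O)
from .discrimination import DiscriminationError, roc_analysis
from .score import SCORE_VARIABLES, ScoreDefinition, score_cohort
from .survival import (
    DEFAULT_CATEGORY_EDGES,
    RECALIBRATED_CATEGORY_EDGES,
    km_estimate,
    logrank,
    stratify_by_category,
)

__all__ = [
    "ValidationOptions",
    "ValidationReport",
    "sensitivity_subset",
    "run_validation",
]

try:
    _VERSION = _pkg_version("appsval")
except PackageNotFoundError:  # pragma: no cover - source tree without install
    _VERSION = "unknown"


@dataclass(frozen=True)
class ValidationOptions:
    """Options controlling a validation run (hashed into provenance)."""

    sensitivity: bool = False
    fio2_unit: str = "percent"  # "percent" (0-100) or "fraction" (0-1)
    trend_method: str = "cochran_armitage"
    hl_grouping: str = "score"
    category_edges: Mapping[str, Sequence[tuple[int, int]]] = field(
        default_factory=lambda: {
            "original": DEFAULT_CATEGORY_EDGES,
            "recalibrated": RECALIBRATED_CATEGORY_EDGES,
        }
    )
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.fio2_unit not in ("percent", "fraction"):
            raise ValueError(
                "fio2 unit must be declared explicitly as 'percent' or 'fraction'"
            )

    def config_hash(self) -> str:
        payload = {
            "sensitivity": self.sensitivity,
            "fio2_unit": self.fio2_unit,
            "trend_method": self.trend_method,
            "hl_grouping": self.hl_grouping,
            "category_edges": {k: [list(e) for e in v] for k, v in sorted(self.category_edges.items())},
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def sensitivity_subset(
    cohort: Sequence[PatientRecord], fio2_unit: str = "percent"
) -> tuple[list[PatientRecord], int]:
    """Patients under standardized ventilation: PEEP >= 10 and FiO2 >= 50 %.

    Records missing either setting are excluded; their count is returned
    alongside the subset.  ``fio2_unit`` must state how FiO2 is recorded
    ("percent": 0–100, threshold 50; "fraction": 0–1, threshold 0.5) —
    it is never guessed from the data.
    """
    if fio2_unit == "percent":
        fio2_threshold = 50.0
    elif fio2_unit == "fraction":
        fio2_threshold = 0.5
    else:
        raise ValueError(f"fio2_unit must be 'percent' or 'fraction', got {fio2_unit!r}")
    subset: list[PatientRecord] = []
    n_missing = 0
    for rec in cohort:
        if rec.peep is None or rec.fio2 is None:
            n_missing += 1
            continue
        if rec.peep >= 10.0 and rec.fio2 >= fio2_threshold:
            subset.append(rec)
    return subset, n_missing


@dataclass(frozen=True)
class ValidationReport:
    """Assembled report; see ``to_json`` / ``to_text``."""

    payload: Mapping

    def to_json(self) -> str:
        return json.dumps(self.payload, sort_keys=True, indent=2, allow_nan=False)

    def to_text(self) -> str:
        p = self.payload
        lines = [
            "APPS validation report",
            "======================",
            f"Cohort: n={p['cohort_summary']['n']}, deaths={p['cohort_summary']['deaths']}, "
            f"mortality={p['cohort_summary']['mortality_pct']:.0f}%",
        ]
        if "sensitivity_subset" in p:
            s = p["sensitivity_subset"]
            lines.append(
                f"Sensitivity subset (PEEP>=10, FiO2>=50%): n={s['n']} "
                f"({s['excluded_missing']} excluded for missing settings)"
            )
        for name, block in sorted(p["definitions"].items()):
            lines.append("")
            lines.append(f"[{name}]")
            roc = block["discrimination"]
            if "error" in roc:
                lines.append(f"  discrimination: unavailable ({roc['error']})")
            else:
                lines.append(
                    f"  ROC {roc['auc']:.2f} (CI {roc['auc_ci95'][0]:.2f}-{roc['auc_ci95'][1]:.2f}) "
                    f"cutoff {roc['cutoff']:.1f} sens {roc['sens']:.2f} spec {roc['spec']:.2f} "
                    f"LR+ {roc['lr_pos']:.2f} LR- {roc['lr_neg']:.2f}"
                )
            cal = block["calibration"]
            if "error" in cal:
                lines.append(f"  calibration: unavailable ({cal['error']})")
            else:
                lines.append(
                    f"  Hosmer-Lemeshow chi2 {cal['hl_statistic']:.2f} "
                    f"(df {cal['hl_df']}) p {cal['hl_p']:.3f}"
                )
            for var, table in sorted(block["strata"].items()):
                ors = ", ".join(
                    "ref" if o is None else f"{o['point']:.2f} ({o['lower95']:.2f}-{o['upper95']:.2f})"
                    for o in table["odds_ratios"]
                )
                lines.append(f"  {var}: OR {ors}; P trend {table['p_trend']:.4f}")
            surv = block.get("survival")
            if surv:
                if "error" in surv:
                    lines.append(f"  survival: unavailable ({surv['error']})")
                else:
                    lines.append(
                        f"  log-rank chi2 {surv['logrank']['statistic']:.2f} "
                        f"(df {surv['logrank']['df']}) p {surv['logrank']['p']:.4f} "
                        f"across {', '.join(sorted(surv['curves']))}"
                    )
        prov = p["provenance"]
        lines.append("")
        lines.append(
            f"provenance: version {prov['version']}, config {prov['config_hash'][:12]}, "
            f"seed {prov['seed']}"
        )
        return "\n".join(lines)


def _roc_block(scored) -> dict:
    scores = [s.total for s in scored]
    outcomes = [s.record.died_in_hospital for s in scored]
    try:
        roc = roc_analysis(scores, outcomes)
    except DiscriminationError as exc:
        return {"error": f"discrimination: {exc}"}
    return {
        "auc": roc.auc,
        "auc_ci95": list(roc.auc_ci95),
        "cutoff": roc.chosen_cutoff,
        "sens": roc.sens_at_cutoff,
        "spec": roc.spec_at_cutoff,
        "lr_pos": roc.lr_pos if math.isfinite(roc.lr_pos) else None,
        "lr_neg": roc.lr_neg if math.isfinite(roc.lr_neg) else None,
        "youden_tied": roc.youden_tied,
    }


def _calibration_block(scored, grouping: str) -> dict:
    try:
        cal = calibration_table(scored, grouping=grouping)
    except (SeparationError, ValueError) as exc:
        return {"error": f"calibration: {exc}"}
    return {
        "groups": cal.to_rows(),
        "hl_statistic": cal.hl_statistic,
        "hl_df": cal.hl_df,
        "hl_p": cal.hl_p,
        "model_intercept": cal.model_intercept,
        "model_slope": cal.model_slope,
    }


def _strata_block(scored, definition, trend_method: str) -> dict:
    out = {}
    for var in SCORE_VARIABLES:
        table = stratify_cohort(scored, var, definition, trend_method=trend_method)
        out[var] = {
            "strata": [
                {"label": s.label, "n": s.n, "deaths": s.deaths}
                for s in table.strata
            ],
            "odds_ratios": [
                None
                if o is None
                else {"point": o.point, "lower95": o.lower95, "upper95": o.upper95}
                for o in table.odds_ratios
            ],
            "p_trend": table.p_trend.p,
            "flags": list(table.flags),
        }
    return out


def _survival_block(scored, edges) -> Optional[dict]:
    with_followup = [s for s in scored if s.record.followup_days is not None]
    if not with_followup:
        return None
    try:
        strata, flags = stratify_by_category(with_followup, edges)
        if len(strata) < 2:
            return {"error": "survival: fewer than two occupied score categories"}
        lr = logrank(strata)
        curves = {
            label: km_estimate(times, events, label=label)
            for label, (times, events) in strata.items()
        }
    except ValueError as exc:
        return {"error": f"survival: {exc}"}
    return {
        "logrank": {"statistic": lr.statistic, "df": lr.df, "p": lr.p},
        "curves": {
            label: {
                "times": list(c.times),
                "survival": list(c.survival_prob),
                "at_risk": list(c.at_risk),
            }
            for label, c in curves.items()
        },
        "flags": flags,
    }


def run_validation(
    cohort: Sequence[PatientRecord],
    definitions: Mapping[str, ScoreDefinition],
    options: ValidationOptions = ValidationOptions(),
) -> ValidationReport:
    """Assemble the full validation report over one or more definitions."""
    if not cohort:
        raise ValueError("empty cohort")
    working = list(cohort)
    payload: dict = {}
    if options.sensitivity:
        working, n_missing = sensitivity_subset(working, fio2_unit=options.fio2_unit)
        payload["sensitivity_subset"] = {"n": len(working), "excluded_missing": n_missing}
        if not working:
            raise ValueError("sensitivity subset is empty")

    deaths = sum(r.died_in_hospital for r in working)
    payload["cohort_summary"] = {
        "n": len(working),
        "deaths": deaths,
        "mortality_pct": 100.0 * deaths / len(working),
    }
    payload["definitions"] = {}
    for name, definition in definitions.items():
        scored = score_cohort(working, definition)
        edges = options.category_edges.get(name, DEFAULT_CATEGORY_EDGES)
        block = {
            "discrimination": _roc_block(scored),
            "calibration": _calibration_block(scored, options.hl_grouping),
            "strata": _strata_block(scored, definition, options.trend_method),
        }
        surv = _survival_block(scored, edges)
        if surv is not None:
            block["survival"] = surv
        payload["definitions"][name] = block
    payload["provenance"] = {
        "version": _VERSION,
        "config_hash": options.config_hash(),
        "seed": options.seed,
    }
    return ValidationReport(payload=payload)
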