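"""Score-level calibration (Hosmer–Lemeshow) and cutoff recalibration.

Calibration is assessed on the integer score levels 3–9: observed deaths
per level are compared with the deaths expected under a univariate
logistic model of death on the score (the reference analysis plots
per-score mortality bars, so score-level grouping is the default;
deciles-of-risk grouping is available).  The Hosmer–Lemeshow statistic is

    H = sum_g (O_g - E_g)^2 / (E_g (1 - E_g / n_g)),

referred to a chi-square with (#groups - 2) degrees of freedom.

``recalibrate`` automates the manual recalibration step: an exhaustive
grid search over ordered cutoff pairs of the tuned variables (age and
Pmax by default; P/F cutoffs are left alone), subject to every band
holding at least 5 % of the cohort and band mortality non-decreasing in
points.  The objective is calibration-first, discrimination-second:
among candidates whose HL p clears an acceptance level (default 0.05),
the one with the highest AUC wins (AUCs within a small tie band count as
equal and resolve toward the base cutoffs); if no candidate calibrates
acceptably, the HL p itself is maximized.  The HL p is a goodness-of-fit
p-value: beyond showing no detectable miscalibration it is noise, and
maximizing it directly cannot identify cutoffs — the per-candidate
logistic refit absorbs banding shifts, so the p at the true cutoffs is
uniformly distributed while the AUC is sharply maximized there.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import chi2

from .discrimination import _delong_components
from .score import (
    SCORE_VARIABLES,
    ScoreDefinition,
    ScoredRecord,
    three_band_definition,
)

__all__ = [
    "CalibrationGroup",
    "CalibrationResult",
    "RecalibrationOutcome",
    "SearchEntry",
    "SeparationError",
    "FeasibilityError",
    "fit_score_logistic",
    "calibration_table",
    "hosmer_lemeshow",
    "recalibrate",
]

#: Grid step of the cutoff search, per variable (years / mmHg / cmH2O).
GRID_STEPS = {"age": 1.0, "pf_ratio": 5.0, "pmax": 1.0}
_MIN_BAND_FRACTION = 0.05
_TIE_TOL = 1e-9


class SeparationError(RuntimeError):
    """Logistic fit failed (complete separation or non-convergence)."""


class FeasibilityError(ValueError):
    """No cutoff pair satisfies the recalibration constraints."""


@dataclass(frozen=True)
class CalibrationGroup:
    score: float
    n: int
    observed: int
    expected: float

    def __post_init__(self) -> None:
        if not 0 <= self.observed <= self.n:
            raise ValueError("observed deaths outside [0, n]")
        if not 0 <= self.expected <= self.n:
            raise ValueError("expected deaths outside [0, n]")


@dataclass(frozen=True)
class CalibrationResult:
    groups: tuple[CalibrationGroup, ...]
    hl_statistic: float
    hl_df: int
    hl_p: float
    model_intercept: float
    model_slope: float
    grouping: str = "score"

    @property
    def n_total(self) -> int:
        return sum(g.n for g in self.groups)

    def to_rows(self) -> list[dict]:
        """Plot-ready per-group rows (observed vs expected mortality %)."""
        return [
            {
                "score": g.score,
                "n": g.n,
                "observed_pct": 100.0 * g.observed / g.n,
                "expected_pct": 100.0 * g.expected / g.n,
            }
            for g in self.groups
        ]


def fit_score_logistic(totals: np.ndarray, died: np.ndarray) -> tuple[float, float]:
    """Fit P(death) = expit(a + b * score) on aggregated score levels."""
    totals = np.asarray(totals, dtype=float)
    died = np.asarray(died, dtype=bool)
    levels, inverse = np.unique(totals, return_inverse=True)
    if levels.size < 2:
        raise SeparationError("needs at least two distinct score levels")
    n_g = np.bincount(inverse)
    d_g = np.bincount(inverse, weights=died.astype(float))
    endog = np.column_stack([d_g, n_g - d_g])
    exog = sm.add_constant(levels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(maxiter=100)
    a, b = float(res.params[0]), float(res.params[1])
    fitted = res.predict(exog)
    degenerate_fit = np.any(fitted < 1e-9) or np.any(fitted > 1 - 1e-9)
    if (
        not getattr(res, "converged", True)
        or abs(b) > 30
        or not np.isfinite([a, b]).all()
        or degenerate_fit
    ):
        raise SeparationError(
            "logistic fit of death on score is degenerate "
            f"(slope {b!r}); the score levels may be completely separated"
        )
    return a, b


def hosmer_lemeshow(
    n: np.ndarray, observed: np.ndarray, expected: np.ndarray
) -> tuple[float, int, float]:
    """HL chi-square over pre-formed groups; df = #groups - 2 (min 1)."""
    n = np.asarray(n, float)
    observed = np.asarray(observed, float)
    expected = np.asarray(expected, float)
    denom = expected * (1.0 - expected / n)
    if np.any(denom <= 0):
        raise ValueError("a group has degenerate expected deaths (0 or n)")
    stat = float(np.sum((observed - expected) ** 2 / denom))
    df = max(int(n.size) - 2, 1)
    p = float(chi2.sf(stat, df))
    return stat, df, max(p, np.finfo(float).tiny)


def calibration_table(
    scored: Sequence[ScoredRecord], grouping: str = "score"
) -> CalibrationResult:
    """Observed vs expected deaths per group plus the HL test.

    ``grouping="score"`` (default) groups by the distinct integer score
    levels actually present; ``grouping="decile"`` groups by deciles of
    fitted risk (with tied quantiles merged).
    """
    totals = np.array([s.total for s in scored], dtype=float)
    died = np.array([s.record.died_in_hospital for s in scored], dtype=bool)
    return _calibration_from_arrays(totals, died, grouping)


def _calibration_from_arrays(
    totals: np.ndarray, died: np.ndarray, grouping: str = "score"
) -> CalibrationResult:
    a, b = fit_score_logistic(totals, died)
    fitted = 1.0 / (1.0 + np.exp(-(a + b * totals)))

    if grouping == "score":
        keys = totals
    elif grouping == "decile":
        edges = np.unique(np.quantile(fitted, np.linspace(0, 1, 11)))
        keys = np.digitize(fitted, edges[1:-1], right=True).astype(float)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    levels, inverse = np.unique(keys, return_inverse=True)
    n_g = np.bincount(inverse)
    o_g = np.bincount(inverse, weights=died.astype(float))
    e_g = np.bincount(inverse, weights=fitted)
    groups = tuple(
        CalibrationGroup(
            score=float(levels[i]), n=int(n_g[i]), observed=int(o_g[i]), expected=float(e_g[i])
        )
        for i in range(levels.size)
    )
    stat, df, p = hosmer_lemeshow(n_g, o_g, e_g)
    return CalibrationResult(
        groups=groups,
        hl_statistic=stat,
        hl_df=df,
        hl_p=p,
        model_intercept=a,
        model_slope=b,
        grouping=grouping,
    )


# ---------------------------------------------------------------------------
# Cutoff-search recalibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SearchEntry:
    variable: str
    low: float
    high: float
    feasible: bool
    hl_p: Optional[float] = None
    auc: Optional[float] = None
    reason: str = ""


@dataclass(frozen=True)
class RecalibrationOutcome:
    definition: ScoreDefinition
    achieved_hl_p: float
    base_hl_p: float
    search_log: tuple[SearchEntry, ...] = field(repr=False)
    tuned_variables: tuple[str, ...] = ()
    hl_acceptance: float = 0.05

    def __post_init__(self) -> None:
        # Calibration never ends up worse than both the base definition and
        # the acceptance level: a well-calibrated base stays acceptable, a
        # miscalibrated base is never degraded further.
        if self.achieved_hl_p < min(self.base_hl_p, self.hl_acceptance) - 1e-12:
            raise ValueError("recalibration must not worsen calibration")


def _component_points(variable: str, values: np.ndarray, low: float, high: float):
    if variable == "pf_ratio":
        return 1 + (values <= high).astype(int) + (values < low).astype(int)
    return 1 + (values >= low).astype(int) + (values > high).astype(int)


def _definition_cutoffs(definition: ScoreDefinition) -> dict[str, tuple[float, float]]:
    out = {}
    for var in SCORE_VARIABLES:
        bands = definition.bands_for(var)  # ordered by points
        mid = bands[1]
        out[var] = (mid.lower, mid.upper) if var != "pf_ratio" else (mid.lower, mid.upper)
    return out


def _fast_auc(totals: np.ndarray, died: np.ndarray) -> float:
    v10, _ = _delong_components(totals.astype(float), died)
    return float(v10.mean())


def recalibrate(
    cohort: Sequence,
    base_definition: ScoreDefinition,
    variables_to_tune: Sequence[str] = ("age", "pmax"),
    grouping: str = "score",
    min_band_fraction: float = _MIN_BAND_FRACTION,
    hl_acceptance: float = 0.05,
    auc_tie_tolerance: float = 0.002,
) -> RecalibrationOutcome:
    """Grid-search new cutoff pairs restoring calibration.

    Variables are tuned sequentially in the given order, each by an
    exhaustive search over ordered cutoff pairs drawn from the variable's
    empirical 5th–95th percentile range (steps: 1 y age, 5 mmHg P/F,
    1 cmH2O Pmax; the base pair is always a candidate).  Among candidates
    with HL p >= ``hl_acceptance`` the highest AUC wins; AUCs within
    ``auc_tie_tolerance`` count as tied and resolve toward the cutoffs
    closest to the base definition, then toward lower cutoffs.  If no
    candidate reaches the acceptance level the HL p itself is maximized.
    The result never has an HL p below min(base HL p, acceptance level).
    """
    if not variables_to_tune:
        raise ValueError("at least one variable must be tuned")
    for var in variables_to_tune:
        if var not in SCORE_VARIABLES:
            raise ValueError(f"unknown variable {var!r}")

    values = {
        var: np.array([float(getattr(rec, var)) for rec in cohort])
        for var in SCORE_VARIABLES
    }
    died = np.array([bool(rec.died_in_hospital) for rec in cohort])
    n = died.size
    if n == 0:
        raise ValueError("empty cohort")

    cutoffs = _definition_cutoffs(base_definition)
    base_cutoffs = dict(cutoffs)

    def totals_for(current: dict[str, tuple[float, float]]) -> np.ndarray:
        return sum(
            _component_points(var, values[var], *current[var]) for var in SCORE_VARIABLES
        )

    def evaluate(current) -> tuple[float, float]:
        totals = totals_for(current)
        result = _calibration_from_arrays(totals.astype(float), died, grouping)
        return result.hl_p, _fast_auc(totals, died)

    base_hl_p, _ = evaluate(base_cutoffs)

    log: list[SearchEntry] = []
    for var in variables_to_tune:
        step = GRID_STEPS[var]
        lo_q, hi_q = np.quantile(values[var], [0.05, 0.95])
        grid = np.arange(math.ceil(lo_q / step) * step, hi_q + step / 2, step)
        pairs = {(lo, hi) for i, lo in enumerate(grid) for hi in grid[i + 1 :]}
        pairs.add(base_cutoffs[var])
        feasible: list[tuple[float, float, float, float, float]] = []  # hl, auc, dist, lo, hi
        n_band_fail = n_mono_fail = 0
        for low, high in sorted(pairs):
            pts = _component_points(var, values[var], low, high)
            counts = np.bincount(pts, minlength=4)[1:]
            if counts.min() < min_band_fraction * n:
                n_band_fail += 1
                log.append(
                    SearchEntry(var, low, high, False, reason="band below minimum size")
                )
                continue
            rates = [died[pts == k].mean() for k in (1, 2, 3)]
            if not (rates[0] <= rates[1] + 1e-12 and rates[1] <= rates[2] + 1e-12):
                n_mono_fail += 1
                log.append(
                    SearchEntry(var, low, high, False, reason="band mortality not monotone")
                )
                continue
            trial = dict(cutoffs)
            trial[var] = (low, high)
            try:
                hl_p, auc = evaluate(trial)
            except SeparationError as exc:
                log.append(SearchEntry(var, low, high, False, reason=str(exc)))
                continue
            log.append(SearchEntry(var, low, high, True, hl_p=hl_p, auc=auc))
            dist = abs(low - base_cutoffs[var][0]) + abs(high - base_cutoffs[var][1])
            feasible.append((hl_p, auc, dist, low, high))
        if not feasible:
            raise FeasibilityError(
                f"no feasible cutoff pair for {var}: "
                f"{n_band_fail} candidates violated the minimum band size, "
                f"{n_mono_fail} violated mortality monotonicity"
            )
        acceptable = [c for c in feasible if c[0] >= hl_acceptance]
        if acceptable:
            best_auc = max(c[1] for c in acceptable)
            tied = [c for c in acceptable if c[1] >= best_auc - auc_tie_tolerance]
            best = min(tied, key=lambda c: (c[2], c[3], c[4]))
        else:
            best_hl = max(c[0] for c in feasible)
            tied = [c for c in feasible if c[0] >= best_hl - _TIE_TOL]
            best = min(tied, key=lambda c: (c[2], c[3], c[4]))
        cutoffs[var] = (best[3], best[4])

    achieved_hl_p, _ = evaluate(cutoffs)
    if achieved_hl_p < min(base_hl_p, hl_acceptance):
        # Guard: keep the base cutoffs if the sequential search ended worse.
        cutoffs = base_cutoffs
        achieved_hl_p = base_hl_p

    definition = three_band_definition(
        name=f"{base_definition.name}+recal({','.join(variables_to_tune)})",
        age_cutoffs=cutoffs["age"],
        pf_cutoffs=cutoffs["pf_ratio"],
        pmax_cutoffs=cutoffs["pmax"],
    )
    return RecalibrationOutcome(
        definition=definition,
        achieved_hl_p=achieved_hl_p,
        base_hl_p=base_hl_p,
        search_log=tuple(log),
        tuned_variables=tuple(variables_to_tune),
        hl_acceptance=hl_acceptance,
    )
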