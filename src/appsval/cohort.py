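"""Synthetic ARDS cohorts and patient-level cohort I/O.

The generator emulates the structure of a two-center moderate/severe ARDS
validation cohort: the three score predictors (age, PaO2/FiO2, maximal
airway pressure) are drawn as independent truncated normals matching the
published marginal means/SDs, and hospital death is induced *only* through
the total point score via a logistic model

    P(death | score) = expit(intercept + slope * (score - 6)),

centred at the score midpoint so the intercept is interpretable as the
log-odds of death at score 6.  ``calibrate_spec_to_margins`` inverts this
mechanism: given target per-category death rates it finds the (intercept,
slope) whose closed-form stratum rates reproduce them.

Truncation bounds are the moderate/severe entry criterion and physiologic
plausibility: age 18–100 y, PaO2/FiO2 30–200 mmHg, Pmax 10–50 cmH2O.

Draw order under the single seed (documented so results are reproducible
across versions): age, pf_ratio, pmax, death uniforms, death times,
discharge times, APACHE IV (survivor draw then non-survivor draw), PEEP,
FiO2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .score import SCORE_VARIABLES, ScoreDefinition, builtin_definition, score_cohort

__all__ = [
    "PatientRecord",
    "NormalParams",
    "CohortSpec",
    "CohortValidationError",
    "InfeasibleTargetsError",
    "SchemaError",
    "TRUNCATION_BOUNDS",
    "DEFAULT_MARGINALS",
    "generate_cohort",
    "simulate_scores",
    "calibrate_spec_to_margins",
    "default_spec",
    "write_cohort",
    "read_cohort",
    "COHORT_COLUMNS",
]


class CohortValidationError(ValueError):
    """Invalid cohort spec or record; names the offending field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


class InfeasibleTargetsError(ValueError):
    """Requested stratum death rates cannot be met by the score mechanism."""


class SchemaError(ValueError):
    """Cohort file does not match the expected column schema."""


#: Physiological truncation bounds applied to every generated predictor.
TRUNCATION_BOUNDS = {
    "age": (18.0, 100.0),
    "pf_ratio": (30.0, 200.0),
    "pmax": (10.0, 50.0),
}


@dataclass(frozen=True)
class NormalParams:
    """Marginal mean and SD of one predictor before truncation."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise CohortValidationError("sd", f"must be positive, got {self.sd}")


#: Pooled marginal parameters.  The published survivor/non-survivor arms
#: (age 58.5±15.4 vs 63.1±12.7 at 43 % mortality, P/F 126.8±38.3 vs
#: 127.7±43.1, Pmax 26.2±7.9 vs 28.2±9.4) pool to these marginals.
DEFAULT_MARGINALS = {
    "age": NormalParams(60.5, 14.5),
    "pf_ratio": NormalParams(127.2, 40.4),
    "pmax": NormalParams(27.1, 8.6),
}

_APACHE_ARMS = {False: NormalParams(85.5, 27.0), True: NormalParams(102.7, 30.7)}
_PEEP_PARAMS = NormalParams(10.6, 3.8)
_FIO2_PARAMS = NormalParams(54.7, 14.7)
_DISCHARGE_MEDIAN_DAYS = 14.0
_DISCHARGE_LOG_SD = 0.6


@dataclass(frozen=True)
class PatientRecord:
    """One patient's predictors, outcome and optional follow-up fields.

    Units: age years, pf_ratio mmHg, pmax/peep cmH2O, fio2 percent,
    followup_days days.
    """

    id: str
    age: float
    pf_ratio: float
    pmax: float
    died_in_hospital: bool
    apache_iv: Optional[float] = None
    followup_days: Optional[float] = None
    event_observed: Optional[bool] = None
    peep: Optional[float] = None
    fio2: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.age >= 18:
            raise CohortValidationError("age", f"must be >= 18 y, got {self.age}")
        if not self.pf_ratio > 0:
            raise CohortValidationError("pf_ratio", f"must be positive, got {self.pf_ratio}")
        if not self.pmax > 0:
            raise CohortValidationError("pmax", f"must be positive, got {self.pmax}")
        if self.apache_iv is not None and self.apache_iv < 0:
            raise CohortValidationError("apache_iv", "must be nonnegative")
        if self.followup_days is not None:
            if self.followup_days < 0:
                raise CohortValidationError("followup_days", "must be nonnegative")
            if self.event_observed is None:
                raise CohortValidationError(
                    "event_observed", "required when followup_days is present"
                )
        if (
            self.event_observed is not None
            and self.died_in_hospital
            and not self.event_observed
        ):
            raise CohortValidationError(
                "event_observed", "in-hospital death implies an observed event"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort draw."""

    n_patients: int
    age_params: NormalParams = DEFAULT_MARGINALS["age"]
    pf_params: NormalParams = DEFAULT_MARGINALS["pf_ratio"]
    pmax_params: NormalParams = DEFAULT_MARGINALS["pmax"]
    mortality_intercept: float = float(logit(0.43))
    mortality_slope: float = 0.35
    #: Optional saturated mortality model: P(death | score = 3..9) as seven
    #: probabilities (need not be monotone, e.g. to emulate disturbed
    #: calibration).  When set it overrides the linear intercept/slope
    #: model; death still depends on the record only through its score.
    mortality_levels: Optional[tuple[float, ...]] = None
    overall_mortality_target: Optional[float] = None
    seed: int = 0
    followup_horizon: float = 60.0
    score_definition: str = "original"
    #: Optional explicit definition driving the mortality mechanism (for
    #: planted-cutoff experiments); overrides ``score_definition``.
    custom_definition: Optional[ScoreDefinition] = None
    provenance: Mapping[str, object] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not (isinstance(self.n_patients, (int, np.integer)) and self.n_patients >= 1):
            raise CohortValidationError(
                "n_patients", f"must be a positive integer, got {self.n_patients!r}"
            )
        if self.overall_mortality_target is not None and not (
            0 < self.overall_mortality_target < 1
        ):
            raise CohortValidationError(
                "overall_mortality_target",
                f"must lie in (0, 1), got {self.overall_mortality_target}",
            )
        if not self.followup_horizon > 0:
            raise CohortValidationError("followup_horizon", "must be positive")
        if not math.isfinite(self.mortality_intercept):
            raise CohortValidationError("mortality_intercept", "must be finite")
        if not math.isfinite(self.mortality_slope):
            raise CohortValidationError("mortality_slope", "must be finite")
        if self.mortality_levels is not None:
            levels = np.asarray(self.mortality_levels, dtype=float)
            if levels.shape != (7,):
                raise CohortValidationError(
                    "mortality_levels", "needs one probability per score level 3–9"
                )
            if not np.all((levels > 0) & (levels < 1)):
                raise CohortValidationError("mortality_levels", "must lie in (0, 1)")

    def marginals(self) -> dict[str, NormalParams]:
        return {"age": self.age_params, "pf_ratio": self.pf_params, "pmax": self.pmax_params}

    def definition(self) -> ScoreDefinition:
        if self.custom_definition is not None:
            return self.custom_definition
        return builtin_definition(self.score_definition)

    # -- serialization (plain structured config) ---------------------------

    def to_yaml(self, path) -> None:
        data: dict = {
            "n_patients": int(self.n_patients),
            "marginals": {
                var: {"mean": float(p.mean), "sd": float(p.sd)} for var, p in self.marginals().items()
            },
            "mortality_model": {
                "intercept": float(self.mortality_intercept),
                "slope": float(self.mortality_slope),
            },
            "seed": int(self.seed),
            "followup_horizon": float(self.followup_horizon),
            "score_definition": self.score_definition,
        }
        if self.mortality_levels is not None:
            data["mortality_model"]["levels"] = [float(x) for x in self.mortality_levels]
        if self.overall_mortality_target is not None:
            data["overall_mortality_target"] = float(self.overall_mortality_target)
        if self.custom_definition is not None:
            data["custom_definition"] = self.custom_definition.to_mapping()
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        marg = data.get("marginals", {})
        model = data.get("mortality_model", {})
        kwargs: dict = {"n_patients": int(data["n_patients"])}
        if "age" in marg:
            kwargs["age_params"] = NormalParams(**marg["age"])
        if "pf_ratio" in marg:
            kwargs["pf_params"] = NormalParams(**marg["pf_ratio"])
        if "pmax" in marg:
            kwargs["pmax_params"] = NormalParams(**marg["pmax"])
        if "intercept" in model:
            kwargs["mortality_intercept"] = float(model["intercept"])
        if "slope" in model:
            kwargs["mortality_slope"] = float(model["slope"])
        if model.get("levels") is not None:
            kwargs["mortality_levels"] = tuple(float(x) for x in model["levels"])
        for key in ("overall_mortality_target", "followup_horizon", "score_definition", "seed"):
            if key in data:
                kwargs[key] = data[key]
        if "custom_definition" in data:
            kwargs["custom_definition"] = ScoreDefinition.from_mapping(data["custom_definition"])
        return cls(**kwargs)

    def death_probability(self, total_score: np.ndarray) -> np.ndarray:
        total_score = np.asarray(total_score)
        if self.mortality_levels is not None:
            levels = np.asarray(self.mortality_levels, dtype=float)
            return levels[total_score.astype(int) - 3]
        return expit(
            self.mortality_intercept + self.mortality_slope * (total_score - 6.0)
        )


def default_spec(n_patients: int = 439, seed: int = 0, **overrides) -> CohortSpec:
    """A cohort spec at the study's size and published marginals."""
    return CohortSpec(n_patients=n_patients, seed=seed, **overrides)


def _truncated_draw(rng, params: NormalParams, bounds: tuple[float, float], size: int):
    a = (bounds[0] - params.mean) / params.sd
    b = (bounds[1] - params.mean) / params.sd
    return truncnorm.rvs(a, b, loc=params.mean, scale=params.sd, size=size, random_state=rng)


def _vector_points(definition: ScoreDefinition, variable: str, values: np.ndarray):
    pts = np.zeros(values.size, dtype=int)
    for band in definition.bands_for(variable):
        above = values >= band.lower if band.lower_closed else values > band.lower
        below = values <= band.upper if band.upper_closed else values < band.upper
        pts = np.where(above & below, band.points, pts)
    return pts


def _simulate_core(rng, spec: CohortSpec):
    """Predictors, totals and death indicators in the documented draw order."""
    n = spec.n_patients
    marg = spec.marginals()
    age = _truncated_draw(rng, marg["age"], TRUNCATION_BOUNDS["age"], n)
    pf = _truncated_draw(rng, marg["pf_ratio"], TRUNCATION_BOUNDS["pf_ratio"], n)
    pmax = _truncated_draw(rng, marg["pmax"], TRUNCATION_BOUNDS["pmax"], n)
    definition = spec.definition()
    totals = (
        _vector_points(definition, "age", age)
        + _vector_points(definition, "pf_ratio", pf)
        + _vector_points(definition, "pmax", pmax)
    )
    died = rng.random(n) < spec.death_probability(totals)
    return age, pf, pmax, totals, died


def simulate_scores(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw only (total score, death indicator) pairs for a spec.

    Same predictor and death draws as ``generate_cohort`` under the same
    seed, without materializing patient records — the fast path for
    simulation studies of score-level statistics.
    """
    rng = np.random.default_rng(spec.seed)
    _, _, _, totals, died = _simulate_core(rng, spec)
    return totals, died


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Draw a cohort; identical spec (incl. seed) gives identical output."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    age, pf, pmax, totals, died = _simulate_core(rng, spec)

    # Deaths occur uniformly over (0, horizon]; survivors are censored at a
    # log-normal discharge time capped at the horizon.
    death_times = spec.followup_horizon * (1.0 - rng.random(n))
    discharge = np.minimum(
        rng.lognormal(mean=math.log(_DISCHARGE_MEDIAN_DAYS), sigma=_DISCHARGE_LOG_SD, size=n),
        spec.followup_horizon,
    )
    followup = np.where(died, death_times, discharge)

    apache_surv = _truncated_draw(rng, _APACHE_ARMS[False], (0.0, math.inf), n)
    apache_dead = _truncated_draw(rng, _APACHE_ARMS[True], (0.0, math.inf), n)
    apache = np.where(died, apache_dead, apache_surv)
    peep = _truncated_draw(rng, _PEEP_PARAMS, (0.0, 25.0), n)
    fio2 = _truncated_draw(rng, _FIO2_PARAMS, (21.0, 100.0), n)

    width = max(5, len(str(n)))
    return [
        PatientRecord(
            id=f"P{i:0{width}d}",
            age=float(age[i]),
            pf_ratio=float(pf[i]),
            pmax=float(pmax[i]),
            died_in_hospital=bool(died[i]),
            apache_iv=float(apache[i]),
            followup_days=float(followup[i]),
            event_observed=bool(died[i]),
            peep=float(peep[i]),
            fio2=float(fio2[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Closed-form stratum rates and margin calibration
# ---------------------------------------------------------------------------


def _band_probabilities(
    definition: ScoreDefinition, marginals: Mapping[str, NormalParams]
) -> dict[str, np.ndarray]:
    """P(points = 1, 2, 3) per variable under the truncated-normal marginals."""
    out = {}
    for var in SCORE_VARIABLES:
        lo, hi = TRUNCATION_BOUNDS[var]
        params = marginals[var]
        a = (lo - params.mean) / params.sd
        b = (hi - params.mean) / params.sd
        dist = truncnorm(a, b, loc=params.mean, scale=params.sd)
        probs = []
        for band in definition.bands_for(var):
            lower = max(band.lower, lo)
            upper = min(band.upper, hi)
            probs.append(max(dist.cdf(upper) - dist.cdf(lower), 0.0))
        probs = np.asarray(probs)
        total = probs.sum()
        if total <= 0:
            raise InfeasibleTargetsError(f"no probability mass in any {var} band")
        out[var] = probs / total
    return out


def _rest_score_distribution(band_probs: Mapping[str, np.ndarray], variable: str):
    """Distribution of the other two variables' point sum (support 2..6)."""
    others = [v for v in SCORE_VARIABLES if v != variable]
    dist = np.zeros(7)  # index = sum of two point values, 2..6 used
    for i, pi in enumerate(band_probs[others[0]], start=1):
        for j, pj in enumerate(band_probs[others[1]], start=1):
            dist[i + j] += pi * pj
    return dist


def predicted_stratum_rates(
    intercept: float,
    slope: float,
    band_probs: Mapping[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Exact death rate per variable band implied by the logistic mechanism."""
    levels = expit(intercept + slope * (np.arange(3, 10) - 6.0))
    return predicted_stratum_rates_levels(levels, band_probs)


def predicted_stratum_rates_levels(
    levels: np.ndarray, band_probs: Mapping[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Stratum death rates for a per-score-level mortality table (3..9)."""
    levels = np.asarray(levels, dtype=float)
    rates = {}
    for var in SCORE_VARIABLES:
        rest = _rest_score_distribution(band_probs, var)  # support 2..6
        var_rates = []
        for pts in (1, 2, 3):
            # total = pts + rest, rest index r covers 0..6 with mass on 2..6
            probs = np.array(
                [levels[pts + r - 3] if 2 <= r <= 6 else 0.0 for r in range(7)]
            )
            var_rates.append(float(np.dot(rest, probs)))
        rates[var] = np.asarray(var_rates)
    return rates


def calibrate_spec_to_margins(
    target_stratum_rates: Mapping[str, Sequence[float]],
    *,
    n_patients: int = 100_000,
    seed: int = 0,
    score_definition: str = "original",
    overall_mortality_target: Optional[float] = None,
    tolerance: float = 0.03,
) -> CohortSpec:
    """Find a CohortSpec whose stratum death rates match published margins.

    ``target_stratum_rates`` maps variable names to the (1-pt, 2-pt, 3-pt)
    band death proportions; any subset of the three variables may be given.
    The (intercept, slope) of the logistic mortality model are fitted by
    least squares against the closed-form stratum rates (band occupancies
    from the truncated-normal marginals; no simulation involved), so the
    calibration itself is deterministic.  When the linear-in-score model
    cannot represent the target gradient (published age strata, for
    example, are markedly concave on the logit scale), the fit falls back
    to a saturated monotone per-score-level mortality table, which still
    drives death only through the total score.  Raises when even the
    saturated fit misses any target by more than ``tolerance``.
    """
    if not target_stratum_rates:
        raise CohortValidationError("target_stratum_rates", "at least one variable required")
    for var, rates in target_stratum_rates.items():
        if var not in SCORE_VARIABLES:
            raise CohortValidationError("target_stratum_rates", f"unknown variable {var!r}")
        rates = np.asarray(rates, dtype=float)
        if rates.shape != (3,) or not np.all((rates > 0) & (rates < 1)):
            raise CohortValidationError(
                "target_stratum_rates",
                f"{var}: need three proportions in (0,1), got {list(rates)}",
            )

    definition = builtin_definition(score_definition)
    band_probs = _band_probabilities(definition, DEFAULT_MARGINALS)

    variables = sorted(target_stratum_rates)
    targets = np.concatenate([np.asarray(target_stratum_rates[v], float) for v in variables])

    def residuals(theta):
        rates = predicted_stratum_rates(theta[0], theta[1], band_probs)
        pred = np.concatenate([rates[v] for v in variables])
        res = pred - targets
        if overall_mortality_target is not None:
            overall = _overall_rate(theta[0], theta[1], band_probs)
            res = np.append(res, overall - overall_mortality_target)
        return res

    start = np.array([logit(float(np.mean(targets))), 0.3])
    fit = optimize.least_squares(residuals, start, method="lm")
    intercept, slope = fit.x
    rates = predicted_stratum_rates(intercept, slope, band_probs)
    pred = np.concatenate([rates[v] for v in variables])
    errors = np.abs(pred - targets)

    common = dict(
        n_patients=n_patients,
        overall_mortality_target=overall_mortality_target,
        seed=seed,
        score_definition=score_definition,
    )
    if errors.max() <= tolerance:
        return CohortSpec(
            mortality_intercept=float(intercept),
            mortality_slope=float(slope),
            provenance={
                "method": (
                    "least-squares fit of (intercept, slope) to closed-form "
                    "stratum rates; band occupancies from truncated-normal marginals"
                ),
                "targets": {v: list(map(float, target_stratum_rates[v])) for v in variables},
                "achieved": {v: [float(x) for x in rates[v]] for v in variables},
                "max_abs_error": float(errors.max()),
            },
            **common,
        )

    # Saturated fallback: monotone per-level probabilities parametrized as a
    # base logit plus non-negative logit increments, so monotonicity holds
    # by construction.
    def levels_from(theta):
        logits = theta[0] + np.concatenate([[0.0], np.cumsum(np.exp(theta[1:]))])
        return expit(logits)

    start_lv = np.concatenate(
        [[intercept + slope * -3.0], np.full(6, math.log(max(abs(slope), 0.05)))]
    )

    def level_residuals(theta):
        rates_lv = predicted_stratum_rates_levels(levels_from(theta), band_probs)
        pred_lv = np.concatenate([rates_lv[v] for v in variables])
        res = pred_lv - targets
        if overall_mortality_target is not None:
            lv = levels_from(theta)
            dist = _score_distribution(band_probs)
            res = np.append(res, float(np.dot(dist, lv)) - overall_mortality_target)
        # Tiny ridge toward the linear-model shape keeps the (possibly
        # underdetermined) saturated fit identifiable; weight is far below
        # the tolerance scale.
        return np.append(res, 1e-4 * (theta - start_lv))

    fit_lv = optimize.least_squares(level_residuals, start_lv, method="trf")
    levels = levels_from(fit_lv.x)
    rates_lv = predicted_stratum_rates_levels(levels, band_probs)
    pred_lv = np.concatenate([rates_lv[v] for v in variables])
    errors_lv = np.abs(pred_lv - targets)
    if errors_lv.max() > tolerance:
        worst = int(np.argmax(errors_lv))
        var = variables[worst // 3]
        raise InfeasibleTargetsError(
            f"targets infeasible under the score-mediated mortality mechanism: "
            f"{var} band {worst % 3 + 1} misses by {errors_lv.max():.3f} "
            f"(tolerance {tolerance}); non-monotone or over-steep gradients "
            f"cannot be produced by a monotone score-level model"
        )
    return CohortSpec(
        mortality_intercept=float(intercept),
        mortality_slope=float(slope),
        mortality_levels=tuple(float(x) for x in levels),
        provenance={
            "method": (
                "saturated monotone per-score-level fit (linear-in-score model "
                "missed tolerance); levels fitted by least squares to "
                "closed-form stratum rates"
            ),
            "targets": {v: list(map(float, target_stratum_rates[v])) for v in variables},
            "achieved": {v: [float(x) for x in rates_lv[v]] for v in variables},
            "max_abs_error": float(errors_lv.max()),
            "linear_fit_max_abs_error": float(errors.max()),
        },
        **common,
    )


def _score_distribution(band_probs) -> np.ndarray:
    """P(total score = 3..9) under independent bands."""
    dist = np.zeros(7)
    for i, pa in enumerate(band_probs["age"], start=1):
        for j, pp in enumerate(band_probs["pf_ratio"], start=1):
            for k, pm in enumerate(band_probs["pmax"], start=1):
                dist[i + j + k - 3] += pa * pp * pm
    return dist


def _overall_rate(intercept, slope, band_probs):
    score_dist = np.zeros(10)
    for i, pa in enumerate(band_probs["age"], start=1):
        for j, pp in enumerate(band_probs["pf_ratio"], start=1):
            for k, pm in enumerate(band_probs["pmax"], start=1):
                score_dist[i + j + k] += pa * pp * pm
    scores = np.arange(10)
    return float(np.dot(score_dist, expit(intercept + slope * (scores - 6.0))))


# ---------------------------------------------------------------------------
# Delimited-text cohort I/O
# ---------------------------------------------------------------------------

COHORT_COLUMNS = (
    "id",
    "age",
    "pf_ratio",
    "pmax",
    "died_in_hospital",
    "apache_iv",
    "followup_days",
    "event_observed",
    "peep",
    "fio2",
)
_REQUIRED_COLUMNS = ("id", "age", "pf_ratio", "pmax", "died_in_hospital")
_FLOAT_COLUMNS = ("age", "pf_ratio", "pmax", "apache_iv", "followup_days", "peep", "fio2")
_BOOL_COLUMNS = ("died_in_hospital", "event_observed")


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    return repr(float(value))


def write_cohort(cohort: Sequence[PatientRecord], path) -> None:
    """Write records as comma-separated UTF-8 text with a header row.

    Floats use ``repr`` so a read/write cycle round-trips exactly; booleans
    are 1/0 and missing optionals are empty fields.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(COHORT_COLUMNS) + "\n")
        for rec in cohort:
            fields = [rec.id] + [
                _fmt(getattr(rec, col)) for col in COHORT_COLUMNS[1:]
            ]
            fh.write(",".join(fields) + "\n")


def _parse_bool(raw: str, row: int, col: str) -> bool:
    if raw in ("1", "true", "True"):
        return True
    if raw in ("0", "false", "False"):
        return False
    raise SchemaError(f"row {row}: field {col!r} is not a boolean indicator: {raw!r}")


def read_cohort(path) -> tuple[list[PatientRecord], list[str]]:
    """Read a cohort file; returns (records, warnings).

    Unknown columns produce a warning and are ignored; a missing required
    column or a malformed row raises ``SchemaError`` naming the row and
    field (rows are numbered from 1, excluding the header).
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    warnings: list[str] = []
    unknown = [c for c in frame.columns if c not in COHORT_COLUMNS]
    if unknown:
        warnings.append(f"ignoring unknown column(s): {', '.join(unknown)}")
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[PatientRecord] = []
    for idx, row in enumerate(frame.itertuples(index=False), start=1):
        row_map = dict(zip(frame.columns, row))
        kwargs: dict = {"id": row_map["id"]}
        for col in _FLOAT_COLUMNS:
            raw = row_map.get(col, "")
            if raw == "":
                if col in _REQUIRED_COLUMNS:
                    raise SchemaError(f"row {idx}: required field {col!r} is empty")
                kwargs[col] = None
            else:
                try:
                    kwargs[col] = float(raw)
                except ValueError:
                    raise SchemaError(
                        f"row {idx}: field {col!r} is not numeric: {raw!r}"
                    ) from None
        for col in _BOOL_COLUMNS:
            raw = row_map.get(col, "")
            if raw == "":
                if col in _REQUIRED_COLUMNS:
                    raise SchemaError(f"row {idx}: required field {col!r} is empty")
                kwargs[col] = None
            else:
                kwargs[col] = _parse_bool(raw, idx, col)
        try:
            records.append(PatientRecord(**kwargs))
        except CohortValidationError as exc:
            raise SchemaError(f"row {idx}: {exc}") from exc
    return records, warnings
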