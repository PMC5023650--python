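"""Per-category mortality strata: odds ratios, Wald intervals, trend tests.

A published stratum table reports, per band of one score variable, the
stratum size and the hospital mortality as a percentage.  Counts are
reconstructed by half-away-from-zero rounding, odds ratios against the
reference (1-point) band use the Wald interval on the log-odds scale, and
the dose-response trend across bands is tested with the Cochran–Armitage
score test for linear trend in proportions (bands coded 1, 2, 3), which
reproduces the reference tables' trend p-values at printed precision.  An
ordinal logistic Wald test is available as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm

from .score import SCORE_VARIABLES, ScoreDefinition, ScoredRecord

__all__ = [
    "Stratum",
    "OddsRatioEstimate",
    "TrendResult",
    "StratumTable",
    "reconstruct_counts",
    "odds_ratio",
    "trend_test",
    "stratify_cohort",
    "table_from_summaries",
]

_Z95 = norm.ppf(0.975)


@dataclass(frozen=True)
class Stratum:
    """One category's size and death count."""

    label: str
    n: int
    deaths: int

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"stratum {self.label!r}: n must be nonnegative")
        if not 0 <= self.deaths <= max(self.n, 0):
            raise ValueError(
                f"stratum {self.label!r}: deaths {self.deaths} outside [0, {self.n}]"
            )

    @property
    def survivors(self) -> int:
        return self.n - self.deaths

    @property
    def mortality_pct(self) -> float:
        return 100.0 * self.deaths / self.n if self.n else float("nan")


@dataclass(frozen=True)
class OddsRatioEstimate:
    point: float
    lower95: float
    upper95: float
    continuity_corrected: bool = False

    def __post_init__(self) -> None:
        if not (self.point > 0 and self.lower95 <= self.point <= self.upper95):
            raise ValueError(
                f"inconsistent odds-ratio estimate {self.point} "
                f"({self.lower95}–{self.upper95})"
            )


@dataclass(frozen=True)
class TrendResult:
    p: float
    statistic: float
    method: str
    degenerate: bool = False


@dataclass(frozen=True)
class StratumTable:
    """Reference-first category table for one score variable."""

    variable_name: str
    strata: tuple[Stratum, ...]
    odds_ratios: tuple[Optional[OddsRatioEstimate], ...]  # None for reference
    p_trend: TrendResult
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.odds_ratios) != len(self.strata):
            raise ValueError("one odds-ratio slot required per stratum")
        if self.odds_ratios and self.odds_ratios[0] is not None:
            raise ValueError("reference stratum must have no odds-ratio estimate")

    def to_text_block(self) -> str:
        lines = [
            f"Variable: {self.variable_name}",
            "Range\tCategory\tN\tHospital mortality (%)\tOR\tOR 2.5 %\tOR 97.5 %\tP for trend",
        ]
        for i, (stratum, orr) in enumerate(zip(self.strata, self.odds_ratios)):
            mort = f"{stratum.mortality_pct:.1f}" if stratum.n else "-"
            if orr is None:
                or_cols = "1\t\t" if i == 0 else "-\t-\t-"
            else:
                or_cols = f"{orr.point:.2f}\t{orr.lower95:.2f}\t{orr.upper95:.2f}"
            trend = f"{self.p_trend.p:.4f}" if i == 0 else ""
            lines.append(
                f"{stratum.label}\t{i + 1}\t{stratum.n}\t{mort}\t{or_cols}\t{trend}"
            )
        for flag in self.flags:
            lines.append(f"# {flag}")
        return "\n".join(lines)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def reconstruct_counts(n: int, mortality_pct: float, label: str = "") -> Stratum:
    """Invert a printed (N, mortality %) summary into integer counts."""
    if n <= 0:
        raise ValueError(f"stratum size must be positive, got {n}")
    if not 0 <= mortality_pct <= 100:
        raise ValueError(f"mortality percentage outside [0, 100]: {mortality_pct}")
    deaths = _round_half_away(mortality_pct * n / 100.0)
    return Stratum(label=label or f"n={n}", n=n, deaths=min(deaths, n))


def odds_ratio(stratum: Stratum, reference: Stratum) -> OddsRatioEstimate:
    """Wald odds ratio of death, stratum vs reference.

    Any zero cell switches to the Haldane–Anscombe continuity correction
    (0.5 added to all four cells) and flags the estimate.
    """
    cells = [stratum.deaths, stratum.survivors, reference.deaths, reference.survivors]
    corrected = any(c == 0 for c in cells)
    if corrected:
        cells = [c + 0.5 for c in cells]
    d1, s1, d0, s0 = cells
    log_or = math.log((d1 / s1) / (d0 / s0))
    se = math.sqrt(1 / d1 + 1 / s1 + 1 / d0 + 1 / s0)
    return OddsRatioEstimate(
        point=math.exp(log_or),
        lower95=math.exp(log_or - _Z95 * se),
        upper95=math.exp(log_or + _Z95 * se),
        continuity_corrected=corrected,
    )


def trend_test(strata: Sequence[Stratum], method: str = "cochran_armitage") -> TrendResult:
    """Two-sided dose-response trend p across ordered strata.

    ``cochran_armitage`` (default): the classical score test for linear
    trend in proportions.  ``logistic``: Wald test on the slope of a
    binomial GLM with the category index (1..k) as a single linear term.
    """
    occupied = [s for s in strata if s.n > 0]
    if len(occupied) < 2:
        raise ValueError("trend test needs at least two non-empty strata")
    total_deaths = sum(s.deaths for s in occupied)
    total_n = sum(s.n for s in occupied)
    if total_deaths == 0 or total_deaths == total_n:
        return TrendResult(p=1.0, statistic=0.0, method=method, degenerate=True)

    codes = np.array(
        [i + 1 for i, s in enumerate(strata) if s.n > 0], dtype=float
    )
    deaths = np.array([s.deaths for s in occupied], dtype=float)
    ns = np.array([s.n for s in occupied], dtype=float)

    if method == "logistic":
        endog = np.column_stack([deaths, ns - deaths])
        exog = sm.add_constant(codes)
        res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        z = res.params[1] / res.bse[1]
        p = 2.0 * norm.sf(abs(z))
        return TrendResult(p=min(max(p, np.finfo(float).tiny), 1.0), statistic=float(z), method=method)
    if method == "cochran_armitage":
        pbar = total_deaths / total_n
        tbar = float(np.dot(ns, codes) / total_n)
        num = float(np.dot(deaths, codes - tbar))
        var = pbar * (1 - pbar) * float(np.dot(ns, (codes - tbar) ** 2))
        if var <= 0:
            return TrendResult(p=1.0, statistic=0.0, method=method, degenerate=True)
        z = num / math.sqrt(var)
        p = 2.0 * norm.sf(abs(z))
        return TrendResult(p=min(max(p, np.finfo(float).tiny), 1.0), statistic=float(z), method=method)
    raise ValueError(f"unknown trend-test method {method!r}")


def _band_label(band) -> str:
    lo, hi = band.lower, band.upper
    if math.isinf(lo) and math.isinf(hi):
        return "all"
    if math.isinf(lo):
        return f"<{hi:g}" if not band.upper_closed else f"<={hi:g}"
    if math.isinf(hi):
        return f">{lo:g}" if not band.lower_closed else f">={lo:g}"
    return f"{lo:g}-{hi:g}"


def stratify_cohort(
    scored: Sequence[ScoredRecord],
    variable: str,
    definition: ScoreDefinition,
    trend_method: str = "cochran_armitage",
) -> StratumTable:
    """Tabulate a scored cohort into the variable's bands and estimate ORs."""
    if not scored:
        raise ValueError("cannot stratify an empty cohort")
    if variable not in SCORE_VARIABLES:
        raise ValueError(f"unknown score variable {variable!r}")
    var_index = SCORE_VARIABLES.index(variable)
    bands = definition.bands_for(variable)

    counts = {pts: [0, 0] for pts in (1, 2, 3)}  # pts -> [n, deaths]
    for rec in scored:
        pts = rec.component_points[var_index]
        counts[pts][0] += 1
        counts[pts][1] += int(rec.record.died_in_hospital)

    strata = tuple(
        Stratum(label=_band_label(band), n=counts[band.points][0], deaths=counts[band.points][1])
        for band in bands
    )
    flags: list[str] = []
    reference = strata[0]
    odds: list[Optional[OddsRatioEstimate]] = [None]
    for stratum in strata[1:]:
        if stratum.n == 0 or reference.n == 0:
            odds.append(None)
            flags.append(f"stratum {stratum.label!r} has no estimable odds ratio (empty cell)")
            continue
        est = odds_ratio(stratum, reference)
        odds.append(est)
        if est.continuity_corrected:
            flags.append(f"stratum {stratum.label!r}: continuity-corrected odds ratio")
    for stratum in strata:
        if stratum.n == 0:
            flags.append(f"stratum {stratum.label!r} is empty")
    estimable = [s for s in strata if s.n > 0]
    if len(estimable) >= 2:
        trend = trend_test(strata, method=trend_method)
    else:
        trend = TrendResult(p=1.0, statistic=0.0, method=trend_method, degenerate=True)
        flags.append("trend test degenerate: fewer than two occupied strata")
    return StratumTable(
        variable_name=variable,
        strata=strata,
        odds_ratios=tuple(odds),
        p_trend=trend,
        flags=tuple(flags),
    )


def table_from_summaries(
    variable: str,
    rows: Sequence[tuple[str, int, float]],
    trend_method: str = "cochran_armitage",
) -> StratumTable:
    """Build a StratumTable from printed (label, N, mortality %) rows.

    The first row is the reference category.  This is the entry point for
    re-deriving a published odds-ratio table from its summary columns.
    """
    strata = tuple(reconstruct_counts(n, pct, label=label) for label, n, pct in rows)
    odds: list[Optional[OddsRatioEstimate]] = [None]
    odds.extend(odds_ratio(s, strata[0]) for s in strata[1:])
    trend = trend_test(strata, method=trend_method)
    return StratumTable(
        variable_name=variable,
        strata=strata,
        odds_ratios=tuple(odds),
        p_trend=trend,
    )
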