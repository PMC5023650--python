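"""ROC analysis of a score against hospital mortality.

The AUC is the tie-corrected concordance probability
P(score_death > score_survivor) + 0.5 * P(equal), computed through
mid-ranks (the Mann–Whitney identity).  Its 95 % interval and the paired
comparison of two scores on the same patients use DeLong's
structural-components estimator of the AUC (co)variance; a nonparametric
bootstrap interval is available as an alternative.  The operating cutoff
is chosen by the Youden index over midpoints between adjacent distinct
score values, with "test positive" meaning score strictly above the
cutoff — for an integer 3–9 score the published cutoff 5.5 therefore
means a positive test at score >= 6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "RocAnalysis",
    "DiscriminationError",
    "roc_auc",
    "roc_analysis",
    "compare_auc_paired",
    "youden_cutoff",
    "likelihood_ratios",
    "auc_ci_bootstrap",
]


class DiscriminationError(ValueError):
    """Invalid input for ROC analysis (e.g. a single outcome class)."""


@dataclass(frozen=True)
class RocAnalysis:
    """ROC curve, AUC with interval, and Youden operating point."""

    thresholds: tuple[float, ...]  # midpoints between distinct score values
    sensitivities: tuple[float, ...]  # per threshold (positive = score > t)
    specificities: tuple[float, ...]
    auc: float
    auc_ci95: tuple[float, float]
    chosen_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    lr_pos: float
    lr_neg: float
    youden_tied: bool = False


def _validate(scores, outcomes) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=bool)
    if scores.shape != outcomes.shape or scores.ndim != 1:
        raise DiscriminationError("scores and outcomes must be 1-D of equal length")
    if scores.size == 0:
        raise DiscriminationError("empty input")
    if outcomes.all() or not outcomes.any():
        raise DiscriminationError("both outcome classes must be present")
    if not np.isfinite(scores).all():
        raise DiscriminationError("scores must be finite")
    return scores, outcomes


def _delong_components(scores: np.ndarray, outcomes: np.ndarray):
    """Per-subject structural components V10 (cases) and V01 (controls).

    V10[i] = P_hat(case_i outranks a random control) via mid-ranks; the
    mean of either vector is the tie-corrected AUC.
    """
    cases = scores[outcomes]
    controls = scores[~outcomes]
    m, n = cases.size, controls.size
    all_ranks = rankdata(np.concatenate([cases, controls]))
    case_ranks = rankdata(cases)
    control_ranks = rankdata(controls)
    v10 = (all_ranks[:m] - case_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - control_ranks) / m
    return v10, v01


def roc_auc(scores, outcomes) -> tuple[float, tuple[float, float]]:
    """Tie-corrected AUC with a DeLong 95 % interval, clipped to [0, 1]."""
    scores, outcomes = _validate(scores, outcomes)
    v10, v01 = _delong_components(scores, outcomes)
    auc = float(v10.mean())
    var = _delong_variance(v10, v01)
    half = norm.ppf(0.975) * math.sqrt(var)
    lo, hi = max(0.0, auc - half), min(1.0, auc + half)
    return auc, (lo, hi)


def _delong_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    s10 = v10.var(ddof=1) if v10.size > 1 else 0.0
    s01 = v01.var(ddof=1) if v01.size > 1 else 0.0
    return s10 / v10.size + s01 / v01.size


def compare_auc_paired(scores_a, scores_b, outcomes) -> float:
    """Two-sided DeLong test of AUC(a) = AUC(b) on the same patients."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise DiscriminationError("paired scores must have equal length")
    scores_a, outcomes = _validate(scores_a, outcomes)
    scores_b, _ = _validate(scores_b, outcomes)
    va10, va01 = _delong_components(scores_a, outcomes)
    vb10, vb01 = _delong_components(scores_b, outcomes)
    auc_a, auc_b = va10.mean(), vb10.mean()
    m, n = va10.size, va01.size
    if m > 1:
        s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
    else:  # pragma: no cover - needs >=2 cases in practice
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
    else:  # pragma: no cover
        s01 = np.zeros((2, 2))
    var_diff = (
        s10[0, 0] / m + s10[1, 1] / m - 2 * s10[0, 1] / m
        + s01[0, 0] / n + s01[1, 1] / n - 2 * s01[0, 1] / n
    )
    diff = auc_a - auc_b
    if var_diff <= 0:
        # Identical (or rank-identical) scores: no evidence of a difference.
        return 1.0
    z = diff / math.sqrt(var_diff)
    return float(min(max(2.0 * norm.sf(abs(z)), np.finfo(float).tiny), 1.0))


def likelihood_ratios(sens: float, spec: float) -> tuple[float, float]:
    """LR+ = sens/(1-spec); LR- = (1-sens)/spec (inf/nan guarded to inf)."""
    lr_pos = sens / (1.0 - spec) if spec < 1.0 else math.inf
    lr_neg = (1.0 - sens) / spec if spec > 0.0 else math.inf
    return lr_pos, lr_neg


def roc_analysis(scores, outcomes) -> RocAnalysis:
    """Full ROC analysis: curve, DeLong AUC interval, Youden cutoff."""
    scores, outcomes = _validate(scores, outcomes)
    auc, ci = roc_auc(scores, outcomes)

    distinct = np.unique(scores)
    if distinct.size >= 2:
        thresholds = (distinct[:-1] + distinct[1:]) / 2.0
    else:
        thresholds = distinct  # all tied: a single degenerate cutoff
    cases = scores[outcomes]
    controls = scores[~outcomes]
    sens = np.array([(cases > t).mean() for t in thresholds])
    spec = np.array([(controls <= t).mean() for t in thresholds])
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax returns the first (lowest) maximizer
    tied = bool(np.all(np.isclose(j, j[best])) and thresholds.size > 1) or distinct.size < 2
    lr_pos, lr_neg = likelihood_ratios(float(sens[best]), float(spec[best]))
    return RocAnalysis(
        thresholds=tuple(map(float, thresholds)),
        sensitivities=tuple(map(float, sens)),
        specificities=tuple(map(float, spec)),
        auc=auc,
        auc_ci95=ci,
        chosen_cutoff=float(thresholds[best]),
        sens_at_cutoff=float(sens[best]),
        spec_at_cutoff=float(spec[best]),
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        youden_tied=tied,
    )


def youden_cutoff(roc: RocAnalysis) -> tuple[float, float, float]:
    """The chosen cutoff and its (sensitivity, specificity)."""
    return roc.chosen_cutoff, roc.sens_at_cutoff, roc.spec_at_cutoff


def auc_ci_bootstrap(
    scores,
    outcomes,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Percentile-bootstrap AUC interval (stratified resampling)."""
    scores, outcomes = _validate(scores, outcomes)
    rng = np.random.default_rng(seed)
    cases = scores[outcomes]
    controls = scores[~outcomes]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        cs = rng.choice(cases, size=cases.size, replace=True)
        ct = rng.choice(controls, size=controls.size, replace=True)
        s = np.concatenate([cs, ct])
        o = np.concatenate([np.ones(cs.size, bool), np.zeros(ct.size, bool)])
        v10, _ = _delong_components(s, o)
        aucs[b] = v10.mean()
    point = float(_delong_components(scores, outcomes)[0].mean())
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return point, (float(lo), float(hi))
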