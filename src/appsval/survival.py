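"""Kaplan–Meier curves and log-rank comparison across score categories.

Follow-up is days from ARDS diagnosis; deaths are events and hospital
discharge censors.  At tied times events are handled before censorings
(the standard product-limit convention).  Estimation and the log-rank
chi-square are delegated to lifelines behind this module's surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .score import ScoredRecord

__all__ = [
    "KMCurve",
    "LogRankResult",
    "km_estimate",
    "logrank",
    "stratify_by_category",
    "DEFAULT_CATEGORY_EDGES",
    "RECALIBRATED_CATEGORY_EDGES",
]

#: Score groupings used for stratified survival: the original 3–4 / 5–7 /
#: 8–9 categories and the recalibrated 3 / 4–7 / 8–9 regrouping.
DEFAULT_CATEGORY_EDGES = ((3, 4), (5, 7), (8, 9))
RECALIBRATED_CATEGORY_EDGES = ((3, 3), (4, 7), (8, 9))


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate for one stratum (time 0 included)."""

    stratum_label: str
    times: tuple[float, ...]
    survival_prob: tuple[float, ...]
    at_risk: tuple[int, ...]

    def __post_init__(self) -> None:
        probs = np.asarray(self.survival_prob)
        if probs.size == 0 or probs[0] != 1.0:
            raise ValueError("survival must start at 1 at time 0")
        if np.any(np.diff(probs) > 1e-12):
            raise ValueError("survival probabilities must be non-increasing")
        if np.any(np.diff(np.asarray(self.at_risk)) > 0):
            raise ValueError("at-risk counts must be non-increasing")

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(np.asarray(self.times), t, side="right") - 1
        return float(self.survival_prob[max(idx, 0)])


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p: float

    def __post_init__(self) -> None:
        if self.statistic < 0 or self.df < 1:
            raise ValueError("invalid log-rank result")


def km_estimate(times, events, label: str = "") -> KMCurve:
    """Kaplan–Meier product-limit estimate.

    Returned grid: time 0 plus every distinct event time, with the number
    at risk just before each time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times < 0):
        raise ValueError("negative follow-up time")
    if np.any((times == 0) & events):
        # time origin is the diagnosis; deaths coincident with it must be
        # recorded at a small positive time for S(0) = 1 to hold
        raise ValueError("event at time 0; record it at a positive time")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events, label=label or "stratum")
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    grid = [0.0] + [float(t) for t in event_rows.index if t > 0]
    survival = [float(kmf.predict(t)) for t in grid]
    at_risk = [int(times.size)] + [int(r) for r in event_rows.loc[event_rows.index > 0, "at_risk"]]
    return KMCurve(
        stratum_label=label or "stratum",
        times=tuple(grid),
        survival_prob=tuple(survival),
        at_risk=tuple(at_risk),
    )


def logrank(strata: Mapping[str, tuple[Sequence[float], Sequence[bool]]]) -> LogRankResult:
    """K-sample log-rank chi-square across labelled (times, events) groups."""
    if len(strata) < 2:
        raise ValueError("log-rank needs at least two strata")
    all_times, all_events, labels = [], [], []
    for label, (times, events) in strata.items():
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=bool)
        if times.size == 0:
            raise ValueError(f"stratum {label!r} has no subjects")
        all_times.append(times)
        all_events.append(events)
        labels.extend([label] * times.size)
    res = multivariate_logrank_test(
        np.concatenate(all_times), np.asarray(labels), np.concatenate(all_events)
    )
    df = len(strata) - 1
    return LogRankResult(
        statistic=float(res.test_statistic), df=df, p=float(min(max(res.p_value, 0.0), 1.0)) or 1.0
    )


def _validate_edges(category_edges: Sequence[tuple[int, int]]) -> None:
    covered: list[int] = []
    for lo, hi in category_edges:
        if lo > hi:
            raise ValueError(f"category ({lo}, {hi}) is empty")
        covered.extend(range(lo, hi + 1))
    if sorted(covered) != list(range(3, 10)):
        raise ValueError(
            f"categories {list(category_edges)} must partition the score range 3–9"
        )


def stratify_by_category(
    scored: Sequence[ScoredRecord],
    category_edges: Sequence[tuple[int, int]] = DEFAULT_CATEGORY_EDGES,
) -> tuple[dict[str, tuple[np.ndarray, np.ndarray]], list[str]]:
    """Split scored patients with follow-up into score categories.

    Returns (strata, flags): strata maps "lo-hi" labels to (times, events)
    arrays; empty categories are omitted from the mapping and flagged.
    """
    _validate_edges(category_edges)
    flags: list[str] = []
    strata: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for lo, hi in category_edges:
        label = f"{lo}" if lo == hi else f"{lo}-{hi}"
        members = [s for s in scored if lo <= s.total <= hi]
        missing = [s for s in members if s.record.followup_days is None]
        if missing:
            raise ValueError(
                f"{len(missing)} record(s) in category {label} lack follow-up data"
            )
        if not members:
            flags.append(f"category {label} is empty")
            continue
        strata[label] = (
            np.array([s.record.followup_days for s in members], dtype=float),
            np.array([s.record.event_observed for s in members], dtype=bool),
        )
    return strata, flags
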