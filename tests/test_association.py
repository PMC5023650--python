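"""Stratum tables: count reconstruction, Wald ORs, trend tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.contingency_tables import Table2x2

from appsval.association import (
    OddsRatioEstimate,
    Stratum,
    odds_ratio,
    reconstruct_counts,
    stratify_cohort,
    table_from_summaries,
    trend_test,
)
from appsval.score import builtin_definition, score_cohort

from conftest import REFERENCE_STRATA_ORIGINAL, REFERENCE_STRATA_RECALIBRATED


@pytest.mark.parametrize(
    "n, pct, deaths",
    [(196, 43.9, 86), (72, 26.4, 19), (1000, 0.0, 0), (134, 52.2, 70), (40, 45.0, 18)],
)
def test_reconstruct_counts_half_away_rounding(n, pct, deaths):
    stratum = reconstruct_counts(n, pct)
    assert stratum.deaths == deaths
    assert stratum.survivors == n - deaths


@given(n=st.integers(1, 5000), pct=st.floats(0, 100))
@settings(max_examples=200, derandomize=True)
def test_reconstruction_consistent_within_rounding_halfwidth(n, pct):
    stratum = reconstruct_counts(n, pct)
    assert abs(stratum.mortality_pct - pct) <= 100.0 / (2 * n) + 1e-9


@pytest.mark.parametrize("table", [REFERENCE_STRATA_ORIGINAL, REFERENCE_STRATA_RECALIBRATED])
def test_published_odds_ratios_reproduced_to_two_decimals(table):
    for variable, block in table.items():
        built = table_from_summaries(variable, block["rows"])
        assert built.odds_ratios[0] is None
        for est, (point, lo, hi) in zip(built.odds_ratios[1:], block["odds_ratios"]):
            assert round(est.point, 2) == pytest.approx(point, abs=1e-9)
            assert round(est.lower95, 2) == pytest.approx(lo, abs=1e-9)
            assert round(est.upper95, 2) == pytest.approx(hi, abs=1e-9)


@pytest.mark.parametrize("table", [REFERENCE_STRATA_ORIGINAL, REFERENCE_STRATA_RECALIBRATED])
def test_published_trend_p_values_reproduced(table):
    for variable, block in table.items():
        built = table_from_summaries(variable, block["rows"])
        assert round(built.p_trend.p, 4) == pytest.approx(block["p_trend"], abs=1e-9)


def test_identical_strata_give_unit_odds_ratio():
    s = Stratum("a", 100, 40)
    est = odds_ratio(s, Stratum("b", 100, 40))
    assert est.point == pytest.approx(1.0)


def test_zero_cell_triggers_continuity_correction():
    est = odds_ratio(Stratum("a", 50, 0), Stratum("b", 50, 10))
    assert est.continuity_corrected
    assert est.point > 0


def test_scaling_cells_keeps_point_and_shrinks_interval():
    base = odds_ratio(Stratum("a", 100, 30), Stratum("b", 100, 20))
    scaled = odds_ratio(Stratum("a", 1000, 300), Stratum("b", 1000, 200))
    assert scaled.point == pytest.approx(base.point, rel=1e-12)
    assert (scaled.upper95 - scaled.lower95) < (base.upper95 - base.lower95)


def test_wald_interval_matches_independent_oracle(rng):
    """Endpoints agree with statsmodels' 2x2 log-odds interval to 1e-10."""
    for _ in range(100):
        d1, s1, d0, s0 = rng.integers(1, 500, size=4)
        est = odds_ratio(Stratum("a", int(d1 + s1), int(d1)), Stratum("b", int(d0 + s0), int(d0)))
        oracle = Table2x2(np.array([[d1, s1], [d0, s0]]))
        lo, hi = oracle.oddsratio_confint(0.05)
        assert est.point == pytest.approx(oracle.oddsratio, rel=1e-10)
        assert est.lower95 == pytest.approx(lo, rel=1e-10)
        assert est.upper95 == pytest.approx(hi, rel=1e-10)


def test_trend_two_identical_strata_is_null():
    res = trend_test([Stratum("a", 200, 60), Stratum("b", 200, 60)])
    assert res.p == pytest.approx(1.0)


def test_trend_degenerate_outcomes_flagged():
    res = trend_test([Stratum("a", 50, 0), Stratum("b", 50, 0)])
    assert res.degenerate and res.p == 1.0


def _permutation_trend_p(deaths_per, n_per, codes, rng, n_perm=10_000):
    """Permutation oracle on the linear-trend statistic sum(code * death)."""
    subject_codes = np.concatenate([
        np.full(n, c) for n, c in zip(n_per, codes)
    ])
    outcomes = np.zeros(sum(n_per))
    start = 0
    for n, d in zip(n_per, deaths_per):
        outcomes[start : start + d] = 1.0
        start += n
    observed = abs(np.dot(subject_codes - subject_codes.mean(), outcomes))
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(outcomes)
        if abs(np.dot(subject_codes - subject_codes.mean(), perm)) >= observed - 1e-9:
            count += 1
    return (count + 1) / (n_perm + 1)


def test_trend_p_agrees_with_permutation_oracle(rng):
    # moderate trend so the p-value is resolvable by 10^4 permutations
    strata = [Stratum("1", 200, 50), Stratum("2", 200, 60), Stratum("3", 200, 70)]
    analytic = trend_test(strata).p
    perm = _permutation_trend_p([50, 60, 70], [200, 200, 200], [1.0, 2.0, 3.0], rng)
    mc_se = np.sqrt(perm * (1 - perm) / 10_000)
    assert abs(analytic - perm) < 4 * mc_se + 0.005


def test_trend_strong_gradient_detected(rng):
    strata = [Stratum("1", 200, 20), Stratum("2", 200, 60), Stratum("3", 200, 100)]
    analytic = trend_test(strata).p
    perm = _permutation_trend_p([20, 60, 100], [200, 200, 200], [1.0, 2.0, 3.0], rng)
    assert analytic < 1e-3
    assert perm <= 10 / 10_000  # no permutation reached the observed trend


def test_stratify_cohort_counts_sum(large_cohort, original_definition):
    scored = score_cohort(large_cohort, original_definition)
    table = stratify_cohort(scored, "pmax", original_definition)
    assert sum(s.n for s in table.strata) == len(large_cohort)
    assert table.strata[0].label == "<27"


def test_stratify_single_patient_single_stratum(original_definition):
    from appsval.cohort import PatientRecord

    rec = PatientRecord(id="p", age=30, pf_ratio=180, pmax=20, died_in_hospital=False)
    scored = score_cohort([rec], original_definition)
    table = stratify_cohort(scored, "age", original_definition)
    assert [s.n for s in table.strata] == [1, 0, 0]
    assert any("empty" in f for f in table.flags)
    assert all(o is None for o in table.odds_ratios)


def test_inconsistent_or_estimate_rejected():
    with pytest.raises(ValueError):
        OddsRatioEstimate(point=2.0, lower95=2.5, upper95=3.0)
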