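"""Score-engine tests: banding, monotonicity, serialization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from appsval.cohort import PatientRecord
from appsval.score import (
    SCORE_VARIABLES,
    ScoreDefinition,
    ScoreError,
    ScoringError,
    VariableBand,
    builtin_definition,
    score_cohort,
    score_record,
    three_band_definition,
)


def _record(age, pf, pmax, rid="r1", **kw):
    return PatientRecord(id=rid, age=age, pf_ratio=pf, pmax=pmax, died_in_hospital=False, **kw)


@pytest.mark.parametrize(
    "which, age, pf, pmax, components, total",
    [
        # worst band for every variable under the original cutoffs
        ("original", 70, 90, 35, (3, 3, 3), 9),
        # best band for every variable: the score floor
        ("original", 30, 180, 20, (1, 1, 1), 3),
        # recalibrated cutoffs: 60 y is >59, P/F 120 mid band, Pmax 31 mid band
        ("recalibrated", 60, 120, 31, (3, 2, 2), 7),
        # inclusive dash-range boundaries
        ("original", 47, 158, 30, (2, 2, 2), 6),
        ("original", 66, 105, 27, (2, 2, 2), 6),
        ("recalibrated", 59, 105, 33, (2, 2, 2), 6),
    ],
)
def test_builtin_definitions_band_examples(which, age, pf, pmax, components, total):
    scored = score_record(_record(age, pf, pmax), builtin_definition(which))
    assert scored.component_points == components
    assert scored.total == total


def test_unknown_builtin_lists_valid_keys():
    with pytest.raises(ScoreError, match="original"):
        builtin_definition("nonsense")


def test_score_cohort_preserves_order_and_range(study_sized_cohort, original_definition):
    scored = score_cohort(study_sized_cohort, original_definition)
    assert len(scored) == len(study_sized_cohort)
    assert [s.record.id for s in scored] == [r.id for r in study_sized_cohort]
    assert all(3 <= s.total <= 9 for s in scored)


def test_missing_predictor_reported_with_record_id(original_definition):
    from types import SimpleNamespace

    good = _record(50, 120, 25, rid="ok")
    bad = SimpleNamespace(id="broken", age=50.0, pf_ratio=120.0, pmax=None)
    with pytest.raises(ScoringError, match="broken") as err:
        score_cohort([good, bad], original_definition)
    assert err.value.failures[0][0] == "broken"


def test_nonsurvivors_score_higher_on_gradient_cohort(large_cohort, original_definition):
    scored = score_cohort(large_cohort, original_definition)
    dead = [s.total for s in scored if s.record.died_in_hospital]
    alive = [s.total for s in scored if not s.record.died_in_hospital]
    assert np.mean(dead) > np.mean(alive)


@given(
    age=st.one_of(st.floats(18, 100), st.sampled_from([47.0, 59.0, 66.0])),
    pf=st.one_of(st.floats(30, 200), st.sampled_from([105.0, 158.0])),
    pmax=st.one_of(st.floats(10, 50), st.sampled_from([27.0, 30.0, 33.0])),
    which=st.sampled_from(["original", "recalibrated"]),
)
@settings(max_examples=200, derandomize=True)
def test_exactly_one_band_matches_any_value(age, pf, pmax, which):
    definition = builtin_definition(which)
    for var, value in zip(SCORE_VARIABLES, (age, pf, pmax)):
        matches = [b for b in definition.bands_for(var) if b.contains(value)]
        assert len(matches) == 1


@given(
    age=st.floats(18, 99), pf=st.floats(31, 200), pmax=st.floats(10, 49),
    d_age=st.floats(0, 30), d_pf=st.floats(0, 100), d_pmax=st.floats(0, 20),
    which=st.sampled_from(["original", "recalibrated"]),
)
@settings(max_examples=200, derandomize=True)
def test_total_monotone_in_risk_direction(age, pf, pmax, d_age, d_pf, d_pmax, which):
    """Older, more hypoxemic or higher-pressure patients never score lower."""
    definition = builtin_definition(which)
    base = score_record(_record(age, pf, pmax), definition).total
    worse = score_record(
        _record(age + d_age, max(pf - d_pf, 30.0), pmax + d_pmax), definition
    ).total
    assert worse >= base


def test_definition_yaml_round_trip(tmp_path, rng):
    definition = three_band_definition("custom", (45.0, 60.0), (100.0, 150.0), (25.0, 31.0))
    path = tmp_path / "custom.yaml"
    definition.to_yaml(path)
    reloaded = ScoreDefinition.from_yaml(path)
    ages = rng.uniform(18, 100, 10_000)
    pfs = rng.uniform(30, 200, 10_000)
    pmaxs = rng.uniform(10, 50, 10_000)
    for var, values in zip(SCORE_VARIABLES, (ages, pfs, pmaxs)):
        for v in values[:: 50]:
            assert definition.points_for(var, v) == reloaded.points_for(var, v)
    # spot-identical on full vectors via the totals
    totals_a = [
        definition.points_for("age", a)
        + definition.points_for("pf_ratio", p)
        + definition.points_for("pmax", m)
        for a, p, m in zip(ages[:2000], pfs[:2000], pmaxs[:2000])
    ]
    totals_b = [
        reloaded.points_for("age", a)
        + reloaded.points_for("pf_ratio", p)
        + reloaded.points_for("pmax", m)
        for a, p, m in zip(ages[:2000], pfs[:2000], pmaxs[:2000])
    ]
    assert totals_a == totals_b


@pytest.mark.parametrize(
    "bands_kwargs, message",
    [
        # a gap between 30 and 33 leaves Pmax values unassigned
        (dict(age_cutoffs=(47.0, 66.0), pf_cutoffs=(105.0, 158.0), pmax_cutoffs=(33.0, 30.0)), "low < high"),
    ],
)
def test_invalid_cutoffs_rejected(bands_kwargs, message):
    with pytest.raises(ScoreError, match=message):
        three_band_definition("bad", **bands_kwargs)


def test_gapped_bands_rejected():
    bands = list(builtin_definition("original").bands)
    # move the upper Pmax band start from 30 to 33, leaving (30, 33] unclaimed
    bands = [
        VariableBand("pmax", 33.0, math.inf, False, False, 3)
        if (b.variable == "pmax" and b.points == 3)
        else b
        for b in bands
    ]
    with pytest.raises(ScoreError, match="gap"):
        ScoreDefinition(name="gapped", bands=tuple(bands))
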