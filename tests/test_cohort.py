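"""Synthetic-cohort generator: determinism, margins, parameter recovery."""

import io
import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import logit

from appsval import (
    CohortSpec,
    CohortValidationError,
    InfeasibleTargetsError,
    PatientRecord,
    SchemaError,
    calibrate_spec_to_margins,
    generate_cohort,
    read_cohort,
    simulate_scores,
    write_cohort,
)
from appsval.association import stratify_cohort
from appsval.score import builtin_definition, score_cohort


def test_identical_seed_gives_byte_identical_cohort(tmp_path):
    spec = CohortSpec(n_patients=300, seed=123)
    a, b = generate_cohort(spec), generate_cohort(spec)
    assert a == b
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    write_cohort(a, pa)
    write_cohort(b, pb)
    assert pa.read_bytes() == pb.read_bytes()


def test_flat_slope_hits_overall_mortality_target():
    """Slope 0 with intercept logit(0.43) reproduces 43 % mortality."""
    spec = CohortSpec(n_patients=100_000, seed=9, mortality_slope=0.0,
                      mortality_intercept=float(logit(0.43)))
    _, died = simulate_scores(spec)
    se = math.sqrt(0.43 * 0.57 / died.size)
    assert abs(died.mean() - 0.43) < 3 * se


def test_invalid_spec_names_field():
    with pytest.raises(CohortValidationError, match="n_patients"):
        CohortSpec(n_patients=0)
    with pytest.raises(CohortValidationError, match="mortality_levels"):
        CohortSpec(n_patients=5, mortality_levels=(0.5,) * 6)


def test_steep_slope_gives_strictly_increasing_level_mortality():
    totals, died = simulate_scores(CohortSpec(n_patients=100_000, seed=4, mortality_slope=0.8))
    rates = [died[totals == s].mean() for s in range(3, 10)]
    assert all(n > 50 for n in np.bincount(totals, minlength=10)[3:10])
    assert all(a < b for a, b in zip(rates, rates[1:]))


def test_predictors_respect_truncation_bounds(study_sized_cohort):
    for rec in study_sized_cohort:
        assert 18 <= rec.age <= 100
        assert 30 <= rec.pf_ratio <= 200
        assert 10 <= rec.pmax <= 50
        assert 0 < rec.followup_days <= 60


@pytest.mark.parametrize(
    "variable, definition_key, targets",
    [
        ("age", "original", (0.264, 0.439, 0.48)),
        ("pmax", "recalibrated", (0.331, 0.45, 0.553)),
    ],
)
def test_margin_calibration_reproduces_stratum_rates(variable, definition_key, targets):
    spec = calibrate_spec_to_margins(
        {variable: targets}, n_patients=100_000, seed=13, score_definition=definition_key
    )
    definition = builtin_definition(definition_key)
    scored = score_cohort(generate_cohort(spec), definition)
    table = stratify_cohort(scored, variable, definition)
    for stratum, target in zip(table.strata, targets):
        assert abs(stratum.mortality_pct / 100.0 - target) < 0.03


def test_equal_targets_recover_zero_slope():
    spec = calibrate_spec_to_margins({"age": (0.43, 0.43, 0.43)})
    assert spec.mortality_levels is None
    assert abs(spec.mortality_slope) < 1e-6


def test_infeasible_targets_raise():
    with pytest.raises(InfeasibleTargetsError):
        calibrate_spec_to_margins({"age": (0.9, 0.1, 0.9)})


def test_increasing_slope_never_lowers_high_score_mortality():
    """The mortality mechanism is monotone in its slope parameter."""
    rates = []
    for slope in (0.2, 0.5):
        totals, died = simulate_scores(
            CohortSpec(n_patients=100_000, seed=21, mortality_slope=slope)
        )
        rates.append(died[totals >= 8].mean())
    assert rates[1] >= rates[0]


def test_logistic_fit_recovers_generating_parameters():
    """Death-on-score logistic recovers intercept and slope within 3 SE."""
    spec = CohortSpec(n_patients=10_000, seed=77, mortality_slope=0.35)
    totals, died = simulate_scores(spec)
    res = sm.Logit(died.astype(float), sm.add_constant(totals.astype(float))).fit(disp=0)
    # generator parametrizes the linear predictor around score 6
    true_const = spec.mortality_intercept - 6.0 * spec.mortality_slope
    assert abs(res.params[0] - true_const) < 3 * res.bse[0]
    assert abs(res.params[1] - spec.mortality_slope) < 3 * res.bse[1]


def test_record_invariants_enforced():
    with pytest.raises(CohortValidationError, match="age"):
        PatientRecord(id="x", age=17, pf_ratio=100, pmax=25, died_in_hospital=False)
    with pytest.raises(CohortValidationError, match="event_observed"):
        PatientRecord(id="x", age=50, pf_ratio=100, pmax=25,
                      died_in_hospital=False, followup_days=10.0)
    with pytest.raises(CohortValidationError, match="event_observed"):
        PatientRecord(id="x", age=50, pf_ratio=100, pmax=25,
                      died_in_hospital=True, followup_days=10.0, event_observed=False)


def test_cohort_file_round_trip(tmp_path, study_sized_cohort):
    path = tmp_path / "cohort.csv"
    write_cohort(study_sized_cohort, path)
    back, warnings = read_cohort(path)
    assert warnings == []
    assert back == list(study_sized_cohort)


def test_missing_required_column_names_it(tmp_path):
    path = tmp_path / "broken.csv"
    path.write_text("id,pf_ratio,pmax,died_in_hospital\np1,100,25,1\n")
    with pytest.raises(SchemaError, match="age"):
        read_cohort(path)


def test_malformed_row_reports_row_and_field(tmp_path):
    path = tmp_path / "broken.csv"
    path.write_text(
        "id,age,pf_ratio,pmax,died_in_hospital\n"
        "p1,50,100,25,0\n"
        "p2,fifty,100,25,0\n"
    )
    with pytest.raises(SchemaError, match=r"row 2.*age"):
        read_cohort(path)


def test_unknown_column_warned_and_ignored(tmp_path):
    path = tmp_path / "extra.csv"
    path.write_text(
        "id,age,pf_ratio,pmax,died_in_hospital,color\np1,50,100,25,0,blue\n"
    )
    records, warnings = read_cohort(path)
    assert len(records) == 1
    assert any("color" in w for w in warnings)


def test_spec_yaml_round_trip(tmp_path):
    spec = CohortSpec(n_patients=64, seed=5, mortality_levels=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7))
    path = tmp_path / "spec.yaml"
    spec.to_yaml(path)
    assert generate_cohort(CohortSpec.from_yaml(path)) == generate_cohort(spec)
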