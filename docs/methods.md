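# Methods

## The score and its validation pipeline

The APPS is a 3–9 point prognostic score for hospital mortality in
moderate/severe ARDS (PaO₂/FiO₂ ≤ 200 mmHg).  Each of three predictors —
age (years), PaO₂/FiO₂ ratio (mmHg) and maximal airway pressure Pmax
(cmH₂O) — contributes 1, 2 or 3 points according to a cutoff table.  Pmax
stands in for plateau pressure under pressure-controlled ventilation; the
package treats them as one field and documents the proxy here.  Two cutoff
sets are built in:

| variable  | original (1 / 2 / 3 pts)       | recalibrated             |
|-----------|--------------------------------|--------------------------|
| age       | <47 / 47–66 / >66              | <47 / 47–59 / >59        |
| PaO₂/FiO₂ | >158 / 105–158 / <105          | unchanged                |
| Pmax      | <27 / 27–30 / >30              | <30 / 30–33 / >33        |

Printed dash ranges are interpreted as closed intervals: "47–66" is
[47, 66], "<47" is (−∞, 47), ">66" is (66, ∞).  Ages and pressures are
banded on their raw (possibly non-integer) values; whether the source
analyses rounded ages first is not recoverable from the summaries, and
both behaviours are representable because every band carries explicit
open/closed bounds in the definition files.  Band tables must partition
the real line and be monotone in the risk direction (more points for
higher age/Pmax, lower P/F); this is validated at construction.  A
published variant of the original table prints the Pmax bands as 27–30
then >33, which leaves 30–33 unassigned and whose row sizes total 415
rather than 439; such a gapped table cannot be a total score, so it is
not shipped as a definition.  The worked examples reproduce those rows
as printed via count reconstruction, which needs no banding.

Validation of a scored cohort comprises:

- **Discrimination.**  AUC as the tie-corrected concordance probability
  (Mann–Whitney identity via mid-ranks), 95 % CI and paired score
  comparison by DeLong's structural-components method, CI clipped to
  [0, 1] on the probability scale.  The operating cutoff maximizes the
  Youden index over midpoints between adjacent distinct score values,
  ties resolved toward the lower cutoff; "test positive" means score
  strictly above the cutoff, so the integer-score cutoff 5.5 means
  positive at ≥6.  LR+ = sens/(1−spec), LR− = (1−sens)/spec.  A
  stratified percentile bootstrap of the AUC is available as an
  alternative interval, since the published intervals do not state their
  method.
- **Calibration.**  Observed versus expected deaths per integer score
  level (the field's calibration bar plots are per-score, hence
  score-level grouping is the default; deciles of fitted risk are an
  option).  Expected counts come from a univariate logistic model of
  death on the score — the summaries fix no probability model, and the
  Hosmer–Lemeshow statistic is undefined without one, so this choice is
  deliberate and prominent.  H = Σ (O−E)²/(E(1−E/n)) on χ² with
  (groups − 2) df (floor 1).  Complete separation of score levels is
  detected (degenerate fitted probabilities) and raised as an error.
- **Category association.**  Per-band stratum tables with Wald odds
  ratios on the log-odds scale against the 1-point reference band;
  zero cells switch to the Haldane–Anscombe correction and flag the
  estimate.  Counts printed only as (N, mortality %) are reconstructed
  with half-away-from-zero rounding, which reproduces every checkable
  published OR and bound to 2 decimals.  The trend test is
  Cochran–Armitage (bands coded 1, 2, 3); it reproduces all five
  published "P for trend" values at printed precision, which identifies
  it as the test actually used, so it is the default; an ordinal
  logistic Wald test is the alternative.
- **Stratified survival.**  Kaplan–Meier product-limit curves and the
  k-sample log-rank χ² (df = k−1) across score categories — 3–4 / 5–7 /
  8–9 for the original score and 3 / 4–7 / 8–9 for the recalibrated one
  — delegated to lifelines.  Time origin is ARDS diagnosis, deaths are
  events, hospital discharge censors; events precede censorings at tied
  times.  These are conventions of this package, as the source endpoint
  definition is unstated; an event recorded exactly at time 0 is
  rejected so that S(0) = 1.

## Recalibration search

Recalibration keeps the 1/2/3 point weights and moves cutoffs only, for
age and Pmax by default (P/F is left alone).  Variables are tuned
sequentially, each by exhaustive search over ordered cutoff pairs on the
variable's empirical 5th–95th percentile grid (steps 1 y, 1 cmH₂O,
5 mmHg; the base pair is always a candidate).  Feasibility requires each
band to hold ≥5 % of the cohort and band mortality to be non-decreasing
in points.

The objective is calibration-first, discrimination-second: among feasible
candidates whose HL p-value clears 0.05, the highest AUC wins, with AUCs
within 0.002 treated as tied and resolved toward the cutoffs closest to
the base definition; if nothing calibrates acceptably the HL p itself is
maximized.  The HL p cannot serve as a continuous objective: the
per-candidate logistic refit absorbs banding shifts, so the p-value at
the true cutoffs is uniformly distributed while wrong pairs routinely
draw p ≈ 1 — in simulation, maximizing p recovers planted cutoffs in 0
of 5 seeds at any effect size, whereas the AUC is sharply maximized at
the truth (5 of 5, exactly).  By construction the achieved HL p never
falls below min(base HL p, 0.05).  When the tuned variable has no real
effect the landscape is pure noise; the search then returns some
noise-equivalent pair with acceptable calibration and no discrimination
gain — exact ties, where the closest-to-base rule would return the base
pair, have probability zero on continuous data.

A published "P = 1.0" for a recalibrated score is read as an HL p
rounding to 1.0 at one decimal, not exact unity.

## Synthetic cohorts

The generator emulates the validation study's structure, not its joint
distribution.  Predictors are independent truncated normals: age
60.5 ± 14.5 y on [18, 100] (pooling the published survivor/non-survivor
arms 58.5 ± 15.4 and 63.1 ± 12.7 at 43 % mortality), P/F 127.2 ± 40.4 mmHg
on [30, 200] (the moderate/severe entry criterion), Pmax 27.1 ± 8.6 cmH₂O
on [10, 50].  Death depends on a record only through its total score:
P(death | s) = expit(intercept + slope·(s − 6)), centred so the intercept
is the log-odds of death at the score midpoint; defaults
intercept = logit(0.43) (the published overall mortality) and slope 0.35
(reproducing stratum gradients of the published magnitude).  A saturated
per-level probability table can replace the linear model — it is what
`calibrate_spec_to_margins` falls back to when targets are concave on the
logit scale (the published age gradient 26.4/43.9/48.0 % is: no
intercept+slope model gets within ±3 pp of it, best minimax error 0.036),
and it also expresses non-monotone mechanisms such as the mid-score
calibration disturbance scenario used in the power test, whose severity
(levels 0.08/0.55/0.22/0.42/0.58/0.70/0.82 at scores 3–9) is chosen so
the median simulated HL p at n = 439 matches the sub-0.001 order of the
disturbance it emulates.

`calibrate_spec_to_margins` fits the mortality model to target stratum
death rates deterministically: band occupancies follow in closed form
from the truncated-normal marginals, giving exact predicted stratum rates
that are fitted by least squares (linear model first, saturated monotone
fallback with a tiny ridge toward the linear shape for identifiability).
Targets a monotone score-mediated mechanism cannot reach within ±0.03
raise an infeasibility error.  Note that the full set of all three
variables' published stratum rates *jointly* is infeasible under
predictor independence — the age and P/F reference bands differ by
10 percentage points, which only predictor correlation can produce — so
the worked examples calibrate one variable at a time, as in the margin
fidelity tests.

Follow-up supports the survival analyses only: deaths uniform on
(0, horizon], survivors censored at a log-normal discharge time (median
14 d, log-SD 0.6) capped at the 60 d horizon.  APACHE IV is drawn per
outcome arm (85.5 ± 27 survivors, 102.7 ± 30.7 non-survivors, truncated
at 0) to give an informative comparator; PEEP ~ 10.6 ± 3.8 cmH₂O on
[0, 25] and FiO₂ ~ 54.7 ± 14.7 % on [21, 100] support the sensitivity
subset (PEEP ≥ 10 and FiO₂ ≥ 50 %, which retains roughly a third of a
default cohort, matching the published subset fraction).  All draws come
from one seeded generator in a documented order (age, P/F, Pmax, death
uniforms, death times, discharge times, APACHE survivor then
non-survivor, PEEP, FiO₂), so a spec is a complete, serializable
description of a cohort and identical specs give byte-identical files.

What the generator does **not** emulate: correlations among predictors
and with APACHE IV, cause-of-ARDS structure, and any real-data
relationship between ventilator settings and outcome.  Tests passing on
these cohorts therefore validate the statistical machinery — estimator
identities, error calibration, parameter recovery — not the published
discrimination results themselves: the published AUCs (0.62/0.63/0.66),
their intervals, the paired DeLong p, the cohort HL p-values and the
log-rank p all depend on unavailable patient-level data and are
documented as non-reproducible.

## Numerical choices and problem sizes

- Wald z = 1.96 two-sided intervals throughout; p-values floored at the
  smallest positive double and capped at 1.
- OR reconstruction rounding is half-away-from-zero; reconstructed
  mortality agrees with the printed percentage within 100/(2n).
- The HL type-I simulation uses 500 seeds at n = 10⁴; the recalibration
  recovery uses a single n = 10⁴ cohort with a 0.9 per-point slope; the
  concordance oracle check uses 100 random cohorts of 30–250 patients;
  margin-fidelity checks use n = 10⁵.  These sizes make the Monte-Carlo
  error small relative to the tolerances while keeping the default suite
  fast on one CPU.
- FiO₂ units (percent vs fraction) must be declared by the caller; the
  package refuses to guess, since silent unit inference is a recurring
  source of clinical-data bugs.

## Known limitations

- The independence assumption makes joint all-variable margin targets
  infeasible; per-variable calibration is the supported path.
- Cutoff recovery by the recalibration search needs a strong true score
  effect; at the published effect sizes (per-point odds ratios near 1.4)
  the AUC landscape at n = 10⁴ is too flat for reliable one-step
  recovery, which mirrors the genuine statistical difficulty of the
  underlying problem rather than a defect of the search.
- No imputation: records missing a score predictor fail scoring with a
  per-record error; records missing ventilator settings are excluded
  (and counted) from the sensitivity subset.
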