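# Methods

## The screening rule and its temporal semantics

The detector is a deterministic rule over a per-encounter stream of
time-stamped observations. Six criteria exist: four SIRS criteria
(temperature ≤ 36 °C or ≥ 38 °C, heart rate ≥ 90 /min, respiratory rate
≥ 20 /min, and a composite WBC criterion — total count ≤ 4,000 or
≥ 12,000 cells/mm³ or > 10 % band forms) and two shock signs (systolic BP
≤ 90 mm Hg, lactate ≥ 2.0). All boundaries are inclusive except bands,
which is strict. The composite WBC criterion counts once however many of
its routes are abnormal.

Three semantic choices define the engine:

1. **Persistence.** A satisfied criterion never expires within the
   encounter. This models an asynchronous EMR screen in which findings
   from different time points combine; it also means the satisfied set is
   monotone non-decreasing, which the oracle tests exploit.
2. **Activation and repeats.** The first alert fires at the timestamp of
   the observation batch that first makes the joint condition
   (≥ `sirs_required` SIRS and ≥ `shock_required` shock) true. A repeat
   fires when a previously unsatisfied criterion becomes satisfied
   ("strict growth"). Under strict growth the per-encounter ceiling is
   `1 + (6 − sirs_required − shock_required)` = 4 alerts at the defaults.
   Production systems of this kind have been observed to produce up to 6
   alerts for one patient, which strict growth cannot do; the config
   switch `repeat_on_reconfirmation` (default off) additionally re-fires
   when an already-satisfied criterion is re-confirmed by a new abnormal
   measurement, which removes the ceiling. Both semantics are implemented;
   neither is guessed to be "the" production behaviour.
3. **Batching.** Observations sharing a timestamp are applied as one
   batch and the condition is checked once per batch — vitals are charted
   as a set, and sub-timestamp ordering carries no information. This makes
   the emitted alerts invariant to permutations within a timestamp.

Timestamp ties are otherwise kept in ingestion order (stable sort).
Ages are carried for description but never alter the rule. Temperature is
accepted in °C or °F and normalized to °C at parse time; lactate is
compared against the configured threshold in whatever unit the deployment
charts (the conventional printed threshold, 2.0, is stored unit-agnostic
and deliberately never converted between mg/dL and mmol/L — flagging this
rather than guessing a conversion). Non-physiologic values still evaluate
(manually charted EMR entries are taken at face value); a separate QC pass
lists values outside broad physiologic ranges without blocking them.

## Accuracy analysis under partial verification

All alerted encounters are adjudicated; only a random sample of
non-alerted ones is. The estimable quantities are PPV = tp/(tp+fp) and an
NPV *estimate* restricted to the reviewed non-alert sample. Sensitivity,
specificity and AUROC are not estimable under this design, and the report
object carries them in a `non_estimable_metrics` list rather than values —
a refusal asserted by test.

Intervals are Clopper–Pearson exact, computed from the beta-quantile
identity (lower = Beta(α/2; k, n−k+1), upper = Beta(1−α/2; k+1, n−k),
with the k = 0 and k = n endpoints pinned at 0 and 1). The exact method is
required because the NPV numerator equals its denominator (300/300), where
Wald-type intervals degenerate; the exact lower bound is (α/2)^(1/n).
Tests verify the implementation against two independent routes: bisection
on the binomial tail probabilities and statsmodels'
`proportion_confint(method="beta")`, plus exact-enumeration coverage
(≥ 0.95 over n = 5..50, p = 0.05..0.95).

Cohen's κ = (p_o − p_e)/(1 − p_e) delegates to scikit-learn with one
documented convention on top: when both raters use a single identical
category, p_e = p_o = 1 and κ is returned as 1.

Category tables are multi-label (a patient may have several infections or
conditions), so percentage columns may sum over 100 %; disposition columns
are exclusive and sum to 100 %. Display rounding is half-up to one decimal
on the percent scale. The packaged reference cohort expands published
group-level summary counts into per-encounter labels whose marginals are
exact; since the joint category structure was never published, categories
are distributed cyclically, which preserves every marginal and guarantees
each septic patient at least one infection category. The published 2×2
table's printed column totals are internally inconsistent with its cells;
totals are always recomputed from cells here.

Alerts-per-patient summaries use Tukey's inclusive hinges for the
quartiles: deterministic, and on small-integer counts the hinges land on
observed values for the cohort sizes of interest.

## Synthetic cohort generator

The generator emulates the *statistical* structure the evaluation
assumes — it is not a physiologic simulator. Each encounter is a 2–12 h
ED stay (uniform) with all four vitals charted every 30 minutes
(a typical nursing cadence; the exact cadence is a package choice) and
labs appearing only when scheduled. Undisturbed values are truncated
normals confined to a safe band at least one measurement resolution away
from every threshold, so no accidental criterion can fire; scheduled
abnormal values are drawn uniformly inside the abnormal region, again one
resolution inside the boundary. This construction tests thresholds and
temporal semantics without claiming clinical realism: it does not model
trends, treatment response, missingness, charting delays or entry errors,
so passing tests demonstrate correctness of the rule engine and
evaluation machinery, not detection performance on real patients.

Alert-target encounters schedule two SIRS criteria and one shock sign at
or before a first-activation slot, then `E` additional distinct criteria
at strictly later, distinct slots; under strict-growth semantics the
encounter emits exactly `1 + E` alerts. `E` is drawn from
`extra_criteria_pmf`, default (0.44, 0.52, 0.04) over {0, 1, 2}. This pmf
is the generator's one tuned constant: it is chosen so the
alerts-per-patient distribution at n = 795 has median 2 and IQR [1, 2]
with overwhelming probability (the median stays at 2 unless a
Binomial(795, 0.44) draw exceeds its mean by ≈ 3.4 standard deviations),
at a mean of 1.60 alerts per alerting patient. A scalar "rate" parameter
fed through a standard counting distribution cannot produce this shape,
which is why the knob is a pmf rather than a mean.

Non-alert encounters draw one of four patterns — unremarkable, a single
SIRS criterion, 2–4 SIRS criteria without any shock sign (the
infected-but-not-septic presentation), or a shock sign with at most one
SIRS criterion — none of which can satisfy the joint condition. They are
nevertheless run through the alert engine and redrawn if they ever alert,
so label purity holds by construction, not by assumption. Labels follow
the published group structure: alerting encounters are septic with
probability `ppv_target` (default 0.447); category sets are independent
per-category Bernoulli draws from the published per-group frequencies
(the multi-label table note supports independence as a modelling choice,
though the true joint distribution is unknown); dispositions are
categorical draws from the per-group admission/death/discharge rates. A
septic label with an empty category draw falls back to the modal
infection category so the label invariant always holds.

All randomness flows through one `numpy` generator seeded from
`CohortSpec.seed`; identical specs produce identical cohorts.

## Numerical and interface choices

* Timestamps are ISO-8601 and must carry a timezone offset (ED streams
  cross midnight and DST); naive timestamps are rejected at parse time.
* CSV dialect is RFC 4180 with a required header; JSON-lines mirrors the
  CSV fields. Unknown observation kinds and config keys are rejected by
  name, malformed rows by line number.
* Validation never raises; it returns a list of named violations.
  Parsing, by contrast, fails fast.
* The problem sizes exercised by the test suite and the acceptance script
  (full 795 + 300 cohort, 10,000 random streams for the engine/oracle
  equivalence, the complete coverage grid) run in seconds; they are the
  study-scale conditions, not reductions.

## Known limitations

* The generator's trajectories are piecewise-constant and
  stationarity-free; no physiologic coupling between vitals.
* The lactate threshold is unit-agnostic by design; deployments charting
  mmol/L must set `lactate_min` accordingly.
* NPV extrapolation beyond the reviewed sample is deliberately not
  offered, and no verification-bias-corrected sensitivity estimator is
  included.
* Pediatric SIRS variants are out of scope; the rule is age-invariant.
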