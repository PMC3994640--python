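# edsepsis

Rule-based sepsis screening for the emergency department, with the
diagnostic-accuracy analysis appropriate to a partial-verification study
design, and a seeded synthetic ED cohort generator so the entire pipeline
can be exercised without any patient data.

## The problem and the rule

Sepsis — serious infection accompanied by systemic inflammation and a sign
of shock — is easy to miss at ED presentation. An EMR-embedded screen can
watch the charted vitals and labs of every patient and raise a **sepsis
alert** when

* at least **2 of 4 SIRS criteria** are fulfilled:
  temperature ≤ 36 °C or ≥ 38 °C; heart rate ≥ 90 /min; respiratory rate
  ≥ 20 /min; WBC ≤ 4,000 or ≥ 12,000 cells/mm³ **or** > 10 % bands
  (one composite criterion), **and**
* at least **1 sign of shock**: systolic BP ≤ 90 mm Hg or lactate ≥ 2.0.

Criteria accumulate **asynchronously**: a criterion satisfied by any
observation stays satisfied for the rest of the encounter, so abnormal
values from different time points combine. The first alert fires the
moment the joint condition becomes true; each *additional* criterion
fulfilled afterwards re-fires the alert (an optional switch also re-fires
on reconfirmation of an already-satisfied criterion).

Because chart review adjudicates *all* alerted patients but only a random
sample of non-alerted ones, only PPV and a sample-based NPV are estimable;
sensitivity, specificity and AUROC are not, and the report says so rather
than printing them. Confidence intervals are Clopper–Pearson exact — with
300/300 sepsis-free reviewed non-alerts the normal approximation degenerates,
while the exact lower bound is (α/2)^(1/300) ≈ 98.8 %.

## Worked example

```python
from edsepsis import (CriteriaConfig, evaluate_cohort, process_encounter,
                      reference_cohort)
from edsepsis.io import render_report_text

# packaged reference cohort: 795 alerted + 300 reviewed non-alert encounters
alerted, labels = reference_cohort()
report = evaluate_cohort(alerted, labels, negatives_sampled=True)
print(render_report_text(report))
```

prints (abridged):

```
Alert vs chart-review sepsis (reviewed encounters)
  Alert     Sepsis  No sepsis  Total
  Yes        355        440    795
  No           0        300    300

PPV 44.7% (95% CI 41.2–48.2%)
Estimated NPV 100.0% (95% CI 98.8–100.0%)
Not estimable under this design: sensitivity, specificity, auroc

Infection types, true-positive alerts
  pneumonia_respiratory         135 (38.0)
  urinary_tract                 116 (32.7)
  ...
```

Meaning: of 795 alerted encounters, 355 had chart-confirmed sepsis
(PPV 44.7 %) — roughly every second alert is a true sepsis case; none of
the 300 reviewed non-alerts was septic, so the sample-based NPV estimate
is 100 % with an exact lower bound of 98.8 %.

The same pipeline is available from the shell:

```bash
edsepsis simulate --out-dir cohort/ --seed 1          # synthetic ED cohort
edsepsis screen   --observations cohort/observations.csv --out alerts.csv
edsepsis evaluate --alerts alerts.csv --labels cohort/labels.csv --out report.json
edsepsis validate --observations cohort/observations.csv
```

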