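"""Packaged reference cohort: summary counts of a published three-month
single-center ED screening evaluation, expanded into per-encounter labels.

The published study adjudicated 795 alerted encounters (355 with confirmed
sepsis, 440 without) and a random sample of 300 non-alerted encounters
(none septic), and reported per-group infection/condition category counts
and ED dispositions. This module rebuilds an encounter-level label set
whose marginal counts reproduce those tables exactly; the joint structure
across categories (which patient has which combination) is not published,
so categories are distributed cyclically — every marginal count is exact
and every septic patient receives at least one infection category.

The fixture is deterministic and involves no randomness.
"""

from __future__ import annotations

from .evaluation import Group
from .model import ChartReviewLabel, Disposition

N_TRUE_POSITIVE = 355
N_FALSE_POSITIVE = 440
N_NONALERT_REVIEWED = 300

#: Infection categories among the 355 confirmed-sepsis alerts (multi-label).
TP_INFECTION_COUNTS: dict[str, int] = {
    "pneumonia_respiratory": 135,
    "urinary_tract": 116,
    "gastrointestinal": 54,
    "bacteremia": 49,
    "cellulitis": 33,
    "abscess": 26,
    "gynecologic": 5,
    "cns": 3,
    "other": 12,
}

#: Medical conditions among the 440 false-positive alerts (multi-label).
FP_CONDITION_COUNTS: dict[str, int] = {
    "gastrointestinal": 115,
    "trauma": 113,
    "cardiovascular": 88,
    "respiratory": 43,
    "overdose_intoxication": 42,
    "cns": 39,
    "renal": 34,
    "hematologic_oncologic": 15,
    "other": 119,
}

#: Medical conditions among the 300 reviewed non-alerts, including
#: infections that did not fulfil the sepsis definition (multi-label).
TN_CONDITION_COUNTS: dict[str, int] = {
    "urinary_tract_infection": 27,
    "respiratory_infection": 25,
    "abscess": 8,
    "cellulitis": 5,
    "gastrointestinal_infection": 4,
    "gynecologic_infection": 4,
    "cns_infection": 0,
    "bacteremia": 0,
    "other_infection": 21,
    "trauma": 42,
    "gastrointestinal": 30,
    "cns": 16,
    "overdose_intoxication": 11,
    "cardiovascular": 8,
    "respiratory": 3,
    "renal": 4,
    "hematologic_oncologic": 1,
    "other": 136,
}

#: ED dispositions per group: (admitted, died in ED, discharged).
DISPOSITION_COUNTS: dict[Group, tuple[int, int, int]] = {
    Group.TRUE_POSITIVE: (323, 1, 31),
    Group.FALSE_POSITIVE: (365, 1, 74),
    Group.TRUE_NEGATIVE: (17, 0, 283),
}

#: Alert-multiplicity summary over the 795 alerted encounters.
TOTAL_ALERTS = 1224
ALERTS_MEDIAN = 2
ALERTS_IQR = (1, 2)
ALERTS_MAX_OBSERVED = 6


def _assign_categories(n: int, counts: dict[str, int]) -> list[set[str]]:
    """Distribute marginal category counts over n patients cyclically.

    Each category's count is assigned to a contiguous (wrapping) run of
    patient indices starting where the previous category ended. Because
    the summed counts reach at least n in every group, the wrap guarantees
    every patient at least one category while keeping each marginal exact.
    """
    sets: list[set[str]] = [set() for _ in range(n)]
    pos = 0
    for cat, count in counts.items():
        for _ in range(count):
            sets[pos % n].add(cat)
            pos += 1
    return sets


def _dispositions(n: int, counts: tuple[int, int, int]) -> list[Disposition]:
    admitted, died, discharged = counts
    assert admitted + died + discharged == n
    return (
        [Disposition.ADMITTED] * admitted
        + [Disposition.DIED_IN_ED] * died
        + [Disposition.DISCHARGED] * discharged
    )


def reference_cohort() -> tuple[set[str], dict[str, ChartReviewLabel]]:
    """Return (alerted encounter ids, labels) reproducing the study tables.

    Encounter ids: ``TP-0001``.., ``FP-0001``.., ``NA-0001``.. (non-alert).
    """
    labels: dict[str, ChartReviewLabel] = {}
    alerted: set[str] = set()

    tp_cats = _assign_categories(N_TRUE_POSITIVE, TP_INFECTION_COUNTS)
    tp_disp = _dispositions(N_TRUE_POSITIVE, DISPOSITION_COUNTS[Group.TRUE_POSITIVE])
    for i in range(N_TRUE_POSITIVE):
        eid = f"TP-{i + 1:04d}"
        alerted.add(eid)
        labels[eid] = ChartReviewLabel(
            encounter_id=eid,
            sepsis=True,
            infection_categories=frozenset(tp_cats[i]),
            disposition=tp_disp[i],
        )

    fp_cats = _assign_categories(N_FALSE_POSITIVE, FP_CONDITION_COUNTS)
    fp_disp = _dispositions(N_FALSE_POSITIVE, DISPOSITION_COUNTS[Group.FALSE_POSITIVE])
    for i in range(N_FALSE_POSITIVE):
        eid = f"FP-{i + 1:04d}"
        alerted.add(eid)
        labels[eid] = ChartReviewLabel(
            encounter_id=eid,
            sepsis=False,
            condition_categories=frozenset(fp_cats[i]),
            disposition=fp_disp[i],
        )

    tn_cats = _assign_categories(N_NONALERT_REVIEWED, TN_CONDITION_COUNTS)
    tn_disp = _dispositions(N_NONALERT_REVIEWED, DISPOSITION_COUNTS[Group.TRUE_NEGATIVE])
    for i in range(N_NONALERT_REVIEWED):
        eid = f"NA-{i + 1:04d}"
        labels[eid] = ChartReviewLabel(
            encounter_id=eid,
            sepsis=False,
            condition_categories=frozenset(tn_cats[i]),
            disposition=tn_disp[i],
        )

    return alerted, labels
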