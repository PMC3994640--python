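"""Seeded generator of labelled synthetic ED encounters.

The generator emulates the statistical structure the accuracy evaluation
assumes, not clinical physiology. Each encounter is a 2–12 hour ED stay
with vitals charted at 30-minute intervals (piecewise-constant with
truncated-normal noise inside a safe normal band) and labs appearing only
when scheduled. Alert-target encounters are built constructively: two SIRS
criteria and one shock sign are scheduled to become abnormal at distinct
charting slots, with optional additional criteria scheduled after the
first activation to drive repeat alerts. Non-alert encounters may satisfy
at most one SIRS criterion, several SIRS criteria without shock, or a
shock sign without SIRS — mirroring infected-but-not-septic ED patients —
and are re-checked against the alert engine so that label purity holds by
construction.

Abnormal values are drawn uniformly inside the abnormal region with a
margin of one measurement resolution, so the generated data exercise the
thresholds without depending on clinical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Optional

import numpy as np

from .alerts import process_encounter
from .criteria import SHOCK_CRITERIA, SIRS_CRITERIA, CriterionId
from .evaluation import Group
from .model import ChartReviewLabel, CriteriaConfig, Disposition, Encounter, Observation, ObservationKind
from .reference import (
    DISPOSITION_COUNTS,
    FP_CONDITION_COUNTS,
    N_FALSE_POSITIVE,
    N_NONALERT_REVIEWED,
    N_TRUE_POSITIVE,
    TN_CONDITION_COUNTS,
    TP_INFECTION_COUNTS,
)

_CHART_INTERVAL_MIN = 30
_STAY_HOURS = (2.0, 12.0)
_BASE_TIME = datetime(2012, 1, 3, tzinfo=timezone.utc)
_WINDOW_DAYS = 88  # encounters scattered over a three-month ED period

_VITAL_KINDS = (
    ObservationKind.TEMPERATURE,
    ObservationKind.HEART_RATE,
    ObservationKind.RESPIRATORY_RATE,
    ObservationKind.SYSTOLIC_BP,
)

_CANONICAL_UNIT = {
    ObservationKind.TEMPERATURE: "degC",
    ObservationKind.HEART_RATE: "beats/min",
    ObservationKind.RESPIRATORY_RATE: "breaths/min",
    ObservationKind.SYSTOLIC_BP: "mm Hg",
    ObservationKind.WBC_COUNT: "cells/mm3",
    ObservationKind.BANDS_PERCENT: "percent",
    ObservationKind.LACTATE: "mg/dL",
}

# Safe bands keep undisturbed draws at least one measurement resolution
# away from every alert threshold: (mean, sd, clip_lo, clip_hi).
_SAFE_PARAMS = {
    ObservationKind.TEMPERATURE: (37.0, 0.3, 36.2, 37.8),
    ObservationKind.HEART_RATE: (75.0, 8.0, 55.0, 88.0),
    ObservationKind.RESPIRATORY_RATE: (14.0, 2.0, 10.0, 18.0),
    ObservationKind.SYSTOLIC_BP: (120.0, 12.0, 96.0, 180.0),
    ObservationKind.WBC_COUNT: (8000.0, 1500.0, 4500.0, 11500.0),
    ObservationKind.BANDS_PERCENT: (3.0, 2.0, 0.0, 9.0),
    ObservationKind.LACTATE: (1.0, 0.3, 0.2, 1.8),
}


def _fractions(counts: dict[str, int], denom: int) -> dict[str, float]:
    return {c: n / denom for c, n in counts.items()}


def _disposition_probs(group: Group) -> dict[Disposition, float]:
    adm, died, disc = DISPOSITION_COUNTS[group]
    n = adm + died + disc
    return {
        Disposition.ADMITTED: adm / n,
        Disposition.DIED_IN_ED: died / n,
        Disposition.DISCHARGED: disc / n,
    }


@dataclass
class CohortSpec:
    """Parameters of a synthetic labelled ED cohort.

    Defaults reproduce the published study conditions: 795 alerting
    encounters with true-sepsis probability 0.447, 300 reviewed
    non-alerting encounters, category mixes and disposition probabilities
    taken from the published per-group tables, and a pmf over the number
    of additional criteria fulfilled after the first activation that
    yields alerts-per-patient median 2 with IQR [1, 2].
    """

    n_alert_target: int = N_TRUE_POSITIVE + N_FALSE_POSITIVE
    ppv_target: float = 0.447
    n_nonalert: int = N_NONALERT_REVIEWED
    category_mix_tp: dict[str, float] = field(
        default_factory=lambda: _fractions(TP_INFECTION_COUNTS, N_TRUE_POSITIVE)
    )
    category_mix_fp: dict[str, float] = field(
        default_factory=lambda: _fractions(FP_CONDITION_COUNTS, N_FALSE_POSITIVE)
    )
    category_mix_tn: dict[str, float] = field(
        default_factory=lambda: _fractions(TN_CONDITION_COUNTS, N_NONALERT_REVIEWED)
    )
    disposition_probs: dict[Group, dict[Disposition, float]] = field(
        default_factory=lambda: {g: _disposition_probs(g) for g in Group}
    )
    #: pmf over 0, 1, 2, ... additional criteria fulfilled after the first
    #: activation; each additional criterion produces one repeat alert.
    extra_criteria_pmf: tuple[float, ...] = (0.44, 0.52, 0.04)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_alert_target < 0 or self.n_nonalert < 0:
            raise ValueError("cohort sizes must be non-negative")
        if not 0.0 <= self.ppv_target <= 1.0:
            raise ValueError("ppv_target must be in [0, 1]")
        for mix in (self.category_mix_tp, self.category_mix_fp, self.category_mix_tn):
            if any(not 0.0 <= p <= 1.0 for p in mix.values()):
                raise ValueError("category probabilities must be in [0, 1]")
        for probs in self.disposition_probs.values():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError("disposition probabilities must sum to 1 per group")
        if abs(sum(self.extra_criteria_pmf) - 1.0) > 1e-9:
            raise ValueError("extra_criteria_pmf must sum to 1")
        if len(self.extra_criteria_pmf) > 4:
            raise ValueError("at most 3 additional criteria exist beyond the first activation")


def _pick(rng: np.random.Generator, seq: list, size: int = 1) -> list:
    """Choose ``size`` distinct items by index (rng.choice coerces enums)."""
    idx = rng.choice(len(seq), size=size, replace=False)
    return [seq[int(i)] for i in np.atleast_1d(idx)]


def _safe_value(rng: np.random.Generator, kind: ObservationKind) -> float:
    mean, sd, lo, hi = _SAFE_PARAMS[kind]
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _abnormal(rng: np.random.Generator, crit: CriterionId) -> tuple[ObservationKind, float]:
    """Draw (kind, value) satisfying the criterion, one resolution inside."""
    if crit is CriterionId.SIRS_TEMP:
        if rng.random() < 0.7:
            return ObservationKind.TEMPERATURE, float(rng.uniform(38.1, 40.5))
        return ObservationKind.TEMPERATURE, float(rng.uniform(34.0, 35.9))
    if crit is CriterionId.SIRS_HR:
        return ObservationKind.HEART_RATE, float(rng.uniform(91.0, 140.0))
    if crit is CriterionId.SIRS_RR:
        return ObservationKind.RESPIRATORY_RATE, float(rng.uniform(21.0, 40.0))
    if crit is CriterionId.SIRS_WBC:
        r = rng.random()
        if r < 0.7:
            return ObservationKind.WBC_COUNT, float(rng.uniform(12500.0, 25000.0))
        if r < 0.9:
            return ObservationKind.WBC_COUNT, float(rng.uniform(1000.0, 3500.0))
        return ObservationKind.BANDS_PERCENT, float(rng.uniform(11.0, 30.0))
    if crit is CriterionId.SHOCK_SBP:
        return ObservationKind.SYSTOLIC_BP, float(rng.uniform(60.0, 89.0))
    if crit is CriterionId.SHOCK_LACTATE:
        return ObservationKind.LACTATE, float(rng.uniform(2.1, 8.0))
    raise ValueError(crit)


def _build_encounter(
    rng: np.random.Generator,
    eid: str,
    schedule: dict[int, list[CriterionId]],
    min_slots: int,
) -> Encounter:
    """Assemble an encounter whose abnormalities follow ``schedule``.

    ``schedule`` maps charting-slot index -> criteria turning abnormal at
    that slot. All vitals are charted every slot; labs appear only when
    scheduled. Unscheduled values stay in the safe band.
    """
    stay_h = rng.uniform(*_STAY_HOURS)
    n_slots = max(int(stay_h * 60 / _CHART_INTERVAL_MIN), min_slots)
    start = _BASE_TIME + timedelta(
        minutes=float(rng.integers(0, _WINDOW_DAYS * 24 * 60))
    )
    obs: list[Observation] = []
    for slot in range(n_slots):
        ts = start + timedelta(minutes=slot * _CHART_INTERVAL_MIN)
        abnormal_here: dict[ObservationKind, float] = {}
        for crit in schedule.get(slot, ()):
            kind, value = _abnormal(rng, crit)
            abnormal_here[kind] = value
        for kind in _VITAL_KINDS:
            value = abnormal_here.pop(kind, None)
            if value is None:
                value = _safe_value(rng, kind)
            obs.append(Observation(eid, ts, kind, value, _CANONICAL_UNIT[kind]))
        for kind, value in abnormal_here.items():  # scheduled labs
            obs.append(Observation(eid, ts, kind, value, _CANONICAL_UNIT[kind]))
    age = float(np.clip(rng.normal(55.0, 20.0), 18.0, 100.0))
    return Encounter(encounter_id=eid, observations=obs, patient_age=age)


def _alert_schedule(
    rng: np.random.Generator, n_extra: int
) -> tuple[dict[int, list[CriterionId]], int]:
    """Schedule 2 SIRS + 1 shock, then ``n_extra`` later distinct criteria.

    Extra criteria are placed at strictly increasing slots after the first
    activation so each produces one repeat alert under strict-growth
    semantics. Returns (schedule, min_slots).
    """
    initial = _pick(rng, sorted(SIRS_CRITERIA), 2) + _pick(rng, sorted(SHOCK_CRITERIA), 1)
    remaining = sorted((SIRS_CRITERIA | SHOCK_CRITERIA) - set(initial))
    extras = _pick(rng, remaining, n_extra) if n_extra else []

    first_alert_slot = int(rng.integers(1, 4))
    schedule: dict[int, list[CriterionId]] = {}
    rng.shuffle(initial)
    for crit in initial[:-1]:
        schedule.setdefault(int(rng.integers(0, first_alert_slot + 1)), []).append(crit)
    schedule.setdefault(first_alert_slot, []).append(initial[-1])
    slot = first_alert_slot
    for crit in extras:
        slot += int(rng.integers(1, 3))
        schedule.setdefault(slot, []).append(crit)
    return schedule, slot + 1


def _nonalert_schedule(rng: np.random.Generator) -> dict[int, list[CriterionId]]:
    """Schedule criteria that can never jointly satisfy the alert rule."""
    pattern = int(rng.choice(4, p=[0.45, 0.30, 0.15, 0.10]))
    if pattern == 0:  # entirely unremarkable
        chosen: list[CriterionId] = []
    elif pattern == 1:  # a single SIRS criterion
        chosen = _pick(rng, sorted(SIRS_CRITERIA), 1)
    elif pattern == 2:  # SIRS without any shock sign (infection, not septic)
        chosen = _pick(rng, sorted(SIRS_CRITERIA), int(rng.integers(2, 5)))
    else:  # shock sign without enough SIRS
        chosen = _pick(rng, sorted(SHOCK_CRITERIA), 1)
        if rng.random() < 0.5:
            chosen += _pick(rng, sorted(SIRS_CRITERIA), 1)
    schedule: dict[int, list[CriterionId]] = {}
    for crit in chosen:
        schedule.setdefault(int(rng.integers(0, 4)), []).append(crit)
    return schedule


def _draw_categories(
    rng: np.random.Generator, mix: dict[str, float], require_one: bool
) -> frozenset[str]:
    cats = {c for c, p in mix.items() if rng.random() < p}
    if require_one and not cats and mix:
        # fall back to the modal category so septic labels stay well-formed
        cats = {max(mix.items(), key=lambda kv: kv[1])[0]}
    return frozenset(cats)


def _draw_disposition(
    rng: np.random.Generator, probs: dict[Disposition, float]
) -> Disposition:
    dispositions = list(probs)
    p = np.array([probs[d] for d in dispositions])
    return dispositions[int(rng.choice(len(dispositions), p=p / p.sum()))]


def generate_cohort(
    spec: CohortSpec, cfg: Optional[CriteriaConfig] = None
) -> tuple[list[Encounter], dict[str, ChartReviewLabel]]:
    """Generate (encounters, labels); deterministic given ``spec.seed``.

    Every alert-target encounter triggers at least one alert and every
    non-alert encounter triggers none — both verified by running the alert
    engine during generation (non-alert draws are rejected and redrawn if
    they ever alert, which the safe-band construction should preclude).
    """
    cfg = cfg or CriteriaConfig()
    rng = np.random.default_rng(spec.seed)
    encounters: list[Encounter] = []
    labels: dict[str, ChartReviewLabel] = {}

    extras_support = np.arange(len(spec.extra_criteria_pmf))
    pmf = np.array(spec.extra_criteria_pmf)

    for i in range(spec.n_alert_target):
        eid = f"SIM-A{i + 1:05d}"
        n_extra = int(rng.choice(extras_support, p=pmf))
        schedule, min_slots = _alert_schedule(rng, n_extra)
        enc = _build_encounter(rng, eid, schedule, min_slots)
        assert process_encounter(enc, cfg), f"{eid}: constructive alert guarantee failed"
        septic = bool(rng.random() < spec.ppv_target)
        group = Group.TRUE_POSITIVE if septic else Group.FALSE_POSITIVE
        disposition = _draw_disposition(rng, spec.disposition_probs[group])
        enc.disposition = disposition
        encounters.append(enc)
        labels[eid] = ChartReviewLabel(
            encounter_id=eid,
            sepsis=septic,
            infection_categories=(
                _draw_categories(rng, spec.category_mix_tp, require_one=True) if septic else frozenset()
            ),
            condition_categories=(
                frozenset() if septic else _draw_categories(rng, spec.category_mix_fp, require_one=False)
            ),
            disposition=disposition,
        )

    for i in range(spec.n_nonalert):
        eid = f"SIM-N{i + 1:05d}"
        for _attempt in range(100):
            enc = _build_encounter(rng, eid, _nonalert_schedule(rng), min_slots=4)
            if not process_encounter(enc, cfg):
                break
        else:  # pragma: no cover - safe-band construction precludes this
            raise RuntimeError(f"{eid}: could not draw a non-alerting encounter")
        disposition = _draw_disposition(rng, spec.disposition_probs[Group.TRUE_NEGATIVE])
        enc.disposition = disposition
        encounters.append(enc)
        labels[eid] = ChartReviewLabel(
            encounter_id=eid,
            sepsis=False,
            condition_categories=_draw_categories(rng, spec.category_mix_tn, require_one=False),
            disposition=disposition,
        )

    return encounters, labels
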