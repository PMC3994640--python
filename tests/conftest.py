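"""Shared fixtures: observation builders, a random stream generator, and a
brute-force prefix-recomputation oracle for the alert engine."""

from __future__ import annotations

import itertools
from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from edsepsis.criteria import SHOCK_CRITERIA, SIRS_CRITERIA, evaluate
from edsepsis.model import CriteriaConfig, Encounter, Observation, ObservationKind

T0 = datetime(2012, 1, 15, 8, 0, tzinfo=timezone.utc)

CANONICAL_UNIT = {
    ObservationKind.TEMPERATURE: "degC",
    ObservationKind.HEART_RATE: "beats/min",
    ObservationKind.RESPIRATORY_RATE: "breaths/min",
    ObservationKind.SYSTOLIC_BP: "mm Hg",
    ObservationKind.WBC_COUNT: "cells/mm3",
    ObservationKind.BANDS_PERCENT: "percent",
    ObservationKind.LACTATE: "mg/dL",
}

# Value pools spanning normal and abnormal ranges for random streams,
# including exact threshold values to exercise boundaries.
VALUE_POOL = {
    ObservationKind.TEMPERATURE: [35.0, 36.0, 36.5, 37.2, 38.0, 39.5],
    ObservationKind.HEART_RATE: [60.0, 89.0, 90.0, 120.0],
    ObservationKind.RESPIRATORY_RATE: [12.0, 19.0, 20.0, 30.0],
    ObservationKind.SYSTOLIC_BP: [80.0, 90.0, 91.0, 130.0],
    ObservationKind.WBC_COUNT: [3000.0, 4000.0, 8000.0, 12000.0, 18000.0],
    ObservationKind.BANDS_PERCENT: [2.0, 10.0, 10.1, 25.0],
    ObservationKind.LACTATE: [0.8, 1.9, 2.0, 4.5],
}


def obs(eid: str, minute: int, kind: ObservationKind, value: float, unit: str | None = None) -> Observation:
    return Observation(
        encounter_id=eid,
        timestamp=T0 + timedelta(minutes=minute),
        kind=kind,
        value=value,
        unit=unit if unit is not None else CANONICAL_UNIT[kind],
    )


def make_encounter(eid: str, specs: list[tuple[int, ObservationKind, float]]) -> Encounter:
    return Encounter(
        encounter_id=eid,
        observations=[obs(eid, m, k, v) for m, k, v in specs],
    ).sorted()


def random_stream(rng: np.random.Generator, eid: str = "R", max_len: int = 12) -> Encounter:
    """Random observation stream with timestamp ties; sorted stably."""
    n = int(rng.integers(0, max_len + 1))
    kinds = list(VALUE_POOL)
    specs = []
    minute = 0
    for _ in range(n):
        if specs and rng.random() < 0.3:
            pass  # reuse current minute -> timestamp tie
        else:
            minute += int(rng.integers(1, 60))
        kind = kinds[int(rng.integers(len(kinds)))]
        pool = VALUE_POOL[kind]
        specs.append((minute, kind, pool[int(rng.integers(len(pool)))]))
    return make_encounter(eid, specs)


def oracle_alerts(e: Encounter, cfg: CriteriaConfig) -> list[tuple[datetime, frozenset]]:
    """Brute force: recompute the satisfied-criteria set from scratch for
    every timestamp-batch prefix; an alert fires at each prefix where the
    joint condition holds and the set strictly grew since the previous
    alert (or first became sufficient). Returns (time, criteria-set) pairs.
    """
    batches = [
        (ts, list(group))
        for ts, group in itertools.groupby(e.observations, key=lambda o: o.timestamp)
    ]
    alerts: list[tuple[datetime, frozenset]] = []
    last_emitted: frozenset | None = None
    for i in range(1, len(batches) + 1):
        prefix = [o for _, batch in batches[:i] for o in batch]
        sat = frozenset(c for c in (evaluate(o, cfg) for o in prefix) if c is not None)
        met = (
            len(sat & SIRS_CRITERIA) >= cfg.sirs_required
            and len(sat & SHOCK_CRITERIA) >= cfg.shock_required
        )
        if met and (last_emitted is None or sat != last_emitted):
            alerts.append((batches[i - 1][0], sat))
            last_emitted = sat
    return alerts


@pytest.fixture
def cfg() -> CriteriaConfig:
    return CriteriaConfig()
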