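"""Stateful per-encounter alert engine with repeat-activation semantics.

The engine mimics a real-time EMR screen that assesses data elements
asynchronously: a criterion, once satisfied by any observation, stays
satisfied for the remainder of the encounter (no expiry window), so
abnormal values from differing time points combine to activate an alert.

The first alert fires at the timestamp of the observation batch that first
makes the joint condition (≥ ``sirs_required`` SIRS criteria AND
≥ ``shock_required`` shock signs) true. Afterwards, a repeat alert fires
whenever a previously unsatisfied criterion becomes satisfied ("strict
growth"). With ``repeat_on_reconfirmation`` enabled in the config, a repeat
additionally fires when an already-satisfied criterion is re-confirmed by a
new abnormal measurement — the behaviour a production system that re-fires
on every qualifying result exhibits.

Observations sharing a timestamp are applied as one batch (vitals are
charted as a set) and the alert condition is checked once per batch, which
makes the output invariant to permutations within a timestamp.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Optional, Sequence

from .criteria import SHOCK_CRITERIA, SIRS_CRITERIA, CriterionId, evaluate
from .model import CriteriaConfig, Encounter

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SepsisAlert:
    """One emitted sepsis alert.

    ``satisfied_sirs`` / ``satisfied_shock`` snapshot the accumulated
    criteria at activation; ``activation_index`` is the 1-based ordinal of
    the alert within its encounter.
    """

    encounter_id: str
    activation_time: datetime
    activation_index: int
    satisfied_sirs: frozenset[CriterionId]
    satisfied_shock: frozenset[CriterionId]

    @property
    def satisfied_criteria(self) -> frozenset[CriterionId]:
        return self.satisfied_sirs | self.satisfied_shock


def process_encounter(e: Encounter, cfg: CriteriaConfig) -> list[SepsisAlert]:
    """Run the alert rule over one encounter; return alerts in time order."""
    satisfied: set[CriterionId] = set()
    alerts: list[SepsisAlert] = []
    condition_met = False

    for ts, batch in itertools.groupby(e.observations, key=lambda o: o.timestamp):
        grew = False
        reconfirmed = False
        for obs in batch:
            crit = evaluate(obs, cfg)
            if crit is None:
                continue
            if crit in satisfied:
                reconfirmed = True
            else:
                satisfied.add(crit)
                grew = True
        n_sirs = len(satisfied & SIRS_CRITERIA)
        n_shock = len(satisfied & SHOCK_CRITERIA)
        now_met = n_sirs >= cfg.sirs_required and n_shock >= cfg.shock_required
        fire = False
        if now_met and not condition_met:
            fire = True  # first activation
        elif condition_met and grew:
            fire = True  # additional criterion fulfilled
        elif condition_met and reconfirmed and cfg.repeat_on_reconfirmation:
            fire = True
        condition_met = condition_met or now_met
        if fire:
            alert = SepsisAlert(
                encounter_id=e.encounter_id,
                activation_time=ts,
                activation_index=len(alerts) + 1,
                satisfied_sirs=frozenset(satisfied & SIRS_CRITERIA),
                satisfied_shock=frozenset(satisfied & SHOCK_CRITERIA),
            )
            alerts.append(alert)
            logger.info(
                "sepsis alert: encounter=%s index=%d time=%s criteria=%s",
                alert.encounter_id,
                alert.activation_index,
                ts.isoformat(),
                ";".join(sorted(c.value for c in alert.satisfied_criteria)),
            )
    return alerts


def max_alerts_ceiling(cfg: CriteriaConfig) -> int:
    """Upper bound on alerts per encounter under strict-growth semantics.

    The first activation needs at least ``sirs_required + shock_required``
    criteria satisfied; each repeat needs one new criterion; six criteria
    exist in total. Under the defaults (2 SIRS + 1 shock) the ceiling is
    1 + (6 - 3) = 4.
    """
    total = len(SIRS_CRITERIA) + len(SHOCK_CRITERIA)
    return 1 + (total - (cfg.sirs_required + cfg.shock_required))


def _tukey_quartiles(sorted_values: Sequence[int]) -> tuple[float, float]:
    """Lower/upper hinges by Tukey's inclusive method.

    Each half includes the median position when n is odd; hinge = median
    of its half. Deterministic and well-behaved on small-integer data.
    """
    n = len(sorted_values)
    half = (n + 1) // 2  # include median in both halves when n odd
    lower = sorted_values[:half]
    upper = sorted_values[n - half:]

    def _median(vals: Sequence[int]) -> float:
        m = len(vals)
        mid = m // 2
        return float(vals[mid]) if m % 2 else (vals[mid - 1] + vals[mid]) / 2.0

    return _median(lower), _median(upper)


@dataclass(frozen=True)
class AlertCountSummary:
    """Alert-multiplicity summary over encounters with at least one alert."""

    n_encounters: int
    n_alerted: int
    total_alerts: int
    median: Optional[float]
    iqr: Optional[tuple[float, float]]
    max_alerts: int


def alert_counts(
    encounters: Iterable[Encounter], cfg: CriteriaConfig
) -> AlertCountSummary:
    """Tabulate per-encounter alert counts (alerting encounters only)."""
    counts = []
    n_total = 0
    for e in encounters:
        n_total += 1
        k = len(process_encounter(e, cfg))
        if k > 0:
            counts.append(k)
    if not counts:
        return AlertCountSummary(n_total, 0, 0, None, None, 0)
    counts.sort()
    mid = len(counts) // 2
    median = (
        float(counts[mid]) if len(counts) % 2 else (counts[mid - 1] + counts[mid]) / 2.0
    )
    return AlertCountSummary(
        n_encounters=n_total,
        n_alerted=len(counts),
        total_alerts=sum(counts),
        median=median,
        iqr=_tukey_quartiles(counts),
        max_alerts=counts[-1],
    )
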