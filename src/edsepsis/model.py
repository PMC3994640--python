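"""Core domain types for ED sepsis screening.

The vocabulary mirrors what an emergency-department EMR records: time-stamped
vital signs and a handful of laboratory results per encounter, plus the
chart-review labels an accuracy study adjudicates afterwards.

Temperature is the only kind accepted in two units; it is normalized to
Celsius at construction/parse time. Lactate thresholds are compared in
whatever unit the configuration states (the conventional printed threshold,
2.0, is treated as unit-agnostic; the stored unit string is kept verbatim).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Iterable, Optional, Sequence


class ObservationKind(str, enum.Enum):
    """Clinical measurement kinds the screening rule consumes."""

    TEMPERATURE = "TEMPERATURE"
    HEART_RATE = "HEART_RATE"
    RESPIRATORY_RATE = "RESPIRATORY_RATE"
    SYSTOLIC_BP = "SYSTOLIC_BP"
    WBC_COUNT = "WBC_COUNT"
    BANDS_PERCENT = "BANDS_PERCENT"
    LACTATE = "LACTATE"


class Disposition(str, enum.Enum):
    ADMITTED = "ADMITTED"
    DIED_IN_ED = "DIED_IN_ED"
    DISCHARGED = "DISCHARGED"


#: Accepted unit strings per observation kind. The first entry is canonical.
ACCEPTED_UNITS: dict[ObservationKind, tuple[str, ...]] = {
    ObservationKind.TEMPERATURE: ("degC", "C", "°C", "degF", "F", "°F"),
    ObservationKind.HEART_RATE: ("beats/min",),
    ObservationKind.RESPIRATORY_RATE: ("breaths/min",),
    ObservationKind.SYSTOLIC_BP: ("mm Hg", "mmHg"),
    ObservationKind.WBC_COUNT: ("cells/mm3", "cells/mm^3", "cells/mm³"),
    ObservationKind.BANDS_PERCENT: ("percent", "%"),
    ObservationKind.LACTATE: ("mg/dL", "mmol/L"),
}

_FAHRENHEIT_UNITS = frozenset({"degF", "F", "°F"})


def fahrenheit_to_celsius(value: float) -> float:
    return (value - 32.0) * 5.0 / 9.0


@dataclass(frozen=True)
class Observation:
    """One time-stamped clinical measurement for an encounter.

    Temperatures given in Fahrenheit are converted to Celsius on
    construction; every other kind is stored as given.
    """

    encounter_id: str
    timestamp: datetime
    kind: ObservationKind
    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.kind is ObservationKind.TEMPERATURE and self.unit in _FAHRENHEIT_UNITS:
            object.__setattr__(self, "value", fahrenheit_to_celsius(self.value))
            object.__setattr__(self, "unit", "degC")


@dataclass
class Encounter:
    """One ED visit: a time-ordered observation stream plus demographics.

    ``patient_age`` is carried for description only; the screening rule is
    age-invariant. ``disposition`` is optional and used only by evaluation.
    """

    encounter_id: str
    observations: list[Observation] = field(default_factory=list)
    patient_age: Optional[float] = None
    disposition: Optional[Disposition] = None

    def sorted(self) -> "Encounter":
        """Copy with observations stably sorted by timestamp.

        Stability preserves ingestion order among equal timestamps; the
        alert engine applies same-timestamp observations as one batch, so
        sub-timestamp order never changes its output.
        """
        return replace(self, observations=sorted(self.observations, key=lambda o: o.timestamp))


@dataclass(frozen=True)
class CriteriaConfig:
    """All thresholds of the screening rule.

    Defaults are the published ED rule: SIRS criteria are temperature
    ≤36 °C or ≥38 °C, respiratory rate ≥20/min, heart rate ≥90/min, and
    WBC ≤4,000 or ≥12,000 cells/mm³ or >10% bands (one composite
    criterion); shock signs are systolic BP ≤90 mm Hg or lactate ≥2.0.
    An alert requires ≥2 SIRS criteria plus ≥1 shock sign, accumulated
    asynchronously across the encounter.
    """

    temp_low: float = 36.0   # degC, inclusive
    temp_high: float = 38.0  # degC, inclusive
    rr_min: float = 20.0     # breaths/min, inclusive
    hr_min: float = 90.0     # beats/min, inclusive
    wbc_low: float = 4000.0  # cells/mm3, inclusive
    wbc_high: float = 12000.0  # cells/mm3, inclusive
    bands_min_pct: float = 10.0  # percent, strict >
    sbp_max: float = 90.0    # mm Hg, inclusive
    lactate_min: float = 2.0  # configured threshold units, inclusive
    sirs_required: int = 2
    shock_required: int = 1
    repeat_on_reconfirmation: bool = False

    def __post_init__(self) -> None:
        if not self.temp_low < self.temp_high:
            raise ValueError("temp_low must be < temp_high")
        if not self.wbc_low < self.wbc_high:
            raise ValueError("wbc_low must be < wbc_high")
        if self.sirs_required not in range(1, 5):
            raise ValueError("sirs_required must be in 1..4")
        if self.shock_required not in (1, 2):
            raise ValueError("shock_required must be 1 or 2")


#: Chart-review infection categories (alerted, sepsis-confirmed patients).
INFECTION_CATEGORIES: tuple[str, ...] = (
    "pneumonia_respiratory",
    "urinary_tract",
    "gastrointestinal",
    "bacteremia",
    "cellulitis",
    "abscess",
    "gynecologic",
    "cns",
    "other",
)

#: Chart-review condition categories (false-positive alerts and reviewed
#: non-alerts; the non-alert sample additionally carries infection kinds
#: that did not fulfil the sepsis definition).
CONDITION_CATEGORIES: tuple[str, ...] = (
    "gastrointestinal",
    "trauma",
    "cardiovascular",
    "respiratory",
    "overdose_intoxication",
    "cns",
    "renal",
    "hematologic_oncologic",
    "other",
    "urinary_tract_infection",
    "respiratory_infection",
    "abscess",
    "cellulitis",
    "gastrointestinal_infection",
    "gynecologic_infection",
    "cns_infection",
    "bacteremia",
    "other_infection",
)


@dataclass
class ChartReviewLabel:
    """Adjudicated outcome for one encounter.

    ``sepsis`` is the chart-review reference standard: serious infection
    plus ≥2 SIRS criteria plus a shock sign. Category sets are multi-label
    (a patient may have more than one infection or condition).
    """

    encounter_id: str
    sepsis: bool
    infection_categories: frozenset[str] = frozenset()
    condition_categories: frozenset[str] = frozenset()
    disposition: Optional[Disposition] = None

    def __post_init__(self) -> None:
        self.infection_categories = frozenset(self.infection_categories)
        self.condition_categories = frozenset(self.condition_categories)
        if self.sepsis and not self.infection_categories:
            raise ValueError(
                f"encounter {self.encounter_id}: sepsis=true requires at least one infection category"
            )


def validate_encounter(e: Encounter) -> list[str]:
    """Check Encounter invariants; return human-readable violations.

    Validation reports rather than raises, and is side-effect free.
    """
    violations: list[str] = []
    for i, obs in enumerate(e.observations):
        where = f"observations[{i}]"
        if obs.encounter_id != e.encounter_id:
            violations.append(
                f"{where}.encounter_id: '{obs.encounter_id}' does not match encounter '{e.encounter_id}'"
            )
        if not isinstance(obs.kind, ObservationKind):
            violations.append(f"{where}.kind: unknown observation kind {obs.kind!r}")
            continue
        if not math.isfinite(obs.value):
            violations.append(f"{where}.value: value must be finite, got {obs.value!r}")
        elif obs.value < 0:
            violations.append(f"{where}.value: value must be >= 0, got {obs.value!r}")
        if obs.unit not in ACCEPTED_UNITS[obs.kind]:
            violations.append(
                f"{where}.unit: unit '{obs.unit}' not accepted for {obs.kind.value} "
                f"(accepted: {', '.join(ACCEPTED_UNITS[obs.kind])})"
            )
    for i in range(1, len(e.observations)):
        if e.observations[i].timestamp < e.observations[i - 1].timestamp:
            violations.append(
                f"observations[{i}].timestamp: observations not in non-decreasing time order"
            )
    return violations


# Physiologic sanity ranges for the optional QC pass. Values outside these
# bands still evaluate against the criteria (entries are taken at face
# value, as a manually-charted EMR does); QC only warns.
PHYSIOLOGIC_RANGES: dict[ObservationKind, tuple[float, float]] = {
    ObservationKind.TEMPERATURE: (25.0, 45.0),
    ObservationKind.HEART_RATE: (20.0, 300.0),
    ObservationKind.RESPIRATORY_RATE: (4.0, 80.0),
    ObservationKind.SYSTOLIC_BP: (30.0, 300.0),
    ObservationKind.WBC_COUNT: (100.0, 200000.0),
    ObservationKind.BANDS_PERCENT: (0.0, 100.0),
    ObservationKind.LACTATE: (0.0, 30.0),
}


def qc_warnings(observations: Iterable[Observation]) -> list[str]:
    """List observations whose values fall outside physiologic ranges."""
    warnings = []
    for obs in observations:
        lo, hi = PHYSIOLOGIC_RANGES[obs.kind]
        if not (lo <= obs.value <= hi):
            warnings.append(
                f"{obs.encounter_id} @ {obs.timestamp.isoformat()}: "
                f"{obs.kind.value}={obs.value} outside physiologic range [{lo}, {hi}]"
            )
    return warnings
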