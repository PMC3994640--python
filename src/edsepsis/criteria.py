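"""Stateless evaluation of single observations against SIRS/shock criteria.

Each observation either satisfies exactly one criterion or none. The WBC
criterion is a single composite: it is satisfied by an abnormal total WBC
count OR by a band (immature neutrophil) fraction >10%; both routes map to
the same criterion id, so simultaneous abnormalities count once toward the
SIRS tally.
"""

from __future__ import annotations

import enum
from typing import Optional

from .model import CriteriaConfig, Observation, ObservationKind


class CriterionId(str, enum.Enum):
    SIRS_TEMP = "SIRS_TEMP"
    SIRS_HR = "SIRS_HR"
    SIRS_RR = "SIRS_RR"
    SIRS_WBC = "SIRS_WBC"
    SHOCK_SBP = "SHOCK_SBP"
    SHOCK_LACTATE = "SHOCK_LACTATE"


SIRS_CRITERIA = frozenset(
    {CriterionId.SIRS_TEMP, CriterionId.SIRS_HR, CriterionId.SIRS_RR, CriterionId.SIRS_WBC}
)
SHOCK_CRITERIA = frozenset({CriterionId.SHOCK_SBP, CriterionId.SHOCK_LACTATE})


def evaluate(obs: Observation, cfg: CriteriaConfig) -> Optional[CriterionId]:
    """Return the criterion this observation satisfies, if any.

    All boundaries are inclusive as conventionally printed (temperature
    ≤36 or ≥38 °C, RR ≥20, HR ≥90, WBC ≤4,000 or ≥12,000, SBP ≤90,
    lactate ≥2.0) except bands, which is strict (>10%).

    Raises ValueError for an unsupported observation kind.
    """
    kind, v = obs.kind, obs.value
    if kind is ObservationKind.TEMPERATURE:
        # Observation normalizes Fahrenheit to Celsius at construction.
        if v <= cfg.temp_low or v >= cfg.temp_high:
            return CriterionId.SIRS_TEMP
        return None
    if kind is ObservationKind.HEART_RATE:
        return CriterionId.SIRS_HR if v >= cfg.hr_min else None
    if kind is ObservationKind.RESPIRATORY_RATE:
        return CriterionId.SIRS_RR if v >= cfg.rr_min else None
    if kind is ObservationKind.WBC_COUNT:
        if v <= cfg.wbc_low or v >= cfg.wbc_high:
            return CriterionId.SIRS_WBC
        return None
    if kind is ObservationKind.BANDS_PERCENT:
        return CriterionId.SIRS_WBC if v > cfg.bands_min_pct else None
    if kind is ObservationKind.SYSTOLIC_BP:
        return CriterionId.SHOCK_SBP if v <= cfg.sbp_max else None
    if kind is ObservationKind.LACTATE:
        # Threshold compared in configured units; no unit conversion.
        return CriterionId.SHOCK_LACTATE if v >= cfg.lactate_min else None
    raise ValueError(f"unsupported observation kind: {kind!r}")
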