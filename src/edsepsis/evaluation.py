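"""Diagnostic-accuracy analysis of sepsis alerts against chart review.

The study design this module serves is *partial verification*: every
alerted encounter is adjudicated, but only a random sample of non-alerted
encounters is. Under that design PPV is directly estimable and NPV is
estimable within the reviewed sample; sensitivity, specificity and AUROC
are not estimable and the report refuses to emit them.

Confidence intervals are Clopper–Pearson exact (inversion of binomial tail
probabilities via the beta quantile identity). The exact method is required
here: with 300/300 sepsis-free reviewed non-alerts the normal approximation
collapses to a degenerate interval at 100%, while the exact lower bound is
(α/2)^(1/n) ≈ 98.8%.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from .model import ChartReviewLabel, Disposition


class StudyDesign(str, enum.Enum):
    FULL_VERIFICATION = "FULL_VERIFICATION"
    SAMPLED_NEGATIVES = "SAMPLED_NEGATIVES"


class Group(str, enum.Enum):
    TRUE_POSITIVE = "TRUE_POSITIVE"
    FALSE_POSITIVE = "FALSE_POSITIVE"
    TRUE_NEGATIVE = "TRUE_NEGATIVE"


#: Metrics that a sampled-negatives design cannot estimate.
NON_ESTIMABLE_UNDER_SAMPLING = ("sensitivity", "specificity", "auroc")


def round_percent(x: float, ndigits: int = 1) -> float:
    """Half-up rounding on the percent scale, as tables conventionally print."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ProportionCI:
    point: float
    lower: float
    upper: float
    level: float = 0.95

    def as_percent(self) -> tuple[float, float, float]:
        return (
            round_percent(100 * self.point),
            round_percent(100 * self.lower),
            round_percent(100 * self.upper),
        )


def proportion_ci(successes: int, trials: int, level: float = 0.95) -> ProportionCI:
    """Clopper–Pearson exact confidence interval for a binomial proportion.

    lower = Beta(α/2; k, n−k+1) quantile (0 when k = 0);
    upper = Beta(1−α/2; k+1, n−k) quantile (1 when k = n).
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must be in [0, trials]")
    alpha = 1.0 - level
    k, n = successes, trials
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return ProportionCI(point=k / n, lower=lower, upper=upper, level=level)


def cohen_kappa(ratings_a: Sequence[int], ratings_b: Sequence[int]) -> float:
    """Cohen's chance-corrected agreement, κ = (p_o − p_e)/(1 − p_e).

    When both raters use one identical category throughout, p_e = p_o = 1
    and κ is defined as 1 (full agreement convention).
    """
    if len(ratings_a) != len(ratings_b):
        raise ValueError(
            f"rating vectors differ in length: {len(ratings_a)} vs {len(ratings_b)}"
        )
    if len(ratings_a) == 0:
        raise ValueError("rating vectors must be non-empty")
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    # Degenerate chance agreement: each rater constant. p_e = 1; kappa is
    # 1 on full agreement and undefined (-> 0 by convention) otherwise.
    if len(np.unique(a)) == 1 and len(np.unique(b)) == 1:
        return 1.0 if a[0] == b[0] else 0.0
    return float(cohen_kappa_score(a, b))


def confusion_counts(
    alerted: set[str],
    labels: Mapping[str, ChartReviewLabel],
    negatives_sampled: bool = True,
) -> dict[str, int]:
    """2×2 counts of alert status against chart-review sepsis.

    Every labelled encounter not in ``alerted`` is treated as a reviewed
    non-alert. Under a sampled-negatives design fn/tn are counts *within
    the reviewed sample only*, not population counts.

    Raises KeyError naming the encounter if an alerted id lacks a label.
    """
    tp = fp = fn = tn = 0
    for eid in alerted:
        if eid not in labels:
            raise KeyError(f"no chart-review label for alerted encounter '{eid}'")
    for eid, lab in labels.items():
        if eid in alerted:
            if lab.sepsis:
                tp += 1
            else:
                fp += 1
        else:
            if lab.sepsis:
                fn += 1
            else:
                tn += 1
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn}


def category_table(
    labels: Iterable[ChartReviewLabel], group: Group
) -> dict[str, tuple[int, float]]:
    """Per-category counts and percentages for one adjudication group.

    True positives are tabulated over infection categories; false positives
    and reviewed non-alerts over condition categories. Categories are
    multi-label, so percentages may sum over 100%. Percentage denominator
    is the number of patients in the group.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("group is empty")
    denom = len(labels)
    counts: dict[str, int] = {}
    for lab in labels:
        cats = lab.infection_categories if group is Group.TRUE_POSITIVE else lab.condition_categories
        for c in cats:
            counts[c] = counts.get(c, 0) + 1
    return {
        c: (n, round_percent(100.0 * n / denom))
        for c, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    }


def disposition_table(
    groups: Mapping[Group, Sequence[ChartReviewLabel]],
) -> dict[Group, dict[Disposition, tuple[int, float]]]:
    """Disposition counts/percentages per group; columns sum to 100%."""
    out: dict[Group, dict[Disposition, tuple[int, float]]] = {}
    for group, labels in groups.items():
        denom = len(labels)
        col: dict[Disposition, tuple[int, float]] = {}
        for d in Disposition:
            n = sum(1 for lab in labels if lab.disposition is d)
            col[d] = (n, round_percent(100.0 * n / denom) if denom else 0.0)
        out[group] = col
    return out


@dataclass
class AccuracyReport:
    """Full accuracy report: 2×2 counts, PPV/NPV with exact CIs, tables."""

    tp: int
    fp: int
    fn_in_sample: int
    tn_in_sample: int
    ppv: Optional[ProportionCI]
    npv_estimated: Optional[ProportionCI]
    design: StudyDesign
    estimable_metrics: list[str] = field(default_factory=list)
    non_estimable_metrics: list[str] = field(default_factory=list)
    infection_table_tp: dict[str, tuple[int, float]] = field(default_factory=dict)
    condition_table_fp: dict[str, tuple[int, float]] = field(default_factory=dict)
    condition_table_tn: dict[str, tuple[int, float]] = field(default_factory=dict)
    dispositions: dict[Group, dict[Disposition, tuple[int, float]]] = field(default_factory=dict)

    @property
    def n_alerted(self) -> int:
        return self.tp + self.fp

    @property
    def n_nonalert_reviewed(self) -> int:
        return self.fn_in_sample + self.tn_in_sample


def evaluate_cohort(
    alerted: set[str],
    labels: Mapping[str, ChartReviewLabel],
    negatives_sampled: bool = True,
    level: float = 0.95,
) -> AccuracyReport:
    """Assemble the full accuracy report from alerts and labels.

    Under ``negatives_sampled`` the report lists sensitivity/specificity/
    AUROC as non-estimable and labels NPV as an estimate within the
    reviewed non-alert sample.
    """
    cc = confusion_counts(alerted, labels, negatives_sampled)
    tp, fp, fn, tn = cc["tp"], cc["fp"], cc["fn"], cc["tn"]
    ppv = proportion_ci(tp, tp + fp, level) if tp + fp > 0 else None
    npv = proportion_ci(tn, tn + fn, level) if tn + fn > 0 else None

    design = StudyDesign.SAMPLED_NEGATIVES if negatives_sampled else StudyDesign.FULL_VERIFICATION
    estimable = ["ppv", "npv_estimated"]
    non_estimable = list(NON_ESTIMABLE_UNDER_SAMPLING) if negatives_sampled else []

    by_group: dict[Group, list[ChartReviewLabel]] = {g: [] for g in Group}
    for eid, lab in labels.items():
        if eid in alerted:
            by_group[Group.TRUE_POSITIVE if lab.sepsis else Group.FALSE_POSITIVE].append(lab)
        elif not lab.sepsis:
            by_group[Group.TRUE_NEGATIVE].append(lab)

    return AccuracyReport(
        tp=tp,
        fp=fp,
        fn_in_sample=fn,
        tn_in_sample=tn,
        ppv=ppv,
        npv_estimated=npv,
        design=design,
        estimable_metrics=estimable,
        non_estimable_metrics=non_estimable,
        infection_table_tp=(
            category_table(by_group[Group.TRUE_POSITIVE], Group.TRUE_POSITIVE)
            if by_group[Group.TRUE_POSITIVE]
            else {}
        ),
        condition_table_fp=(
            category_table(by_group[Group.FALSE_POSITIVE], Group.FALSE_POSITIVE)
            if by_group[Group.FALSE_POSITIVE]
            else {}
        ),
        condition_table_tn=(
            category_table(by_group[Group.TRUE_NEGATIVE], Group.TRUE_NEGATIVE)
            if by_group[Group.TRUE_NEGATIVE]
            else {}
        ),
        dispositions=disposition_table(
            {g: labs for g, labs in by_group.items()}
        ),
    )
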