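"""Diagnostic-accuracy statistics: confusion counts, exact binomial CIs,
Cohen's kappa, category/disposition tables, and design-awareness."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from edsepsis.evaluation import (
    Group,
    NON_ESTIMABLE_UNDER_SAMPLING,
    StudyDesign,
    category_table,
    cohen_kappa,
    confusion_counts,
    disposition_table,
    evaluate_cohort,
    proportion_ci,
    round_percent,
)
from edsepsis.model import ChartReviewLabel, Disposition
from edsepsis.reference import reference_cohort


def _label(eid, sepsis, inf=(), cond=(), disp=None):
    return ChartReviewLabel(eid, sepsis, frozenset(inf), frozenset(cond), disp)


# --- confusion counts -------------------------------------------------------

def test_confusion_counts_reference_cohort():
    alerted, labels = reference_cohort()
    cc = confusion_counts(alerted, labels)
    assert cc == {"tp": 355, "fp": 440, "fn": 0, "tn": 300}


def test_confusion_counts_small_and_empty():
    assert confusion_counts(set(), {}) == {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    labels = {
        "a": _label("a", True, inf={"urinary_tract"}),
        "b": _label("b", True, inf={"bacteremia"}),
        "c": _label("c", False),
    }
    assert confusion_counts({"a", "b"}, labels) == {"tp": 2, "fp": 0, "fn": 0, "tn": 1}


def test_missing_label_names_the_encounter():
    with pytest.raises(KeyError, match="E-77"):
        confusion_counts({"E-77"}, {})


# --- Clopper-Pearson exact intervals ---------------------------------------

def cp_bisect(successes, trials, level=0.95, tol=1e-12):
    """Independent oracle: invert binomial tail probabilities by bisection.

    lower solves P(X >= k | p) = alpha/2, upper solves P(X <= k | p) = alpha/2.
    """
    alpha = 1 - level

    def solve(f, target):
        lo, hi = 0.0, 1.0
        while hi - lo > tol:
            mid = (lo + hi) / 2
            if f(mid) < target:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    k, n = successes, trials
    lower = 0.0 if k == 0 else solve(lambda p: stats.binom.sf(k - 1, n, p), alpha / 2)
    upper = 1.0 if k == n else 1.0 - solve(
        lambda p: stats.binom.cdf(k, n, 1.0 - p), alpha / 2
    )
    return lower, upper


@pytest.mark.parametrize("k,n", [(5, 10), (1, 8), (17, 20), (0, 10), (10, 10), (355, 795)])
def test_cp_interval_matches_binomial_tail_inversion(k, n):
    ci = proportion_ci(k, n)
    lo, hi = cp_bisect(k, n)
    assert ci.lower == pytest.approx(lo, abs=1e-9)
    assert ci.upper == pytest.approx(hi, abs=1e-9)
    sm_lo, sm_hi = proportion_confint(k, n, alpha=0.05, method="beta")
    assert ci.lower == pytest.approx(0.0 if np.isnan(sm_lo) else sm_lo, abs=1e-12)
    assert ci.upper == pytest.approx(1.0 if np.isnan(sm_hi) else sm_hi, abs=1e-12)


def test_cp_interval_published_examples():
    ppv = proportion_ci(355, 795)
    assert ppv.as_percent() == (44.7, 41.2, 48.2)
    npv = proportion_ci(300, 300)
    assert npv.point == 1.0 and npv.upper == 1.0
    assert npv.lower == pytest.approx(0.025 ** (1 / 300), abs=1e-12)
    assert round_percent(100 * npv.lower) == 98.8


def test_cp_interval_boundaries_and_errors():
    zero = proportion_ci(0, 10)
    assert zero.point == 0.0 and zero.lower == 0.0
    with pytest.raises(ValueError):
        proportion_ci(5, 0)
    with pytest.raises(ValueError):
        proportion_ci(11, 10)


def test_cp_interval_brackets_point_and_narrows_with_n():
    prev_width = None
    for n in (10, 40, 160, 640):
        k = n // 4
        ci = proportion_ci(k, n)
        assert ci.lower <= ci.point <= ci.upper
        width = ci.upper - ci.lower
        if prev_width is not None:
            assert width < prev_width
        prev_width = width


# --- Cohen's kappa ----------------------------------------------------------

def test_kappa_perfect_and_inverse_agreement():
    assert cohen_kappa([1, 0, 1, 0], [1, 0, 1, 0]) == pytest.approx(1.0)
    # p_o = 0, p_e = 0.5 by hand -> kappa = -1
    assert cohen_kappa([1, 1, 0, 0], [0, 0, 1, 1]) == pytest.approx(-1.0)


def test_kappa_reproduces_high_interrater_agreement():
    """30 paired sepsis adjudications with 27/30 raw agreement and chance
    agreement 49/90 give kappa = 32/41 ~ 0.78 (hand-computed from the
    2x2 contingency table a=18, b=2, c=1, d=9)."""
    a = [1] * 18 + [0] * 9 + [1] * 2 + [0]
    b = [1] * 18 + [0] * 9 + [0] * 2 + [1]
    assert cohen_kappa(a, b) == pytest.approx(32 / 41)
    assert round(cohen_kappa(a, b), 2) == 0.78


def test_kappa_degenerate_and_errors():
    assert cohen_kappa([1, 1, 1], [1, 1, 1]) == 1.0
    with pytest.raises(ValueError, match="length"):
        cohen_kappa([1, 0], [1])
    with pytest.raises(ValueError):
        cohen_kappa([], [])


# --- category and disposition tables ---------------------------------------

def test_category_table_multilabel_single_patient():
    table = category_table(
        [_label("a", True, inf={"urinary_tract", "bacteremia"})], Group.TRUE_POSITIVE
    )
    assert table == {"bacteremia": (1, 100.0), "urinary_tract": (1, 100.0)}


def test_category_table_matches_membership_recount():
    rng = np.random.default_rng(5)
    cats = ["gastrointestinal", "trauma", "cardiovascular", "renal", "other"]
    labels = []
    for i in range(137):
        chosen = {c for c in cats if rng.random() < 0.3}
        labels.append(_label(f"e{i}", False, cond=chosen))
    table = category_table(labels, Group.FALSE_POSITIVE)
    for cat in cats:
        expected = sum(1 for lab in labels if cat in lab.condition_categories)
        if expected == 0:
            assert cat not in table
        else:
            n, pct = table[cat]
            assert n == expected
            assert pct == round_percent(100 * expected / len(labels))


def test_category_table_empty_group_rejected():
    with pytest.raises(ValueError, match="empty"):
        category_table([], Group.TRUE_POSITIVE)


def test_disposition_table_columns_sum_to_100():
    labels = [
        _label("a", False, disp=Disposition.ADMITTED),
        _label("b", False, disp=Disposition.ADMITTED),
        _label("c", False, disp=Disposition.DISCHARGED),
    ]
    table = disposition_table({Group.FALSE_POSITIVE: labels})
    col = table[Group.FALSE_POSITIVE]
    assert sum(pct for _, pct in col.values()) == pytest.approx(100.0, abs=0.11)
    assert col[Disposition.ADMITTED] == (2, 66.7)


def test_all_discharged_column():
    labels = [_label(str(i), False, disp=Disposition.DISCHARGED) for i in range(4)]
    col = disposition_table({Group.TRUE_NEGATIVE: labels})[Group.TRUE_NEGATIVE]
    assert col[Disposition.DISCHARGED] == (4, 100.0)
    assert col[Disposition.ADMITTED] == (0, 0.0)


# --- design awareness -------------------------------------------------------

def test_sampled_negatives_design_refuses_sensitivity_specificity():
    alerted, labels = reference_cohort()
    report = evaluate_cohort(alerted, labels, negatives_sampled=True)
    assert report.design is StudyDesign.SAMPLED_NEGATIVES
    assert set(NON_ESTIMABLE_UNDER_SAMPLING) <= set(report.non_estimable_metrics)
    for metric in ("sensitivity", "specificity", "auroc"):
        assert metric not in report.estimable_metrics
        assert not hasattr(report, metric)


def test_full_verification_design_has_no_refusals():
    labels = {
        "a": _label("a", True, inf={"urinary_tract"}),
        "b": _label("b", False),
    }
    report = evaluate_cohort({"a"}, labels, negatives_sampled=False)
    assert report.design is StudyDesign.FULL_VERIFICATION
    assert report.non_estimable_metrics == []
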