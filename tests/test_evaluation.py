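import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.proportion import proportion_confint

import slemine as sm
from slemine.evaluation import (
    AlignmentError,
    InfluenceError,
    metrics_exact,
)
from slemine.labels import ClinDet, Determination as D


# ------------------------------------------------------------- confusion

def test_confusion_counts_and_unspecified_exclusion():
    truth = {f"p{i}": ClinDet.POS for i in range(10)}
    truth |= {f"n{i}": ClinDet.NEG for i in range(5)}
    truth |= {f"u{i}": ClinDet.UNSPECIFIED for i in range(3)}
    preds = {pid: pid.startswith(("p", "u")) for pid in truth}
    cm = sm.confusion(preds, truth)
    assert (cm.tp, cm.fn, cm.fp, cm.tn) == (10, 0, 0, 5)
    assert cm.n == 15


def test_confusion_not_reported_counts_as_predicted_negative():
    truth = {"a": ClinDet.POS, "b": ClinDet.NEG}
    preds = {"a": D.NOT_REPORTED, "b": D.NOT_REPORTED}
    cm = sm.confusion(preds, truth)
    assert (cm.tp, cm.fn, cm.fp, cm.tn) == (0, 1, 0, 1)


def test_confusion_alignment_error_and_empty():
    with pytest.raises(AlignmentError, match="mismatch"):
        sm.confusion({"a": True}, {"b": ClinDet.POS})
    cm = sm.confusion({}, {})
    assert (cm.tp, cm.fn, cm.fp, cm.tn) == (0, 0, 0, 0)


# --------------------------------------------------------------- metrics

def test_metrics_reproduce_reported_ana_row():
    pm = sm.metrics(sm.ConfusionMatrix(43, 14, 9, 12))
    assert pm.rendered(2) == {"sensitivity": "0.75", "specificity": "0.57",
                              "ppv": "0.83", "npv": "0.46"}


def test_metrics_leukopenia_style_row():
    pm = sm.metrics(sm.ConfusionMatrix(0, 1, 1, 13))
    assert pm.sensitivity == 0
    assert pm.ppv == 0
    assert pm.specificity == pytest.approx(13 / 14)
    assert pm.npv == pytest.approx(13 / 14)
    assert pm.rendered(2)["specificity"] == "0.93"


def test_metrics_undefined_cells_render_na():
    pm = sm.metrics(sm.ConfusionMatrix(0, 1, 0, 5))
    assert pm.ppv is None and pm.ppv_ci is None
    assert pm.rendered()["ppv"] == "n/a"
    pm = sm.metrics(sm.ConfusionMatrix(0, 0, 1, 5))
    assert pm.sensitivity is None
    assert pm.rendered()["sensitivity"] == "n/a"


@settings(max_examples=200, derandomize=True)
@given(st.tuples(*(st.integers(min_value=0, max_value=40),) * 4))
def test_metric_rational_identities(cells):
    cm = sm.ConfusionMatrix(*cells)
    exact = metrics_exact(cm)
    if exact["sensitivity"] is not None:
        assert exact["sensitivity"] * (cm.tp + cm.fn) == cm.tp
    if cm.n:
        assert exact["accuracy"] == Fraction(cm.tp + cm.tn, cm.n)
    pm = sm.metrics(cm)
    for name in ("sensitivity", "specificity", "ppv", "npv"):
        if exact[name] is not None:
            assert getattr(pm, name) == pytest.approx(float(exact[name]))
            lo, hi = getattr(pm, f"{name}_ci")
            assert lo <= float(exact[name]) <= hi


# ---------------------------------------------------------------- wilson

def test_wilson_zero_successes_pins_lower_bound():
    lo, hi = sm.wilson_ci(0, 10)
    assert lo == 0.0 and 0 < hi < 1


def test_wilson_symmetric_at_half():
    lo, hi = sm.wilson_ci(5, 10)
    assert lo + hi == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("successes,n", [(43, 57), (1, 15), (14, 15), (30, 57)])
def test_wilson_matches_independent_implementation(successes, n):
    lo, hi = sm.wilson_ci(successes, n)
    ref_lo, ref_hi = proportion_confint(successes, n, alpha=0.05, method="wilson")
    assert lo == pytest.approx(ref_lo, abs=1e-12)
    assert hi == pytest.approx(ref_hi, abs=1e-12)


def test_wilson_rejects_empty_sample():
    with pytest.raises(ValueError):
        sm.wilson_ci(0, 0)


# ---------------------------------------------------------------- fisher

def enum_fisher_two_sided(a, b, c, d):
    """Exhaustive hypergeometric enumeration in rational arithmetic."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = comb(r1 + r2, c1)
    def prob(x):
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
    p_obs = prob(a)
    return float(sum(prob(x)
                     for x in range(max(0, c1 - r2), min(r1, c1) + 1)
                     if prob(x) <= p_obs))


def test_fisher_trivial_tables():
    assert sm.fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)
    assert sm.fisher_exact([[2, 0], [0, 2]]) == pytest.approx(1 / 3)


def test_fisher_ads_style_table_matches_enumeration():
    # 23/48 SLE+ vs 0/9 UCTD positives; significant at 0.05 but the
    # exact two-sided p is 0.0078, not reproducing any smaller printed
    # threshold
    p = sm.fisher_exact([[23, 25], [0, 9]])
    assert p == pytest.approx(enum_fisher_two_sided(23, 25, 0, 9), abs=1e-12)
    assert p < 0.01


# ------------------------------------------------------------- influence

def test_influence_single_and_symmetric():
    catalog = sm.load_catalog()
    table = sm.influence_table({15: 7, 22: 0}, catalog, sm.SleClass.SLE_POS)
    by_cid = {t.criterion_id: t for t in table}
    assert by_cid[15].influence == pytest.approx(1.0)
    assert by_cid[22].influence == 0.0 and by_cid[22].interval == (0.0, 0.0)
    # equal N*W: joint involvement (w6, n2) vs LN34 (w10, n... ) pick equal products
    table = sm.influence_table({15: 5, 18: 3}, catalog, sm.SleClass.SLE_POS)
    infl = {t.criterion_id: t.influence for t in table}
    assert infl[15] == pytest.approx(0.5)
    assert infl[18] == pytest.approx(0.5)


def test_influence_normalization_and_intervals():
    catalog = sm.load_catalog()
    counts = {3: 19, 9: 10, 10: 19, 15: 40, 16: 9, 20: 14, 22: 23}
    table = sm.influence_table(counts, catalog, sm.SleClass.SLE_POS)
    total = sum(t.influence for t in table)
    assert total == pytest.approx(1.0, abs=1e-12)
    for t in table:
        if t.count:
            assert t.interval[0] <= t.influence <= t.interval[1]


def test_influence_all_zero_counts_errors():
    with pytest.raises(InfluenceError, match="UCTD"):
        sm.influence_table({3: 0, 15: 0}, klass=sm.SleClass.UCTD)


def test_criterion_positive_counts_by_class(catalog):
    profiles = {
        "a": {cid: D.POSITIVE if cid in (1, 15) else D.NEGATIVE for cid in catalog.ids},
        "b": {cid: D.POSITIVE if cid == 15 else D.NOT_REPORTED for cid in catalog.ids},
        "c": {cid: D.NEGATIVE for cid in catalog.ids},
    }
    classes = {"a": sm.SleClass.SLE_POS, "b": sm.SleClass.SLE_POS,
               "c": sm.SleClass.UCTD}
    counts = sm.criterion_positive_counts(profiles, classes, sm.SleClass.SLE_POS,
                                          catalog)
    assert counts[15] == 2 and counts[3] == 0
    assert 1 not in counts  # entry criterion carries no influence weight


# ----------------------------------------------------------- concordance

def test_concordance_identity_and_total_mismatch():
    truth = {f"p{i}": sm.SleClass.SLE_POS for i in range(4)}
    assert sm.concordance(dict(truth), truth).exact_match == 1.0
    wrong = {pid: sm.SleClass.SLE_NEG for pid in truth}
    assert sm.concordance(wrong, truth).exact_match == 0.0


def test_concordance_contingency_conservation():
    rng = np.random.default_rng(3)
    classes = list(sm.SleClass)
    truth = {f"p{i}": classes[rng.integers(3)] for i in range(60)}
    pred = {pid: classes[rng.integers(3)] for pid in truth}
    summary = sm.concordance(pred, truth)
    assert summary.n == 60
    from collections import Counter
    t_counts = Counter(truth.values())
    p_counts = Counter(pred.values())
    for i, klass in enumerate((sm.SleClass.SLE_NEG, sm.SleClass.UCTD,
                               sm.SleClass.SLE_POS)):
        assert summary.contingency[i].sum() == t_counts[klass]
        assert summary.contingency[:, i].sum() == p_counts[klass]
        assert summary.clinical_fractions[klass] == pytest.approx(t_counts[klass] / 60)


def test_concordance_fixture_with_42_of_78_matches():
    truth = {}
    pred = {}
    for i in range(78):
        truth[f"p{i}"] = sm.SleClass.SLE_POS
        pred[f"p{i}"] = sm.SleClass.SLE_POS if i < 42 else sm.SleClass.UCTD
    summary = sm.concordance(pred, truth)
    assert summary.exact_match == pytest.approx(42 / 78)


# -------------------------------------------------------- evaluate_cohort

def test_evaluate_cohort_perfect_predictions(catalog):
    truth = {
        f"p{i}": {cid: (ClinDet.POS if (i + cid) % 3 == 0 else ClinDet.NEG)
                  for cid in catalog.ids}
        for i in range(12)
    }
    profiles = {
        pid: {cid: (D.POSITIVE if det is ClinDet.POS else D.NEGATIVE)
              for cid, det in dets.items()}
        for pid, dets in truth.items()
    }
    report = sm.evaluate_cohort(profiles, truth, catalog)
    for _, pm in report.per_criterion.values():
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            assert getattr(pm, name) in (None, 1.0)
    cm, pm = report.pooled
    assert cm.fn == cm.fp == 0
    assert pm.sensitivity == 1.0


def test_evaluate_cohort_pools_summed_cells(catalog):
    truth = {"a": {1: ClinDet.POS, 2: ClinDet.NEG},
             "b": {1: ClinDet.NEG, 2: ClinDet.POS}}
    profiles = {"a": {1: D.POSITIVE, 2: D.POSITIVE},
                "b": {1: D.NEGATIVE, 2: D.NEGATIVE}}
    report = sm.evaluate_cohort(profiles, truth, catalog)
    pooled_cm, _ = report.pooled
    total = sm.ConfusionMatrix(0, 0, 0, 0)
    for cm, _ in report.per_criterion.values():
        total = total + cm
    assert pooled_cm == total
    assert "micro" in report.averaging
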