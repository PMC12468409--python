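"""Diagnostic-accuracy evaluation: confusion metrics, Wilson intervals,
Fisher exact tests, weighted criterial influence and tripartite
concordance.

Conventions:

* Patients whose clinical determination for a criterion is
  ``unspecified`` are excluded from that criterion's confusion matrix.
* An extraction outcome of ``not_reported`` counts as a predicted
  negative — a criterion absent from the record is scored as a miss
  against a clinical positive.
* Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV = TP/(TP+FP),
  NPV = TN/(TN+FN); a metric with a zero denominator is undefined and
  rendered "n/a".  95% intervals are Wilson score intervals on each
  metric's own numerator/denominator.
* Rounding (2 decimals, matching conventional reporting) happens only
  at rendering; internal values keep full precision.
* The pooled "total" row over all criteria micro-averages (sums
  confusion cells); a macro-average (mean of defined per-criterion
  metrics) is also emitted so both conventions are inspectable.

Weighted criterial influence: for a class (SLE+ or UCTD), a criterion's
influence is N*W / sum_i(N_i*W_i), where N counts positive
determinations for that criterion within the class and W is its
catalog weight; the sum runs over criteria with non-zero counts, so
influences sum to 1 per class.  The attached interval is the Wilson
interval on the count share N/sum(N), rescaled by the criterion's
weight share — an approximation, flagged as such in output.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import CriteriaCatalog, load_catalog
from .labels import ClinDet, Determination, SleClass


class AlignmentError(ValueError):
    """Predictions and truth do not cover the same patients."""


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion cells must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fn + other.fn,
            self.fp + other.fp, self.tn + other.tn,
        )


Interval = tuple[float, float]


@dataclass(frozen=True)
class PerformanceMetrics:
    """Point estimates with Wilson intervals; ``None`` marks a metric
    whose denominator is zero (rendered "n/a")."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    sensitivity_ci: Interval | None
    specificity_ci: Interval | None
    ppv_ci: Interval | None
    npv_ci: Interval | None

    def rendered(self, decimals: int = 2) -> dict[str, str]:
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            value = getattr(self, name)
            out[name] = "n/a" if value is None else f"{round(value, decimals):g}"
        return out


def wilson_ci(successes, n, confidence: float = 0.95) -> Interval:
    """Wilson score interval for a binomial proportion.

    Accepts scalars or numpy arrays (broadcast elementwise); bounds are
    clipped to [0, 1].  ``n`` must be >= 1.
    """
    successes = np.asarray(successes, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("wilson_ci requires n >= 1")
    if np.any((successes < 0) | (successes > n)):
        raise ValueError("successes must lie in [0, n]")
    z = stats.norm.ppf(0.5 + confidence / 2)
    phat = successes / n
    denom = 1 + z**2 / n
    centre = (phat + z**2 / (2 * n)) / denom
    half = (z / denom) * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2))
    # analytically exact endpoints at the boundary proportions
    low = np.where(successes == 0, 0.0, np.clip(centre - half, 0.0, 1.0))
    high = np.where(successes == n, 1.0, np.clip(centre + half, 0.0, 1.0))
    if low.ndim == 0:
        return float(low), float(high)
    return low, high


def _ratio_ci(num: int, den: int) -> tuple[float | None, Interval | None]:
    if den == 0:
        return None, None
    return num / den, wilson_ci(num, den)


def metrics(cm: ConfusionMatrix, rounding: int = 2) -> PerformanceMetrics:
    """Sensitivity/specificity/PPV/NPV with Wilson 95% intervals.

    ``rounding`` only affects :meth:`PerformanceMetrics.rendered`.
    """
    del rounding  # rendering-time concern; kept for interface clarity
    sens, sens_ci = _ratio_ci(cm.tp, cm.tp + cm.fn)
    spec, spec_ci = _ratio_ci(cm.tn, cm.tn + cm.fp)
    ppv, ppv_ci = _ratio_ci(cm.tp, cm.tp + cm.fp)
    npv, npv_ci = _ratio_ci(cm.tn, cm.tn + cm.fn)
    return PerformanceMetrics(sens, spec, ppv, npv, sens_ci, spec_ci, ppv_ci, npv_ci)


def metrics_exact(cm: ConfusionMatrix) -> dict[str, Fraction | None]:
    """Rational-arithmetic metric identities (audit helper)."""
    def frac(a: int, b: int) -> Fraction | None:
        return None if b == 0 else Fraction(a, b)
    return {
        "sensitivity": frac(cm.tp, cm.tp + cm.fn),
        "specificity": frac(cm.tn, cm.tn + cm.fp),
        "ppv": frac(cm.tp, cm.tp + cm.fp),
        "npv": frac(cm.tn, cm.tn + cm.fn),
        "accuracy": frac(cm.tp + cm.tn, cm.n) if cm.n else None,
    }


def _predicted_positive(det) -> bool:
    if isinstance(det, bool):
        return det
    return Determination(det) is Determination.POSITIVE


def confusion(predictions: dict, truth: dict) -> ConfusionMatrix:
    """Confusion matrix of predicted vs clinical determinations.

    ``truth`` values are :class:`ClinDet`; ``unspecified`` patients are
    excluded before counting.  Predictions must cover exactly the same
    patient ids as the truth table.
    """
    if set(predictions) != set(truth):
        missing = sorted(set(truth) - set(predictions))
        extra = sorted(set(predictions) - set(truth))
        raise AlignmentError(f"patient id mismatch: missing={missing} extra={extra}")
    tp = fn = fp = tn = 0
    for pid, t in truth.items():
        t = ClinDet(t)
        if t is ClinDet.UNSPECIFIED:
            continue
        pred_pos = _predicted_positive(predictions[pid])
        if t is ClinDet.POS:
            tp += pred_pos
            fn += not pred_pos
        else:
            fp += pred_pos
            tn += not pred_pos
    return ConfusionMatrix(tp, fn, fp, tn)


def fisher_exact(table, sided: str = "two_sided") -> float:
    """Fisher exact test p-value for a 2x2 table of non-negative counts
    (two-sided: sum of hypergeometric probabilities of all tables with
    the observed margins no more probable than the observed one)."""
    if sided != "two_sided":
        raise ValueError("only the two-sided test is provided")
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("table must be 2x2 with non-negative integers")
    return float(stats.fisher_exact(arr, alternative="two-sided").pvalue)


@dataclass(frozen=True)
class CriterionInfluence:
    criterion_id: int
    klass: SleClass
    count: int
    weight: int
    influence: float
    interval: Interval


class InfluenceError(ValueError):
    """All counts zero: influence undefined for the class."""


def influence_table(
    positives_by_class: dict[int, int],
    catalog: CriteriaCatalog | None = None,
    klass: SleClass = SleClass.SLE_POS,
    confidence: float = 0.95,
) -> list[CriterionInfluence]:
    """Normalized weighted influence of each criterion within a class.

    ``positives_by_class`` maps criterion id -> count of positive
    determinations among patients of ``klass``.  Zero-count criteria
    get influence 0 and are excluded from the normalizing denominator.
    """
    catalog = catalog or load_catalog()
    counts = {cid: int(n) for cid, n in positives_by_class.items()}
    if any(n < 0 for n in counts.values()):
        raise ValueError("counts must be non-negative")
    included = {cid: n for cid, n in counts.items() if n > 0}
    if not included:
        raise InfluenceError(f"all criterion counts are zero for class {klass.value}")
    total_nw = sum(n * catalog.weight(cid) for cid, n in included.items())
    total_n = sum(included.values())
    out = []
    for cid, n in sorted(counts.items()):
        w = catalog.weight(cid)
        if n == 0:
            out.append(CriterionInfluence(cid, klass, 0, w, 0.0, (0.0, 0.0)))
            continue
        infl = n * w / total_nw
        lo, hi = wilson_ci(n, total_n, confidence)
        scale = total_n * w / total_nw  # influence = share * scale
        out.append(CriterionInfluence(cid, klass, n, w, infl, (lo * scale, hi * scale)))
    return out


def criterion_positive_counts(
    profiles,
    truth_classes: dict[str, SleClass],
    klass: SleClass,
    catalog: CriteriaCatalog | None = None,
) -> dict[int, int]:
    """Count positive determinations per non-entry criterion among the
    patients whose clinical class is ``klass`` (the N of the influence
    statistic)."""
    catalog = catalog or load_catalog()
    if not isinstance(profiles, dict):
        profiles = {p.patient_id: p.determinations() for p in profiles}
    counts = {c.id: 0 for c in catalog.scored}
    for pid, dets in profiles.items():
        if SleClass(truth_classes[pid]) is not klass:
            continue
        for c in catalog.scored:
            counts[c.id] += _predicted_positive(dets.get(c.id, Determination.NOT_REPORTED))
    return counts


_CLASS_ORDER = (SleClass.SLE_NEG, SleClass.UCTD, SleClass.SLE_POS)


@dataclass(frozen=True)
class ConcordanceSummary:
    """3x3 clinical-vs-predicted contingency with exact-match fraction
    and per-class partition proportions (rows: clinical, columns:
    predicted, in SLE-/UCTD/SLE+ order)."""

    contingency: np.ndarray
    exact_match: float
    clinical_fractions: dict[SleClass, float]
    predicted_fractions: dict[SleClass, float]

    @property
    def n(self) -> int:
        return int(self.contingency.sum())

    def to_frame(self) -> pd.DataFrame:
        names = [k.value for k in _CLASS_ORDER]
        return pd.DataFrame(self.contingency, index=names, columns=names)


def concordance(predicted: dict[str, SleClass], truth: dict[str, SleClass]) -> ConcordanceSummary:
    """Tripartite concordance of predicted vs clinical classes."""
    if set(predicted) != set(truth):
        raise AlignmentError("predicted and clinical classes cover different patients")
    table = np.zeros((3, 3), dtype=int)
    idx = {k: i for i, k in enumerate(_CLASS_ORDER)}
    for pid, t in truth.items():
        table[idx[SleClass(t)], idx[SleClass(predicted[pid])]] += 1
    n = table.sum()
    exact = float(np.trace(table) / n) if n else float("nan")
    clinical = {k: float(table[i].sum() / n) if n else float("nan") for k, i in idx.items()}
    pred = {k: float(table[:, i].sum() / n) if n else float("nan") for k, i in idx.items()}
    return ConcordanceSummary(table, exact, clinical, pred)


@dataclass(frozen=True)
class EvaluationReport:
    per_criterion: dict[int, tuple[ConfusionMatrix, PerformanceMetrics]]
    pooled: tuple[ConfusionMatrix, PerformanceMetrics]
    macro: dict[str, float | None]
    averaging: str = "pooled row micro-averages summed confusion cells"

    def to_frame(self, decimals: int = 2) -> pd.DataFrame:
        rows = []
        for cid, (cm, pm) in sorted(self.per_criterion.items()):
            rows.append({"criterion_id": cid, "tp": cm.tp, "fn": cm.fn,
                         "fp": cm.fp, "tn": cm.tn, **pm.rendered(decimals)})
        cm, pm = self.pooled
        rows.append({"criterion_id": "total", "tp": cm.tp, "fn": cm.fn,
                     "fp": cm.fp, "tn": cm.tn, **pm.rendered(decimals)})
        return pd.DataFrame(rows)


def evaluate_cohort(
    profiles,
    truth_labels,
    catalog: CriteriaCatalog | None = None,
) -> EvaluationReport:
    """Per-criterion confusion and metrics plus pooled and macro rows.

    ``profiles`` is an iterable of CriterionProfile (or a mapping
    patient id -> {criterion id -> determination}); ``truth_labels`` an
    iterable of GroundTruthLabel (or a mapping patient id ->
    {criterion id -> ClinDet}).
    """
    catalog = catalog or load_catalog()
    if not isinstance(profiles, dict):
        profiles = {p.patient_id: p.determinations() for p in profiles}
    if not isinstance(truth_labels, dict):
        truth_labels = {t.patient_id: t.determinations for t in truth_labels}
    if set(profiles) != set(truth_labels):
        raise AlignmentError("profiles and truth cover different patients")

    per_criterion = {}
    pooled_cm = ConfusionMatrix(0, 0, 0, 0)
    for c in catalog:
        preds = {pid: dets.get(c.id, Determination.NOT_REPORTED)
                 for pid, dets in profiles.items()}
        truth = {pid: dets.get(c.id, ClinDet.UNSPECIFIED)
                 for pid, dets in truth_labels.items()}
        cm = confusion(preds, truth)
        per_criterion[c.id] = (cm, metrics(cm))
        pooled_cm = pooled_cm + cm

    macro: dict[str, float | None] = {}
    for name in ("sensitivity", "specificity", "ppv", "npv"):
        vals = [getattr(pm, name) for _, pm in per_criterion.values()
                if getattr(pm, name) is not None]
        macro[name] = float(np.mean(vals)) if vals else None
    return EvaluationReport(per_criterion, (pooled_cm, metrics(pooled_cm)), macro)
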