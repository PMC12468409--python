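"""Two-pass rule-based criterion extraction with replicate consensus.

Stage 1 (:func:`first_pass`) is deliberately permissive: every keyword,
keyphrase or quantitative-pattern hit in any note becomes an
:class:`EvidenceMention`, including sub-threshold ANA titers, negated
phrasing and evidence dated before the record window (flagged, not
dropped — window filtering is a second-pass rule).

Stage 2 (:func:`second_pass`) adjudicates one determination per
criterion from the surviving mentions: quantitative evidence outranks
phrasing, with the latest-dated quantitative result winning (e.g. an
ANA titer >= 1:80 in-window is positive, a 1:40 titer is insufficient);
an uncorroborated positivity phrase counts as positive only while
``accept_uncorroborated_phrase`` is on; negation cues within the same
sentence flip phrase polarity; a criterion with no surviving relevant
mention is ``not_reported``.

Extraction is run in replicates (:func:`run_replicates`), each using a
seeded dropout of non-core lexicon keys to emulate the run-to-run
variability of stochastic generative extraction; replicate agreement is
reduced to a consistency score by :func:`consensus` (5 agree -> 1.0,
4 -> 0.6, 3 -> 0.2 on the positive vs not-positive contrast).
"""

from __future__ import annotations

import datetime
import re
from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .catalog import CriteriaCatalog, load_catalog
from .labels import Determination
from .lexicon import NEGATION_PATTERN, Lexicon, RuleSet, default_lexicon
from .templates import EvidenceKind
from .synthetic import PatientRecord

DateWindow = tuple[datetime.date, datetime.date]

CONSISTENCY_BY_AGREEMENT = {5: 1.0, 4: 0.6, 3: 0.2}


@dataclass(frozen=True)
class EvidenceMention:
    """A dated text span in one note supporting a criterion.

    ``span`` is a 0-based half-open character interval into the note
    text; ``snippet`` is exactly the text at that span and ``sentence``
    the containing sentence (used for negation scoping).  ``value``
    carries the captured quantity for numerical mentions (for ANA, the
    titer denominator N of 1:N).
    """

    patient_id: str
    criterion_id: int
    doc_id: str
    date: datetime.date
    span: tuple[int, int]
    snippet: str
    kind: EvidenceKind
    sentence: str
    in_window: bool = True
    value: float | None = None


@dataclass(frozen=True)
class CriterionCall:
    patient_id: str
    criterion_id: int
    replicate_index: int
    determination: Determination
    mentions: tuple[EvidenceMention, ...]


@dataclass(frozen=True)
class ProfileEntry:
    consensus: Determination
    consistency: float
    calls: tuple[CriterionCall, ...]


@dataclass(frozen=True)
class CriterionProfile:
    """Per-patient consensus determination for every criterion."""

    patient_id: str
    criteria: dict[int, ProfileEntry]

    def determinations(self) -> dict[int, Determination]:
        return {cid: e.consensus for cid, e in self.criteria.items()}


_SENTENCE_RE = re.compile(r"[^.!?\n]+[.!?]?")


def _sentence_spans(text: str) -> list[tuple[int, int]]:
    return [m.span() for m in _SENTENCE_RE.finditer(text)]


def _containing_sentence(spans: list[tuple[int, int]], pos: int, text: str) -> str:
    idx = bisect_right([s for s, _ in spans], pos) - 1
    if idx < 0:
        return text
    start, end = spans[idx]
    return text[start:end].strip()


def first_pass(
    record: PatientRecord,
    lexicon: Lexicon | None = None,
    window: DateWindow | None = None,
    catalog: CriteriaCatalog | None = None,
) -> list[EvidenceMention]:
    """Harvest every candidate mention from a patient's notes.

    Mentions dated outside ``window`` are retained but flagged
    ``in_window=False``; with no window, everything is in-window.
    """
    catalog = catalog or load_catalog()
    lexicon = lexicon or default_lexicon()
    lexicon.require_coverage(catalog)

    mentions: list[EvidenceMention] = []
    for note in record.notes:
        in_window = window is None or (window[0] <= note.date <= window[1])
        spans = _sentence_spans(note.text)
        seen: set[tuple[int, int, int]] = set()
        for cid, entry in lexicon.entries.items():
            if entry.numeric is not None:
                for m in entry.numeric.compile().finditer(note.text):
                    key = (cid, *m.span())
                    if key in seen:
                        continue
                    seen.add(key)
                    mentions.append(EvidenceMention(
                        record.patient_id, cid, note.doc_id, note.date, m.span(),
                        m.group(0), EvidenceKind.NUMERICAL,
                        _containing_sentence(spans, m.start(), note.text),
                        in_window, float(m.group(1)),
                    ))
            for lk in entry.keys:
                for m in lk.compile().finditer(note.text):
                    key = (cid, *m.span())
                    if key in seen:
                        continue
                    seen.add(key)
                    mentions.append(EvidenceMention(
                        record.patient_id, cid, note.doc_id, note.date, m.span(),
                        m.group(0), lk.kind,
                        _containing_sentence(spans, m.start(), note.text),
                        in_window, None,
                    ))
    return mentions


def _numeric_positive(m: EvidenceMention, lexicon: Lexicon, rules: RuleSet) -> bool:
    rule = lexicon.entries[m.criterion_id].numeric
    if rule is None or m.value is None:
        return False
    threshold = float(rules.titer_threshold) if m.criterion_id == 1 else rule.threshold
    if rule.op == ">=":
        return m.value >= threshold
    if rule.op == ">":
        return m.value > threshold
    return m.value < threshold


def _phrase_positive(m: EvidenceMention) -> bool:
    return NEGATION_PATTERN.search(m.sentence) is None


def second_pass(
    mentions: list[EvidenceMention],
    rules: RuleSet | None = None,
    lexicon: Lexicon | None = None,
    catalog: CriteriaCatalog | None = None,
) -> dict[int, Determination]:
    """Adjudicate one determination per criterion for one patient."""
    rules = rules or RuleSet()
    lexicon = lexicon or default_lexicon()
    catalog = catalog or load_catalog()
    patients = {m.patient_id for m in mentions}
    if len(patients) > 1:
        raise ValueError(f"second_pass expects one patient's mentions, got {sorted(patients)}")

    by_cid: dict[int, list[EvidenceMention]] = {c.id: [] for c in catalog}
    for m in mentions:
        if rules.enforce_window and not m.in_window:
            continue
        by_cid.setdefault(m.criterion_id, []).append(m)

    out: dict[int, Determination] = {}
    for cid, ms in by_cid.items():
        numericals = [m for m in ms if m.kind is EvidenceKind.NUMERICAL]
        if numericals:
            latest = max(m.date for m in numericals)
            at_latest = [m for m in numericals if m.date == latest]
            positive = any(_numeric_positive(m, lexicon, rules) for m in at_latest)
            out[cid] = Determination.POSITIVE if positive else Determination.NEGATIVE
            continue
        phrases = ms
        if not rules.accept_uncorroborated_phrase:
            phrases = [m for m in phrases if not _phrase_positive(m)]
        if not phrases:
            out[cid] = Determination.NOT_REPORTED
        elif any(_phrase_positive(m) for m in phrases):
            out[cid] = Determination.POSITIVE
        else:
            out[cid] = Determination.NEGATIVE
    return out


def run_replicates(
    record: PatientRecord,
    lexicon: Lexicon | None = None,
    rules: RuleSet | None = None,
    window: DateWindow | None = None,
    k: int = 5,
    seed: int = 0,
    catalog: CriteriaCatalog | None = None,
) -> list[CriterionCall]:
    """Run ``k`` seeded replicate extractions over one patient record.

    Replicate ``r`` drops each non-core lexicon key independently with
    probability ``rules.perturbation`` under a generator seeded from
    ``(seed, r)``; with perturbation 0 all replicates are identical.
    """
    if k < 1:
        raise ValueError("replicate count k must be >= 1")
    rules = rules or RuleSet()
    lexicon = lexicon or default_lexicon()
    catalog = catalog or load_catalog()
    lexicon.require_coverage(catalog)

    calls: list[CriterionCall] = []
    for r in range(1, k + 1):
        rng = np.random.default_rng([seed, r])
        lex_r = lexicon.perturbed(rules.perturbation, rng)
        mentions = first_pass(record, lex_r, window, catalog)
        dets = second_pass(mentions, rules, lex_r, catalog)
        surviving = {
            cid: tuple(
                m for m in mentions
                if m.criterion_id == cid and (not rules.enforce_window or m.in_window)
            )
            for cid in dets
        }
        for cid, det in sorted(dets.items()):
            support = surviving[cid] if det is not Determination.NOT_REPORTED else ()
            calls.append(CriterionCall(record.patient_id, cid, r, det, support))
    return calls


def _binary_majority(dets: list[Determination]) -> tuple[Determination, int]:
    """Majority over the positive vs not-positive contrast.

    Returns (determination, agreement count).  Ties on even arity go to
    positive.  A not-positive majority resolves to the modal specific
    label among its calls, ties favouring negative.
    """
    n_pos = sum(d is Determination.POSITIVE for d in dets)
    n_not = len(dets) - n_pos
    if n_pos >= n_not:
        return Determination.POSITIVE, max(n_pos, n_not)
    counts = Counter(d for d in dets if d is not Determination.POSITIVE)
    label = max(counts, key=lambda d: (counts[d], d is Determination.NEGATIVE))
    return label, n_not


def consensus(calls: list[CriterionCall]) -> tuple[Determination, float]:
    """Reduce exactly five replicate calls for one (patient, criterion)
    to a consensus determination and a consistency score: 5 replicates
    agreeing -> 1.0, 4 -> 0.6, 3 -> 0.2."""
    if len(calls) != 5:
        raise ValueError(f"consensus requires exactly 5 replicate calls, got {len(calls)}")
    pids = {c.patient_id for c in calls}
    cids = {c.criterion_id for c in calls}
    if len(pids) != 1 or len(cids) != 1:
        raise ValueError("consensus calls must share one patient and one criterion")
    det, agreement = _binary_majority([c.determination for c in calls])
    return det, CONSISTENCY_BY_AGREEMENT[agreement]


def extract_profile(
    record: PatientRecord,
    lexicon: Lexicon | None = None,
    rules: RuleSet | None = None,
    window: DateWindow | None = None,
    k: int = 5,
    seed: int = 0,
    catalog: CriteriaCatalog | None = None,
) -> CriterionProfile:
    """Replicated extraction plus consensus for one patient."""
    catalog = catalog or load_catalog()
    calls = run_replicates(record, lexicon, rules, window, k, seed, catalog)
    by_cid: dict[int, list[CriterionCall]] = {}
    for call in calls:
        by_cid.setdefault(call.criterion_id, []).append(call)
    criteria: dict[int, ProfileEntry] = {}
    for cid, cid_calls in sorted(by_cid.items()):
        if k == 5:
            det, score = consensus(cid_calls)
        else:
            det, agreement = _binary_majority([c.determination for c in cid_calls])
            score = agreement / k
        criteria[cid] = ProfileEntry(det, score, tuple(cid_calls))
    return CriterionProfile(record.patient_id, criteria)


def extract_cohort(
    records: list[PatientRecord],
    lexicon: Lexicon | None = None,
    rules: RuleSet | None = None,
    window: DateWindow | None = None,
    k: int = 5,
    seed: int = 0,
    catalog: CriteriaCatalog | None = None,
) -> list[CriterionProfile]:
    """Extraction profiles for a whole cohort (per-patient seeds are
    derived from ``seed`` and the patient's position)."""
    catalog = catalog or load_catalog()
    lexicon = lexicon or default_lexicon()
    return [
        extract_profile(rec, lexicon, rules, window, k, seed + i, catalog)
        for i, rec in enumerate(records)
    ]
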