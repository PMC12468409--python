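"""Synthetic cohort generator: dated free-text notes with known truth.

Emulates the statistical structure of a private rheumatology record
cohort: a fixed split between histories ending at clinical SLE
classification (pre_SC) and histories beginning after classification
(post_SC); heterogeneous evidence styles (numerical, phrase,
descriptive, or simply absent from the record); ANA evidence that can
predate the compiled 1-2 year record window (the dominant
false-negative mechanism in record mining); sub-threshold 1:40 titer
"traps" asserting positivity; and sparse clinical criterion
determination (most criteria clinically adjudicated only for a small
pre-SC subset).

The latent per-criterion truth is *constructed to be consistent with
the classification rule*: a patient's class equals the outcome of the
entry-gate / clinical-gate / 10-point decision tree applied to their
latent criterion statuses.  All randomness flows from one seeded
generator, so a config (including its seed) reproduces a byte-identical
cohort.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace

import numpy as np

from .catalog import CLINICAL_IDS, CriteriaCatalog, CriterionDefinition, load_catalog
from .labels import ClinDet, Group, SleClass
from .templates import (
    DISTRACTORS,
    EvidenceKind,
    EvidenceStyle,
    render_template,
)

SLE_POS_THRESHOLD = 10

#: Per-criterion positivity probability by latent class.  Criteria with
#: published per-class positive counts are anchored on them (/48 SLE+,
#: /9 UCTD); the remainder use flat class-level defaults.  These are
#: modelling assumptions, documented in the methods note.
_ANCHORED_RATES: dict[int, tuple[float, float]] = {
    # cid: (P(pos | SLE_pos), P(pos | UCTD))
    3: (19 / 48, 1 / 9),
    9: (10 / 48, 5 / 9),
    10: (19 / 48, 4 / 9),
    15: (40 / 48, 8 / 9),
    16: (9 / 48, 5 / 9),
    20: (14 / 48, 0.05),
    22: (23 / 48, 0.05),
}
_DEFAULT_RATE = {SleClass.SLE_POS: 0.15, SleClass.UCTD: 0.10, SleClass.SLE_NEG: 0.05}


def default_positivity_rates() -> dict[int, dict[SleClass, float]]:
    rates: dict[int, dict[SleClass, float]] = {}
    for cid in range(2, 23):
        by_class = dict(_DEFAULT_RATE)
        if cid in _ANCHORED_RATES:
            p_sle, p_uctd = _ANCHORED_RATES[cid]
            by_class[SleClass.SLE_POS] = p_sle
            by_class[SleClass.UCTD] = p_uctd
        rates[cid] = by_class
    return rates


def _default_style_mix() -> dict[EvidenceStyle, float]:
    return {
        EvidenceStyle.NUMERICAL: 0.45,
        EvidenceStyle.PHRASE: 0.30,
        EvidenceStyle.DESCRIPTIVE: 0.10,
        EvidenceStyle.NOT_REPORTED: 0.15,
    }


def _check_simplex(name: str, probs: dict) -> None:
    vals = list(probs.values())
    if any(p < 0 for p in vals) or abs(sum(vals) - 1.0) > 1e-9:
        raise ConfigError(f"{name} must be non-negative and sum to 1, got {probs}")


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort.

    ``out_of_window_prob`` is the probability that a truth-positive
    patient's ANA evidence predates the record window (and is therefore
    absent from the notes, unless ``retain_dated_history`` prints it in
    a pre-window history note instead).  ``low_titer_trap_prob`` is the
    probability that a truth-negative ANA patient's record asserts
    positivity at a 1:40 titer.
    """

    n_patients: int = 78
    group_mix: dict[Group, float] = field(
        default_factory=lambda: {Group.PRE_SC: 0.5, Group.POST_SC: 0.5}
    )
    class_mix: dict[SleClass, float] = field(
        default_factory=lambda: {
            SleClass.SLE_NEG: 21 / 78,
            SleClass.UCTD: 9 / 78,
            SleClass.SLE_POS: 48 / 78,
        }
    )
    positivity_rates: dict[int, dict[SleClass, float]] = field(
        default_factory=default_positivity_rates
    )
    evidence_style_mix: dict[EvidenceStyle, float] = field(
        default_factory=_default_style_mix
    )
    out_of_window_prob: float = 0.0
    low_titer_trap_prob: float = 0.0
    window_days: int = 540
    distractor_rate: float = 2.0
    retain_dated_history: bool = False
    n_full_determinations: int | None = None
    anchor_date: datetime.date = datetime.date(2024, 6, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be non-negative")
        _check_simplex("group_mix", self.group_mix)
        _check_simplex("class_mix", self.class_mix)
        _check_simplex("evidence_style_mix", self.evidence_style_mix)
        for prob, name in ((self.out_of_window_prob, "out_of_window_prob"),
                           (self.low_titer_trap_prob, "low_titer_trap_prob")):
            if not 0.0 <= prob <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.window_days < 1:
            raise ConfigError("window_days must be positive")
        if self.distractor_rate < 0:
            raise ConfigError("distractor_rate must be non-negative")
        for cid, by_class in self.positivity_rates.items():
            for p in by_class.values():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"positivity rate out of [0,1] for criterion {cid}")

    @property
    def window(self) -> tuple[datetime.date, datetime.date]:
        """Record window [anchor - window_days, anchor], inclusive."""
        return (self.anchor_date - datetime.timedelta(days=self.window_days),
                self.anchor_date)


def reference_cohort_config(seed: int = 0) -> SyntheticCohortConfig:
    """Config emulating the benchmark cohort structure: 78 patients in
    an exact 39/39 pre-SC/post-SC split; expected class counts of about
    48 SLE+, 9 UCTD and 21 SLE-; ANA evidence predating the record
    window for roughly a quarter of ANA-positive patients (14/57); 1:40
    titer traps for roughly a quarter of ANA-negative patients (5/21);
    full non-ANA clinical determination for 15 patients."""
    return SyntheticCohortConfig(
        n_patients=78,
        out_of_window_prob=14 / 57,
        low_titer_trap_prob=5 / 21,
        n_full_determinations=15,
        seed=seed,
    )


@dataclass(frozen=True)
class Note:
    doc_id: str
    date: datetime.date
    text: str


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    group: Group
    notes: tuple[Note, ...]


@dataclass(frozen=True)
class EvidenceLedgerEntry:
    """What the generator decided for one (patient, criterion): the
    latent truth, the style it was conveyed in, whether its evidence
    falls inside the record window, and the exact rendered snippet (for
    exact back-matching in audits); ``snippet`` is None when the
    evidence never appears in any note."""

    truth_positive: bool
    style: EvidenceStyle
    in_window: bool
    trap: bool = False
    snippet: str | None = None
    kind: EvidenceKind | None = None
    doc_id: str | None = None
    date: datetime.date | None = None


@dataclass(frozen=True)
class GroundTruthLabel:
    patient_id: str
    clinical_class: SleClass
    determinations: dict[int, ClinDet]
    evidence: dict[int, EvidenceLedgerEntry]


def score(statuses: dict[int, bool], catalog: CriteriaCatalog) -> int:
    """Additive weighted score over positive non-entry criteria."""
    return sum(c.weight for c in catalog.scored if statuses.get(c.id, False))


def latent_class(statuses: dict[int, bool], catalog: CriteriaCatalog) -> SleClass:
    """Classification rule applied to latent boolean statuses."""
    if not statuses.get(catalog.entry.id, False):
        return SleClass.SLE_NEG
    clinical_any = any(statuses.get(c.id, False) for c in catalog.clinical)
    if clinical_any and score(statuses, catalog) >= SLE_POS_THRESHOLD:
        return SleClass.SLE_POS
    return SleClass.UCTD

# Mutually exclusive criterion pairs under plain additive scoring: the
# graded variants (nephritis class II/V vs III/IV, one vs both
# complement components low) are assigned at most one positive.
_EXCLUSIVE_PAIRS = ((17, 18), (20, 21))


def _apply_exclusivity(statuses: dict[int, bool], rng: np.random.Generator) -> None:
    for low_id, high_id in _EXCLUSIVE_PAIRS:
        if statuses.get(low_id) and statuses.get(high_id):
            drop = low_id if rng.random() < 0.5 else high_id
            statuses[drop] = False


def _excluded_partner(cid: int, statuses: dict[int, bool]) -> bool:
    return any(
        statuses.get(other, False)
        for pair in _EXCLUSIVE_PAIRS if cid in pair
        for other in pair if other != cid
    )


def _repair_statuses(
    statuses: dict[int, bool],
    klass: SleClass,
    catalog: CriteriaCatalog,
    rates: dict[int, dict[SleClass, float]],
) -> None:
    """Minimal deterministic edits making the statuses consistent with
    the target class under the classification rule."""
    entry_id = catalog.entry.id
    if klass is SleClass.SLE_NEG:
        statuses[entry_id] = False
        return
    statuses[entry_id] = True
    if klass is SleClass.SLE_POS:
        if not any(statuses.get(cid, False) for cid in CLINICAL_IDS):
            statuses[15] = True  # joint involvement: the most prevalent clinical sign
        # flip on further criteria in decreasing order of class prevalence
        order = sorted(
            (c for c in catalog.scored if not statuses.get(c.id, False)),
            key=lambda c: (-rates[c.id][klass], c.id),
        )
        for c in order:
            if score(statuses, catalog) >= SLE_POS_THRESHOLD:
                break
            if _excluded_partner(c.id, statuses):
                continue
            statuses[c.id] = True
    else:  # UCTD: ANA+ but short of SLE+; shed heaviest positives first
        while (
            any(statuses.get(cid, False) for cid in CLINICAL_IDS)
            and score(statuses, catalog) >= SLE_POS_THRESHOLD
        ):
            positives = [c for c in catalog.scored if statuses.get(c.id, False)]
            heaviest = max(positives, key=lambda c: (c.weight, c.id))
            statuses[heaviest.id] = False


def render_evidence(
    criterion: CriterionDefinition,
    style: EvidenceStyle,
    positive: bool,
    rng: np.random.Generator,
    trap: bool = False,
) -> tuple[str, EvidenceKind, EvidenceStyle]:
    """Render one evidence snippet for a criterion; see
    :func:`slemine.templates.render_template` for fallback rules."""
    return render_template(criterion.id, style, positive, rng, trap=trap)


def _allocate_groups(config: SyntheticCohortConfig, rng: np.random.Generator) -> list[Group]:
    """Largest-remainder allocation of exact group counts, shuffled."""
    groups = list(config.group_mix.keys())
    quotas = np.array([config.group_mix[g] * config.n_patients for g in groups])
    counts = np.floor(quotas).astype(int)
    remainder = config.n_patients - counts.sum()
    for idx in np.argsort(-(quotas - counts))[:remainder]:
        counts[idx] += 1
    assignment = [g for g, c in zip(groups, counts) for _ in range(c)]
    rng.shuffle(assignment)
    return assignment


def generate_cohort(
    config: SyntheticCohortConfig,
    catalog: CriteriaCatalog | None = None,
) -> tuple[list[PatientRecord], list[GroundTruthLabel]]:
    """Generate a cohort of note records plus aligned ground truth."""
    catalog = catalog or load_catalog()
    rng = np.random.default_rng(config.seed)
    classes = list(config.class_mix.keys())
    class_p = np.array([config.class_mix[k] for k in classes])
    styles = list(config.evidence_style_mix.keys())
    style_p = np.array([config.evidence_style_mix[s] for s in styles])
    groups = _allocate_groups(config, rng)
    win_start, win_end = config.window

    records: list[PatientRecord] = []
    labels: list[GroundTruthLabel] = []
    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        klass = classes[rng.choice(len(classes), p=class_p)]

        statuses = {catalog.entry.id: klass is not SleClass.SLE_NEG}
        for c in catalog.scored:
            statuses[c.id] = rng.random() < config.positivity_rates[c.id][klass]
        _apply_exclusivity(statuses, rng)
        _repair_statuses(statuses, klass, catalog, config.positivity_rates)

        # notes skeleton: sentences accumulated per note, then shuffled
        n_notes = int(3 + rng.integers(0, 3))
        offsets = np.sort(rng.integers(0, config.window_days, size=n_notes))
        note_dates = [win_start + datetime.timedelta(days=int(o)) for o in offsets]
        note_sentences: list[list[str]] = [[] for _ in range(n_notes)]
        history_sentences: list[str] = []

        evidence: dict[int, EvidenceLedgerEntry] = {}
        for c in catalog:
            truth = statuses[c.id]
            style = styles[rng.choice(len(styles), p=style_p)]
            in_window = True
            trap = False
            if c.id == catalog.entry.id:
                if truth and style is not EvidenceStyle.NOT_REPORTED:
                    in_window = rng.random() >= config.out_of_window_prob
                if not truth and style is not EvidenceStyle.NOT_REPORTED:
                    trap = rng.random() < config.low_titer_trap_prob
            entry = EvidenceLedgerEntry(truth, style, in_window, trap=trap)
            if style is not EvidenceStyle.NOT_REPORTED:
                text, kind, realized = render_evidence(c, style, truth, rng, trap=trap)
                if in_window:
                    note_idx = int(rng.integers(0, n_notes))
                    note_sentences[note_idx].append(text)
                    entry = replace(
                        entry, style=realized, snippet=text, kind=kind,
                        doc_id=f"{pid}-N{note_idx + 1:02d}", date=note_dates[note_idx],
                    )
                elif config.retain_dated_history:
                    history_sentences.append(text)
                    entry = replace(entry, style=realized, snippet=text, kind=kind)
                else:
                    entry = replace(entry, style=realized)
            evidence[c.id] = entry

        notes = []
        for j, (sentences, day) in enumerate(zip(note_sentences, note_dates)):
            n_distract = int(rng.poisson(config.distractor_rate))
            sentences = sentences + [
                DISTRACTORS[rng.integers(0, len(DISTRACTORS))] for _ in range(n_distract)
            ]
            rng.shuffle(sentences)
            notes.append(Note(f"{pid}-N{j + 1:02d}", day, " ".join(sentences)))
        if history_sentences:
            hist_date = win_start - datetime.timedelta(days=int(rng.integers(30, 400)))
            doc_id = f"{pid}-H01"
            notes.append(Note(doc_id, hist_date, " ".join(history_sentences)))
            for cid, entry in evidence.items():
                if entry.snippet is not None and not entry.in_window:
                    evidence[cid] = replace(entry, doc_id=doc_id, date=hist_date)

        determinations = {
            catalog.entry.id: ClinDet.POS if statuses[catalog.entry.id] else ClinDet.NEG
        }
        for c in catalog.scored:
            determinations[c.id] = ClinDet.POS if statuses[c.id] else ClinDet.NEG

        records.append(PatientRecord(pid, groups[i], tuple(notes)))
        labels.append(GroundTruthLabel(pid, klass, determinations, evidence))

    _sparsify_determinations(config, records, labels, rng, catalog)
    return records, labels


def _sparsify_determinations(
    config: SyntheticCohortConfig,
    records: list[PatientRecord],
    labels: list[GroundTruthLabel],
    rng: np.random.Generator,
    catalog: CriteriaCatalog,
) -> None:
    """Keep non-entry clinical determinations only for a fully-determined
    subset (drawn from pre-SC patients first); ANA stays determined for
    everyone."""
    if config.n_full_determinations is None:
        return
    n_full = min(config.n_full_determinations, len(records))
    pre = [i for i, r in enumerate(records) if r.group is Group.PRE_SC]
    post = [i for i, r in enumerate(records) if r.group is not Group.PRE_SC]
    pool = pre + post
    chosen = set(
        rng.choice(pre, size=n_full, replace=False) if n_full <= len(pre)
        else pool[:n_full]
    )
    for i, label in enumerate(labels):
        if i in chosen:
            continue
        for c in catalog.scored:
            label.determinations[c.id] = ClinDet.UNSPECIFIED
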