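"""EULAR/ACR 2019 decision-tree classifier: SLE- / UCTD / SLE+.

The decision tree: (1) the ANA entry criterion must be met, otherwise
the patient is SLE-negative outright; (2) at least one clinical
criterion (ids 2-18) must be positive; (3) the additive weighted score
over positive criteria must reach 10.  A patient passing the entry gate
but failing either later gate is labelled UCTD (undifferentiated
connective tissue disorder) — the mapping of "entered but unmet" to
UCTD is this package's explicit reading of the tripartite outcome.

``not_reported`` determinations score as negative: a criterion absent
from the record contributes no points and cannot open the clinical
gate.

Scoring is the plain weighted sum by default.  The official
EULAR/ACR rule counts only the highest-weighted positive criterion per
organ domain; that behaviour is available via ``domain_max=True`` with
the standard ten-domain partition, but is off by default because the
plain sum is the rule the rest of this package's statistics are built
around.

``first_to_ten`` mode evaluates criteria in descending weight order
(ties broken by ascending id) and stops as soon as the score reaches 10
with a clinical criterion present; the final class is provably
identical to exhaustive evaluation, only the visited prefix differs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .catalog import CriteriaCatalog, Role, load_catalog
from .labels import Determination, SleClass
from .synthetic import SLE_POS_THRESHOLD

#: Organ-domain partition used when ``domain_max`` is on (one scored
#: contribution per domain: the highest-weighted positive criterion).
DOMAIN_PARTITION: dict[str, tuple[int, ...]] = {
    "constitutional": (2,),
    "hematologic": (3, 4, 5),
    "neuropsychiatric": (6, 7, 8),
    "mucocutaneous": (9, 10, 11, 12),
    "serosal": (13, 14),
    "musculoskeletal": (15,),
    "renal": (16, 17, 18),
    "antiphospholipid": (19,),
    "complement": (20, 21),
    "sle_specific_antibodies": (22,),
}


class ClassifierInputError(ValueError):
    """Raised for profiles that cannot be classified."""


@dataclass(frozen=True)
class ClassificationResult:
    patient_id: str
    klass: SleClass
    entry_passed: bool
    clinical_gate_passed: bool
    total_score: int
    contributing: tuple[tuple[int, int], ...]  # (criterion id, weight)
    evaluation_order_used: tuple[int, ...] = ()


@dataclass(frozen=True)
class AttritionReport:
    """Cohort counts at successive decision branches."""

    entered: int
    failed_entry: int
    failed_clinical_gate: int
    failed_score: int
    sle_pos: int

    def as_dict(self) -> dict[str, int]:
        return {
            "entered": self.entered,
            "failed_entry": self.failed_entry,
            "failed_clinical_gate": self.failed_clinical_gate,
            "failed_score": self.failed_score,
            "sle_pos": self.sle_pos,
        }


def _positive(det: Determination | str | bool) -> bool:
    if isinstance(det, bool):
        return det
    return Determination(det) is Determination.POSITIVE


def _domain_filtered(
    positives: list[int], catalog: CriteriaCatalog
) -> list[int]:
    """Keep only the highest-weighted positive per organ domain."""
    kept: list[int] = []
    for ids in DOMAIN_PARTITION.values():
        present = [cid for cid in ids if cid in positives]
        if present:
            kept.append(max(present, key=lambda cid: (catalog.weight(cid), -cid)))
    extra = [cid for cid in positives if not any(cid in ids for ids in DOMAIN_PARTITION.values())]
    return sorted(kept + extra)


def classify(
    profile: dict[int, Determination | str | bool],
    catalog: CriteriaCatalog | None = None,
    mode: str = "exhaustive",
    patient_id: str = "",
    domain_max: bool = False,
) -> ClassificationResult:
    """Classify one patient from per-criterion determinations.

    ``profile`` maps criterion id to a determination (or a plain bool);
    criteria 2-22 missing from the mapping are treated as negative, but
    the entry criterion must be present.
    """
    catalog = catalog or load_catalog()
    if mode not in ("exhaustive", "first_to_ten"):
        raise ClassifierInputError(f"unknown mode {mode!r}")
    if hasattr(profile, "determinations"):  # accept a CriterionProfile
        patient_id = patient_id or profile.patient_id
        profile = profile.determinations()
    entry_id = catalog.entry.id
    if entry_id not in profile:
        raise ClassifierInputError(
            f"profile for {patient_id or '<patient>'} lacks entry criterion {entry_id}"
        )

    entry_passed = _positive(profile[entry_id])
    if not entry_passed:
        return ClassificationResult(
            patient_id, SleClass.SLE_NEG, False, False, 0, (), (entry_id,)
        )

    positives = [
        c.id for c in catalog.scored if _positive(profile.get(c.id, False))
    ]
    if domain_max:
        positives = _domain_filtered(positives, catalog)
    order = sorted(
        (c for c in catalog.scored),
        key=lambda c: (-c.weight, c.id),
    )

    visited: list[int] = [entry_id]
    score = 0
    clinical = False
    contributing: list[tuple[int, int]] = []
    for c in order:
        visited.append(c.id)
        if c.id in positives:
            score += c.weight
            contributing.append((c.id, c.weight))
            clinical = clinical or c.role is Role.CLINICAL
        if (
            mode == "first_to_ten"
            and clinical
            and score >= SLE_POS_THRESHOLD
        ):
            break

    klass = (
        SleClass.SLE_POS
        if clinical and score >= SLE_POS_THRESHOLD
        else SleClass.UCTD
    )
    order_used = tuple(visited) if mode == "first_to_ten" else tuple(
        [entry_id] + [c.id for c in order]
    )
    return ClassificationResult(
        patient_id, klass, True, clinical, score, tuple(contributing), order_used
    )


def classify_cohort(
    profiles,
    catalog: CriteriaCatalog | None = None,
    mode: str = "exhaustive",
    domain_max: bool = False,
) -> list[ClassificationResult]:
    """Classify a cohort; order-stable, one result per patient.

    ``profiles`` is either a mapping ``patient_id -> determinations`` or
    an iterable of :class:`~slemine.extraction.CriterionProfile`.
    """
    if isinstance(profiles, dict):
        items = list(profiles.items())
    else:
        items = [(p.patient_id, p.determinations()) for p in profiles]
    counts = Counter(pid for pid, _ in items)
    dupes = sorted(pid for pid, n in counts.items() if n > 1)
    if dupes:
        raise ClassifierInputError(f"duplicate patient ids: {dupes}")
    catalog = catalog or load_catalog()
    return [
        classify(profile, catalog, mode, patient_id=pid, domain_max=domain_max)
        for pid, profile in items
    ]


def attrition_report(results: list[ClassificationResult]) -> AttritionReport:
    """Branch-by-branch case attrition in decision-tree order."""
    failed_entry = sum(not r.entry_passed for r in results)
    failed_gate = sum(r.entry_passed and not r.clinical_gate_passed for r in results)
    failed_score = sum(
        r.entry_passed and r.clinical_gate_passed and r.klass is not SleClass.SLE_POS
        for r in results
    )
    sle_pos = sum(r.klass is SleClass.SLE_POS for r in results)
    return AttritionReport(len(results), failed_entry, failed_gate, failed_score, sle_pos)
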