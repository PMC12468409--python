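"""Readers and writers binding pipeline stages into reproducible runs.

Plain-text interchange only: notes as line-delimited JSON (one object
per note), tables as CSV with header rows, configuration as YAML.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import pandas as pd
import yaml

from .catalog import CriteriaCatalog, load_catalog
from .classify import ClassificationResult
from .evaluation import CriterionInfluence, ConcordanceSummary
from .extraction import CriterionProfile, EvidenceMention, CriterionCall
from .labels import ClinDet, Determination, Group, SleClass
from .synthetic import (
    GroundTruthLabel,
    Note,
    PatientRecord,
    SyntheticCohortConfig,
)
from .templates import EvidenceStyle


def _criterion_columns(catalog: CriteriaCatalog) -> list[str]:
    return [f"c{cid}" for cid in catalog.ids]


# ---------------------------------------------------------------- notes

def write_notes(records: list[PatientRecord], path: str | Path) -> None:
    """One JSON object per note: patient_id, group, doc_id, date, text."""
    with open(path, "w") as fh:
        for rec in records:
            for note in rec.notes:
                fh.write(json.dumps({
                    "patient_id": rec.patient_id,
                    "group": rec.group.value,
                    "doc_id": note.doc_id,
                    "date": note.date.isoformat(),
                    "text": note.text,
                }, sort_keys=True) + "\n")


def read_notes(path: str | Path) -> list[PatientRecord]:
    by_patient: dict[str, tuple[Group, list[Note]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            group = Group(obj.get("group", Group.PRE_SC.value))
            slot = by_patient.setdefault(obj["patient_id"], (group, []))
            slot[1].append(Note(
                obj["doc_id"], datetime.date.fromisoformat(obj["date"]), obj["text"],
            ))
    return [
        PatientRecord(pid, group, tuple(notes))
        for pid, (group, notes) in by_patient.items()
    ]


# ---------------------------------------------------------------- truth

def write_truth(labels: list[GroundTruthLabel], path: str | Path,
                catalog: CriteriaCatalog | None = None) -> None:
    catalog = catalog or load_catalog()
    rows = []
    for lab in labels:
        row = {"patient_id": lab.patient_id, "clinical_class": lab.clinical_class.value}
        for cid in catalog.ids:
            row[f"c{cid}"] = lab.determinations.get(cid, ClinDet.UNSPECIFIED).value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_truth(path: str | Path, catalog: CriteriaCatalog | None = None
               ) -> list[GroundTruthLabel]:
    catalog = catalog or load_catalog()
    df = pd.read_csv(path)
    labels = []
    for _, row in df.iterrows():
        dets = {cid: ClinDet(row[f"c{cid}"]) for cid in catalog.ids}
        labels.append(GroundTruthLabel(
            str(row["patient_id"]), SleClass(row["clinical_class"]), dets, {},
        ))
    return labels


# -------------------------------------------------------------- profiles

def write_profiles(profiles: list[CriterionProfile], path: str | Path,
                   consistency_path: str | Path | None = None,
                   catalog: CriteriaCatalog | None = None) -> None:
    catalog = catalog or load_catalog()
    det_rows, cons_rows = [], []
    for prof in profiles:
        det_row = {"patient_id": prof.patient_id}
        cons_row = {"patient_id": prof.patient_id}
        for cid in catalog.ids:
            entry = prof.criteria[cid]
            det_row[f"c{cid}"] = entry.consensus.value
            cons_row[f"c{cid}"] = entry.consistency
        det_rows.append(det_row)
        cons_rows.append(cons_row)
    pd.DataFrame(det_rows).to_csv(path, index=False)
    if consistency_path is not None:
        pd.DataFrame(cons_rows).to_csv(consistency_path, index=False)


def read_profiles(path: str | Path, catalog: CriteriaCatalog | None = None
                  ) -> dict[str, dict[int, Determination]]:
    catalog = catalog or load_catalog()
    df = pd.read_csv(path)
    return {
        str(row["patient_id"]): {
            cid: Determination(row[f"c{cid}"]) for cid in catalog.ids
        }
        for _, row in df.iterrows()
    }


# ------------------------------------------------------- mentions/calls

def write_mentions(mentions: list[EvidenceMention], path: str | Path) -> None:
    rows = [{
        "patient_id": m.patient_id, "criterion_id": m.criterion_id,
        "doc_id": m.doc_id, "date": m.date.isoformat(),
        "start": m.span[0], "end": m.span[1], "snippet": m.snippet,
        "kind": m.kind.value, "in_window": m.in_window, "value": m.value,
    } for m in mentions]
    pd.DataFrame(rows, columns=[
        "patient_id", "criterion_id", "doc_id", "date", "start", "end",
        "snippet", "kind", "in_window", "value",
    ]).to_csv(path, index=False)


def write_calls(calls: list[CriterionCall], path: str | Path) -> None:
    rows = [{
        "patient_id": c.patient_id, "criterion_id": c.criterion_id,
        "replicate_index": c.replicate_index,
        "determination": c.determination.value, "n_mentions": len(c.mentions),
    } for c in calls]
    pd.DataFrame(rows, columns=[
        "patient_id", "criterion_id", "replicate_index", "determination",
        "n_mentions",
    ]).to_csv(path, index=False)


# --------------------------------------------------------------- results

def write_results(results: list[ClassificationResult], path: str | Path) -> None:
    rows = [{
        "patient_id": r.patient_id, "class": r.klass.value,
        "entry_passed": r.entry_passed,
        "clinical_gate_passed": r.clinical_gate_passed,
        "total_score": r.total_score,
    } for r in results]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_results(path: str | Path) -> dict[str, SleClass]:
    df = pd.read_csv(path)
    return {str(row["patient_id"]): SleClass(row["class"]) for _, row in df.iterrows()}


def write_influence(influences: list[CriterionInfluence], path: str | Path) -> None:
    rows = [{
        "criterion_id": i.criterion_id, "class": i.klass.value,
        "count": i.count, "weight": i.weight,
        "influence": i.influence,
        "ci_low": i.interval[0], "ci_high": i.interval[1],
        "interval_method": "wilson count-share, weight-rescaled (approximation)",
    } for i in influences]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_concordance(summary: ConcordanceSummary, path: str | Path) -> None:
    doc = {
        "contingency": {
            "order": [k.value for k in (SleClass.SLE_NEG, SleClass.UCTD, SleClass.SLE_POS)],
            "rows_clinical_columns_predicted": summary.contingency.tolist(),
        },
        "exact_match_fraction": summary.exact_match,
        "clinical_fractions": {k.value: v for k, v in summary.clinical_fractions.items()},
        "predicted_fractions": {k.value: v for k, v in summary.predicted_fractions.items()},
        "n": summary.n,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------- config

def config_to_dict(config: SyntheticCohortConfig) -> dict:
    doc = dataclasses.asdict(config)
    doc["group_mix"] = {k.value: v for k, v in config.group_mix.items()}
    doc["class_mix"] = {k.value: v for k, v in config.class_mix.items()}
    doc["evidence_style_mix"] = {k.value: v for k, v in config.evidence_style_mix.items()}
    doc["positivity_rates"] = {
        cid: {k.value: p for k, p in by_class.items()}
        for cid, by_class in config.positivity_rates.items()
    }
    doc["anchor_date"] = config.anchor_date.isoformat()
    return doc


def config_from_dict(doc: dict) -> SyntheticCohortConfig:
    doc = dict(doc)
    doc["group_mix"] = {Group(k): v for k, v in doc["group_mix"].items()}
    doc["class_mix"] = {SleClass(k): v for k, v in doc["class_mix"].items()}
    doc["evidence_style_mix"] = {
        EvidenceStyle(k): v for k, v in doc["evidence_style_mix"].items()
    }
    doc["positivity_rates"] = {
        int(cid): {SleClass(k): p for k, p in by_class.items()}
        for cid, by_class in doc["positivity_rates"].items()
    }
    doc["anchor_date"] = datetime.date.fromisoformat(doc["anchor_date"])
    return SyntheticCohortConfig(**doc)


def write_config(config: SyntheticCohortConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=True))


def read_config(path: str | Path) -> SyntheticCohortConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))
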