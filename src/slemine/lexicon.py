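"""Keyword lexicons and relevance rules for criterion extraction.

The extraction stage is a deterministic, seedable stand-in for a
generative-model document reader: a permissive first pass harvests any
sentence matching a criterion's keyword/keyphrase list or quantitative
pattern, and a stringent second pass adjudicates polarity.  The default
lexicon is engineered against the synthetic template banks; users can
supply their own lexicon as YAML for real note collections.

Each criterion carries:

* keyword keys, each tagged with the evidence kind it indicates
  (phrase vs descriptive) and whether it is *core*.  Replicate runs
  perturb the lexicon by seeded dropout of non-core keys, emulating the
  run-to-run variability of stochastic generative extraction; core keys
  are never dropped.
* optionally a quantitative pattern (regex with one captured value) and
  a threshold, e.g. ANA titers ``1:N`` positive at N >= 80, WBC below
  4.0 for leukopenia.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .catalog import CriteriaCatalog
from .templates import EvidenceKind


class LexiconError(ValueError):
    """Raised for lexicons that do not cover the catalog or fail to parse."""


#: Negation cues searched within the sentence containing a keyword hit.
NEGATION_PATTERN = re.compile(
    r"\b(?:no|not|without|negative|denies|denied|absent|ruled out|free of)\b"
    r"|within normal limits",
    re.IGNORECASE,
)


@dataclass(frozen=True)
class LexiconKey:
    phrase: str
    kind: EvidenceKind = EvidenceKind.PHRASE
    core: bool = False

    def compile(self) -> re.Pattern[str]:
        pat = r"\b" + re.escape(self.phrase)
        if self.phrase[-1].isalpha():
            pat += r"s?"  # tolerate simple plurals
        return re.compile(pat + r"\b", re.IGNORECASE)


@dataclass(frozen=True)
class NumericRule:
    """Quantitative pattern with positivity threshold.

    ``op`` is one of ``>=``, ``>``, ``<``: a captured value satisfying
    ``value op threshold`` is positive evidence, otherwise negative.
    """

    pattern: str
    op: str
    threshold: float

    def compile(self) -> re.Pattern[str]:
        return re.compile(self.pattern, re.IGNORECASE)

    def is_positive(self, value: float) -> bool:
        if self.op == ">=":
            return value >= self.threshold
        if self.op == ">":
            return value > self.threshold
        if self.op == "<":
            return value < self.threshold
        raise LexiconError(f"unknown comparison operator {self.op!r}")


@dataclass(frozen=True)
class CriterionLexicon:
    criterion_id: int
    keys: tuple[LexiconKey, ...]
    numeric: NumericRule | None = None


@dataclass(frozen=True)
class Lexicon:
    entries: dict[int, CriterionLexicon] = field(default_factory=dict)

    def require_coverage(self, catalog: CriteriaCatalog) -> None:
        missing = [c.id for c in catalog if c.id not in self.entries]
        if missing:
            raise LexiconError(f"lexicon missing criteria: {missing}")

    def perturbed(self, dropout: float, rng: np.random.Generator) -> "Lexicon":
        """Seeded dropout of non-core keys (numeric rules are kept)."""
        if dropout <= 0:
            return self
        entries = {}
        for cid, entry in self.entries.items():
            keys = tuple(
                k for k in entry.keys if k.core or rng.random() >= dropout
            )
            entries[cid] = replace(entry, keys=keys)
        return Lexicon(entries)

    def to_yaml(self, path: str | Path) -> None:
        doc = {}
        for cid, entry in sorted(self.entries.items()):
            item: dict = {
                "keys": [
                    {"phrase": k.phrase, "kind": k.kind.value, "core": k.core}
                    for k in entry.keys
                ]
            }
            if entry.numeric is not None:
                item["numeric"] = {
                    "pattern": entry.numeric.pattern,
                    "op": entry.numeric.op,
                    "threshold": entry.numeric.threshold,
                }
            doc[cid] = item
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Lexicon":
        try:
            doc = yaml.safe_load(Path(path).read_text())
            entries = {}
            for cid, item in doc.items():
                cid = int(cid)
                keys = tuple(
                    LexiconKey(k["phrase"], EvidenceKind(k.get("kind", "phrase")),
                               bool(k.get("core", False)))
                    for k in item.get("keys", [])
                )
                numeric = None
                if "numeric" in item:
                    n = item["numeric"]
                    numeric = NumericRule(n["pattern"], n["op"], float(n["threshold"]))
                entries[cid] = CriterionLexicon(cid, keys, numeric)
            return cls(entries)
        except (KeyError, TypeError, ValueError) as exc:
            raise LexiconError(f"malformed lexicon file {path}: {exc}") from exc


@dataclass(frozen=True)
class RuleSet:
    """Second-pass relevance rules.

    ``accept_uncorroborated_phrase`` (default on) scores an explicit
    positivity phrase as positive even without quantitative
    corroboration — the permissive behaviour that produces phrase-only
    false positives in real record mining.  ``enforce_window`` drops
    evidence dated before the record window from scoring.
    ``perturbation`` is the non-core key dropout fraction applied per
    replicate.
    """

    enforce_window: bool = True
    accept_uncorroborated_phrase: bool = True
    titer_threshold: int = 80
    perturbation: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.perturbation <= 1.0:
            raise ValueError("perturbation must lie in [0, 1]")


_K = EvidenceKind


def default_lexicon() -> Lexicon:
    """Lexicon covering all 22 criteria, matched to the synthetic
    template banks (and serving as a worked example for real notes)."""
    def keys(core: str, *rest: tuple[str, EvidenceKind]) -> tuple[LexiconKey, ...]:
        out = [LexiconKey(core, _K.PHRASE, core=True)]
        out += [LexiconKey(p, kind) for p, kind in rest]
        return tuple(out)

    entries = {
        1: CriterionLexicon(1, keys("ANA", ("speckled", _K.DESCRIPTIVE),
                                    ("homogeneous ANA", _K.DESCRIPTIVE)),
                            NumericRule(r"\bANA\b[^.!?\n]*?1:(\d+)", ">=", 80)),
        2: CriterionLexicon(2, keys("fever", ("febrile", _K.DESCRIPTIVE)),
                            NumericRule(r"Temperature (\d{2}\.\d) C", ">=", 38.3)),
        3: CriterionLexicon(3, keys("leukopenia", ("low white cell count", _K.DESCRIPTIVE)),
                            NumericRule(r"WBC (\d+(?:\.\d)?) x10", "<", 4.0)),
        4: CriterionLexicon(4, keys("thrombocytopenia", ("low platelet count", _K.DESCRIPTIVE)),
                            NumericRule(r"Platelets (\d+) x10", "<", 100)),
        5: CriterionLexicon(5, keys("autoimmune hemolysis", ("hemolytic anemia", _K.DESCRIPTIVE)),
                            NumericRule(r"Haptoglobin (\d+) mg/dL", "<", 30)),
        6: CriterionLexicon(6, keys("delirium", ("confusional state", _K.DESCRIPTIVE))),
        7: CriterionLexicon(7, keys("psychosis", ("hallucinations", _K.DESCRIPTIVE),
                                    ("delusions", _K.DESCRIPTIVE))),
        8: CriterionLexicon(8, keys("seizure", ("convulsion", _K.DESCRIPTIVE))),
        9: CriterionLexicon(9, keys("alopecia", ("hair thinning", _K.DESCRIPTIVE))),
        10: CriterionLexicon(10, keys("oral ulcer",
                                      ("ulceration of the hard palate", _K.DESCRIPTIVE))),
        11: CriterionLexicon(11, keys("discoid", ("annular polycyclic", _K.DESCRIPTIVE))),
        12: CriterionLexicon(12, keys("malar rash", ("acute cutaneous lupus", _K.PHRASE),
                                      ("butterfly-distribution erythema", _K.DESCRIPTIVE))),
        13: CriterionLexicon(13, keys("effusion", ("costophrenic", _K.DESCRIPTIVE))),
        14: CriterionLexicon(14, keys("pericarditis", ("friction rub", _K.DESCRIPTIVE))),
        15: CriterionLexicon(15, keys("synovitis", ("joint swelling", _K.PHRASE),
                                      ("swollen joints", _K.DESCRIPTIVE))),
        16: CriterionLexicon(16, keys("proteinuria", ("frothy urine", _K.DESCRIPTIVE)),
                             NumericRule(r"Urine protein (\d+) mg/24h", ">", 500)),
        17: CriterionLexicon(17, keys("lupus nephritis class II",
                                      ("lupus nephritis class V", _K.PHRASE),
                                      ("membranous", _K.DESCRIPTIVE))),
        18: CriterionLexicon(18, keys("lupus nephritis class III",
                                      ("lupus nephritis class IV", _K.PHRASE),
                                      ("proliferative glomerulonephritis", _K.DESCRIPTIVE))),
        19: CriterionLexicon(19, keys("antiphospholipid", ("anticardiolipin", _K.PHRASE),
                                      ("lupus anticoagulant", _K.DESCRIPTIVE)),
                             NumericRule(r"Anticardiolipin IgG (\d+) GPL", ">", 40)),
        20: CriterionLexicon(20, keys("complement C3", ("low C3", _K.PHRASE),
                                      ("low C4", _K.PHRASE)),
                             NumericRule(r"Complement C3 (\d+) mg/dL", "<", 90)),
        21: CriterionLexicon(21, keys("C3 and C4", ("hypocomplementemia", _K.DESCRIPTIVE))),
        22: CriterionLexicon(22, keys("anti-dsDNA", ("anti-Smith", _K.PHRASE),
                                      ("double-stranded DNA", _K.DESCRIPTIVE)),
                             NumericRule(r"Anti-dsDNA (\d+) IU/mL", ">", 30)),
    }
    return Lexicon(entries)
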