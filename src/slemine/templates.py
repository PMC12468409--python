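"""Evidence snippet templates for the synthetic note generator.

Real medical records convey the same finding in heterogeneous styles:
numerically ("ANA titer 1:160"), as a phrase ("positive ANA result") or
descriptively ("speckled ANA pattern").  Each criterion here carries a
small bank of templates per (style, polarity); the lexicon module's
default keyword lists are written against these banks, and the
round-trip (render -> first-pass harvest -> second-pass scoring) is
exercised by the test suite, including a full cross-criterion collision
matrix.

Numeric templates embed a value drawn from clinically sensible positive
or negative ranges (e.g. WBC below 4.0 x10^9/L for leukopenia); the
extraction ruleset carries the matching thresholds.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np


class EvidenceKind(str, enum.Enum):
    NUMERICAL = "numerical"
    PHRASE = "phrase"
    DESCRIPTIVE = "descriptive"


class EvidenceStyle(str, enum.Enum):
    """Style assigned by the generator; NOT_REPORTED means the finding
    never made it into the record."""

    NUMERICAL = "numerical"
    PHRASE = "phrase"
    DESCRIPTIVE = "descriptive"
    NOT_REPORTED = "not_reported"


@dataclass(frozen=True)
class NumericTemplate:
    fmt: str
    positive_values: tuple
    negative_values: tuple


#: ANA titer dilutions considered positive (>= 1:80) vs sub-threshold.
ANA_POSITIVE_TITERS = (80, 160, 320, 640, 1280)
ANA_NEGATIVE_TITERS = (40,)
ANA_TRAP_SNIPPET = "ANA reported positive at 1:40 titer."

NUMERIC_TEMPLATES: dict[int, NumericTemplate] = {
    1: NumericTemplate("ANA titer 1:{v} on immunofluorescence.", ANA_POSITIVE_TITERS, ANA_NEGATIVE_TITERS),
    2: NumericTemplate("Temperature {v} C recorded.", ("38.6", "38.9", "39.4"), ("36.8", "37.1")),
    3: NumericTemplate("WBC {v} x10^9/L on CBC.", ("2.4", "2.8", "3.3"), ("5.6", "6.2", "7.4")),
    4: NumericTemplate("Platelets {v} x10^9/L.", ("54", "78", "92"), ("180", "240", "310")),
    5: NumericTemplate("Haptoglobin {v} mg/dL with reticulocytosis.", ("6", "12", "21"), ("96", "140")),
    16: NumericTemplate("Urine protein {v} mg/24h.", ("640", "820", "1450"), ("90", "110", "160")),
    19: NumericTemplate("Anticardiolipin IgG {v} GPL.", ("48", "62", "95"), ("6", "8", "12")),
    20: NumericTemplate("Complement C3 {v} mg/dL.", ("52", "62", "74"), ("104", "118")),
    22: NumericTemplate("Anti-dsDNA {v} IU/mL by ELISA.", ("86", "118", "240"), ("9", "12", "18")),
}

# (positive phrases, negative phrases, positive descriptive renderings).
# Descriptive banks are positive-only: a pattern-style description of an
# absent finding is not a construct seen in records, so negative
# descriptive requests fall back to phrase style.
PHRASE_TEMPLATES: dict[int, tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]] = {
    1: (
        ("Positive ANA result documented.", "ANA screen positive."),
        ("ANA negative on screening.", "Negative ANA result."),
        ("Speckled ANA pattern noted.", "Homogeneous ANA pattern reported."),
    ),
    2: (
        ("Recurrent fever episodes reported.", "Unexplained fever during admission."),
        ("No fever reported at any visit.",),
        ("Febrile on examination.",),
    ),
    3: (
        ("Leukopenia noted on CBC.", "Persistent leukopenia documented."),
        ("No leukopenia on serial counts.",),
        ("Persistently low white cell count.",),
    ),
    4: (
        ("Thrombocytopenia documented.", "Recurrent thrombocytopenia on CBC."),
        ("No thrombocytopenia observed.",),
        ("Low platelet count persisting over months.",),
    ),
    5: (
        ("Autoimmune hemolysis confirmed on workup.",),
        ("No evidence of autoimmune hemolysis.",),
        ("Coombs-positive hemolytic anemia.",),
    ),
    6: (
        ("Episode of delirium documented during admission.",),
        ("No delirium observed.",),
        ("Acute confusional state with fluctuating attention.",),
    ),
    7: (
        ("New-onset psychosis documented.",),
        ("No psychosis elicited on review.",),
        ("Auditory hallucinations and paranoid delusions reported.",),
    ),
    8: (
        ("Generalized seizure witnessed.", "Recurrent seizures reported."),
        ("No seizures reported.",),
        ("Tonic-clonic convulsion lasting two minutes.",),
    ),
    9: (
        ("Non-scarring alopecia present on scalp exam.",),
        ("No alopecia on examination.",),
        ("Diffuse hair thinning, scalp otherwise intact.",),
    ),
    10: (
        ("Recurrent oral ulcers on exam.",),
        ("No oral ulcers seen.",),
        ("Painless ulceration of the hard palate.",),
    ),
    11: (
        ("Discoid lupus lesions on the scalp.",),
        ("No discoid lesions identified.",),
        ("Annular polycyclic lesions over the upper back.",),
    ),
    12: (
        ("Malar rash consistent with acute cutaneous lupus.",),
        ("No malar rash observed.",),
        ("Butterfly-distribution erythema sparing the nasolabial folds.",),
    ),
    13: (
        ("Small pleural effusion on chest imaging.",),
        ("No pleural or pericardial effusion on imaging.",),
        ("Blunting of the costophrenic angles suggesting effusion.",),
    ),
    14: (
        ("Acute pericarditis diagnosed this visit.",),
        ("No pericarditis on cardiac review.",),
        ("Diffuse ST elevation with a pericardial friction rub.",),
    ),
    15: (
        ("Active synovitis in two or more joints.",),
        ("No synovitis or joint swelling today.",),
        ("Morning stiffness with tender swollen joints.",),
    ),
    16: (
        ("Significant proteinuria on urinalysis.",),
        ("No proteinuria detected.",),
        ("Frothy urine with 3+ protein on dipstick.",),
    ),
    17: (
        ("Renal biopsy demonstrating lupus nephritis class V.",
         "Renal biopsy demonstrating lupus nephritis class II."),
        ("Biopsy negative for lupus nephritis class II or V.",),
        ("Membranous glomerulopathy, lupus nephritis class V pattern.",),
    ),
    18: (
        ("Renal biopsy demonstrating lupus nephritis class IV.",
         "Renal biopsy demonstrating lupus nephritis class III."),
        ("Biopsy negative for lupus nephritis class III or IV.",),
        ("Diffuse proliferative glomerulonephritis, lupus nephritis class IV pattern.",),
    ),
    19: (
        ("Antiphospholipid antibodies positive.",),
        ("Antiphospholipid antibodies negative.",),
        ("Lupus anticoagulant detected on repeat testing.",),
    ),
    20: (
        ("Low C3 noted on complement testing.", "Low C4 noted on complement testing."),
        ("Complement C3 within normal limits.",),
        (),
    ),
    21: (
        ("Both C3 and C4 depressed on complement panel.",),
        ("No combined depression of C3 and C4.",),
        ("Marked hypocomplementemia with depletion of C3 and C4.",),
    ),
    22: (
        ("Anti-dsDNA antibodies positive.", "Anti-Smith antibodies detected."),
        ("Anti-dsDNA and anti-Smith antibodies negative.",),
        ("Strongly elevated double-stranded DNA antibody binding.",),
    ),
}

#: Criterion-irrelevant filler sentences; none matches any default
#: lexicon key or numeric pattern (asserted in the test suite).
DISTRACTORS: tuple[str, ...] = (
    "Patient arrived on time for scheduled follow-up.",
    "Vital signs stable; blood pressure well controlled.",
    "Discussed medication adherence and refill schedule.",
    "Counseled on sun protection and sleep hygiene.",
    "Routine dental cleaning recommended.",
    "Lipid panel reviewed; continue current statin.",
    "Influenza vaccination administered this visit.",
    "Patient reports walking thirty minutes daily.",
    "Family history reviewed and unchanged.",
    "Insurance documentation updated at front desk.",
    "Mild seasonal allergies managed with antihistamine.",
    "Hydration and balanced diet encouraged.",
)


def available_styles(criterion_id: int, positive: bool) -> tuple[EvidenceStyle, ...]:
    """Styles that have a template for this criterion and polarity."""
    styles = [EvidenceStyle.PHRASE]
    if criterion_id in NUMERIC_TEMPLATES:
        styles.insert(0, EvidenceStyle.NUMERICAL)
    pos, _neg, descr = PHRASE_TEMPLATES[criterion_id]
    if positive and descr:
        styles.append(EvidenceStyle.DESCRIPTIVE)
    return tuple(styles)


def render_template(
    criterion_id: int,
    style: EvidenceStyle,
    positive: bool,
    rng: np.random.Generator,
    trap: bool = False,
) -> tuple[str, EvidenceKind, EvidenceStyle]:
    """Render one evidence sentence.

    Returns ``(text, kind, realized_style)``.  Unsupported style
    requests fall back: numerical -> phrase for criteria without a
    quantitative rendering, descriptive -> phrase for negatives.
    A ``trap`` (ANA only) asserts positivity at a 1:40 titer, i.e. a
    snippet a careless reader scores positive but that fails the
    >= 1:80 positivity threshold.
    """
    if style is EvidenceStyle.NOT_REPORTED:
        raise ValueError("not_reported has no rendering")
    if trap:
        if criterion_id != 1:
            raise ValueError("titer traps are an ANA mechanism")
        return ANA_TRAP_SNIPPET, EvidenceKind.NUMERICAL, EvidenceStyle.NUMERICAL

    if style is EvidenceStyle.NUMERICAL and criterion_id not in NUMERIC_TEMPLATES:
        style = EvidenceStyle.PHRASE
    pos_bank, neg_bank, descr_bank = PHRASE_TEMPLATES[criterion_id]
    if style is EvidenceStyle.DESCRIPTIVE and not (positive and descr_bank):
        style = EvidenceStyle.PHRASE

    if style is EvidenceStyle.NUMERICAL:
        tpl = NUMERIC_TEMPLATES[criterion_id]
        values = tpl.positive_values if positive else tpl.negative_values
        v = values[rng.integers(len(values))]
        return tpl.fmt.format(v=v), EvidenceKind.NUMERICAL, style
    if style is EvidenceStyle.DESCRIPTIVE:
        bank = descr_bank
        kind = EvidenceKind.DESCRIPTIVE
    else:
        bank = pos_bank if positive else neg_bank
        kind = EvidenceKind.PHRASE
    return bank[rng.integers(len(bank))], kind, style
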