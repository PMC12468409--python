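"""EULAR/ACR 2019 SLE classification criteria catalog.

The 2019 EULAR/ACR classification model for systemic lupus erythematosus
consists of 22 criteria: a mandatory antinuclear-antibody (ANA) entry
criterion, 17 weighted clinical criteria (ids 2-18) and 4 weighted
immunologic criteria (ids 19-22).  A patient is classified SLE-positive
when the entry criterion is met, at least one clinical criterion is
positive, and the additive weighted score reaches 10 points.

This module is the single source of truth for criterion identities,
roles and weights; every other stage (generation, extraction,
classification, evaluation) resolves criteria through it.  The built-in
catalog is immutable; alternative weightings are supplied only through
an explicit catalog file, never by mutation.
"""

from __future__ import annotations

import csv
import enum
from collections.abc import Iterable, Iterator
from dataclasses import dataclass
from pathlib import Path


class Role(str, enum.Enum):
    """Classification role of a criterion."""

    ENTRY = "entry"
    CLINICAL = "clinical"
    IMMUNOLOGIC = "immunologic"


class DataType(str, enum.Enum):
    """How evidence for the criterion is typically recorded."""

    QUANTITATIVE_TEST = "quantitative_test"
    QUALITATIVE_EXAM = "qualitative_exam"
    QUALITATIVE_IMAGING = "qualitative_imaging"
    QUALITATIVE_OR_IMAGING = "qualitative_or_imaging"
    SEPARATE_CLASSIFICATION = "separate_classification"


@dataclass(frozen=True)
class CriterionDefinition:
    """One classification criterion.

    ``weight`` is the additive point value used for scoring; it is
    ``None`` only for the entry criterion (ANA), which gates
    classification but contributes no points.
    """

    id: int
    name: str
    abbreviation: str
    role: Role
    weight: int | None
    data_type: DataType

    def __post_init__(self) -> None:
        if self.role is Role.ENTRY:
            if self.weight is not None:
                raise ValueError(f"entry criterion {self.id} must not carry a weight")
        else:
            if self.weight is None or self.weight < 0:
                raise ValueError(
                    f"criterion {self.id} ({self.abbreviation}) needs a non-negative weight"
                )


_D = DataType
_BUILTIN: tuple[tuple[int, str, str, Role, int | None, DataType], ...] = (
    (1, "Antinuclear antibodies", "ANA", Role.ENTRY, None, _D.QUANTITATIVE_TEST),
    (2, "Fever", "Fever", Role.CLINICAL, 2, _D.QUANTITATIVE_TEST),
    (3, "Leukopenia", "Leukopenia", Role.CLINICAL, 3, _D.QUANTITATIVE_TEST),
    (4, "Thrombocytopenia", "Thromb", Role.CLINICAL, 4, _D.QUANTITATIVE_TEST),
    (5, "Autoimmune hemolysis", "AIH", Role.CLINICAL, 4, _D.QUANTITATIVE_TEST),
    (6, "Delirium", "Delirium", Role.CLINICAL, 2, _D.QUALITATIVE_EXAM),
    (7, "Psychosis", "Psychosis", Role.CLINICAL, 3, _D.QUALITATIVE_EXAM),
    (8, "Seizure", "Seizure", Role.CLINICAL, 2, _D.QUALITATIVE_EXAM),
    (9, "Non-scarring alopecia", "NSA", Role.CLINICAL, 2, _D.QUALITATIVE_EXAM),
    (10, "Oral ulcers", "Oral ulcers", Role.CLINICAL, 2, _D.QUALITATIVE_EXAM),
    (11, "Subacute cutaneous/discoid lupus", "SCD", Role.CLINICAL, 4, _D.QUALITATIVE_EXAM),
    (12, "Acute cutaneous lupus", "ACL", Role.CLINICAL, 6, _D.QUANTITATIVE_TEST),
    (13, "Pleural/pericardial effusion", "PPE", Role.CLINICAL, 5, _D.QUALITATIVE_IMAGING),
    (14, "Acute pericarditis", "Pericarditis", Role.CLINICAL, 6, _D.QUALITATIVE_OR_IMAGING),
    (15, "Joint involvement", "Joint involvement", Role.CLINICAL, 6, _D.QUALITATIVE_EXAM),
    (16, "Proteinuria", "Proteinuria", Role.CLINICAL, 4, _D.QUANTITATIVE_TEST),
    (17, "Lupus nephritis class II/V", "LN25", Role.CLINICAL, 8, _D.SEPARATE_CLASSIFICATION),
    (18, "Lupus nephritis class III/IV", "LN34", Role.CLINICAL, 10, _D.SEPARATE_CLASSIFICATION),
    (19, "Anti-phospholipid antibodies", "APL", Role.IMMUNOLOGIC, 2, _D.QUANTITATIVE_TEST),
    (20, "Low C3 OR low C4", "C3/4", Role.IMMUNOLOGIC, 3, _D.QUANTITATIVE_TEST),
    (21, "Low C3 AND low C4", "C3+4", Role.IMMUNOLOGIC, 4, _D.QUANTITATIVE_TEST),
    (22, "Anti-dsDNA/anti-Smith antibodies", "ADS", Role.IMMUNOLOGIC, 6, _D.QUANTITATIVE_TEST),
)

ENTRY_CRITERION_ID = 1
#: ids of clinical criteria (at least one must be positive for SLE+)
CLINICAL_IDS = tuple(range(2, 19))
IMMUNOLOGIC_IDS = tuple(range(19, 23))

_CSV_COLUMNS = ("id", "name", "abbreviation", "role", "weight", "data_type")


class CatalogError(ValueError):
    """Raised for malformed or inconsistent catalog definitions."""


class CriteriaCatalog:
    """Immutable ordered collection of :class:`CriterionDefinition`.

    Generic structural invariants (unique ids, exactly one unweighted
    entry criterion) are enforced on construction; full 22-criterion
    coverage is enforced by :func:`load_catalog`.  Reduced catalogs can
    be constructed directly, e.g. for exhaustive enumeration tests.
    """

    def __init__(self, criteria: Iterable[CriterionDefinition]):
        ordered = tuple(sorted(criteria, key=lambda c: c.id))
        ids = [c.id for c in ordered]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CatalogError(f"duplicate criterion ids: {dupes}")
        entries = [c for c in ordered if c.role is Role.ENTRY]
        if len(entries) != 1:
            raise CatalogError(f"catalog needs exactly one entry criterion, found {len(entries)}")
        self._criteria = ordered
        self._by_id = {c.id: c for c in ordered}
        self._by_abbr = {c.abbreviation.lower(): c for c in ordered}
        self._entry = entries[0]

    def __len__(self) -> int:
        return len(self._criteria)

    def __iter__(self) -> Iterator[CriterionDefinition]:
        return iter(self._criteria)

    def __getitem__(self, index: int) -> CriterionDefinition:
        return self._criteria[index]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CriteriaCatalog):
            return NotImplemented
        return self._criteria == other._criteria

    @property
    def entry(self) -> CriterionDefinition:
        return self._entry

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(c.id for c in self._criteria)

    def by_id(self, criterion_id: int) -> CriterionDefinition:
        try:
            return self._by_id[criterion_id]
        except KeyError:
            raise CatalogError(f"unknown criterion id {criterion_id}") from None

    def by_abbreviation(self, abbr: str) -> CriterionDefinition:
        try:
            return self._by_abbr[abbr.lower()]
        except KeyError:
            valid = ", ".join(c.abbreviation for c in self._criteria)
            raise CatalogError(f"unknown abbreviation {abbr!r}; valid: {valid}") from None

    @property
    def clinical(self) -> tuple[CriterionDefinition, ...]:
        return tuple(c for c in self._criteria if c.role is Role.CLINICAL)

    @property
    def immunologic(self) -> tuple[CriterionDefinition, ...]:
        return tuple(c for c in self._criteria if c.role is Role.IMMUNOLOGIC)

    @property
    def scored(self) -> tuple[CriterionDefinition, ...]:
        """All weighted (non-entry) criteria."""
        return tuple(c for c in self._criteria if c.role is not Role.ENTRY)

    @property
    def total_weight(self) -> int:
        return sum(c.weight for c in self.scored)

    def weight(self, criterion_id: int) -> int:
        w = self.by_id(criterion_id).weight
        return 0 if w is None else w

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_COLUMNS)
            for c in self._criteria:
                writer.writerow(
                    [c.id, c.name, c.abbreviation, c.role.value,
                     "" if c.weight is None else c.weight, c.data_type.value]
                )


def _builtin_catalog() -> CriteriaCatalog:
    return CriteriaCatalog(CriterionDefinition(*row) for row in _BUILTIN)


def _parse_row(row: dict[str, str], line_no: int) -> CriterionDefinition:
    try:
        weight_cell = (row["weight"] or "").strip()
        return CriterionDefinition(
            id=int(row["id"]),
            name=row["name"].strip(),
            abbreviation=row["abbreviation"].strip(),
            role=Role(row["role"].strip()),
            weight=None if weight_cell == "" else int(weight_cell),
            data_type=DataType(row["data_type"].strip()),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise CatalogError(f"malformed catalog row at line {line_no}: {row!r} ({exc})") from exc


def load_catalog(source: str | Path | None = None) -> CriteriaCatalog:
    """Load the criteria catalog.

    Without ``source`` the built-in 2019 EULAR/ACR catalog is returned.
    A source file must be a CSV with columns
    ``id,name,abbreviation,role,weight,data_type`` (empty weight cell
    for the entry criterion) and must cover ids 1..22 exactly.
    """
    if source is None:
        return _builtin_catalog()
    path = Path(source)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(reader.fieldnames) != set(_CSV_COLUMNS):
            raise CatalogError(
                f"catalog file {path} must have columns {','.join(_CSV_COLUMNS)}"
            )
        criteria = [_parse_row(row, i) for i, row in enumerate(reader, start=2)]
    catalog = CriteriaCatalog(criteria)
    if catalog.ids != tuple(range(1, 23)):
        raise CatalogError(f"catalog must cover criterion ids 1..22, got {catalog.ids}")
    if catalog.entry.id != ENTRY_CRITERION_ID:
        raise CatalogError("criterion 1 (ANA) must be the entry criterion")
    for c in catalog:
        expected = (
            Role.ENTRY if c.id == 1 else Role.CLINICAL if c.id <= 18 else Role.IMMUNOLOGIC
        )
        if c.role is not expected:
            raise CatalogError(f"criterion {c.id} must have role {expected.value}")
    return catalog


def criterion_by_abbreviation(abbr: str, catalog: CriteriaCatalog | None = None) -> CriterionDefinition:
    """Look up a criterion by its (case-insensitive) abbreviation."""
    return (catalog or _builtin_catalog()).by_abbreviation(abbr)
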