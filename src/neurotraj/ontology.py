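"""Data model and I/O for the clinical-history and diagnosis ontologies.

Two small controlled vocabularies anchor every downstream analysis:

* the *attribute ontology* — neuropsychiatric signs and symptoms, each
  assigned to one of five broad domains (psychiatric, cognitive, motor,
  sensory/autonomic, general) and one of fourteen finer groupings, carrying
  an a-priori diagnostic-importance set (the neuropathological diagnoses for
  which the attribute is considered diagnostic) and a flag marking it as a
  neurodegeneration-associated trait (used by persistence imputation);
* the *neuropathological-diagnosis ontology* — postmortem diagnostic labels
  (AD, PD, MSA, ...) with an ICD-10 code, a broad category, and a flag for
  progressive neurodegenerative disease.

On top of these sits the *accuracy dictionary*: for each covered
neuropathological diagnosis, which clinical-diagnosis ontology classes count
as an accurate antemortem diagnosis, and which umbrella classes (e.g. a
generic "dementia") count as merely ambiguous.

Serialization is plain TSV so that fixtures stay hand-writable; set-valued
fields are semicolon-joined in the TSV and the accuracy dictionary is JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "DOMAINS",
    "DIAGNOSIS_CATEGORIES",
    "AttributeDef",
    "DiagnosisDef",
    "AccuracyDictionary",
    "SchemaError",
    "OntologyValidationError",
    "load_attribute_ontology",
    "write_attribute_ontology",
    "load_nd_ontology",
    "write_nd_ontology",
    "build_accuracy_dictionary",
]

DOMAINS = frozenset(
    {"psychiatric", "cognitive", "motor", "sensory/autonomic", "general"}
)

DIAGNOSIS_CATEGORIES = frozenset(
    {
        "progressive neurodegenerative",
        "psychiatric",
        "neuroinflammatory",
        "vascular",
        "control",
        "other",
    }
)

_ATTR_COLUMNS = [
    "id",
    "name",
    "domain",
    "grouping",
    "diagnostic_importance",
    "is_neurodegeneration_associated",
    "umls_id",
]

_ND_COLUMNS = ["nd_code", "name", "icd10", "category"]


class SchemaError(ValueError):
    """A tabular ontology file is missing required columns or is empty."""


class OntologyValidationError(ValueError):
    """Row content violates an ontology invariant (duplicate id, bad domain...)."""


@dataclass(frozen=True)
class AttributeDef:
    """One sign/symptom of the clinical-history ontology."""

    attribute_id: str
    name: str
    domain: str
    grouping: str
    diagnostic_importance: frozenset[str] = frozenset()
    is_neurodegeneration_associated: bool = False
    umls_id: str | None = None

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise OntologyValidationError(
                f"unknown domain {self.domain!r} for attribute {self.attribute_id!r}"
            )


@dataclass(frozen=True)
class DiagnosisDef:
    """One neuropathological diagnosis label."""

    nd_code: str
    name: str
    category: str
    icd10: str | None = None

    def __post_init__(self) -> None:
        if self.category not in DIAGNOSIS_CATEGORIES:
            raise OntologyValidationError(
                f"unknown diagnosis category {self.category!r} for {self.nd_code!r}"
            )

    @property
    def is_progressive_neurodegenerative(self) -> bool:
        return self.category == "progressive neurodegenerative"


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"1", "true", "yes"}:
        return True
    if text in {"0", "false", "no", ""}:
        return False
    raise OntologyValidationError(f"cannot interpret {value!r} as a boolean flag")


def _split_set(value) -> frozenset[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return frozenset()
    text = str(value).strip()
    if not text:
        return frozenset()
    return frozenset(tok.strip() for tok in text.split(";") if tok.strip())


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path} is empty") from exc
    missing = [col for col in required if col not in frame.columns]
    if missing:
        raise SchemaError(f"{path} is missing required columns: {missing}")
    return frame


def load_attribute_ontology(path: str | Path) -> list[AttributeDef]:
    """Read the attribute ontology TSV and return validated definitions.

    Raises
    ------
    SchemaError
        if the file is empty or a required column is absent.
    OntologyValidationError
        on duplicate attribute ids or unknown domains.
    """
    frame = _read_table(path, _ATTR_COLUMNS)
    attrs: list[AttributeDef] = []
    seen: set[str] = set()
    for row in frame.itertuples(index=False):
        attr_id = str(row.id).strip()
        if attr_id in seen:
            raise OntologyValidationError(f"duplicate attribute_id {attr_id!r}")
        seen.add(attr_id)
        attrs.append(
            AttributeDef(
                attribute_id=attr_id,
                name=str(row.name),
                domain=str(row.domain).strip(),
                grouping=str(row.grouping).strip(),
                diagnostic_importance=_split_set(row.diagnostic_importance),
                is_neurodegeneration_associated=_parse_bool(
                    row.is_neurodegeneration_associated
                ),
                umls_id=(str(row.umls_id).strip() or None),
            )
        )
    return attrs


def write_attribute_ontology(attrs: Iterable[AttributeDef], path: str | Path) -> None:
    rows = [
        {
            "id": a.attribute_id,
            "name": a.name,
            "domain": a.domain,
            "grouping": a.grouping,
            "diagnostic_importance": ";".join(sorted(a.diagnostic_importance)),
            "is_neurodegeneration_associated": str(
                a.is_neurodegeneration_associated
            ).lower(),
            "umls_id": a.umls_id or "",
        }
        for a in attrs
    ]
    pd.DataFrame(rows, columns=_ATTR_COLUMNS).to_csv(path, sep="\t", index=False)


def load_nd_ontology(path: str | Path) -> list[DiagnosisDef]:
    """Read the neuropathological-diagnosis ontology TSV."""
    frame = _read_table(path, _ND_COLUMNS)
    defs: list[DiagnosisDef] = []
    seen: set[str] = set()
    for row in frame.itertuples(index=False):
        code = str(row.nd_code).strip()
        if code in seen:
            raise OntologyValidationError(f"duplicate nd_code {code!r}")
        seen.add(code)
        category = str(row.category).strip()
        diagnosis = DiagnosisDef(
            nd_code=code,
            name=str(row.name),
            category=category,
            icd10=(str(row.icd10).strip() or None),
        )
        if category == "control" and diagnosis.is_progressive_neurodegenerative:
            raise OntologyValidationError("control category cannot be progressive")
        defs.append(diagnosis)
    return defs


def write_nd_ontology(defs: Iterable[DiagnosisDef], path: str | Path) -> None:
    rows = [
        {
            "nd_code": d.nd_code,
            "name": d.name,
            "icd10": d.icd10 or "",
            "category": d.category,
        }
        for d in defs
    ]
    pd.DataFrame(rows, columns=_ND_COLUMNS).to_csv(path, sep="\t", index=False)


@dataclass
class AccuracyDictionary:
    """Which clinical-diagnosis classes are accurate/ambiguous per ND code.

    ``mapping`` holds, per covered neuropathological diagnosis, the set of
    clinical-diagnosis ontology classes counted as an accurate antemortem
    diagnosis. ``ambiguous_classes`` holds umbrella classes (ancestors in the
    disease hierarchy, such as a bare "dementia") that are counted as
    ambiguous rather than accurate or inaccurate.
    """

    mapping: dict[str, frozenset[str]]
    ambiguous_classes: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for nd, accurate in self.mapping.items():
            if not accurate:
                raise OntologyValidationError(f"ND {nd!r} has an empty accurate set")
            overlap = accurate & self.ambiguous_classes.get(nd, frozenset())
            if overlap:
                raise OntologyValidationError(
                    f"ND {nd!r}: classes {sorted(overlap)} are both accurate and ambiguous"
                )

    @property
    def covered_nds(self) -> frozenset[str]:
        return frozenset(self.mapping)

    def accurate_for(self, nd_code: str) -> frozenset[str]:
        if nd_code not in self.mapping:
            raise KeyError(f"ND {nd_code!r} not covered by the accuracy dictionary")
        return self.mapping[nd_code]

    def ambiguous_for(self, nd_code: str) -> frozenset[str]:
        return self.ambiguous_classes.get(nd_code, frozenset())

    def disease_specific_classes(self) -> frozenset[str]:
        """All classes that are accurate for at least one covered ND."""
        out: set[str] = set()
        for classes in self.mapping.values():
            out |= classes
        return frozenset(out)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "accurate": {nd: sorted(v) for nd, v in self.mapping.items()},
            "ambiguous": {nd: sorted(v) for nd, v in self.ambiguous_classes.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AccuracyDictionary":
        payload = json.loads(Path(path).read_text())
        return cls(
            mapping={nd: frozenset(v) for nd, v in payload["accurate"].items()},
            ambiguous_classes={
                nd: frozenset(v) for nd, v in payload.get("ambiguous", {}).items()
            },
        )


def _ancestors(cls_name: str, parents: Mapping[str, Iterable[str]]) -> frozenset[str]:
    out: set[str] = set()
    stack = list(parents.get(cls_name, ()))
    while stack:
        cur = stack.pop()
        if cur in out:
            continue
        out.add(cur)
        stack.extend(parents.get(cur, ()))
    return frozenset(out)


def build_accuracy_dictionary(
    nd_codes: Sequence[str],
    cd_class_map: Mapping[str, Iterable[str]],
    nd_to_classes: Mapping[str, Iterable[str]],
    umbrella_classes: Iterable[str] | None = None,
) -> AccuracyDictionary:
    """Build the accuracy dictionary from a disease-class hierarchy.

    Parameters
    ----------
    nd_codes:
        Neuropathological diagnoses to cover.
    cd_class_map:
        Acyclic parent hierarchy over clinical-diagnosis classes
        (class -> iterable of direct parents).
    nd_to_classes:
        The disease class(es) of each ND. Combined handling (e.g. PD and PDD
        sharing one class set) is expressed by mapping both codes to the same
        classes.
    umbrella_classes:
        If given, only ancestors in this set become ambiguous; otherwise every
        proper ancestor of an accurate class does.

    Raises
    ------
    OntologyValidationError
        if an ND has no mapped class.
    """
    umbrella = frozenset(umbrella_classes) if umbrella_classes is not None else None
    mapping: dict[str, frozenset[str]] = {}
    ambiguous: dict[str, frozenset[str]] = {}
    for nd in nd_codes:
        accurate = frozenset(nd_to_classes.get(nd, ()))
        if not accurate:
            raise OntologyValidationError(f"ND {nd!r} has no mapped CD class")
        anc: set[str] = set()
        for cls_name in accurate:
            anc |= _ancestors(cls_name, cd_class_map)
        anc -= accurate
        if umbrella is not None:
            anc &= umbrella
        mapping[nd] = accurate
        ambiguous[nd] = frozenset(anc)
    return AccuracyDictionary(mapping=mapping, ambiguous_classes=ambiguous)
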