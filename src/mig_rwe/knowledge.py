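"""Knowledge resources: concept lexicon, code maps, association weights.

Three tab-separated tables drive extraction:

* the **lexicon** maps surface strings (preferred terms, synonyms,
  abbreviations) to concept ids; a surface naming more than one concept
  (e.g. ``MA`` -> migraine with aura / mass) is *ambiguous* and must be
  resolved from longitudinal context;
* the **code map** assigns diagnosis (ICD-9/ICD-10) and medication codes to
  concepts for the structured-data arm;
* the **association table** holds symmetric non-negative co-occurrence
  weights between concepts.  It is a plain, inspectable stand-in for a
  learned clinical-association resource: disambiguation scores a candidate
  sense by summing its weights against the concepts documented elsewhere in
  the patient's record.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "CATEGORIES",
    "TARGET_CONCEPTS",
    "SYMPTOM_CONCEPTS",
    "MEDICATION_CONCEPTS",
    "CONCEPT_PARENTS",
    "ConceptDef",
    "LexiconEntry",
    "Lexicon",
    "CodeMap",
    "AssociationTable",
    "default_concepts",
    "concept_registry",
    "load_lexicon",
    "load_code_map",
    "load_association_table",
    "default_lexicon",
    "default_code_map",
    "default_association_table",
    "lookup_code",
    "association_score",
]

CATEGORIES = ("diagnosis", "symptom", "medication")

#: The ten evaluation-target concepts, in reporting order.
TARGET_CONCEPTS: tuple[str, ...] = (
    "migraine",
    "headache",
    "nausea",
    "vomiting",
    "light_sensitivity",
    "loss_of_appetite",
    "dizziness",
    "fatigue",
    "rizatriptan",
    "sumatriptan",
)

SYMPTOM_CONCEPTS: tuple[str, ...] = (
    "nausea",
    "vomiting",
    "light_sensitivity",
    "loss_of_appetite",
    "dizziness",
    "fatigue",
)

MEDICATION_CONCEPTS: tuple[str, ...] = ("rizatriptan", "sumatriptan")

#: Evaluation roll-up: a child concept counts as its parent when reducing to
#: per-encounter presence (migraine with aura is a migraine).  Configurable at
#: the evaluation surface.
CONCEPT_PARENTS: dict[str, str] = {"migraine_with_aura": "migraine"}


@dataclass(frozen=True)
class ConceptDef:
    concept_id: str
    label: str
    category: str

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for {self.concept_id!r}")


_TARGET_DEFS = (
    ConceptDef("migraine", "Migraine", "diagnosis"),
    ConceptDef("headache", "Headache", "symptom"),
    ConceptDef("nausea", "Nausea", "symptom"),
    ConceptDef("vomiting", "Vomiting", "symptom"),
    ConceptDef("light_sensitivity", "Light sensitivity", "symptom"),
    ConceptDef("loss_of_appetite", "Loss of appetite", "symptom"),
    ConceptDef("dizziness", "Dizziness", "symptom"),
    ConceptDef("fatigue", "Fatigue", "symptom"),
    ConceptDef("rizatriptan", "Rizatriptan", "medication"),
    ConceptDef("sumatriptan", "Sumatriptan", "medication"),
)

# Auxiliary concepts: recognizable by the lexicon (senses of ambiguous
# abbreviations, distractor context) but never evaluation targets.
_AUX_DEFS = (
    ConceptDef("migraine_with_aura", "Migraine with aura", "diagnosis"),
    ConceptDef("mass", "Mass", "diagnosis"),
    ConceptDef("lung_cancer", "Lung cancer", "diagnosis"),
    ConceptDef("tumor", "Tumor", "diagnosis"),
)


def default_concepts() -> tuple[ConceptDef, ...]:
    """The shipped evaluation-target concept set (exactly the ten targets)."""
    return _TARGET_DEFS


def concept_registry() -> dict[str, ConceptDef]:
    """All known concepts: the ten targets plus auxiliary/distractor concepts."""
    return {c.concept_id: c for c in _TARGET_DEFS + _AUX_DEFS}


@dataclass(frozen=True)
class LexiconEntry:
    surface: str  # stored lowercase
    concept_ids: tuple[str, ...]
    term_type: str  # preferred | synonym | abbreviation

    def __post_init__(self):
        object.__setattr__(self, "surface", self.surface.lower())
        if self.term_type not in ("preferred", "synonym", "abbreviation"):
            raise ValueError(f"unknown term_type {self.term_type!r}")
        if not self.concept_ids:
            raise ValueError(f"lexicon surface {self.surface!r} has no concepts")

    @property
    def ambiguous(self) -> bool:
        return len(self.concept_ids) > 1


class Lexicon:
    """Surface -> entry lookup table, case-insensitive."""

    def __init__(self, entries: Iterable[LexiconEntry] = ()):
        self._by_surface: dict[str, LexiconEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: LexiconEntry) -> None:
        prev = self._by_surface.get(entry.surface)
        if prev is not None:
            merged = tuple(dict.fromkeys(prev.concept_ids + entry.concept_ids))
            entry = LexiconEntry(entry.surface, merged, prev.term_type)
        self._by_surface[entry.surface] = entry

    def lookup(self, surface: str) -> LexiconEntry | None:
        return self._by_surface.get(surface.lower())

    def entries(self) -> list[LexiconEntry]:
        return list(self._by_surface.values())

    def surfaces_for(self, concept_id: str, term_type: str | None = None,
                     ambiguous: bool | None = None) -> list[str]:
        out = []
        for e in self._by_surface.values():
            if concept_id not in e.concept_ids:
                continue
            if term_type is not None and e.term_type != term_type:
                continue
            if ambiguous is not None and e.ambiguous != ambiguous:
                continue
            out.append(e.surface)
        return out

    def __len__(self) -> int:
        return len(self._by_surface)

    def __iter__(self):
        return iter(self._by_surface.values())


class CodeMap:
    """(code_system, code) -> concept_id.  Codes are trimmed and uppercased."""

    def __init__(self, rows: Iterable[tuple[str, str, str]] = ()):
        self._map: dict[tuple[str, str], str] = {}
        self._by_concept: dict[str, list[tuple[str, str]]] = {}
        for concept_id, code_system, code in rows:
            self.add(concept_id, code_system, code)

    @staticmethod
    def _key(code_system: str, code: str) -> tuple[str, str]:
        return (code_system.strip().upper(), code.strip().upper())

    def add(self, concept_id: str, code_system: str, code: str) -> None:
        key = self._key(code_system, code)
        prev = self._map.get(key)
        if prev is not None and prev != concept_id:
            raise ValueError(f"code {key} maps to both {prev!r} and {concept_id!r}")
        self._map[key] = concept_id
        self._by_concept.setdefault(concept_id, []).append(key)

    def lookup(self, code_system: str, code: str) -> str | None:
        return self._map.get(self._key(code_system, code))

    def codes_for(self, concept_id: str) -> list[tuple[str, str]]:
        return list(self._by_concept.get(concept_id, ()))

    def concepts(self) -> set[str]:
        return set(self._by_concept)

    def __len__(self) -> int:
        return len(self._map)


class AssociationTable:
    """Symmetric non-negative concept-pair weights; missing pairs weigh 0."""

    def __init__(self, weights: Mapping[tuple[str, str], float] | None = None):
        self._w: dict[frozenset, float] = {}
        if weights:
            for (a, b), w in weights.items():
                self.set(a, b, w)

    def set(self, a: str, b: str, weight: float) -> None:
        if weight < 0:
            raise ValueError(f"association weight must be non-negative, got {weight}")
        self._w[frozenset((a, b))] = float(weight)

    def weight(self, a: str, b: str) -> float:
        return self._w.get(frozenset((a, b)), 0.0)

    def __len__(self) -> int:
        return len(self._w)


def association_score(candidate: str, context: Iterable[str], table: AssociationTable) -> float:
    """Sum of association weights between ``candidate`` and each context concept.

    Additive over disjoint context sets; an empty context scores 0.
    """
    return sum(table.weight(candidate, c) for c in set(context))


def lookup_code(code_system: str, code: str, code_map: CodeMap) -> str | None:
    """Exact (trimmed, uppercased) code lookup; None when unmapped."""
    return code_map.lookup(code_system, code)


# ---------------------------------------------------------------------------
# TSV loaders


def _read_tsv(path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = [(i, row) for i, row in enumerate(reader, start=1) if row and any(f.strip() for f in row)]
    if not rows:
        raise ValueError(f"{path}: empty table (missing header)")
    header = [h.strip() for h in rows[0][1]]
    return header, rows[1:]


def load_lexicon(path, known_concepts: Iterable[str] | None = None) -> Lexicon:
    """Load a lexicon TSV (columns: surface, concept_ids '|'-separated, term_type).

    Unknown concept ids are fatal with the offending row number; duplicate
    (surface, concept_id) rows are collapsed with a warning; a header-only
    file yields an empty lexicon with a warning.
    """
    known = set(known_concepts) if known_concepts is not None else set(concept_registry())
    header, rows = _read_tsv(path)
    if header[:3] != ["surface", "concept_ids", "term_type"]:
        raise ValueError(f"{path}: unexpected lexicon header {header}")
    lex = Lexicon()
    seen: set[tuple[str, str]] = set()
    for lineno, row in rows:
        if len(row) < 3:
            raise ValueError(f"{path}: row {lineno}: expected 3 columns")
        surface = row[0].strip().lower()
        concept_ids = tuple(c.strip() for c in row[1].split("|") if c.strip())
        term_type = row[2].strip()
        for cid in concept_ids:
            if known and cid not in known:
                raise ValueError(f"{path}: row {lineno}: unknown concept_id {cid!r}")
        dup = [c for c in concept_ids if (surface, c) in seen]
        if dup:
            warnings.warn(f"{path}: row {lineno}: duplicate lexicon row(s) for "
                          f"surface {surface!r} collapsed", stacklevel=2)
        seen.update((surface, c) for c in concept_ids)
        lex.add(LexiconEntry(surface, concept_ids, term_type))
    if len(lex) == 0:
        warnings.warn(f"{path}: lexicon file has a header but no entries", stacklevel=2)
    return lex


def load_code_map(path, known_concepts: Iterable[str] | None = None) -> CodeMap:
    """Load a code map TSV (columns: concept_id, code_system, code)."""
    known = set(known_concepts) if known_concepts is not None else set(concept_registry())
    header, rows = _read_tsv(path)
    if header[:3] != ["concept_id", "code_system", "code"]:
        raise ValueError(f"{path}: unexpected code map header {header}")
    cmap = CodeMap()
    for lineno, row in rows:
        if len(row) < 3:
            raise ValueError(f"{path}: row {lineno}: expected 3 columns")
        concept_id = row[0].strip()
        if known and concept_id not in known:
            raise ValueError(f"{path}: row {lineno}: unknown concept_id {concept_id!r}")
        cmap.add(concept_id, row[1], row[2])
    return cmap


def load_association_table(path) -> AssociationTable:
    """Load an association TSV (columns: concept_a, concept_b, weight)."""
    header, rows = _read_tsv(path)
    if header[:3] != ["concept_a", "concept_b", "weight"]:
        raise ValueError(f"{path}: unexpected association header {header}")
    table = AssociationTable()
    for lineno, row in rows:
        if len(row) < 3:
            raise ValueError(f"{path}: row {lineno}: expected 3 columns")
        try:
            w = float(row[2])
        except ValueError:
            raise ValueError(f"{path}: row {lineno}: weight {row[2]!r} is not a number") from None
        table.set(row[0].strip(), row[1].strip(), w)
    return table


def _data_path(name: str) -> Path:
    return Path(resources.files("mig_rwe").joinpath("data", name))  # type: ignore[arg-type]


def default_lexicon() -> Lexicon:
    return load_lexicon(_data_path("lexicon.tsv"))


def default_code_map() -> CodeMap:
    return load_code_map(_data_path("code_map.tsv"))


def default_association_table() -> AssociationTable:
    return load_association_table(_data_path("associations.tsv"))
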