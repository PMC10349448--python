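"""Core EHR corpus data model.

An *encounter* is a single visit by one patient with one physician on a
specific date.  It carries three structured fields (problem list, medication
list, encounter-associated open claims), each a list of coded entries, plus
one free-text note.  A *corpus* is an ordered collection of encounters,
serialized as JSON Lines (one encounter object per line, UTF-8, dates as
ISO 8601).

This module owns reading/writing/validating corpora and the term-based
encounter preselection filter that both study arms consume.
"""

from __future__ import annotations

import datetime as dt
import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "KNOWN_CODE_SYSTEMS",
    "CodedEntry",
    "Encounter",
    "Corpus",
    "FilterSpec",
    "CorpusError",
    "read_corpus",
    "write_corpus",
    "validate_corpus",
    "filter_encounters",
]

#: Code systems the model understands.  DRUG holds normalized drug-name
#: strings; a deployment may substitute a national drug vocabulary.
KNOWN_CODE_SYSTEMS = frozenset({"ICD9", "ICD10", "DRUG"})

STRUCTURED_FIELDS = ("problem_list", "medication_list", "claims")


class CorpusError(ValueError):
    """Fatal corpus-level problem (missing file, malformed lines, duplicate ids)."""


@dataclass(frozen=True)
class CodedEntry:
    """One coded entry in a structured field: a code system plus a code string."""

    code_system: str
    code: str

    def to_obj(self) -> list[str]:
        return [self.code_system, self.code]

    @classmethod
    def from_obj(cls, obj: Sequence[str]) -> "CodedEntry":
        if not isinstance(obj, (list, tuple)) or len(obj) != 2:
            raise ValueError(f"coded entry must be a [code_system, code] pair, got {obj!r}")
        return cls(str(obj[0]), str(obj[1]))


@dataclass
class Encounter:
    patient_id: str
    encounter_id: str
    physician_id: str
    date: dt.date
    problem_list: list[CodedEntry] = field(default_factory=list)
    medication_list: list[CodedEntry] = field(default_factory=list)
    claims: list[CodedEntry] = field(default_factory=list)
    note_text: str = ""

    def coded_entries(self) -> Iterator[tuple[str, CodedEntry]]:
        """Yield (source_field, entry) for all structured entries in field order."""
        for fname in STRUCTURED_FIELDS:
            for entry in getattr(self, fname):
                yield fname, entry

    def to_obj(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "encounter_id": self.encounter_id,
            "physician_id": self.physician_id,
            "date": self.date.isoformat(),
            "problem_list": [e.to_obj() for e in self.problem_list],
            "medication_list": [e.to_obj() for e in self.medication_list],
            "claims": [e.to_obj() for e in self.claims],
            "note_text": self.note_text,
        }

    @classmethod
    def from_obj(cls, obj: dict) -> "Encounter":
        missing = [k for k in ("patient_id", "encounter_id", "physician_id", "date") if k not in obj]
        if missing:
            raise ValueError(f"missing field(s): {', '.join(missing)}")
        try:
            date = dt.date.fromisoformat(obj["date"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"field 'date': {exc}") from None
        def entries(key: str) -> list[CodedEntry]:
            raw = obj.get(key, [])
            if not isinstance(raw, list):
                raise ValueError(f"field {key!r}: expected a list")
            return [CodedEntry.from_obj(e) for e in raw]
        return cls(
            patient_id=str(obj["patient_id"]),
            encounter_id=str(obj["encounter_id"]),
            physician_id=str(obj["physician_id"]),
            date=date,
            problem_list=entries("problem_list"),
            medication_list=entries("medication_list"),
            claims=entries("claims"),
            note_text=str(obj.get("note_text", "")),
        )


@dataclass
class Corpus:
    """Ordered encounter collection; iteration order equals file order."""

    encounters: list[Encounter] = field(default_factory=list)
    source_tag: str = ""

    def __iter__(self) -> Iterator[Encounter]:
        return iter(self.encounters)

    def __len__(self) -> int:
        return len(self.encounters)

    def encounter_ids(self) -> list[str]:
        return [e.encounter_id for e in self.encounters]

    def by_patient(self) -> dict[str, list[Encounter]]:
        """Group encounters per patient, preserving corpus order (the longitudinal record)."""
        out: dict[str, list[Encounter]] = {}
        for enc in self.encounters:
            out.setdefault(enc.patient_id, []).append(enc)
        return out


@dataclass(frozen=True)
class FilterSpec:
    """Term-based preselection filter.

    ``terms`` are matched case-insensitively; on ``note_text`` as plain
    substrings, on ``structured_codes`` via the concept(s) each term names in
    the lexicon and the codes the code map assigns to those concepts.
    """

    terms: tuple[str, ...]
    match_fields: frozenset = frozenset({"note_text"})

    def __post_init__(self):
        terms = tuple(t.lower() for t in self.terms)
        if not terms:
            raise ValueError("FilterSpec.terms must be non-empty")
        object.__setattr__(self, "terms", terms)
        fields_ = frozenset(self.match_fields)
        unknown = fields_ - {"note_text", "structured_codes"}
        if unknown or not fields_:
            raise ValueError(f"invalid match_fields: {sorted(fields_)}")
        object.__setattr__(self, "match_fields", fields_)


def read_corpus(path: str | os.PathLike, source_tag: str | None = None) -> Corpus:
    """Read a JSON Lines corpus file, preserving line order.

    Raises :class:`CorpusError` if the file is missing, if any line is
    malformed (all offending lines are listed with their line numbers), or if
    an encounter_id occurs on more than one line.
    """
    path = Path(path)
    if not path.exists():
        raise CorpusError(f"corpus file not found: {path}")
    encounters: list[Encounter] = []
    problems: list[str] = []
    seen: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                enc = Encounter.from_obj(json.loads(line))
            except (json.JSONDecodeError, ValueError) as exc:
                problems.append(f"line {lineno}: {exc}")
                continue
            if enc.encounter_id in seen:
                raise CorpusError(
                    f"duplicate encounter_id {enc.encounter_id!r} on lines "
                    f"{seen[enc.encounter_id]} and {lineno}"
                )
            seen[enc.encounter_id] = lineno
            encounters.append(enc)
    if problems:
        raise CorpusError("malformed corpus lines:\n" + "\n".join(problems))
    return Corpus(encounters, source_tag=source_tag if source_tag is not None else str(path))


def write_corpus(corpus: Corpus, path: str | os.PathLike) -> None:
    """Write a corpus as JSON Lines (UTF-8, non-ASCII preserved verbatim)."""
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    with open(tmp, "w", encoding="utf-8") as fh:
        for enc in corpus:
            fh.write(json.dumps(enc.to_obj(), ensure_ascii=False) + "\n")
    os.replace(tmp, path)


def validate_corpus(corpus: Corpus) -> list[str]:
    """Return a list of validation warnings (empty when the corpus is clean).

    Flags duplicate (patient, physician, date) visit triples and coded entries
    naming unknown code systems.  Duplicate encounter_ids are fatal at read
    time and re-checked here.
    """
    warnings: list[str] = []
    ids: dict[str, str] = {}
    triples: dict[tuple, str] = {}
    for enc in corpus:
        if enc.encounter_id in ids:
            warnings.append(f"duplicate encounter_id {enc.encounter_id!r}")
        ids[enc.encounter_id] = enc.encounter_id
        triple = (enc.patient_id, enc.physician_id, enc.date)
        if triple in triples:
            warnings.append(
                f"encounters {triples[triple]!r} and {enc.encounter_id!r} share the "
                f"visit triple (patient={enc.patient_id}, physician={enc.physician_id}, "
                f"date={enc.date.isoformat()})"
            )
        else:
            triples[triple] = enc.encounter_id
        for fname, entry in enc.coded_entries():
            if entry.code_system not in KNOWN_CODE_SYSTEMS:
                warnings.append(
                    f"encounter {enc.encounter_id!r}: unknown code system "
                    f"{entry.code_system!r} in {fname}"
                )
    return warnings


def filter_encounters(corpus: Corpus, spec: FilterSpec, code_map=None, lexicon=None) -> Corpus:
    """Return the sub-corpus of encounters matching at least one filter term.

    Applied once and shared by both study arms so that preselection cannot
    bias the arm comparison.  Matching on ``note_text`` is a case-insensitive
    substring test on the raw note.  Matching on ``structured_codes`` retains
    an encounter whose coded entries map (via ``code_map``) to a concept that
    a filter term names; terms are resolved to concepts through ``lexicon``
    when given, else each term is taken to be a concept_id itself.

    Filtering never mutates encounters; it only subsets, so it is idempotent.
    """
    want_note = "note_text" in spec.match_fields
    want_struct = "structured_codes" in spec.match_fields
    term_concepts: set[str] = set()
    if want_struct:
        if code_map is None:
            raise ValueError("structured_codes matching requires a code map")
        for term in spec.terms:
            if lexicon is not None:
                entry = lexicon.lookup(term)
                if entry is not None:
                    term_concepts.update(entry.concept_ids)
                    continue
            term_concepts.add(term)

    kept: list[Encounter] = []
    for enc in corpus:
        hit = False
        if want_note and enc.note_text:
            low = enc.note_text.lower()
            hit = any(t in low for t in spec.terms)
        if not hit and want_struct:
            for _fname, entry in enc.coded_entries():
                concept = code_map.lookup(entry.code_system, entry.code)
                if concept is not None and concept in term_concepts:
                    hit = True
                    break
        if hit:
            kept.append(enc)
    return Corpus(kept, source_tag=corpus.source_tag)
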