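"""The structured-data ("Traditional RWE") extraction arm.

Concepts are identified solely from coded structured fields — problem list,
medication list, and encounter-associated open claims — by code-map lookup,
emulating plain SQL queries over an EHR/claims store.  The free-text note is
never consulted; the arm's well-documented weakness on symptoms reflects how
rarely clinicians *code* symptoms, not an inability to code them, and is
modelled by the synthetic generator's structured documentation probabilities
rather than by this extractor.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .corpus_model import Corpus, Encounter
from .knowledge import CodeMap

__all__ = ["StructuredHit", "extract_traditional", "extract_traditional_corpus",
           "write_hits", "read_hits"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StructuredHit:
    """One coded entry resolved to a concept; one hit per matching entry.

    Duplicate coded entries yield duplicate hits on purpose: concept-level
    occurrence counting needs the multiplicity, and encounter-level
    de-duplication belongs to evaluation.
    """

    encounter_id: str
    concept_id: str
    source_field: str  # problem_list | medication_list | claims
    code_system: str
    code: str

    # hits are always asserted, present-tense facts; these properties let the
    # evaluation layer treat hits and NLP mentions uniformly.
    @property
    def asserted(self) -> bool:
        return True

    def to_obj(self) -> dict:
        return {
            "encounter_id": self.encounter_id,
            "concept_id": self.concept_id,
            "source_field": self.source_field,
            "code_system": self.code_system,
            "code": self.code,
        }

    @classmethod
    def from_obj(cls, obj: dict) -> "StructuredHit":
        return cls(obj["encounter_id"], obj["concept_id"], obj["source_field"],
                   obj["code_system"], obj["code"])


def extract_traditional(encounter: Encounter, code_map: CodeMap) -> list[StructuredHit]:
    """Map every coded structured entry to a concept; deterministic.

    Entries whose code system or code is absent from the map are skipped
    (unknown systems with a logged warning); the note text is ignored.
    """
    hits: list[StructuredHit] = []
    for fname, entry in encounter.coded_entries():
        concept = code_map.lookup(entry.code_system, entry.code)
        if concept is None:
            if entry.code_system.strip().upper() not in {"ICD9", "ICD10", "DRUG"}:
                log.warning("encounter %s: skipping entry with unknown code system %r",
                            encounter.encounter_id, entry.code_system)
            continue
        hits.append(StructuredHit(encounter.encounter_id, concept, fname,
                                  entry.code_system, entry.code))
    return hits


def extract_traditional_corpus(corpus: Corpus, code_map: CodeMap) -> list[StructuredHit]:
    hits: list[StructuredHit] = []
    for enc in corpus:
        hits.extend(extract_traditional(enc, code_map))
    return hits


def write_hits(hits: Iterable[StructuredHit], path) -> None:
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    with open(tmp, "w", encoding="utf-8") as fh:
        for h in hits:
            fh.write(json.dumps(h.to_obj(), ensure_ascii=False) + "\n")
    os.replace(tmp, path)


def read_hits(path) -> list[StructuredHit]:
    with open(path, encoding="utf-8") as fh:
        return [StructuredHit.from_obj(json.loads(line)) for line in fh if line.strip()]
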