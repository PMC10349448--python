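"""The NLP ("Advanced RWE") extraction arm.

Concepts are identified from the free-text clinical note only, in five
deterministic, rule-based stages:

1. **Sentence segmentation** — split on sentence-final punctuation and
   newlines; clinical notes are strongly newline-structured, so no
   statistical segmenter is needed.
2. **Dictionary matching** — case-insensitive, whole-token, longest-match-
   first scan against the lexicon within each sentence; ambiguous surfaces
   (e.g. ``MA``) emit every candidate sense for later resolution.
3. **Attribute detection** — trigger-scope rules inside the sentence
   boundary: a negation trigger (``no``, ``denies``, ``without`` ...)
   preceding the match with no scope-terminating conjunction (``but``,
   ``however``, ``although``, ``;``) in between marks the mention not
   asserted; historical triggers (``history of``, ``prior`` ...) set
   temporality; adjacent severity cues (``mild``/``mod``/``moderate``/
   ``severe``) set severity.
4. **Sign-template parsing with encounter-level support** — review-of-systems
   lines like ``-headache, +nausea`` assert ``+`` concepts and *provisionally*
   negate ``-`` concepts; a provisional negative is emitted only when the
   concept has no asserted free-text mention elsewhere in the encounter
   (free text wins).
5. **Longitudinal abbreviation disambiguation** — an ambiguous surface is
   resolved by scoring each candidate sense against the union of asserted
   concepts across *all* of the patient's encounters using the association
   table; the top sense wins only if it beats the runner-up by the margin
   (default: any strictly positive difference), otherwise the mention is
   dropped as unresolvable.

Structured fields are never consulted: the arm's output is invariant to
problem-list/medication-list/claims content.
"""

from __future__ import annotations

import json
import logging
import os
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .corpus_model import Corpus, Encounter
from .knowledge import (AssociationTable, Lexicon, association_score,
                        default_association_table, default_lexicon)

__all__ = [
    "Sentence",
    "RawMatch",
    "TemplateAssertion",
    "ConceptMention",
    "segment_sentences",
    "match_concepts",
    "detect_attributes",
    "parse_templates",
    "resolve_template_support",
    "disambiguate",
    "extract_advanced",
    "write_mentions",
    "read_mentions",
]

log = logging.getLogger(__name__)

TEMPORALITIES = ("current", "historical", "unspecified")
SEVERITIES = ("mild", "moderate", "severe", "unspecified")
PROVENANCES = ("free_text", "template", "disambiguated")

NEGATION_TRIGGERS = frozenset({"no", "denies", "denied", "deny", "without", "not", "negative", "neg"})
SCOPE_TERMINATORS = frozenset({"but", "however", "although", ";"})
HISTORICAL_TRIGGERS = frozenset({"history", "hx", "prior", "past", "previous", "h/o"})
SEVERITY_CUES = {"mild": "mild", "mod": "moderate", "moderate": "moderate", "severe": "severe"}

_WORD_RE = re.compile(r"[A-Za-z][A-Za-z'/]*|\d+(?:\.\d+)?")
_FULL_RE = re.compile(r"[A-Za-z][A-Za-z'/]*|\d+(?:\.\d+)?|[;]")


@dataclass(frozen=True)
class Sentence:
    """A segment of the note; offsets are 0-based half-open into note_text."""

    encounter_id: str
    start: int
    end: int
    text: str


@dataclass(frozen=True)
class RawMatch:
    """A dictionary match before attribute detection / disambiguation."""

    surface: str
    start: int  # note-absolute offsets
    end: int
    concept_ids: tuple[str, ...]

    @property
    def ambiguous(self) -> bool:
        return len(self.concept_ids) > 1


@dataclass(frozen=True)
class TemplateAssertion:
    """One sign-prefixed token from a review-of-systems template line."""

    surface: str
    sign: str  # '+' or '-'
    start: int
    end: int


@dataclass(frozen=True)
class ConceptMention:
    encounter_id: str
    concept_id: str
    start: int
    end: int
    surface: str
    asserted: bool
    temporality: str = "current"
    severity: str = "unspecified"
    provenance: str = "free_text"

    def __post_init__(self):
        if self.temporality not in TEMPORALITIES:
            raise ValueError(f"bad temporality {self.temporality!r}")
        if self.severity not in SEVERITIES:
            raise ValueError(f"bad severity {self.severity!r}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"bad provenance {self.provenance!r}")

    def to_obj(self) -> dict:
        return {
            "encounter_id": self.encounter_id,
            "concept_id": self.concept_id,
            "start": self.start,
            "end": self.end,
            "surface": self.surface,
            "asserted": self.asserted,
            "temporality": self.temporality,
            "severity": self.severity,
            "provenance": self.provenance,
        }

    @classmethod
    def from_obj(cls, obj: dict) -> "ConceptMention":
        return cls(**{k: obj[k] for k in ("encounter_id", "concept_id", "start", "end",
                                          "surface", "asserted", "temporality",
                                          "severity", "provenance")})


# ---------------------------------------------------------------------------
# 1. Sentence segmentation

def segment_sentences(note_text: str, encounter_id: str = "") -> list[Sentence]:
    """Deterministic split on sentence-final punctuation and newlines.

    Returned sentences carry their exact character spans; inter-sentence
    whitespace belongs to no sentence.
    """
    segments: list[tuple[int, int]] = []
    cur = 0
    for i, ch in enumerate(note_text):
        if ch in ".!?":
            segments.append((cur, i + 1))
            cur = i + 1
        elif ch == "\n":
            segments.append((cur, i))
            cur = i + 1
    segments.append((cur, len(note_text)))

    sentences: list[Sentence] = []
    for s, e in segments:
        text = note_text[s:e]
        lead = len(text) - len(text.lstrip())
        trail = len(text) - len(text.rstrip())
        s2, e2 = s + lead, e - trail
        if s2 < e2:
            sentences.append(Sentence(encounter_id, s2, e2, note_text[s2:e2]))
    return sentences


# ---------------------------------------------------------------------------
# 2. Dictionary matching

_INDEX_CACHE: dict[int, tuple[int, dict]] = {}


def _lexicon_index(lexicon: Lexicon) -> dict:
    """first-token -> [(token_tuple, entry)], longest token tuples first."""
    key = id(lexicon)
    cached = _INDEX_CACHE.get(key)
    if cached is not None and cached[0] == len(lexicon):
        return cached[1]
    index: dict[str, list] = {}
    for entry in lexicon:
        toks = tuple(t.lower() for t in _WORD_RE.findall(entry.surface))
        if not toks:
            continue
        index.setdefault(toks[0], []).append((toks, entry))
    for lst in index.values():
        lst.sort(key=lambda te: len(te[0]), reverse=True)
    _INDEX_CACHE[key] = (len(lexicon), index)
    return index


def match_concepts(sentence: Sentence, lexicon: Lexicon) -> list[RawMatch]:
    """Whole-token, case-insensitive, longest-match-first dictionary scan.

    Overlapping shorter matches are suppressed by the greedy scan; an
    ambiguous surface yields one match carrying all candidate concepts.
    """
    index = _lexicon_index(lexicon)
    toks = [(m.group(0), m.start(), m.end()) for m in _WORD_RE.finditer(sentence.text)]
    matches: list[RawMatch] = []
    i = 0
    while i < len(toks):
        word = toks[i][0].lower()
        found = None
        for tup, entry in index.get(word, ()):
            k = len(tup)
            if i + k <= len(toks) and tuple(t[0].lower() for t in toks[i:i + k]) == tup:
                found = (k, entry)
                break
        if found is None:
            i += 1
            continue
        k, entry = found
        start = sentence.start + toks[i][1]
        end = sentence.start + toks[i + k - 1][2]
        matches.append(RawMatch(sentence.text[toks[i][1]:toks[i + k - 1][2]],
                                start, end, entry.concept_ids))
        i += k
    return matches


# ---------------------------------------------------------------------------
# 3. Attribute detection (within the sentence boundary)

def detect_attributes(sentence: Sentence, match: RawMatch) -> tuple[bool, str, str]:
    """Apply trigger-scope rules; returns (asserted, temporality, severity).

    Only tokens between the last scope terminator and the match are eligible
    trigger positions, so ``no prior migraine, but migraine today`` negates
    the first mention only.
    """
    rel_start = match.start - sentence.start
    if not (0 <= rel_start <= len(sentence.text)):
        raise ValueError("match does not lie inside the sentence")
    toks = [(m.group(0).lower(), m.start(), m.end()) for m in _FULL_RE.finditer(sentence.text)]
    preceding = [t for t in toks if t[2] <= rel_start]
    # restrict to the window after the last scope terminator
    window = preceding
    for idx in range(len(preceding) - 1, -1, -1):
        if preceding[idx][0] in SCOPE_TERMINATORS:
            window = preceding[idx + 1:]
            break
    words = [w for w, _s, _e in window]
    asserted = not any(w in NEGATION_TRIGGERS for w in words)
    temporality = "historical" if any(w in HISTORICAL_TRIGGERS for w in words) else "current"
    severity = "unspecified"
    for w in reversed(words[-2:]):  # adjacency: at most two tokens back
        if w in SEVERITY_CUES:
            severity = SEVERITY_CUES[w]
            break
    return asserted, temporality, severity


# ---------------------------------------------------------------------------
# 4. Sign-prefixed templates with encounter-level support

_CHUNK_RE = re.compile(r"([+-])\s*([A-Za-z](?:[A-Za-z ]*[A-Za-z])?)")


def _template_lines(note_text: str) -> list[tuple[int, int, list[TemplateAssertion]]]:
    """Find review-of-systems template lines; returns (line_start, line_end, assertions)."""
    out = []
    offset = 0
    for line in note_text.split("\n"):
        stripped = line.strip()
        if stripped and stripped[0] in "+-":
            chunks = list(_CHUNK_RE.finditer(line))
            if chunks:
                residue = _CHUNK_RE.sub("", line)
                if not residue.strip(" \t,;"):
                    assertions = []
                    for m in chunks:
                        surface = m.group(2).rstrip()
                        start = offset + m.start(2)
                        assertions.append(TemplateAssertion(surface, m.group(1),
                                                            start, start + len(surface)))
                    out.append((offset, offset + len(line), assertions))
        offset += len(line) + 1
    return out


def parse_templates(note_text: str) -> list[TemplateAssertion]:
    """Parse sign-prefixed template lines (``-headache, +nausea``); prose lines
    yield nothing."""
    assertions: list[TemplateAssertion] = []
    for _s, _e, line_assertions in _template_lines(note_text):
        assertions.extend(line_assertions)
    return assertions


def resolve_template_support(
    assertions: Iterable[TemplateAssertion],
    free_text_mentions: Sequence[ConceptMention],
    lexicon: Lexicon,
    note_text: str,
    encounter_id: str,
) -> list[ConceptMention]:
    """Turn template assertions into mentions, honouring encounter support.

    A ``+`` token asserts its concept.  A ``-`` token is only a *provisional*
    negative: it is emitted as a not-asserted mention unless the same concept
    has an asserted free-text mention elsewhere in the encounter, in which
    case the free-text assertion stands and no negative is produced.
    Surfaces absent from the lexicon, or ambiguous ones, are skipped.
    """
    supported = {m.concept_id for m in free_text_mentions if m.asserted}
    mentions: list[ConceptMention] = []
    for a in assertions:
        entry = lexicon.lookup(a.surface)
        if entry is None or entry.ambiguous:
            continue
        concept = entry.concept_ids[0]
        if a.sign == "-" and concept in supported:
            continue
        mentions.append(ConceptMention(
            encounter_id, concept, a.start, a.end, note_text[a.start:a.end],
            asserted=(a.sign == "+"), temporality="current",
            severity="unspecified", provenance="template"))
    return mentions


# ---------------------------------------------------------------------------
# 5. Longitudinal abbreviation disambiguation

def disambiguate(
    match: RawMatch,
    patient_context: Iterable[str],
    table: AssociationTable,
    margin: float = 0.0,
) -> str | None:
    """Resolve an ambiguous surface from the patient's longitudinal record.

    Each candidate sense is scored additively against the context concepts;
    the top sense is returned only when it beats the runner-up strictly and
    by at least ``margin``.  Ties and zero-evidence contexts abstain (None):
    dropping an unresolvable mention is preferred to silently asserting a
    wrong sense.
    """
    context = set(patient_context) - set(match.concept_ids)
    scored = sorted(
        ((association_score(c, context, table), c) for c in match.concept_ids),
        key=lambda sc: (-sc[0], sc[1]))
    if len(scored) == 1:
        return scored[0][1]
    top_score, top = scored[0]
    second_score = scored[1][0]
    if top_score - second_score > 0 and top_score - second_score >= margin:
        return top
    return None


# ---------------------------------------------------------------------------
# Orchestration

def extract_advanced(
    corpus: Corpus,
    lexicon: Lexicon | None = None,
    table: AssociationTable | None = None,
    margin: float = 0.0,
    strict: bool = True,
    failures: list | None = None,
) -> list[ConceptMention]:
    """Run the full NLP pipeline over a corpus; deterministic.

    Per patient: template lines are parsed first and their spans excluded
    from sentence-level matching; unambiguous matches get attributes;
    template negatives are resolved against free-text support; finally
    ambiguous matches are resolved against the union of the patient's
    asserted concepts across all encounters (the longitudinal record,
    excluding concepts that themselves came from ambiguous surfaces).

    With ``strict=False`` per-encounter errors are logged and skipped; pass a
    ``failures`` list to collect the offending encounter ids.
    """
    lexicon = lexicon if lexicon is not None else default_lexicon()
    table = table if table is not None else default_association_table()

    all_mentions: list[ConceptMention] = []
    for patient_id, encounters in corpus.by_patient().items():
        per_enc: list[list[ConceptMention]] = []
        pending: list[tuple[int, Sentence, RawMatch]] = []
        for idx, enc in enumerate(encounters):
            mentions: list[ConceptMention] = []
            try:
                note = enc.note_text
                tmpl = _template_lines(note)
                tmpl_spans = [(s, e) for s, e, _a in tmpl]
                assertions = [a for _s, _e, line in tmpl for a in line]
                sentences = [
                    s for s in segment_sentences(note, enc.encounter_id)
                    if not any(s.start < te and ts < s.end for ts, te in tmpl_spans)
                ]
                for sent in sentences:
                    for m in match_concepts(sent, lexicon):
                        if m.ambiguous:
                            pending.append((idx, sent, m))
                            continue
                        asserted, temporality, severity = detect_attributes(sent, m)
                        mentions.append(ConceptMention(
                            enc.encounter_id, m.concept_ids[0], m.start, m.end,
                            m.surface, asserted, temporality, severity, "free_text"))
                mentions.extend(resolve_template_support(
                    assertions, mentions, lexicon, note, enc.encounter_id))
            except Exception:
                if strict:
                    raise
                log.exception("skipping encounter %s (patient %s)",
                              enc.encounter_id, patient_id)
                if failures is not None:
                    failures.append(enc.encounter_id)
                mentions = []
            per_enc.append(mentions)

        # longitudinal context: unambiguously asserted concepts anywhere in
        # the patient's record
        context = {m.concept_id for ms in per_enc for m in ms if m.asserted}
        for idx, sent, m in pending:
            resolved = disambiguate(m, context, table, margin)
            if resolved is None:
                continue
            asserted, temporality, severity = detect_attributes(sent, m)
            per_enc[idx].append(ConceptMention(
                encounters[idx].encounter_id, resolved, m.start, m.end,
                m.surface, asserted, temporality, severity, "disambiguated"))
        for ms in per_enc:
            all_mentions.extend(ms)
    return all_mentions


def write_mentions(mentions: Iterable[ConceptMention], path) -> None:
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    with open(tmp, "w", encoding="utf-8") as fh:
        for m in mentions:
            fh.write(json.dumps(m.to_obj(), ensure_ascii=False) + "\n")
    os.replace(tmp, path)


def read_mentions(path) -> list[ConceptMention]:
    with open(path, encoding="utf-8") as fh:
        return [ConceptMention.from_obj(json.loads(line)) for line in fh if line.strip()]
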