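"""Seeded synthetic EHR corpus generator with exhaustive ground truth.

Real migraine EHR extracts from tertiary care are not redistributable, so
this module emulates one: per encounter it samples which concepts are
*clinically present* (symptoms enriched in migraine encounters), then
renders each present concept into the structured fields with probability
``structured_doc_prob`` and into the narrative with probability
``narrative_doc_prob``.  The gap between those two probabilities is the
documentation-completeness gap that separates the structured-query arm from
the NLP arm: clinicians narrate symptoms far more often than they code them.

Rendering noise exercises every extractor rule — abbreviation surfaces,
sign-prefixed review-of-systems template lines, explicit denial sentences
for absent concepts, and ambiguous-abbreviation distractor contexts for the
longitudinal disambiguator.  Every rendered asserted mention is recorded
with exact character offsets in a truth file that doubles as gold standoff
annotation, and generation is a pure function of (config, seed).

The shipped default profile targets a 6,032-encounter corpus whose expected
per-concept narrated-mention counts and arm-level documentation
probabilities match the calibration table in ``CALIBRATION``.
"""

from __future__ import annotations

import datetime as dt
import json
import math
import os
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import yaml

from .corpus_model import CodedEntry, Corpus, Encounter
from .knowledge import (CodeMap, Lexicon, MEDICATION_CONCEPTS, SYMPTOM_CONCEPTS,
                        TARGET_CONCEPTS, default_code_map, default_lexicon)
from .reference_standard import AnnotationRound, ReferenceAnnotation

__all__ = [
    "ConceptProfile",
    "GeneratorConfig",
    "TruthMention",
    "TruthRecord",
    "CALIBRATION",
    "default_profile",
    "generate_corpus",
    "expected_concept_occurrences",
    "truth_mentions",
    "truth_reference_annotations",
    "simulate_annotators",
    "write_truth",
    "read_truth",
    "config_from_yaml",
    "config_to_yaml",
]


@dataclass(frozen=True)
class ConceptProfile:
    """Per-concept generation parameters.

    truth_prevalence        per-encounter probability the concept is clinically
                            present (marginal; symptoms are redistributed
                            conditionally on migraine, preserving the marginal)
    structured_doc_prob     probability a present concept is coded in a
                            structured field
    narrative_doc_prob      probability a present concept is written in the note
    mention_multiplicity    mean number of *extra* narrated mentions (Poisson)
    """

    truth_prevalence: float
    structured_doc_prob: float
    narrative_doc_prob: float
    mention_multiplicity: float = 0.0

    def validate(self, concept_id: str) -> None:
        for name in ("truth_prevalence", "structured_doc_prob", "narrative_doc_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{concept_id}.{name} = {v} outside [0, 1]")
        if self.mention_multiplicity < 0:
            raise ValueError(f"{concept_id}.mention_multiplicity must be >= 0")


@dataclass
class GeneratorConfig:
    n_patients: int
    encounters_per_patient: tuple[int, int]  # inclusive uniform range
    concepts: dict[str, ConceptProfile]
    migraine_symptom_lift: float = 2.0
    severity_cue_prob: float = 0.3
    abbreviation_prob: float = 0.3
    template_prob: float = 0.15
    negated_absent_prob: float = 0.10
    distractor_prob: float = 0.05
    seed: int = 0
    start_date: dt.date = dt.date(2010, 1, 4)

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        lo, hi = self.encounters_per_patient
        if not (1 <= lo <= hi):
            raise ValueError("encounters_per_patient must be a 1 <= lo <= hi range")
        for name in ("severity_cue_prob", "abbreviation_prob", "template_prob",
                     "negated_absent_prob", "distractor_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.migraine_symptom_lift < 1.0:
            raise ValueError("migraine_symptom_lift must be >= 1")
        for cid, prof in self.concepts.items():
            prof.validate(cid)


@dataclass(frozen=True)
class TruthMention:
    """One rendered asserted narrative mention (gold standoff annotation)."""

    encounter_id: str
    concept_id: str
    start: int
    end: int
    surface: str
    asserted: bool = True
    temporality: str = "current"
    severity: str = "unspecified"

    def to_obj(self) -> dict:
        return {k: getattr(self, k) for k in
                ("concept_id", "start", "end", "surface", "asserted",
                 "temporality", "severity")}


@dataclass
class TruthRecord:
    """Truth for one encounter x target concept cell; the truth file covers
    every such cell exhaustively."""

    encounter_id: str
    concept_id: str
    clinically_present: bool
    structured_rendered: bool = False
    narrative_rendered: bool = False
    mentions: list[TruthMention] = field(default_factory=list)

    def to_obj(self) -> dict:
        return {
            "encounter_id": self.encounter_id,
            "concept_id": self.concept_id,
            "clinically_present": self.clinically_present,
            "structured_rendered": self.structured_rendered,
            "narrative_rendered": self.narrative_rendered,
            "mentions": [m.to_obj() for m in self.mentions],
        }

    @classmethod
    def from_obj(cls, obj: dict) -> "TruthRecord":
        return cls(
            encounter_id=obj["encounter_id"],
            concept_id=obj["concept_id"],
            clinically_present=obj["clinically_present"],
            structured_rendered=obj.get("structured_rendered", False),
            narrative_rendered=obj.get("narrative_rendered", False),
            mentions=[TruthMention(encounter_id=obj["encounter_id"], **m)
                      for m in obj.get("mentions", ())],
        )


# ---------------------------------------------------------------------------
# Default calibration profile
#
# Per concept: (target narrated-mention count over the default corpus,
# narrative_doc_prob, structured_doc_prob, mention_multiplicity).  The
# narrative/structured probabilities are the documentation-completeness
# profile of a tertiary-care migraine corpus: diagnoses coded somewhat often,
# symptoms almost never, medications reliably; nearly everything narrated.

CALIBRATION: dict[str, tuple[int, float, float, float]] = {
    "migraine":          (2642, 0.968, 0.666, 0.15),
    "headache":          (6530, 0.929, 0.296, 0.37),
    "nausea":            (4057, 0.93,  0.05,  0.20),
    "vomiting":          (3197, 0.90,  0.04,  0.20),
    "light_sensitivity": (243,  0.88,  0.00,  0.05),
    "loss_of_appetite":  (377,  0.86,  0.02,  0.05),
    "dizziness":         (3391, 0.90,  0.179, 0.15),
    "fatigue":           (4088, 0.95,  0.10,  0.15),
    "rizatriptan":       (102,  0.99,  0.80,  0.00),
    "sumatriptan":       (510,  0.98,  0.80,  0.00),
}

_DEFAULT_N_PATIENTS = 1508
_DEFAULT_ENC_RANGE = (4, 4)  # 1508 x 4 = 6,032 encounters
_DEFAULT_DISTRACTOR = 0.05


def default_profile(seed: int = 0) -> GeneratorConfig:
    """The shipped calibration: a 6,032-encounter migraine-enriched corpus.

    Truth prevalences are back-computed so the expected number of narrated
    mentions per concept, n * p * u * (1 + multiplicity), hits the
    calibration count (migraine additionally receives ambiguous-abbreviation
    mentions from the distractor channel, included in its expectation).
    """
    n_enc = _DEFAULT_N_PATIENTS * _DEFAULT_ENC_RANGE[0]
    concepts: dict[str, ConceptProfile] = {}
    for cid, (count, u, s, mult) in CALIBRATION.items():
        denom = n_enc * (u * (1.0 + mult) + (_DEFAULT_DISTRACTOR if cid == "migraine" else 0.0))
        concepts[cid] = ConceptProfile(
            truth_prevalence=count / denom,
            structured_doc_prob=s,
            narrative_doc_prob=u,
            mention_multiplicity=mult,
        )
    return GeneratorConfig(
        n_patients=_DEFAULT_N_PATIENTS,
        encounters_per_patient=_DEFAULT_ENC_RANGE,
        concepts=concepts,
        seed=seed,
    )


def expected_concept_occurrences(config: GeneratorConfig) -> dict[str, float]:
    """Analytic expectation of narrated (asserted) mention counts per concept."""
    lo, hi = config.encounters_per_patient
    n_enc = config.n_patients * (lo + hi) / 2.0
    out = {}
    for cid, prof in config.concepts.items():
        e = n_enc * prof.truth_prevalence * prof.narrative_doc_prob * (1.0 + prof.mention_multiplicity)
        if cid == "migraine":
            e += n_enc * prof.truth_prevalence * config.distractor_prob
        out[cid] = e
    return out


# ---------------------------------------------------------------------------
# Note assembly

_INTRO_SENTENCES = (
    "Seen in clinic for follow-up.",
    "Office visit for ongoing care.",
    "Clinic visit for evaluation.",
    "Return visit today.",
)

_SYMPTOM_TEMPLATES = (
    ("Patient reports ", "."),
    ("Reports ", " over the past week."),
    ("", " noted on review."),
    ("Complains of ", " today."),
)

_DRUG_TEMPLATES = (
    ("Prescribed ", " at this visit."),
    ("Continue ", " as needed."),
    ("Refill provided for ", "."),
)

_DENIAL_TEMPLATES = (
    ("Denies ", "."),
    ("No ", " today."),
    ("Without ", " at present."),
)

_SEVERITY_RENDER = {"mild": "mild", "moderate": "mod", "severe": "severe"}


class _NoteBuilder:
    def __init__(self):
        self._parts: list[str] = []
        self._len = 0

    def raw(self, text: str) -> int:
        start = self._len
        self._parts.append(text)
        self._len += len(text)
        return start

    def _sep(self, sep: str = " ") -> None:
        if self._len and not self._parts[-1].endswith("\n"):
            self.raw(sep)

    def sentence(self, prefix: str, core: str, suffix: str) -> tuple[int, int]:
        """Append one sentence; returns the span of ``core`` in the note."""
        self._sep(" ")
        start = self._len + len(prefix)
        self.raw(prefix + core + suffix)
        return start, start + len(core)

    def text(self) -> str:
        return "".join(self._parts)

    @property
    def pos(self) -> int:
        return self._len


def _poisson(rng: random.Random, lam: float) -> int:
    if lam <= 0:
        return 0
    limit = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def _pick_surface(rng: random.Random, lexicon: Lexicon, concept: str,
                  abbreviation_prob: float) -> str:
    """Choose a rendering surface; ambiguous abbreviations are never used here
    (they belong to the distractor channel)."""
    if rng.random() < abbreviation_prob:
        abbrevs = sorted(lexicon.surfaces_for(concept, term_type="abbreviation",
                                              ambiguous=False))
        if abbrevs:
            return rng.choice(abbrevs).upper()
    preferred = sorted(lexicon.surfaces_for(concept, term_type="preferred", ambiguous=False))
    synonyms = sorted(lexicon.surfaces_for(concept, term_type="synonym", ambiguous=False))
    if synonyms and rng.random() < 0.3:
        return rng.choice(synonyms)
    return preferred[0] if preferred else (synonyms[0] if synonyms else concept)


# ---------------------------------------------------------------------------
# Generation

def generate_corpus(
    config: GeneratorConfig,
    seed: int | None = None,
    lexicon: Lexicon | None = None,
    code_map: CodeMap | None = None,
) -> tuple[Corpus, list[TruthRecord]]:
    """Generate a corpus and its exhaustive truth; identical (config, seed)
    inputs produce byte-identical outputs."""
    config.validate()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = random.Random(config.seed)
    lexicon = lexicon if lexicon is not None else default_lexicon()
    code_map = code_map if code_map is not None else default_code_map()

    target_order = [c for c in TARGET_CONCEPTS if c in config.concepts]
    target_order += [c for c in config.concepts if c not in target_order]
    p_mig = config.concepts.get("migraine", ConceptProfile(0, 0, 0)).truth_prevalence
    lift = config.migraine_symptom_lift

    encounters: list[Encounter] = []
    truth: list[TruthRecord] = []
    enc_counter = 0
    physicians = [f"D{i:03d}" for i in range(25)]

    for pnum in range(config.n_patients):
        patient_id = f"P{pnum:05d}"
        n_enc = rng.randint(*config.encounters_per_patient)
        # sample truth for the whole patient first: the distractor channel
        # needs to know whether the patient has migraine anywhere on record
        enc_truth: list[dict[str, bool]] = []
        for _ in range(n_enc):
            present: dict[str, bool] = {}
            mig = rng.random() < p_mig if "migraine" in config.concepts else False
            present["migraine"] = mig
            for cid in target_order:
                if cid == "migraine":
                    continue
                prof = config.concepts[cid]
                p = prof.truth_prevalence
                if cid in SYMPTOM_CONCEPTS and lift > 1.0 and p_mig > 0:
                    base = p / (1.0 + p_mig * (lift - 1.0))
                    p = min(1.0, lift * base) if mig else base
                present[cid] = rng.random() < p
            enc_truth.append(present)
        patient_has_migraine = any(t.get("migraine", False) for t in enc_truth)

        date = config.start_date + dt.timedelta(days=rng.randint(0, 365))
        for eidx in range(n_enc):
            enc_counter += 1
            encounter_id = f"E{enc_counter:06d}"
            present = enc_truth[eidx]
            builder = _NoteBuilder()
            builder.raw(rng.choice(_INTRO_SENTENCES))
            problem_list: list[CodedEntry] = []
            medication_list: list[CodedEntry] = []
            claims: list[CodedEntry] = []
            ros: list[tuple[str, str, str]] = []  # (sign, concept, surface)
            records: dict[str, TruthRecord] = {
                cid: TruthRecord(encounter_id, cid, present[cid]) for cid in target_order}

            for cid in target_order:
                prof = config.concepts[cid]
                rec = records[cid]
                if present[cid]:
                    if rng.random() < prof.structured_doc_prob:
                        codes = code_map.codes_for(cid)
                        if codes:
                            system, code = rng.choice(sorted(codes))
                            entry = CodedEntry(system, code)
                            if cid in MEDICATION_CONCEPTS:
                                medication_list.append(entry)
                            elif rng.random() < 0.5:
                                problem_list.append(entry)
                            else:
                                claims.append(entry)
                            rec.structured_rendered = True
                    if rng.random() < prof.narrative_doc_prob:
                        rec.narrative_rendered = True
                        n_mentions = 1 + _poisson(rng, prof.mention_multiplicity)
                        for mnum in range(n_mentions):
                            surface = _pick_surface(rng, lexicon, cid,
                                                    config.abbreviation_prob)
                            if (mnum == 0 and config.template_prob > 0
                                    and cid not in MEDICATION_CONCEPTS
                                    and rng.random() < config.template_prob):
                                ros.append(("+", cid, surface))
                                continue
                            severity = "unspecified"
                            if cid in MEDICATION_CONCEPTS:
                                prefix, suffix = rng.choice(_DRUG_TEMPLATES)
                            else:
                                prefix, suffix = rng.choice(_SYMPTOM_TEMPLATES)
                                if rng.random() < config.severity_cue_prob:
                                    severity = rng.choice(("mild", "moderate", "severe"))
                                    prefix = prefix + _SEVERITY_RENDER[severity] + " "
                            start, end = builder.sentence(prefix, surface, suffix)
                            rec.mentions.append(TruthMention(
                                encounter_id, cid, start, end, surface,
                                True, "current", severity))
                else:
                    if rng.random() < config.negated_absent_prob:
                        surface = _pick_surface(rng, lexicon, cid, 0.0)
                        if config.template_prob > 0 and rng.random() < 0.5 \
                                and cid not in MEDICATION_CONCEPTS:
                            ros.append(("-", cid, surface))
                        else:
                            prefix, suffix = rng.choice(_DENIAL_TEMPLATES)
                            builder.sentence(prefix, surface, suffix)

            # ambiguous-abbreviation distractor channel
            if config.distractor_prob > 0 and rng.random() < config.distractor_prob:
                if present.get("migraine", False):
                    start, end = builder.sentence("Pt with ", "MA", ".")
                    records["migraine"].narrative_rendered = True
                    records["migraine"].mentions.append(TruthMention(
                        encounter_id, "migraine_with_aura", start, end, "MA",
                        True, "current", "unspecified"))
                elif not patient_has_migraine:
                    builder.sentence("Followed for ", "lung cancer", ".")
                    builder.sentence("Known ", "tumor", " on imaging.")
                    builder.sentence("Pt with ", "MA", ".")

            if ros:
                builder.raw("\n")
                for i, (sign, cid, surface) in enumerate(ros):
                    if i:
                        builder.raw(", ")
                    builder.raw(sign)
                    start = builder.raw(surface)
                    if sign == "+":
                        records[cid].mentions.append(TruthMention(
                            encounter_id, cid, start, start + len(surface), surface,
                            True, "current", "unspecified"))
                builder.raw("\n")

            encounters.append(Encounter(
                patient_id=patient_id,
                encounter_id=encounter_id,
                physician_id=rng.choice(physicians),
                date=date,
                problem_list=problem_list,
                medication_list=medication_list,
                claims=claims,
                note_text=builder.text(),
            ))
            truth.extend(records[cid] for cid in target_order)
            date += dt.timedelta(days=rng.randint(20, 90))

    return Corpus(encounters, source_tag=f"synthetic(seed={config.seed})"), truth


# ---------------------------------------------------------------------------
# Truth utilities

def truth_mentions(records: Iterable[TruthRecord]) -> Iterator[TruthMention]:
    """All gold asserted narrative mentions across truth records."""
    for rec in records:
        yield from rec.mentions


def truth_reference_annotations(records: Iterable[TruthRecord]) -> list[ReferenceAnnotation]:
    """Perfect-annotator reference labels: one asserted annotation per
    clinically-present encounter x concept cell."""
    return [ReferenceAnnotation(r.encounter_id, "truth", r.concept_id, True)
            for r in records if r.clinically_present]


def simulate_annotators(
    records: Sequence[TruthRecord],
    encounter_ids: Sequence[str],
    concepts: Sequence[str],
    seed: int,
    n_annotators: int = 7,
    batch_size: int = 250,
    miss_prob: float = 0.03,
    false_positive_prob: float = 0.002,
) -> list[AnnotationRound]:
    """Emulate dual annotation with rotated pairs and a third-annotator tiebreak.

    Annotator error is asymmetric — a present concept is missed with
    ``miss_prob`` and an absent one hallucinated with ``false_positive_prob`` —
    which keeps chance-corrected agreement high even for rare concepts, as it
    is for trained human annotators.  The tiebreaker labels every encounter
    in the batch (so each dispute has a verdict, including "absent" ones).
    """
    rng = random.Random(seed)
    truth_present = {(r.encounter_id, r.concept_id)
                     for r in records if r.clinically_present}
    annotators = [f"A{i + 1}" for i in range(n_annotators)]
    rounds: list[AnnotationRound] = []
    for b, i in enumerate(range(0, len(encounter_ids), batch_size)):
        batch = list(encounter_ids[i:i + batch_size])
        a_id = annotators[b % n_annotators]
        b_id = annotators[(b + 1) % n_annotators]
        t_id = annotators[(b + 2) % n_annotators]

        def annotate(annotator: str, mark_reviewed: bool = False) -> list[ReferenceAnnotation]:
            out = []
            for eid in batch:
                reviewed = False
                for concept in concepts:
                    truly = (eid, concept) in truth_present
                    labeled = (rng.random() >= miss_prob) if truly \
                        else (rng.random() < false_positive_prob)
                    if labeled:
                        out.append(ReferenceAnnotation(eid, annotator, concept, True))
                        reviewed = True
                if mark_reviewed and not reviewed:
                    # explicit "nothing present" verdict so adjudication knows
                    # the tiebreaker reviewed this encounter
                    out.append(ReferenceAnnotation(eid, annotator, concepts[0], False))
            return out

        rounds.append(AnnotationRound(
            annotator_pair=(a_id, b_id),
            encounter_ids=batch,
            annotations_a=annotate(a_id),
            annotations_b=annotate(b_id),
            adjudicator_id=t_id,
            annotations_tiebreak=annotate(t_id, mark_reviewed=True),
        ))
    return rounds


# ---------------------------------------------------------------------------
# Serialization

def write_truth(records: Iterable[TruthRecord], path) -> None:
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    with open(tmp, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps(r.to_obj(), ensure_ascii=False) + "\n")
    os.replace(tmp, path)


def read_truth(path) -> list[TruthRecord]:
    with open(path, encoding="utf-8") as fh:
        return [TruthRecord.from_obj(json.loads(line)) for line in fh if line.strip()]


def config_from_yaml(path) -> GeneratorConfig:
    with open(path, encoding="utf-8") as fh:
        obj = yaml.safe_load(fh)
    concepts = {cid: ConceptProfile(**prof) for cid, prof in obj.pop("concepts").items()}
    if "start_date" in obj and isinstance(obj["start_date"], str):
        obj["start_date"] = dt.date.fromisoformat(obj["start_date"])
    if "encounters_per_patient" in obj:
        obj["encounters_per_patient"] = tuple(obj["encounters_per_patient"])
    cfg = GeneratorConfig(concepts=concepts, **obj)
    cfg.validate()
    return cfg


def config_to_yaml(config: GeneratorConfig, path) -> None:
    obj = {
        "n_patients": config.n_patients,
        "encounters_per_patient": list(config.encounters_per_patient),
        "concepts": {cid: vars(prof).copy() for cid, prof in config.concepts.items()},
        "migraine_symptom_lift": config.migraine_symptom_lift,
        "severity_cue_prob": config.severity_cue_prob,
        "abbreviation_prob": config.abbreviation_prob,
        "template_prob": config.template_prob,
        "negated_absent_prob": config.negated_absent_prob,
        "distractor_prob": config.distractor_prob,
        "seed": config.seed,
        "start_date": config.start_date.isoformat(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
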