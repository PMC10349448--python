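"""Reference standard: dual annotation, Cohen's kappa, adjudication.

Every encounter is labeled independently by two annotators (pairings rotate
across batches to avoid systematic error); chance-corrected agreement is
measured with Cohen's kappa *before* any disagreement is resolved, per
concept on binary per-encounter presence — the same surface on which recall
is later computed.  Disagreements are resolved by a third annotator, and the
adjudicated label set is the reference standard both extraction arms are
scored against.  The study-level agreement requirement is an average kappa
of at least 0.8.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "KAPPA_THRESHOLD",
    "ReferenceAnnotation",
    "AnnotationRound",
    "AdjudicationError",
    "compute_kappa",
    "presence_labels",
    "average_kappa",
    "adjudicate",
    "write_annotations",
    "read_annotations",
]

KAPPA_THRESHOLD = 0.8


@dataclass(frozen=True)
class ReferenceAnnotation:
    """One manually assigned concept label; spans are optional because the
    evaluation unit is the encounter, not the character offset."""

    encounter_id: str
    annotator_id: str
    concept_id: str
    asserted: bool = True
    temporality: str = "unspecified"
    severity: str = "unspecified"
    start: int | None = None
    end: int | None = None

    def to_obj(self) -> dict:
        obj = {
            "encounter_id": self.encounter_id,
            "annotator_id": self.annotator_id,
            "concept_id": self.concept_id,
            "asserted": self.asserted,
            "temporality": self.temporality,
            "severity": self.severity,
        }
        if self.start is not None:
            obj["start"] = self.start
            obj["end"] = self.end
        return obj

    @classmethod
    def from_obj(cls, obj: dict) -> "ReferenceAnnotation":
        return cls(
            encounter_id=obj["encounter_id"],
            annotator_id=obj.get("annotator_id", ""),
            concept_id=obj["concept_id"],
            asserted=bool(obj.get("asserted", True)),
            temporality=obj.get("temporality", "unspecified"),
            severity=obj.get("severity", "unspecified"),
            start=obj.get("start"),
            end=obj.get("end"),
        )


@dataclass
class AnnotationRound:
    """One batch of encounters labeled by a rotated annotator pair."""

    annotator_pair: tuple[str, str]
    encounter_ids: list[str]
    annotations_a: list[ReferenceAnnotation] = field(default_factory=list)
    annotations_b: list[ReferenceAnnotation] = field(default_factory=list)
    adjudicator_id: str | None = None
    annotations_tiebreak: list[ReferenceAnnotation] = field(default_factory=list)


class AdjudicationError(ValueError):
    """Disagreements that cannot be resolved (no tiebreak label supplied)."""


def presence_labels(
    annotations: Iterable[ReferenceAnnotation],
    encounter_ids: Sequence[str],
    concept_id: str,
) -> list[bool]:
    """Reduce annotations to per-encounter binary presence of an asserted concept.

    Span mismatches are irrelevant at this level: two annotators marking the
    same concept anywhere in the encounter agree.
    """
    present = {a.encounter_id for a in annotations
               if a.concept_id == concept_id and a.asserted}
    return [eid in present for eid in encounter_ids]


def compute_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's kappa, (p_o - p_e) / (1 - p_e), on two aligned label vectors.

    Expected agreement uses the marginal product.  Degenerate case: when both
    marginals are concentrated on one class (p_e = 1, which forces perfect
    observed agreement) kappa is 1 by convention.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors differ in length")
    n = len(labels_a)
    if n == 0:
        raise ValueError("empty encounter set")
    classes = sorted(set(labels_a) | set(labels_b), key=repr)
    counts = {(x, y): 0 for x in classes for y in classes}
    for x, y in zip(labels_a, labels_b):
        counts[(x, y)] += 1
    p_o = sum(counts[(c, c)] for c in classes) / n
    p_e = sum(
        (sum(counts[(c, y)] for y in classes) / n)
        * (sum(counts[(x, c)] for x in classes) / n)
        for c in classes
    )
    if p_e >= 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def average_kappa(
    rounds: Iterable[AnnotationRound],
    concepts: Sequence[str],
) -> tuple[float, bool, dict[tuple[str, str], float]]:
    """Unweighted mean of per-round, per-concept kappas, with pass/fail.

    Kappa is computed prior to any resolution of disagreement.  Returns
    (mean kappa, mean >= 0.8, per-(pair-batch, concept) kappas).
    """
    per: dict[tuple[str, str], float] = {}
    for i, rnd in enumerate(rounds):
        for concept in concepts:
            la = presence_labels(rnd.annotations_a, rnd.encounter_ids, concept)
            lb = presence_labels(rnd.annotations_b, rnd.encounter_ids, concept)
            key = (f"round{i}:{rnd.annotator_pair[0]}|{rnd.annotator_pair[1]}", concept)
            per[key] = compute_kappa(la, lb)
    if not per:
        raise ValueError("no annotation rounds supplied")
    mean = sum(per.values()) / len(per)
    return mean, mean >= KAPPA_THRESHOLD, per


def adjudicate(
    labels_a: Iterable[ReferenceAnnotation],
    labels_b: Iterable[ReferenceAnnotation],
    labels_tiebreak: Iterable[ReferenceAnnotation],
    encounter_ids: Sequence[str],
    concepts: Sequence[str],
) -> list[ReferenceAnnotation]:
    """Resolve dual annotation into the reference standard.

    Agreement keeps the shared label; disagreement takes the third
    annotator's label.  Every reference label therefore originates either
    from agreement or from the tiebreaker.  A disagreement with no tiebreak
    label for that encounter is fatal, listing the offending encounter ids.
    """
    a_list, b_list, t_list = list(labels_a), list(labels_b), list(labels_tiebreak)
    a_by = {(x.encounter_id, x.concept_id): x for x in a_list if x.asserted}
    b_by = {(x.encounter_id, x.concept_id): x for x in b_list if x.asserted}
    t_by = {(x.encounter_id, x.concept_id): x for x in t_list if x.asserted}
    t_covered = {x.encounter_id for x in t_list}

    reference: list[ReferenceAnnotation] = []
    unresolved: list[str] = []
    for eid in encounter_ids:
        for concept in concepts:
            key = (eid, concept)
            in_a, in_b = key in a_by, key in b_by
            if in_a and in_b:
                src = a_by[key]
            elif not in_a and not in_b:
                continue
            else:  # dispute
                if key not in t_by and eid not in t_covered:
                    unresolved.append(eid)
                    continue
                if key not in t_by:
                    continue  # tiebreaker reviewed the encounter and says absent
                src = t_by[key]
            reference.append(ReferenceAnnotation(
                eid, "reference", concept, True, src.temporality, src.severity))
    if unresolved:
        raise AdjudicationError(
            "disagreement without tiebreak label for encounter(s): "
            + ", ".join(dict.fromkeys(unresolved)))
    return reference


def write_annotations(annotations: Iterable[ReferenceAnnotation], path) -> None:
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    with open(tmp, "w", encoding="utf-8") as fh:
        for a in annotations:
            fh.write(json.dumps(a.to_obj(), ensure_ascii=False) + "\n")
    os.replace(tmp, path)


def read_annotations(path) -> list[ReferenceAnnotation]:
    with open(path, encoding="utf-8") as fh:
        return [ReferenceAnnotation.from_obj(json.loads(line)) for line in fh if line.strip()]
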