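"""Outcome framework: occurrence counts, recall/precision/F1, arm comparison.

Concepts are discrete, time-specific events, so the primary evaluation unit
is the *encounter*: a concept predicted for an encounter is correct only if
the reference standard asserts it in that same encounter — presence never
propagates across a patient's record.  Recall (primary endpoint) is the
proportion of reference-positive encounters the arm identified; precision is
the proportion of identified encounters that are reference-positive
(undefined when an arm identifies nothing); F1 is their harmonic mean,
2·(precision·recall)/(precision+recall), taken as 0 when there are no true
positives.  Arm recalls are compared per concept with a Pearson chi-square
on the 2x2 [[tp, fn], [tp, fn]] table without continuity correction, and the
protocol's success criterion is a recall of at least 80% or an absolute
recall difference of at least 25 percentage points.

Descriptive *concept occurrence* (all mention instances) and *encounter
occurrence* (encounters with at least one instance) counts accompany the
metrics.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats

from .knowledge import CONCEPT_PARENTS, TARGET_CONCEPTS

__all__ = [
    "OccurrenceCounts",
    "MetricResult",
    "ArmComparison",
    "count_occurrences",
    "presence_set",
    "compute_metrics",
    "f1_score",
    "chi2_2x2",
    "compare_arms",
    "evaluation_report",
    "render_report_table",
    "write_report",
]

RECALL_THRESHOLD = 0.80
DIFFERENCE_THRESHOLD_PP = 25.0


@dataclass(frozen=True)
class OccurrenceCounts:
    concept_id: str
    concept_occurrences: int
    encounter_occurrences: int

    def __post_init__(self):
        if not (0 <= self.encounter_occurrences <= self.concept_occurrences):
            raise ValueError("encounter occurrences must be between 0 and concept occurrences")


@dataclass(frozen=True)
class MetricResult:
    concept_id: str
    arm: str  # traditional | advanced
    tp: int
    fp: int
    fn: int

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def precision(self) -> float | None:
        """None when the arm identified nothing (undefined, reported as NA)."""
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None

    @property
    def f1(self) -> float:
        if self.tp == 0:
            return 0.0
        return f1_score(self.precision, self.recall)

    def to_obj(self) -> dict:
        return {
            "concept_id": self.concept_id, "arm": self.arm,
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "recall": self.recall, "precision": self.precision, "f1": self.f1,
        }


@dataclass(frozen=True)
class ArmComparison:
    concept_id: str
    recall_traditional: float
    recall_advanced: float
    abs_recall_difference: float  # percentage points
    chi2_statistic: float
    p_value: float
    success: bool
    warning: str | None = None

    def to_obj(self) -> dict:
        return {
            "concept_id": self.concept_id,
            "recall_traditional": self.recall_traditional,
            "recall_advanced": self.recall_advanced,
            "abs_recall_difference": self.abs_recall_difference,
            "chi2_statistic": self.chi2_statistic,
            "p_value": self.p_value,
            "success": self.success,
            "warning": self.warning,
        }


def count_occurrences(items: Iterable, concept_id: str, roll_up: bool = True) -> OccurrenceCounts:
    """Count asserted instances and distinct encounters for one concept.

    ``items`` may be NLP mentions, structured hits, or reference annotations —
    anything with encounter_id, concept_id and asserted attributes.
    """
    total = 0
    encounters: set[str] = set()
    for it in items:
        cid = _effective_concept(it.concept_id, roll_up)
        if cid != concept_id or not it.asserted:
            continue
        total += 1
        encounters.add(it.encounter_id)
    return OccurrenceCounts(concept_id, total, len(encounters))


def _effective_concept(concept_id: str, roll_up: bool) -> str:
    return CONCEPT_PARENTS.get(concept_id, concept_id) if roll_up else concept_id


def presence_set(items: Iterable, roll_up: bool = True) -> set[tuple[str, str]]:
    """Reduce items to {(encounter_id, concept_id)} asserted presence pairs.

    Only asserted labels create presence; negated mentions never do.  With
    ``roll_up`` (default) child concepts count as their parent (a
    migraine-with-aura mention is migraine presence).
    """
    return {(it.encounter_id, _effective_concept(it.concept_id, roll_up))
            for it in items if it.asserted}


def _strict_presence(items: Iterable, roll_up: bool) -> set[tuple]:
    return {(it.encounter_id, _effective_concept(it.concept_id, roll_up),
             getattr(it, "temporality", "unspecified"),
             getattr(it, "severity", "unspecified"))
            for it in items if it.asserted}


def compute_metrics(
    predictions: Iterable,
    reference: Iterable,
    concept_id: str,
    encounter_ids: Sequence[str],
    arm: str = "advanced",
    roll_up: bool = True,
    attribute_strict: bool = False,
) -> MetricResult:
    """Encounter-level tp/fp/fn for one concept over a fixed encounter universe.

    Both inputs are reduced to per-encounter asserted presence.  Labels
    referring to encounters outside the shared (post-filter) universe are
    fatal: the arms must be evaluated on the identical encounter set.  With
    ``attribute_strict`` a prediction only counts when temporality and
    severity also agree with the reference (off by default: the endpoints
    concern concept identification).
    """
    universe = set(encounter_ids)
    if attribute_strict:
        pred = {(e, *attrs) for e, c, *attrs in _strict_presence(predictions, roll_up)
                if c == concept_id}
        ref = {(e, *attrs) for e, c, *attrs in _strict_presence(reference, roll_up)
               if c == concept_id}
        stray = {x[0] for x in (pred | ref)} - universe
        if stray:
            raise ValueError(
                f"labels outside the evaluation encounter universe: {sorted(stray)[:5]}")
        return MetricResult(concept_id, arm, tp=len(pred & ref),
                            fp=len(pred - ref), fn=len(ref - pred))
    pred = {e for e, c in presence_set(predictions, roll_up) if c == concept_id}
    ref = {e for e, c in presence_set(reference, roll_up) if c == concept_id}
    stray = (pred | ref) - universe
    if stray:
        raise ValueError(
            f"labels outside the evaluation encounter universe: {sorted(stray)[:5]}")
    tp = len(pred & ref)
    fp = len(pred - ref)
    fn = len(ref - pred)
    return MetricResult(concept_id, arm, tp, fp, fn)


def f1_score(precision: float | None, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when recall is 0."""
    if precision is None:
        raise ValueError("F1 is undefined when precision is undefined")
    if precision == 0 and recall == 0:
        return 0.0
    return 2.0 * (precision * recall) / (precision + recall)


def chi2_2x2(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-square without continuity correction on a 2x2 table.

    Degenerate tables (a zero row or column margin) carry no evidence of a
    difference: chi2 = 0, p = 1.
    """
    (a, b), (c, d) = table
    n = a + b + c + d
    margins = (a + b, c + d, a + c, b + d)
    if n == 0 or any(m == 0 for m in margins):
        return 0.0, 1.0
    chi2, p, _dof, _exp = stats.chi2_contingency([[a, b], [c, d]], correction=False)
    return float(chi2), float(p)


def compare_arms(metric_trad: MetricResult, metric_adv: MetricResult) -> ArmComparison:
    """Compare per-concept recalls between arms.

    The absolute recall difference is in percentage points; the chi-square is
    computed on [[tp_trad, fn_trad], [tp_adv, fn_adv]].  The success flag
    applies the protocol threshold to the advanced arm: it outperforms when
    its recall exceeds the traditional arm's and reaches 80%, or the absolute
    difference reaches 25 percentage points.
    """
    if metric_trad.concept_id != metric_adv.concept_id:
        raise ValueError("arm metrics refer to different concepts")
    r_t, r_a = metric_trad.recall, metric_adv.recall
    diff = abs(r_a - r_t) * 100.0
    table = [[metric_trad.tp, metric_trad.fn], [metric_adv.tp, metric_adv.fn]]
    chi2, p = chi2_2x2(table)
    warning = None
    n = sum(sum(row) for row in table)
    if n:
        margins_r = [sum(row) for row in table]
        margins_c = [table[0][j] + table[1][j] for j in range(2)]
        expected = [margins_r[i] * margins_c[j] / n for i in range(2) for j in range(2)]
        if any(e < 1 for e in expected):
            warning = "expected cell count < 1; chi-square approximation unreliable"
    success = (r_a > r_t) and (r_a >= RECALL_THRESHOLD or diff >= DIFFERENCE_THRESHOLD_PP)
    return ArmComparison(metric_trad.concept_id, r_t, r_a, diff, chi2, p, success, warning)


def evaluation_report(
    metrics: Iterable[MetricResult],
    comparisons: Iterable[ArmComparison],
    occurrences: Iterable[OccurrenceCounts],
    concepts: Sequence[str] = TARGET_CONCEPTS,
) -> dict:
    """Assemble the machine-readable study report.

    Requires a metric for every concept x arm cell and a comparison for every
    concept; output is deterministic (fixed concept order, no timestamps).
    """
    by_cell = {(m.concept_id, m.arm): m for m in metrics}
    by_cmp = {c.concept_id: c for c in comparisons}
    by_occ = {o.concept_id: o for o in occurrences}
    missing = [f"{c}/{arm}" for c in concepts for arm in ("traditional", "advanced")
               if (c, arm) not in by_cell]
    missing += [f"{c}/comparison" for c in concepts if c not in by_cmp]
    if missing:
        raise ValueError("missing report cell(s): " + ", ".join(missing))

    report: dict = {"concepts": {}, "summary": {}}
    for c in concepts:
        entry = {
            "occurrences": by_occ[c].__dict__ if c in by_occ else None,
            "traditional": by_cell[(c, "traditional")].to_obj(),
            "advanced": by_cell[(c, "advanced")].to_obj(),
            "comparison": by_cmp[c].to_obj(),
        }
        report["concepts"][c] = entry
    adv_recalls = [by_cell[(c, "advanced")].recall for c in concepts]
    trad_recalls = [by_cell[(c, "traditional")].recall for c in concepts]
    report["summary"] = {
        "mean_recall_traditional": sum(trad_recalls) / len(trad_recalls),
        "mean_recall_advanced": sum(adv_recalls) / len(adv_recalls),
        "advanced_meets_recall_threshold": min(adv_recalls) >= RECALL_THRESHOLD,
        "n_concepts": len(concepts),
    }
    return report


def _pct(x: float | None) -> str:
    return "NA" if x is None else f"{100.0 * x:.1f}"


def render_report_table(report: dict) -> str:
    """Human-readable per-concept table (recall/precision/F1 per arm, in %)."""
    header = (f"{'concept':<18}{'occ':>7}{'enc':>7}"
              f"{'R_trad':>8}{'P_trad':>8}{'F1_trad':>9}"
              f"{'R_adv':>8}{'P_adv':>8}{'F1_adv':>9}{'diff_pp':>9}{'p':>12}")
    lines = [header, "-" * len(header)]
    for concept, entry in report["concepts"].items():
        occ = entry.get("occurrences") or {}
        t, a, cmpo = entry["traditional"], entry["advanced"], entry["comparison"]
        p = cmpo["p_value"]
        lines.append(
            f"{concept:<18}{occ.get('concept_occurrences', 0):>7}"
            f"{occ.get('encounter_occurrences', 0):>7}"
            f"{_pct(t['recall']):>8}{_pct(t['precision']):>8}{_pct(t['f1']):>9}"
            f"{_pct(a['recall']):>8}{_pct(a['precision']):>8}{_pct(a['f1']):>9}"
            f"{cmpo['abs_recall_difference']:>9.1f}"
            f"{('<0.001' if p < 0.001 else f'{p:.3f}'):>12}")
    s = report["summary"]
    lines.append("-" * len(header))
    lines.append(f"mean recall: traditional {100 * s['mean_recall_traditional']:.1f}%  "
                 f"advanced {100 * s['mean_recall_advanced']:.1f}%")
    return "\n".join(lines) + "\n"


def write_report(report: dict, path) -> None:
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    with open(tmp, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    os.replace(tmp, path)
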