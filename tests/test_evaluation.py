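"""Occurrence counting, encounter-level metrics, chi-square arm comparison."""

import random

import pytest
from scipy import stats

from mig_rwe.evaluation import (MetricResult, chi2_2x2, compare_arms,
                                compute_metrics, count_occurrences,
                                evaluation_report, f1_score, presence_set,
                                render_report_table)
from mig_rwe.knowledge import TARGET_CONCEPTS
from mig_rwe.reference_standard import ReferenceAnnotation


def _ann(encounter_id, concept="headache", asserted=True):
    return ReferenceAnnotation(encounter_id, "x", concept, asserted)


class TestOccurrences:
    def test_instances_and_distinct_encounters(self):
        items = [_ann("E1"), _ann("E1"), _ann("E2")]
        counts = count_occurrences(items, "headache")
        assert (counts.concept_occurrences, counts.encounter_occurrences) == (3, 2)

    def test_empty_input(self):
        counts = count_occurrences([], "headache")
        assert (counts.concept_occurrences, counts.encounter_occurrences) == (0, 0)

    def test_single_encounter_collapse(self):
        counts = count_occurrences([_ann("E1")] * 5, "headache")
        assert (counts.concept_occurrences, counts.encounter_occurrences) == (5, 1)

    def test_negated_mentions_never_count(self):
        counts = count_occurrences([_ann("E1", asserted=False)], "headache")
        assert counts.concept_occurrences == 0

    def test_child_concept_rolls_up(self):
        counts = count_occurrences([_ann("E1", "migraine_with_aura")], "migraine")
        assert counts.concept_occurrences == 1


class TestMetrics:
    UNIVERSE = [f"E{i}" for i in range(20)]

    def test_identity_gives_perfect_scores(self):
        labels = [_ann(e) for e in self.UNIVERSE[:5]]
        m = compute_metrics(labels, labels, "headache", self.UNIVERSE)
        assert (m.recall, m.precision, m.f1) == (1.0, 1.0, 1.0)

    def test_worked_partition(self):
        ref = [_ann(f"E{i}") for i in range(10)]
        pred = [_ann(f"E{i}") for i in range(6)] + [_ann("E15"), _ann("E16")]
        m = compute_metrics(pred, ref, "headache", self.UNIVERSE)
        assert (m.tp, m.fn, m.fp) == (6, 4, 2)
        assert m.recall == pytest.approx(0.6)
        assert m.precision == pytest.approx(0.75)
        assert m.f1 == pytest.approx(2 * 0.45 / 1.35)

    def test_zero_predictions_precision_undefined(self):
        ref = [_ann("E1"), _ann("E2")]
        m = compute_metrics([], ref, "headache", self.UNIVERSE)
        assert m.recall == 0.0 and m.precision is None and m.f1 == 0.0

    def test_presence_never_propagates_across_encounters(self):
        ref = [_ann("E1"), _ann("E2")]
        pred = [_ann("E1")]  # same patient record, different encounter
        m = compute_metrics(pred, ref, "headache", self.UNIVERSE)
        assert (m.tp, m.fn) == (1, 1)

    def test_attribute_strict_mode_requires_matching_attributes(self):
        ref = [ReferenceAnnotation("E1", "r", "headache", True,
                                   temporality="current", severity="severe")]
        pred_wrong = [ReferenceAnnotation("E1", "p", "headache", True,
                                          temporality="current", severity="mild")]
        lax = compute_metrics(pred_wrong, ref, "headache", self.UNIVERSE)
        strict = compute_metrics(pred_wrong, ref, "headache", self.UNIVERSE,
                                 attribute_strict=True)
        assert lax.tp == 1
        assert (strict.tp, strict.fp, strict.fn) == (0, 1, 1)

    def test_label_outside_universe_is_fatal(self):
        with pytest.raises(ValueError, match="universe"):
            compute_metrics([_ann("E99")], [], "headache", self.UNIVERSE)

    def test_matches_brute_force_oracle_on_random_sets(self):
        rng = random.Random(31)
        universe = [f"E{i}" for i in range(40)]
        for _ in range(100):
            pred_ids = {e for e in universe if rng.random() < rng.random()}
            ref_ids = {e for e in universe if rng.random() < rng.random()}
            m = compute_metrics([_ann(e) for e in pred_ids],
                                [_ann(e) for e in ref_ids], "headache", universe)
            tp = fp = fn = 0  # independent double loop
            for e in universe:
                if e in pred_ids and e in ref_ids:
                    tp += 1
                elif e in pred_ids:
                    fp += 1
                elif e in ref_ids:
                    fn += 1
            assert (m.tp, m.fp, m.fn) == (tp, fp, fn)
            assert m.tp + m.fn == len(ref_ids)  # conservation

    def test_f1_bounded_by_precision_and_recall(self):
        m = MetricResult("headache", "advanced", tp=30, fp=10, fn=20)
        assert min(m.precision, m.recall) <= m.f1 <= max(m.precision, m.recall)
        assert 0.0 <= m.f1 <= 1.0


@pytest.mark.parametrize("precision,recall,expected", [
    (1.0, 1.0, 1.0),
    (0.5, 0.5, 0.5),
    (0.75, 0.6, 2 * 0.45 / 1.35),
    (0.0, 0.0, 0.0),
    (1.0, 0.0, 0.0),
])
def test_f1_harmonic_mean(precision, recall, expected):
    assert f1_score(precision, recall) == pytest.approx(expected)


class TestChiSquare:
    def test_worked_table_closed_form(self):
        # N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 200*5000^2 / (100*100*110*90)
        chi2, p = chi2_2x2([[30, 70], [80, 20]])
        assert chi2 == pytest.approx(200 * 5000 ** 2 / (100 * 100 * 110 * 90), abs=1e-9)
        assert p < 0.001

    def test_no_effect_table(self):
        chi2, p = chi2_2x2([[40, 10], [40, 10]])
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_degenerate_margin(self):
        assert chi2_2x2([[0, 0], [5, 5]]) == (0.0, 1.0)

    def test_matches_closed_form_on_random_tables(self):
        rng = random.Random(17)
        for _ in range(200):
            a, b, c, d = (rng.randint(1, 500) for _ in range(4))
            chi2, p = chi2_2x2([[a, b], [c, d]])
            n = a + b + c + d
            expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert chi2 == pytest.approx(expected, abs=1e-9)
            assert p == pytest.approx(stats.chi2.sf(expected, 1), abs=1e-12)


class TestArmComparison:
    def test_percentage_point_difference(self):
        trad = MetricResult("migraine", "traditional", tp=666, fp=0, fn=334)
        adv = MetricResult("migraine", "advanced", tp=968, fp=0, fn=32)
        cmp_ = compare_arms(trad, adv)
        assert cmp_.abs_recall_difference == pytest.approx(30.2)
        assert cmp_.p_value < 0.001 and cmp_.success

    def test_identical_arms(self):
        m = MetricResult("headache", "traditional", tp=50, fp=5, fn=50)
        cmp_ = compare_arms(m, MetricResult("headache", "advanced", tp=50, fp=5, fn=50))
        assert cmp_.chi2_statistic == pytest.approx(0.0, abs=1e-12)
        assert cmp_.p_value == pytest.approx(1.0)
        assert cmp_.abs_recall_difference == 0.0 and not cmp_.success

    def test_small_expected_cell_warns(self):
        trad = MetricResult("rizatriptan", "traditional", tp=1, fp=0, fn=1)
        adv = MetricResult("rizatriptan", "advanced", tp=2, fp=0, fn=0)
        assert compare_arms(trad, adv).warning is not None

    def test_mismatched_concepts_rejected(self):
        with pytest.raises(ValueError):
            compare_arms(MetricResult("a", "traditional", 1, 0, 1),
                         MetricResult("b", "advanced", 1, 0, 1))


class TestReport:
    def _full_report(self):
        metrics, comparisons, occurrences = [], [], []
        from mig_rwe.evaluation import OccurrenceCounts, count_occurrences
        for i, c in enumerate(TARGET_CONCEPTS):
            trad = MetricResult(c, "traditional", tp=0 if i == 4 else 10, fp=0, fn=10)
            adv = MetricResult(c, "advanced", tp=18, fp=1, fn=2)
            metrics += [trad, adv]
            comparisons.append(compare_arms(trad, adv))
            occurrences.append(OccurrenceCounts(c, 25, 20))
        return evaluation_report(metrics, comparisons, occurrences)

    def test_completeness_and_determinism(self):
        rep1, rep2 = self._full_report(), self._full_report()
        assert list(rep1["concepts"]) == list(TARGET_CONCEPTS)
        assert rep1 == rep2

    def test_undefined_precision_rendered_na_not_zero(self):
        table = render_report_table(self._full_report())
        row = [ln for ln in table.splitlines() if ln.startswith("light_sensitivity")][0]
        assert "NA" in row

    def test_missing_cell_is_fatal(self):
        rep = self._full_report()
        with pytest.raises(ValueError, match="missing"):
            evaluation_report(
                [MetricResult("migraine", "traditional", 1, 0, 1)], [], [])


def test_presence_set_only_asserted_and_rolled_up():
    items = [_ann("E1", "migraine_with_aura"), _ann("E2", "nausea", asserted=False)]
    assert presence_set(items) == {("E1", "migraine")}
    assert presence_set(items, roll_up=False) == {("E1", "migraine_with_aura")}
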