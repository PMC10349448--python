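"""NLP arm: segmentation, matching, attributes, templates, disambiguation."""

import dataclasses
import datetime as dt

import pytest

from mig_rwe import synthetic_data as syn
from mig_rwe.advanced_extractor import (RawMatch, Sentence, detect_attributes,
                                        disambiguate, extract_advanced,
                                        match_concepts, parse_templates,
                                        resolve_template_support,
                                        segment_sentences)
from mig_rwe.evaluation import presence_set

from conftest import make_corpus, make_encounter


def _sentence(text: str) -> Sentence:
    return Sentence("E1", 0, len(text), text)


class TestSegmentation:
    def test_two_sentences_with_exact_offsets(self):
        out = segment_sentences("No HA today. Nausea persists.")
        assert [(s.start, s.end) for s in out] == [(0, 12), (13, 29)]
        assert [s.text for s in out] == ["No HA today.", "Nausea persists."]

    def test_empty_text_yields_no_sentences(self):
        assert segment_sentences("") == []

    def test_text_without_boundary_is_one_sentence(self):
        out = segment_sentences("single sentence no period")
        assert len(out) == 1 and (out[0].start, out[0].end) == (0, 25)

    def test_newline_is_a_boundary_and_spans_index_the_note(self):
        note = "Plan stable.\n+nausea\nFollow up."
        out = segment_sentences(note)
        assert [note[s.start:s.end] for s in out] == ["Plan stable.", "+nausea", "Follow up."]


class TestMatching:
    def test_abbreviation_matches_whole_token(self, lexicon):
        out = match_concepts(_sentence("mod HA"), lexicon)
        assert len(out) == 1 and out[0].concept_ids == ("headache",)
        assert (out[0].start, out[0].end, out[0].surface) == (4, 6, "HA")

    def test_ambiguous_surface_emits_all_candidates(self, lexicon):
        out = match_concepts(_sentence("pt with MA"), lexicon)
        assert len(out) == 1
        assert set(out[0].concept_ids) == {"migraine_with_aura", "mass"}

    def test_embedded_substring_blocked_by_token_boundary(self, lexicon):
        assert match_concepts(_sentence("asthma exacerbation"), lexicon) == []

    def test_longest_match_suppresses_contained_shorter_match(self, lexicon):
        out = match_concepts(_sentence("known migraine with aura today"), lexicon)
        assert [m.concept_ids for m in out] == [("migraine_with_aura",)]
        assert out[0].surface == "migraine with aura"

    def test_multiword_symptom_surface(self, lexicon):
        out = match_concepts(_sentence("reports loss of appetite"), lexicon)
        assert [m.concept_ids for m in out] == [("loss_of_appetite",)]


class TestAttributes:
    def _attrs(self, lexicon, text, which=0):
        sent = _sentence(text)
        return detect_attributes(sent, match_concepts(sent, lexicon)[which])

    def test_negation_trigger_scopes_over_coordination(self, lexicon):
        sent = _sentence("denies nausea or vomiting")
        matches = match_concepts(sent, lexicon)
        assert [m.concept_ids[0] for m in matches] == ["nausea", "vomiting"]
        assert all(detect_attributes(sent, m)[0] is False for m in matches)

    def test_severity_cue_adjacent_to_abbreviation(self, lexicon):
        asserted, temporality, severity = self._attrs(lexicon, "mod HA")
        assert (asserted, temporality, severity) == (True, "current", "moderate")

    def test_scope_terminator_releases_second_mention(self, lexicon):
        sent = _sentence("no prior migraine, but migraine today")
        first, second = match_concepts(sent, lexicon)
        assert detect_attributes(sent, first)[:2] == (False, "historical")
        assert detect_attributes(sent, second)[:2] == (True, "current")

    def test_history_of_marks_historical_but_asserted(self, lexicon):
        asserted, temporality, _ = self._attrs(lexicon, "history of migraine")
        assert (asserted, temporality) == (True, "historical")

    def test_match_outside_sentence_rejected(self, lexicon):
        sent = _sentence("nausea")
        bad = RawMatch("nausea", 100, 106, ("nausea",))
        with pytest.raises(ValueError):
            detect_attributes(sent, bad)


class TestTemplates:
    def test_mixed_sign_line(self):
        out = parse_templates("-headache, +nausea")
        assert [(a.sign, a.surface) for a in out] == [("-", "headache"), ("+", "nausea")]

    def test_prose_line_ignored(self):
        assert parse_templates("Patient is resting comfortably") == []

    def test_two_plus_tokens_without_commas(self):
        out = parse_templates("+photophobia +phonophobia")
        assert [(a.sign, a.surface) for a in out] == [("+", "photophobia"),
                                                      ("+", "phonophobia")]

    def test_multiword_surface_and_offsets(self):
        note = "ROS below.\n-light sensitivity, +dizziness\n"
        out = parse_templates(note)
        assert [(a.sign, a.surface) for a in out] == [("-", "light sensitivity"),
                                                      ("+", "dizziness")]
        for a in out:
            assert note[a.start:a.end] == a.surface


class TestTemplateSupport:
    def test_unsupported_negative_is_emitted_negated(self, lexicon):
        note = "-headache"
        out = resolve_template_support(parse_templates(note), [], lexicon, note, "E1")
        assert len(out) == 1
        assert out[0].concept_id == "headache" and out[0].asserted is False
        assert out[0].provenance == "template"

    def test_free_text_assertion_wins_over_template_negative(self, lexicon):
        from mig_rwe.advanced_extractor import ConceptMention
        note = "severe headache x3 days.\n-headache"
        free = [ConceptMention("E1", "headache", 7, 15, "headache", True)]
        out = resolve_template_support(parse_templates(note), free, lexicon, note, "E1")
        assert out == []  # no negated mention emitted

    def test_positive_sign_asserts(self, lexicon):
        note = "+nausea"
        out = resolve_template_support(parse_templates(note), [], lexicon, note, "E1")
        assert out[0].concept_id == "nausea" and out[0].asserted is True


class TestDisambiguation:
    def _ma(self):
        return RawMatch("MA", 8, 10, ("migraine_with_aura", "mass"))

    def test_migraine_context_favours_migraine_with_aura(self, assoc_table):
        assert disambiguate(self._ma(), {"headache", "light_sensitivity"},
                            assoc_table) == "migraine_with_aura"

    def test_oncology_context_favours_mass(self, assoc_table):
        assert disambiguate(self._ma(), {"lung_cancer", "tumor"}, assoc_table) == "mass"

    def test_zero_evidence_tie_abstains(self, assoc_table):
        assert disambiguate(self._ma(), set(), assoc_table) is None

    def test_margin_requirement(self, assoc_table):
        # headache alone gives migraine_with_aura a lead of exactly 2
        ctx = {"headache"}
        assert disambiguate(self._ma(), ctx, assoc_table, margin=2.0) == "migraine_with_aura"
        assert disambiguate(self._ma(), ctx, assoc_table, margin=2.5) is None

    def test_candidate_senses_excluded_from_context(self, assoc_table):
        # a previously resolved "mass" concept must not feed back into scoring
        assert disambiguate(self._ma(), {"mass"}, assoc_table) is None


class TestOrchestration:
    def test_hand_traced_fixture(self, lexicon, assoc_table):
        corpus = make_corpus(make_encounter(
            "E1", note_text="Pt reports severe HA with photophobia. Denies vomiting."))
        mentions = extract_advanced(corpus, lexicon, assoc_table)
        by_concept = {m.concept_id: m for m in mentions}
        assert set(by_concept) == {"headache", "light_sensitivity", "vomiting"}
        assert by_concept["headache"].asserted and by_concept["headache"].severity == "severe"
        assert by_concept["light_sensitivity"].asserted
        assert by_concept["vomiting"].asserted is False

    def test_empty_notes_yield_no_mentions(self, lexicon, assoc_table):
        corpus = make_corpus(make_encounter("E1"), make_encounter(
            "E2", date=dt.date(2011, 5, 1)))
        assert extract_advanced(corpus, lexicon, assoc_table) == []

    def test_deterministic_over_repeated_runs(self, lexicon, assoc_table, tiny_corpus):
        assert extract_advanced(tiny_corpus, lexicon, assoc_table) == \
            extract_advanced(tiny_corpus, lexicon, assoc_table)

    def test_invariant_to_structured_fields(self, lexicon, assoc_table):
        note = "Pt reports severe HA with photophobia."
        plain = make_corpus(make_encounter("E1", note_text=note))
        coded = make_corpus(make_encounter("E1", note_text=note,
                                           claims=[("ICD10", "G43.909")],
                                           medication_list=[("DRUG", "SUMATRIPTAN")]))
        assert extract_advanced(plain, lexicon, assoc_table) == \
            extract_advanced(coded, lexicon, assoc_table)

    def test_template_line_not_rematched_as_free_text(self, lexicon, assoc_table):
        corpus = make_corpus(make_encounter("E1", note_text="Plan reviewed.\n-headache, +nausea\n"))
        mentions = extract_advanced(corpus, lexicon, assoc_table)
        by_concept = {m.concept_id: m for m in mentions}
        assert by_concept["headache"].asserted is False
        assert by_concept["nausea"].asserted is True
        assert all(m.provenance == "template" for m in mentions)

    def test_longitudinal_disambiguation_across_encounters(self, lexicon, assoc_table):
        corpus = make_corpus(
            make_encounter("E1", "P1", note_text="Reports headache and photophobia."),
            make_encounter("E2", "P1", date=dt.date(2011, 4, 1), note_text="Pt with MA."),
            make_encounter("E3", "P2", note_text="Followed for lung cancer. Known tumor."),
            make_encounter("E4", "P2", date=dt.date(2011, 4, 2), note_text="Pt with MA."),
        )
        mentions = extract_advanced(corpus, lexicon, assoc_table)
        resolved = {m.encounter_id: m.concept_id for m in mentions
                    if m.provenance == "disambiguated"}
        assert resolved == {"E2": "migraine_with_aura", "E4": "mass"}

    def test_mention_offsets_round_trip_on_generated_corpus(self, lexicon, assoc_table):
        cfg = dataclasses.replace(syn.default_profile(seed=5), n_patients=40)
        corpus, _truth = syn.generate_corpus(cfg)
        notes = {e.encounter_id: e.note_text for e in corpus}
        mentions = extract_advanced(corpus, lexicon, assoc_table)
        assert mentions  # the generated notes exercise the extractor
        for m in mentions:
            assert notes[m.encounter_id][m.start:m.end] == m.surface

    def test_perfect_recall_with_rendering_noise_disabled(self, lexicon, assoc_table):
        cfg = dataclasses.replace(
            syn.default_profile(seed=9), n_patients=60,
            abbreviation_prob=0.0, template_prob=0.0,
            negated_absent_prob=0.0, distractor_prob=0.0)
        corpus, truth = syn.generate_corpus(cfg)
        predicted = presence_set(extract_advanced(corpus, lexicon, assoc_table))
        narrated = {(r.encounter_id, r.concept_id) for r in truth if r.narrative_rendered}
        assert narrated <= predicted  # every narrated concept recovered
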