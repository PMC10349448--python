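# Methods

## Study emulation

The package reproduces a two-arm extraction comparison on one shared,
preselected encounter corpus. An *encounter* is one patient–physician–date
visit carrying three structured fields (problem list, medication list, open
claims; coded entries under ICD9/ICD10/DRUG) and one free-text note.
Preselection keeps encounters containing at least one of the study terms
(*migraine*, *headache*, *rizatriptan*, *sumatriptan*), case-insensitive
substring on the raw note by default; matching structured codes is available
behind a flag (`filter --match note_text,structured_codes`) since enrichment
filtering is about data relevance, not assertion, and word-boundary rules
would only lose recall there. The identical filtered set feeds both arms so
preselection cannot bias the comparison.

## Traditional arm

Pure code-map lookup over the three structured fields; one hit per coded
entry, duplicates preserved (encounter-level de-duplication belongs to
evaluation, keeping the concept-occurrence vs. encounter-occurrence
distinction intact). Symptom concepts *do* have diagnosis codes in the
shipped map (e.g. R11.0 nausea, H53.14 photophobia): the arm's near-zero
symptom recall is a documentation-behaviour effect modelled by the
generator, not an impossibility of coding.

## Advanced arm

Deterministic rule-based NLP; no learned components, so behaviour is fully
inspectable and reproducible.

* **Segmentation** splits on sentence-final punctuation and newlines.
  Clinical notes are newline-structured; abbreviation-aware statistical
  segmenters would add a model dependency for little gain here.
* **Matching** is a case-insensitive, whole-token, longest-match-first
  dictionary scan ("asthma" never matches the abbreviation "HA";
  "migraine with aura" suppresses the contained "migraine"). Ambiguous
  surfaces emit all candidate senses.
* **Attributes** follow a trigger–scope design: negation triggers (*no,
  denies, without, not, negative*) and historical triggers (*history of,
  prior, past*) preceding the mention apply unless a scope terminator
  (*but, however, although, ";"*) intervenes; severity cues
  (*mild/mod/moderate/severe*) must be adjacent (≤ 2 tokens before the
  mention). The scope rule is the standard clinical-negation treatment;
  only the trigger inventory is a package choice.
* **Templates**: a line consisting entirely of sign-prefixed tokens
  ("-headache, +nausea") is parsed as review-of-systems shorthand. `+`
  asserts; `-` is a *provisional* negative that is dropped when the same
  concept has an asserted free-text mention elsewhere in the encounter
  (free text wins). Template lines are excluded from sentence-level
  matching — otherwise "-headache" would re-match as a positive free-text
  mention and defeat its own negative. Ambiguous surfaces inside templates
  are skipped rather than routed to disambiguation; a sign token carries no
  sentence context to score against.
* **Disambiguation** resolves an ambiguous surface against the union of the
  patient's asserted concepts across *all* encounters (a retrospective
  study sees the whole record; the candidates' own senses are excluded from
  the context). Each sense scores the sum of its association-table weights
  against the context; the top sense wins only if it strictly beats the
  runner-up by at least `margin` (default 0: any strictly positive lead).
  Ties and empty evidence abstain — the mention is dropped, trading a little
  recall for not asserting a wrong sense. The shipped weight table is a
  small, inspectable stand-in for a learned clinical-association resource;
  it encodes migraine-with-aura ↔ headache/photophobia/migraine and
  mass ↔ lung-cancer/tumor affinities and is user-replaceable (TSV).

The abbreviation inventory in the shipped lexicon (HA, MA, lung ca, …) is a
plausible clinical reconstruction, not a published standard. Conjunctive
abbreviations ("N/V" = nausea *and* vomiting) are deliberately omitted:
they fit neither the unambiguous nor the pick-one-sense model, and
mis-modelling them as a disambiguation problem would be worse than leaving
them out. "Migraine with aura" is a distinct lexicon concept that rolls up
to migraine at evaluation time (configurable via `roll_up`).

## Reference standard

Two annotators label every encounter; pairings rotate across batches.
Cohen's κ = (p_o − p_e)/(1 − p_e) is computed per concept on binary
per-encounter presence — the same reduction the recall endpoint uses — and
averaged unweighted over (batch, concept); the degenerate p_e = 1 case
(both annotators one-class, which forces perfect agreement) returns 1 by
convention. Span mismatches with concept agreement count as agreement, since
the evaluation unit is the encounter. The study requirement is mean κ ≥ 0.8,
computed prior to any disagreement resolution; adjudication then keeps
agreed labels and takes the third annotator's verdict on disputes, so every
reference label originates from agreement or the tiebreaker.

## Evaluation

Encounter-level binary presence is the primary surface: presence never
propagates across a patient's encounters, only asserted labels create
presence, and negated mentions never do. Precision is reported `NA` (not 0)
when an arm identifies nothing. Attribute-strict matching
(temporality/severity must also agree) exists as an option but is off by
default; the endpoints concern concept identification. Occurrence-level
counts (`count_occurrences`) are descriptive companions, not the metric
denominator — the denominator question is genuinely ambiguous, and the
encounter level is the one the success criterion is defined on.

The chi-square is Pearson's on [[TP, FN]] per arm, no continuity correction
(counts in the hundreds to thousands) and no multiple-testing adjustment
(per-concept tests are reported individually). Degenerate tables (a zero
margin) return χ² = 0, p = 1; expected cells < 1 attach a warning. The
per-concept success flag requires the advanced arm to lead and to reach
recall ≥ 80% or an absolute difference ≥ 25 percentage points; the
report-level summary also gives per-arm mean recall across concepts.

## Synthetic corpus generator

What it emulates: a migraine-enriched tertiary-care extract (default
1,508 patients × 4 encounters = 6,032) with per-concept clinical
prevalence, conditional symptom enrichment under migraine (lift 2.0 by
default — a package choice, not an external estimate), and independent
structured/narrative documentation channels. Notes are assembled from a
sentence-template bank (complaint, denial, plan, review-of-systems lines)
so that every extractor rule is exercised under full control; every
rendered asserted mention is recorded with exact offsets in the truth file.

Default calibration (`CALIBRATION`): narrative documentation probabilities
u_c sit at the advanced-arm recall profile the study design anticipates
(0.968 migraine, 0.929 headache, 0.86–0.95 symptoms, 0.98–0.99 drugs) and
structured probabilities s_c at the traditional-arm profile (0.666, 0.296,
0–0.179, 0.80). Truth prevalence is back-computed as
p_c = count / (n · u_c · (1 + multiplicity)) so the *expected number of
narrated mentions* per concept hits the target occurrence counts (2,642
migraine, 6,530 headache, …); migraine's denominator adds the
distractor-channel term. Mention multiplicities (0–0.37 extra mentions,
Poisson) reflect that headache-type complaints are restated within a note
more often than drug mentions.

Noise channels, all per-encounter Bernoulli: abbreviation rendering (0.3,
unambiguous abbreviations only), review-of-systems templates (0.15),
explicit denial of absent concepts (0.10), and ambiguous-abbreviation
distractors (0.05): a migraine-positive encounter may carry "Pt with MA"
(truth: migraine with aura), while patients with no migraine anywhere on
record may carry a lung-cancer/tumor context with "Pt with MA" (truth:
mass) — the two directions the disambiguator must separate. Restricting the
oncology distractor to migraine-free patients keeps the mass sense's
evidence dominant, mirroring the real-world fact that the two readings of
"MA" live in different patient populations.

Annotator simulation uses asymmetric error — miss probability 0.03,
false-positive probability 0.002 — because trained annotators rarely
hallucinate concepts; symmetric flip noise would collapse chance-corrected
agreement for rare concepts (for a concept present in 2% of encounters, a
3% symmetric flip rate alone drives κ toward 0.3). With these rates mean κ
lands near 0.9 across the ten concepts. The third annotator labels every
encounter in the batch, so each dispute has a verdict.

All randomness flows through one `random.Random(seed)` stream; identical
(config, seed) pairs produce byte-identical corpora, truth files and
reports.

### What the generator does not model

Realistic clinical language (sentence variety is template-bank deep),
historical/temporal narrative ("h/o migraine" is detected but never
generated), misspellings, section structure, coding errors in structured
fields (structured-arm precision is therefore near 1 by construction),
inter-annotator bias beyond independent noise, and disease progression over
calendar time. Passing tests on this corpus therefore demonstrate that the
extraction and evaluation machinery is correct and that the arms recover
the configured documentation profile — not that the NLP rules would reach
these recalls on real tertiary-care notes.

## Numerical and degenerate-input choices

Character offsets are 0-based half-open everywhere; surfaces always equal
`note_text[start:end]`. Dates are ISO 8601, files UTF-8 JSON Lines (one
record per line), TSV for knowledge tables. Empty corpora are legal
everywhere except kappa (an empty encounter set is an error). Duplicate
encounter ids are fatal at read time with both line numbers; malformed
lines are collected and reported together. F1 is 0 when TP = 0 and raises
when precision is undefined. Problem sizes in the test suite (40–500
patients for property tests, the full 6,032-encounter profile for the
end-to-end threshold check, 2,000 true-positive encounters per concept for
parameter recovery at 3 binomial standard errors) were chosen to make
sampling error small relative to the margins being asserted.
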