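# Methods

## The rules-based context model

The RB arm follows the ConText family of clinical negation systems.  Text
is segmented into sentences (terminators `.!?` followed by whitespace;
newlines before list items or section headers; a header line such as
`PMH:` forms its own segment).  Within each sentence, all target patterns
are matched case-insensitively on word boundaries; overlapping matches are
resolved longest-first, ties to the leftmost.  Modifier matches that
overlap a chosen target span are discarded, so a modifier token embedded in
a target surface form never fires.

Scope is sentence-bounded by construction: a forward modifier covers the
characters from its end to the sentence end, a backward modifier from the
sentence start to its own start, a bidirectional modifier the whole
sentence.  A mention is *absent* iff at least one negation, historical or
hypothetical modifier's scope overlaps it (logical OR); all in-scope
modifiers are recorded with the mention.  There is no termination-term
truncation ("but", "however") in this version; that is a known extension
point, and section-aware handling of medical-history lists is a documented
limitation (a bare "GI bleed" in a PMH list without an explicit historical
cue is read as present).

De-identification placeholders of the form `[**...**]` are masked to
whitespace before matching, so they can neither create nor negate mentions,
while all reported character offsets index the original text.

### The knowledge base

The packaged lexicon has exactly 16 target stems.  Nine come directly from
the term-frequency analysis of bleeding language in ICU notes (bleed,
hemorr, hematoma, BRBPR, GIB, ICH, SAH, SDH, melena); seven are
reconstructions from standard clinical bleeding vocabulary (ecchymos-,
epistaxis, hematemesis, hematochezia, hemoptysis, hematuria,
coffee-ground) and are flagged as such in the TSV.  Abbreviation patterns
require a full-token match so `SAH` never fires inside a longer word.
Lexicons are tab-separated so clinicians can audit and edit them; every
rule carries example surface forms, and validation asserts each example is
matched by its own pattern.

### Note-level classification

Three per-note quantities — bleeding-present mentions, bleeding-absent
mentions, total mentions — are swept over integer thresholds; the
sensitivity-maximizing (quantity, threshold) pair is selected, ties broken
by specificity, then lower threshold, then quantity order.  Thresholds
below 1 are excluded because threshold 0 trivially labels every note
positive; if no threshold ≥ 1 detects any positive note, the degenerate
threshold-0 rule is returned.  The C statistic is pairwise concordance
with ties counted one half, computed as the area under the ROC curve.

## The supervised arm

- **Features.** Raw-count TF over all 1–3-grams of lowercased,
  punctuation-stripped tokens; smoothed idf `ln((1+N)/(1+df)) + 1`; L2 row
  normalization.  Out-of-vocabulary n-grams in unseen notes are dropped.
- **Selection.** χ² association between non-negative feature mass and the
  label, keeping k = 100 features; boundary ties resolve in vocabulary
  order.  A `binary=True` variant reduces each feature to presence/absence
  and scores the full 2×2 contingency χ².  By default selection is refit
  inside every cross-validation fold (no selection leakage); a
  `select_once` flag reproduces the simpler select-once-on-train variant.
- **Models and grids.** SVM: C ∈ {0.1, 1, 10, 100} × kernel ∈ {linear,
  RBF}.  Extra trees: n_estimators ∈ {100, 300, 500} × max_depth ∈ {∞, 10,
  30}.  Grid search uses stratified k-fold CV scored by sensitivity —
  sensitivity is the priority metric throughout, since a missed bleed costs
  more than a false alarm.  k = 10 folds by default, reduced to the
  minority-class count when a corpus is too small to stratify 10 ways.
- **Down-sampling.** All minority-class notes are kept and the majority
  class is sampled without replacement to the same count (seeded), giving
  the `-DS` variants their class-balanced training sets (e.g. 990 notes
  with 225 positives → 450).
- **Conv-net.** Notes are token sequences (padded/truncated to `max_len`,
  default 100) over a trainable embedding table (dimension 100) learned
  jointly with the network — no external embedding file is required.  The
  architecture is four hidden layers in conv/pool alternation: conv1d
  (width 3, 64 filters, ReLU) → max-pool (width 2) → conv1d (width 5, 64
  filters, ReLU) → max-pool; the second pool is global over the remaining
  sequence so the output layer — one dense unit with sigmoid — sees a
  fixed-size vector.  Binary cross-entropy loss, Adam (lr 1e-3), a fixed
  seeded 80/20 train/validation split, early stopping on validation loss
  (patience 3) with best-weights restore, prediction threshold 0.5.  The
  forward and backward passes are implemented directly on numpy, which
  keeps training bit-deterministic for a given seed.

## Evaluation statistics

Metrics use the diagnostic-test convention with bleeding-present positive;
zero-denominator quantities are reported as explicit undefined markers,
never silent zeros.  The F score is the harmonic mean of sensitivity and
PPV.  The McNemar comparison is computed on correctness against the gold
standard (the standard convention for paired diagnostic tests; comparison
on raw label agreement is the documented alternative).  The p-value is the
exact two-sided binomial for fewer than 25 discordant pairs and the
continuity-corrected χ² statistic `(|b−c|−1)²/(b+c)` otherwise — the
correction keeps the asymptotic p within about 0.002 of the exact value at
moderate discordant counts, where the uncorrected statistic can be off by
more than 0.1.  Both routes are available via a flag.  The sensitivity
difference carries a paired Wald 95% CI restricted to gold-positive notes;
the CI method is a package choice, as none is standard for this design.

## The synthetic-note generator

The generator emulates adult ICU notes: HPI / PMH / ALLERGIES / A&P
section headers, affirmed bleeding phrases, negated ("Patient denies
{target}"), historical ("History of {target} several years ago") and
hypothetical ("Transfuse if {target} recurs") references, distractor
sentences, and bracketed de-identification placeholders.  Default
prevalence is 0.225 — the bleeding-present rate of the ICU population the
generator emulates — with on average 1.6 affirmed mentions per positive
note, absent-type mention probabilities of 0.35 / 0.2 / 0.2
(negated / historical / hypothetical) and 3 distractor sentences per note;
these are fixed study conditions, not tuning knobs.  Every bleeding phrase
comes from a versioned plain-text template bank instantiated with a
lexicon surface form, so gold mention spans are exact; the positive-note
count is `round(n·prevalence)` half-up, and generation is byte-identical
for equal parameters.

What it does *not* emulate: misspellings, ambiguous abbreviations (MS,
ICH-as-typo), copy-forward duplication, ungrammatical fragments, bleeding
phrasing outside the template bank, and genuinely novel vocabulary.
Perfect rules-engine recovery on clean synthetic corpora therefore shows
internal consistency of engine and generator, not real-world accuracy; on
real ICU text both arms perform far from perfectly.  An `adversarial` mode
splits the modifier and target across sentence boundaries, which any
same-sentence scope rule must misread — it is used as a regression canary
that must strictly lower specificity.

## Problem sizes and determinism

The acceptance script runs the full comparison at the emulated study scale
(990 training notes with 225 positives, 660 test notes at 22.1%
prevalence) and the recovery canary at 500 notes; the test suite uses
smaller corpora (60–500 notes) with reduced grids and conv-net budgets,
sizes chosen so the whole suite exercises every component end to end while
staying quick to run.  All randomness flows through explicit integer
seeds (numpy `default_rng`, sklearn `random_state`), and the train/eval
report serializes to byte-identical JSON across repeated runs with the
same config and corpus.

## Known limitations

- Same-sentence scope only; no termination terms, no section demarcation.
- Reconstructed lexicon stems approximate, not reproduce, the original
  curated regex tables; real-corpus performance depends on that curation.
- The conv-net is a minimal implementation (single filter width per layer,
  no dropout or batching heuristics); it is the weakest model family on
  small corpora, as expected for data-hungry methods.
- Note-level classification only; no encounter/patient aggregation, no
  bleeding-site or severity subtyping.
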