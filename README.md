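# bleednlp

Bleeding is one of the most common complications of hospital care, and
finding bleeding *events* at scale — across thousands of ICU notes — is a
prerequisite for any model that tries to predict or prevent them.  Billing
codes miss most events and chart review does not scale, but clinicians
document bleeding in free text ("right femoral hematoma", "patient denies
bleeding").  `bleednlp` detects clinically relevant bleeding at the note
level from that text, for informaticists and clinical researchers doing
EHR phenotyping, safety surveillance, or outcome labeling.

The package implements two complete detection arms plus the statistics to
compare them:

- **Rules-based (RB) arm.** A target/modifier context classifier in the
  ConText/NegEx family.  A knowledge base of 16 bleeding target stems
  (`bleed`, `hemorr`, `hematoma`, `BRBPR`, `GIB`, `ICH`, `SAH`, `SDH`,
  `melena`, ...) and negation / historical / hypothetical modifier rules
  assigns every mention a polarity: a mention is *bleeding-absent* iff an
  in-scope modifier covers it within the same sentence (forward modifiers
  scope to the sentence end, backward to the sentence start).  Note-level
  labels come from a count heuristic selected by ROC sweep over the three
  per-note quantities n_present, n_absent, n_total; the operating rule is
  *positive iff at least one bleeding-present mention* (n_present ≥ 1).
  The C statistic is the pairwise concordance P(score⁺ > score⁻) with ties
  counted ½.
- **Machine-learning arm.** TF-IDF over all 1–3-grams
  (idf = ln((1+N)/(1+df)) + 1, L2-normalized rows), χ² feature selection to
  a 100-dimensional representation, then SVM and extra-trees classifiers
  tuned by stratified cross-validated grid search scored by sensitivity,
  plus a word-embedding conv-net (conv1d → max-pool → conv1d → max-pool →
  dense sigmoid, binary cross-entropy).  Each family is trained on the full
  training set (`-FS`) and on a class-balanced down-sampled subset (`-DS`),
  six variants in all.
- **Evaluation.** Sensitivity, specificity, PPV, NPV, accuracy and the
  F score (harmonic mean of sensitivity and PPV), and a McNemar test on the
  discordant correct/incorrect pairs of two classifiers, with a paired Wald
  95% CI on the sensitivity difference.

Because real ICU corpora are access-restricted, the package ships a
synthetic-note generator that emulates their structure (section headers,
affirmed/negated/historical/hypothetical bleeding phrases, distractor
sentences, bracketed de-identification placeholders) with gold labels and
exact gold mention spans, so the whole pipeline is testable offline.

## Worked example

```python
import numpy as np
import bleednlp as b

lex = b.default_lexicon()
for m in b.find_mentions(b.Note("n1", "HPI:\nPatient denies bleeding. New hematoma on exam."), lex):
    print(m.stem_id, m.polarity)
# bleed absent
# hematoma present

corpus = b.generate_corpus(b.GenParams(n_notes=500, prevalence=0.22,
                                       distractor_rate=0.0, seed=7))
mentions, counts, pred = b.annotate_corpus(corpus.notes)
m = b.metrics(b.confusion(pred, corpus.labels()))
print(m.sensitivity, m.specificity)
# 1.0 1.0
```

The first block classifies the negated mention (`denies` scopes forward
over `bleeding`) as absent and the affirmed hematoma as present; the second
generates a clean 500-note corpus at 22% prevalence and shows the rules
engine recovering the generated gold labels exactly.

The same pipeline is available from a shell:

```bash
bleednlp simulate --n-notes 500 --seed 7 --out notes.jsonl
bleednlp annotate notes.jsonl --predictions-out pred.csv
bleednlp train-eval notes.jsonl --out report.json   # 7-model comparison
```

## Layout

| Module | Role |
| --- | --- |
| `bleednlp.lexicon` | knowledge base: target stems and context modifiers, TSV I/O |
| `bleednlp.context` | sentence segmentation, mention finding, modifier scope |
| `bleednlp.note_classifier` | mention counts, heuristics, ROC / C statistic |
| `bleednlp.ml` | TF-IDF n-grams, χ² selection, down-sampling, SVM/ET/CNN |
| `bleednlp.evalstats` | confusion metrics, F score, McNemar comparison |
| `bleednlp.synth` | synthetic gold-labeled clinical-note corpora |
| `bleednlp.pipeline` / `bleednlp.cli` | orchestration and command-line surface |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
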