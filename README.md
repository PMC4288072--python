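# adetag

Medication and adverse-event named-entity tagging for spontaneous
drug-safety report narratives.

Post-marketing surveillance databases (FAERS-style spontaneous reporting
systems) pair structured fields with free-text narratives, and much of
what matters for pharmacovigilance — concomitant medications, dosing,
severity, the clinical course of an adverse event — lives only in the
narrative. `adetag` is a toolkit for extracting that information as
typed entity spans. It targets nine entity classes:

`Medication`, `Dosage`, `Route`, `Frequency`, `Duration`, `Indication`,
`AdverseEvent`, `OSSD` (other signs, symptoms and diseases), and
`Treatment`.

The package is aimed at NLP and pharmacovigilance researchers who need a
transparent, fully inspectable pipeline: every component — tokenizer,
feature extractor, sequence model, evaluation — is implemented in the
open and covered by enumeration- or oracle-based tests.

## What is inside

- **Linear-chain CRF tagger** built from first principles. Entity spans
  are BIO-encoded (19 labels); the model scores a label sequence
  *y*₁…*y*_T for a token sequence *x* as

  score(y | x) = b[y₁] + Σ_t θ·f(x, t, y_t) + Σ_t T[y_{t−1}, y_t] + e[y_T]

  with P(y | x) = exp(score) / Z(x). Training maximizes the
  ℓ2-regularized conditional log-likelihood with L-BFGS; the partition
  function Z and the marginals come from forward–backward and decoding
  from Viterbi, all in log space. Transitions that violate the BIO
  grammar are hard-masked by default.
- **Seven switchable feature families** (orthographic default, affix,
  morphological, syntactic, semantic-lexicon, negation/hedge scope,
  discourse connectives) with an ablation runner that emits
  addition-style and removal-style result tables.
- **Baselines**: a dictionary tagger over a packaged drug/adverse-event
  lexicon (semantic types T200 → Medication, T047 → AdverseEvent) and a
  per-token multinomial Naive-Bayes tagger.
- **Evaluation machinery**: strict (exact span + class) and unstrict
  (same class, ≥ 1 shared token) matching; per-class and micro/macro
  P/R/F1; token-level Cohen's κ per class in both modes; document-level
  k-fold cross-validation with mean (SD) reporting; paired t-tests and
  Pearson correlations; a three-way disagreement taxonomy (boundary /
  missed / category).
- **Synthetic corpus generator** emulating a double-annotated corpus of
  122 adverse-event-report narratives (~190 words per document, SD
  ~130; class frequencies proportional to the reference distribution;
  singleton surfaces for data sparseness; punctuation-attachment
  noise), plus a perturbation model that simulates a second annotator
  with controllable boundary/miss/confusion rates. Real report
  narratives are not redistributable, so all experiments here run on
  generated corpora with exact gold spans and a full provenance ledger.

## Worked example

```
adetag generate --out demo --n-docs 20 --seed 7
adetag train    --corpus demo --features all --max-iter 100 --out demo/model.json
adetag tag      --corpus demo --model demo/model.json
adetag evaluate --corpus demo --pred-annotator system
```

which prints (training-set evaluation, so scores are near-perfect —
use `adetag crossval` for honest held-out numbers):

```
class         precision  recall   f1      tp   fp  fn
Medication    0.9865     0.9865   0.9865  220  3   3
Dosage        1.0000     1.0000   1.0000  31   0   0
...
AdverseEvent  0.9786     0.9786   0.9786  274  6   6
overall       0.9822     0.9822   0.9822  608  11  11
```

`precision` is TP/(TP+FP) over strictly matched spans, `recall`
TP/(TP+FN), `f1` their harmonic mean; `overall` pools counts over all
nine classes. The few residual errors come from the generator's
punctuation-attachment noise: gold spans that inconsistently include a
trailing period are a documented error source in annotated report
narratives, and the generator reproduces it.

The generator also writes a simulated second annotator, so the
agreement machinery can be exercised immediately:

```
adetag agreement --corpus demo
class         kappa_strict  kappa_unstrict
Medication    0.8687        0.8994
AdverseEvent  0.8510        0.8746
...
disagreement  tokens  share_pct
boundary      28      15.82
missed        145     81.92
category      4       2.26
```

κ is token-level chance-corrected agreement per class; unstrict mode
forgives pure boundary differences, so κ(unstrict) ≥ κ(strict). The
disagreement table assigns every disagreeing token to exactly one of
the three categories.

Cross-validation and the ablation tables:

```
adetag crossval --corpus demo --features all --folds 10 --seed 0 --out cv.tsv
adetag ablate   --corpus demo --folds 10 --seed 0 --out ablation/
```

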