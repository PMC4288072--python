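# Methods

This note documents the models and procedures implemented in `adetag`,
the choices made where the design was genuinely open, and what the
synthetic experiments do and do not demonstrate.

## Task and data model

The unit of analysis is a narrative document with typed, non-overlapping
character spans from nine entity classes (Medication, Dosage, Route,
Frequency, Duration, Indication, AdverseEvent, OSSD, Treatment). Offsets
are 0-based, half-open. Within one annotator's set, mentions may not
overlap — guideline-driven corpora resolve overlaps before release, and
the non-overlap invariant is enforced at load time rather than silently
repaired.

**Tokenization.** Whitespace splitting followed by edge-punctuation
detachment (`. , ; : ! ? ( ) " ' [ ] { }`), with three deliberate
exceptions: `%` stays attached to a numeric quantity (`0.9%`), digit- or
code-bearing forms stay intact (`280`, `T200`, `G-CSF`, `NCI/CTC`), and
a slash between plain lowercase alphabetic words splits (`and/or`).
Error analyses of report narratives show punctuation attachment
(`neutropenia.`) is a real source of span disagreement, so the rule set
is explicit and idempotent (property-tested) rather than borrowed from a
general-purpose tokenizer whose behaviour here would be incidental.

**BIO encoding.** Spans become per-token labels (19-label alphabet:
`O` + `B-`/`I-` per class). BIO rather than BIOES keeps the transition
table small and matches the scheme of the classical biomedical NER
toolkits this package's tagger is patterned on. At decode time an
`I-X` with an illegal predecessor is repaired to `B-X`: this preserves
the model's positive token decisions instead of dropping them, and with
transition masking on (the default) the repair never fires.

## Lexicons

A packaged lexicon maps terms to semantic type codes and codes to
classes (`T200` → Medication, `T047` → AdverseEvent, the two
dictionary-taggable classes). Matching is case-insensitive exact
longest-match, greedy left-to-right — no stemming or variant generation,
since any normalization would make the dictionary baseline's behaviour
untestable against the brute-force matching oracle. The packaged lists
(230+ drug surfaces, 250+ adverse-event surfaces, plus pools for the
other classes used only by the generator) are plain TSV and fully
user-overridable; they stand in for a licensed terminology service,
which cannot be redistributed.

Negation, hedge and connective cues ship as one-cue-per-line text files.
Cue scope is forward-only: from the cue to the first scope terminator,
sentence boundary, or a 6-token cap, whichever comes first. This is a
deliberately simple, testable scope rule in the NegEx tradition; the
cue *feature* contract (which tokens carry `neg:cue` / `neg:in_scope`)
is what the tagger consumes, so a more sophisticated scope detector can
be swapped in behind the same interface.

## Feature families

Seven families, each independently switchable; the extraction contract
guarantees (and tests verify) that the all-families output is the exact
set union of the per-family outputs, so ablation results compose.

- `default`: lowercased word identity and word shape for the token and
  its neighbours in a ±1 window (window width configurable). This is
  the baseline bag-of-words/orthographic template every tagger variant
  keeps.
- `affix`: lowercased 3- and 4-character prefixes/suffixes; shorter
  tokens contribute the whole token in each slot.
- `morphological`: digit/capitalization/all-caps flags, alphanumeric
  order (letters-then-digits etc.), hyphen/comma/punctuation presence.
- `syntactic`: POS tag, phrasal class (NP/VP/other) and left-neighbour
  POS (NONE at sentence starts). The provider is a pluggable annotator
  contract; the bundled implementation is a rule-and-lexicon tagger
  (closed-class word lists, suffix heuristics, and the NP chunk rule
  DT? (JJ|CD)* (NN|PRP)+). A full constituency parser would add a heavy
  dependency while the tagger only consumes these three values per
  token.
- `semantic`: semantic type code and match position (B/I) for tokens
  covered by a longest-match lexicon hit.
- `neghedge`: cue and in-scope indicators for negation and hedging.
- `connective`: a cue indicator on the first token of each discourse
  connective and a sentence-level presence flag.

## The CRF

Linear-chain CRF with begin/end potentials:

    score(y | x) = b[y₁] + Σ_t U(t, y_t) + Σ_{t>1} T[y_{t−1}, y_t] + e[y_T]

where `U(t, y)` sums the weights of the indicator features active at
position t paired with label y (plus an always-on bias feature).
Inference is entirely in log space with −∞ for masked transitions; no
scaling tricks are needed at narrative lengths (hundreds of tokens).
The dynamic-programming kernels (forward, backward, Viterbi, per-
sequence gradient accumulation) are numba-compiled loops, generic in
the label count — the enumeration tests exercise them on tiny alphabets.

- **Masking.** O→I-X, B-Y→I-X and I-Y→I-X (Y≠X), and I-X at sequence
  start are hard-masked by default; masked parameters are frozen at
  zero (excluded from gradient and regularizer) since the lattice never
  reads them. Masking can be disabled to mimic unconstrained taggers.
- **Training.** Full-batch ℓ2-regularized NLL, objective
  Σ(log Z − gold score) + (λ/2)‖w‖², minimized with L-BFGS-B
  (deterministic given corpus order; line search guarantees descent
  across accepted steps). Defaults: λ = 1.0, `max_iter` = 200, stop when
  the projected-gradient max-norm < 1e-5. The reference toolkits do not
  publish their regularization constants; these defaults are declared,
  not inferred, and exposed as flags.
- **Tie-breaking.** Viterbi backtracks choose the lowest label index on
  ties; `O` is index 0, so an untrained model deterministically outputs
  all-O.
- **Serialization.** Versioned JSON: label alphabet, feature→row index,
  weights, feature configuration, mask flag, training metadata.

Verification: log-partition, Viterbi and forward–backward marginals are
checked against exhaustive path enumeration (≤ 4 positions × 4 labels,
200 random lattices, 1e-9 agreement), and the analytic gradient against
central differences (relative error < 1e-5).

## Baselines

**Dictionary tagger:** emits every longest lexicon match whose type maps
to a class; by construction it can only produce Medication and
AdverseEvent mentions. **Naive Bayes:** per-token multinomial NB over
the same indicator features with add-one smoothing (the standard
minimal choice for binary indicator features), decoded with the BIO
repair rule; ties in the per-token argmax resolve to the first label in
the canonical alphabet (O). The NB classifier is scikit-learn's
`MultinomialNB` behind the package's own feature/label plumbing.

## Evaluation

- **Matching.** Strict = identical span and class; unstrict = same
  class with at least one shared token. Matching is one-to-one and
  greedy by position. Tagger scores use strict matching by default
  (unstrict is available behind a flag); unstrict is primarily an
  agreement notion.
- **P/R/F1.** Per class and pooled. The pooled ("overall") score is
  micro-averaged; macro is also emitted for transparency since
  published overall scores do not always state which average they use.
- **Cohen's κ.** Token level, per class, binary in-class/out-of-class,
  κ = (p_o − p_e)/(1 − p_e) over the pooled 2×2 table (O–O agreements
  included in p_o). In unstrict mode a token covered by only one
  annotator counts as agreement when its covering mention overlaps a
  same-class mention of the other annotator. Degenerate p_e = 1 is
  defined as κ = 1 if p_o = 1 else 0, with a logged warning.
- **Cross-validation.** Document-level k-fold; documents are shuffled
  by seed and dealt round-robin, so fold sizes differ by at most one
  (122 docs / 10 folds → eight folds of 12, two of 13). Reported SDs
  over folds are population SDs (ddof = 0).
- **Statistics.** Two-sided paired t-test on fold-wise differences
  (t-distribution, k−1 df; identical vectors → (0, 1); zero-variance
  nonzero difference → (±inf, 0) as the degenerate limit) and sample
  Pearson correlation.
- **Disagreement taxonomy.** Every token the two annotators label
  differently falls in exactly one category: *category confusion* (both
  annotate, classes differ), *boundary* (one covers the token and their
  mention overlaps a same-class mention of the other), *missed*
  (otherwise).

## Synthetic corpus

The generator emulates the measurable surface statistics of a
double-annotated 122-narrative adverse-event-report corpus:

- document word counts from a truncated normal (mean 190.2, SD 130.3,
  minimum 30 — the truncation point is a generator choice);
- mention density ≈ 0.146 mentions/word (3365 mentions over ~23,000
  words in the reference corpus), allocated per class by multinomial
  sampling with weights proportional to the reference class counts
  (AdverseEvent 1646, Medication 1152, Dosage 137, Indication 126,
  Route 107, OSSD 90, Treatment 62, Duration 24, Frequency 21);
- singleton surfaces: with probability `singleton_rate` (default 0.2, a
  generator choice: sparse singleton mentions are a documented major
  error source in this kind of corpus) a mention draws a surface used
  nowhere else — first unused lexicon/pool terms, then invented forms
  (morpheme-composed drug names, modifier+head adverse-event phrases,
  fresh numeric dosages/durations/frequencies) verified to contain no
  lexicon term;
- punctuation-attachment noise: with probability `punct_attach_rate`
  (default 0.05) a gold span absorbs an immediately following
  punctuation token, reproducing the boundary-inconsistency error mode.

Text is assembled from slot templates (treatment sentences consuming
Medication/Dosage/Route/Frequency/Duration/Indication, event sentences
consuming AdverseEvents with occasional negated OSSD attachments,
history/management sentences, and mention-free filler). Template
generation — rather than language modelling — keeps gold spans exact by
construction and gives the tagger the kind of local lexical context it
actually consumes. Every mention is recorded in a ledger with its
provenance and pre-noise core span, which makes two quantities exactly
computable without running the tagger: dictionary-baseline precision on
lexicon-exact spans (1.0 by construction, verified) and its strict
recall (the ledger's lexicon-coverage fraction).

**What the generator does not emulate:** discourse structure and
clinical chronology, referring expressions/anaphora, misspellings and
transcription noise, and class ambiguity beyond the explicit confusion
model. Template locality also makes context more predictive than in
real narratives. Cross-validation F1 on generated corpora (~0.97
overall) therefore demonstrates *parameter recovery under the stated
conditions* — that the training pipeline can learn the generating
regularities — not expected performance on real report narratives,
which is substantially lower for the real-data counterparts of this
design.

**Simulated second annotator.** Per mention, mutually exclusive events
sampled in the order boundary → miss → confusion: boundary shifts one
span edge by one token (skipping shifts that would create overlaps),
miss deletes the mention, confusion relabels it (AdverseEvent↔OSSD with
weight 0.7, the dominant confusion pair in annotated report corpora;
uniform otherwise). Defaults (0.05 / 0.18 / 0.015 per mention) were
derived once from the reference token-level disagreement mixture
(13.94% boundary / 79.69% missed / 6.36% category) by dividing each
share by its expected tokens-per-event (1 for boundary, the mean
mention length ≈ 1.6 tokens otherwise) at a total event rate of ~0.25;
`rates_for_token_shares` performs the same inversion for any target
mixture. The round trip — configure rates from the mixture, perturb,
recover the mixture from the disagreement report — closes to within 3
percentage points on 122 documents (5-seed average).

## Numerical and degenerate-input conventions

- All-masked lattices: log Z and Viterbi return −∞ with a warning;
  marginals raise.
- Empty documents tag to an empty mention list; empty text tokenizes to
  an empty token list.
- P or R with a zero denominator is 0; F1 is 0 when P + R = 0.
- Readers reject malformed records (bad offsets, unknown classes,
  labels outside the alphabet) rather than skipping them.
- κ over zero tokens raises; Pearson r over constant input raises.

## Problem sizes

The test and acceptance runs use the full 122-document corpus for
cross-validation and agreement experiments, 200 random lattices for the
enumeration checks, and 50 random instances for the gradient checks;
smaller 8–20-document corpora back the fast unit tests. These sizes
were chosen to match the reference study design (122 narratives,
ten-fold CV) while keeping a full suite run in the minutes range.

## Known limitations

- The rule-based POS annotator is intentionally crude; its errors feed
  the syntactic family, which on synthetic data contributes little
  (template text is already near-separable from lexical features).
- Exact dictionary matching has no term-variant handling, so the
  dictionary baseline's recall is a lower bound on what a terminology
  server with normalization would achieve.
- Kappa is computed at token level; mention-level agreement statistics
  would weight long mentions differently.
- The CRF is full-batch; corpora orders of magnitude larger than the
  study design would want a stochastic optimizer, which is out of
  scope.
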