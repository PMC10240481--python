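# Methods

This note documents the models and procedures implemented in
`litriage`, the parameters that matter, the design choices made where
the design was genuinely open, and the limitations of what the synthetic
test battery can show.

## The label space and roll-ups

The taxonomy is a strict three-level forest: every sub-subclass (leaf)
has exactly one subclass parent, every subclass one class parent. The
packaged default is the COAP living-evidence scheme (22 leaves → EPI /
BASIC / OTHER → ORIGINAL / NON-ORIGINAL); any other scheme with the same
shape can be loaded from a declarative JSON/YAML node list. Leaf order
is fixed by the specification document and is the column order of every
probability matrix; matrix files carry the leaf ids in their header and
are refused when the header does not match the active taxonomy, because
silent column misalignment is the dominant corruption risk in this kind
of pipeline. The snapshot used for default frequencies records two
spellings of one leaf ("Within-host modelling"/"modeling"); the spec
fixes the double-l form as the id and resolves the other via an alias
table.

Probability roll-up is exact summation over descendant leaves; inputs
must be nonnegative and sum to 1 within 1e-9 (single vectors) or 1e-6
(classifier rows, where float32 upstream arithmetic is common). Count
roll-up requires nonnegative integers and preserves the grand total.

## Corpus handling and splits

Records without a title or without an abstract are excluded before
training (with a per-document reason report); a missing source is not a
reason for exclusion — the composed classifier input simply omits it.
The input text is title, abstract, source concatenated in that order
with single spaces; the concatenation order is fixed, the separator is a
package choice.

Cross-validation uses k equal test sets tiling the corpus (k·test
fraction must be 1) with the remaining documents split into train/dev at
7:1, i.e. 70/10/20 at the default k = 5. Splits are stratified by leaf
label by default because leaves at 0.5% frequency would otherwise vanish
from folds; a leaf rarer than k documents relaxes stratification with a
warning, and a label-blind mode is available since the original
protocol's stratification is unknown. Splits are reproducible from the
seed.

## The baseline classifier

The packaged member model is a multinomial logistic regression over
lowercased word-count features (tokens `\w+`, minimum document frequency
configurable). The inverse-regularization strength C is selected from a
grid (default 0.001–10, five decades) by dev-set micro F1 — in this
single-label setting identical to accuracy. The wide grid matters at the
extremes: with no lexical signal the strongly regularized end collapses
to the prior-driven majority prediction instead of overfitting noise
tokens. Leaves absent from training receive probability 0 (with a
warning); a single-class training corpus degenerates to a constant,
still row-stochastic predictor. Training is deterministic given the
seed. Fitted models persist with the taxonomy fingerprint and refuse to
predict under a mismatched taxonomy. Externally trained models (e.g.
fine-tuned transformers) participate through the probability-matrix text
format; no gradient access to them is assumed anywhere.

## Ensembles, abstention, thresholds

Probability-sum scores are reported unnormalized (range [0, M]) with an
option to divide by M for plotting. Ties anywhere (argmax of a rolled
distribution, top summed score) go to the earlier label in canonical
order; this is a reproducibility choice.

A vote is cast when the member's top rolled-up probability is ≥ t_v
(inclusive). Inclusivity makes the binary-level guarantee exact: at
t_v = 0.5 the larger of two probabilities always reaches the threshold,
so all members vote and, with five voters at the class level, a static
threshold of 3 always decides. The decision rule requires the top tally
to be a *unique* maximum and to reach the effective threshold: static t
(an absolute count regardless of abstentions), majority (⌊M/2⌋+1 static,
⌊v/2⌋+1 dynamic over the v non-abstaining voters), or unanimity (M
static, v dynamic with v ≥ 1). Everything else — ties, insufficient
tallies, all-abstain — is UNKNOWN.

One property worth knowing: coverage is monotone non-increasing in the
vote threshold t, but **not** in t_v. Raising t_v can remove one vote of
a tied pair ({A:2, B:2, C:1} → {A:2, B:1}), converting an UNKNOWN tie
into a decision. The number of cast votes, by contrast, is monotone in
t_v. The test suite asserts the true monotonicities.

## Evaluation conventions

- Zero denominators: precision and recall are 0 when undefined, F1 is 0
  when tp = 0. This keeps macro averages defined for never-predicted
  rare leaves.
- Micro averages pool one-vs-rest counts; in single-label multiclass
  evaluation micro precision = recall = F1 = accuracy (asserted in the
  suite).
- AUC-ROC is macro one-vs-rest over the level's labels from rolled-up
  probabilities, trapezoidal; labels missing a truth class are skipped
  with a warning. The averaging scheme behind a single per-level AUC is
  a package choice; micro-OVR is the plausible alternative.
- Bootstrap CIs: documents resampled with replacement, default 2000
  resamples, 2.5/97.5 percentiles, bit-reproducible from the seed.
  Resamples on which the metric is undefined (e.g. one-class for AUC)
  are redrawn and counted.
- McNemar: exact two-sided binomial when the discordant count b + c is
  below 25, else chi-square with continuity correction
  (|b−c|−1)²/(b+c). The switch point is configurable; both variants are
  standard and the choice is documented rather than silent.
- Ranking: descending probability with ties to the earlier leaf; with
  exactly one relevant label AP@k reduces to 1/rank when the truth is
  within the top k. Hence P@1 = R@1 = MAP@1, R@L = 1 over all L leaves,
  and P@k ≤ 1/k.
- Abstention in metrics: decided-documents-only by default, with
  coverage reported alongside; a strict mode counts UNKNOWN as wrong for
  sensitivity analysis. The k-vote grid reports coverage 0 rows with NaN
  metrics rather than dropping them.
- Attribution toward the *predicted* subclass by default (a flag
  switches to the annotated one).

## Integrated gradients and word impacts

Attributions use the straight-line path from an all-zero baseline (an
empty document in count-feature space) with a midpoint Riemann
approximation; `steps` (default 50) controls the completeness error,
which is exactly 0 for linear scorers and ≤ 1e-3 for logistic scorers at
200 steps. For the baseline classifier the scorer is the analytic
softmax mass of a subclass's leaves, so no numeric differentiation is
involved. Sub-word scores (marked continuations, `#`-prefixed) average
into word scores; words pool by lowercased lemma via a small
rule-plus-exception lemmatizer (pluggable — any deterministic
string→string map); the report keeps lemmas with ≥ 5 occurrences and
positive mean score, ranked descending with lexicographic tie-break,
truncated to 20.

## The synthetic-data generator

The corpus generator emulates an annotation snapshot: leaf labels drawn
from the packaged frequency profile (0.5%–27.6% per leaf), three text
fields of background tokens (shared vocabulary, default 500 types)
mixed with per-leaf signature tokens at probability `signal_strength`.
Defaults: 5 signature types per leaf, titles of 4–10 tokens, abstracts
of 40–80, four source names. At signal 0 the text is uninformative and a
well-regularized classifier falls back to the prior; near 1 the task is
separable — both ends are asserted empirically.

The prediction simulator draws, per member and document, a modal label
equal to the truth with the member's configured accuracy; errors land on
a confusable leaf with same-subclass leaves weighted 3:1 over
cross-subclass, mirroring the intra-subclass confusion structure of real
nested taxonomies. The row is a Gamma-normalized distribution whose
modal mass has shape `concentration` (default 20; ~6 produces enough
soft rows for abstention thresholds to bite), with a swap guaranteeing
the argmax equals the modal label so configured accuracies are exactly
recoverable. A shared latent uniform correlates error events: agreement
0 gives independent errors (majority vote of five members at 0.8
accuracy then reaches the closed-form Σ_{j≥3} C(5,j)0.8^j 0.2^{5−j} ≈
0.942), agreement 1 with equal accuracies gives identical error sets
(majority accuracy = single-member accuracy).

What the generator does **not** emulate: real linguistic structure,
polysemy, field-length and vocabulary distributions, annotation noise,
temporal drift, or correlations between label and source. Passing tests
therefore demonstrate the correctness of the mechanics (roll-ups,
voting, metrics, attribution aggregation) and the qualitative behavior
of the pipeline, not the absolute performance attainable on real
literature.

## Problem sizes

The test suite and the acceptance script run at desk scale: corpora of
500–2000 documents for classifier checks, 5000 simulated documents for
parameter-recovery and ensemble-lift checks (standard error ≈ 0.006 on
an accuracy, comfortably inside the ±0.02 assertions), 4000 for ranking
baselines, and 2000 bootstrap resamples as the default CI setting.

## Known limitations

- The voting rules assume a single-label taxonomy; polyhierarchies and
  multi-label leaves are out of scope.
- The baseline classifier is a bag-of-words model; it exists to exercise
  the pipeline and to provide a differentiable scorer, not to compete
  with fine-tuned language models.
- The bootstrap treats documents as exchangeable; clustered sampling
  designs are not supported.
- The rule lemmatizer handles regular English plurals and a short
  irregular list only; plug in a full lemmatizer for serious
  interpretability work.
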