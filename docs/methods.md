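# Methods

## The classification problem

Input: an ordered list of symptom terms for one patient, where the order
carries information — the first three entries are by clinical convention
the *main symptoms*. Output: a ranked list of candidate diseases,
truncated to the top 3. The class variable is a disease label in the TCM
sense (a named pattern such as "cough" or "insomnia"); the features are
binary symptom presences. A recommendation *hits* when the true disease is
anywhere in the top 3 — the operating point of an assistant that shows a
clinician a short differential list.

## Estimators and the scoring algebra

All estimates are record-level Bernoulli presence counts: a symptom counts
once per record however often it appears. Writing N, N(d), N(s), N(d,s)
for the total, per-disease, per-symptom and pair counts,

    P̂(s|d) = N(d,s)/N(d),   P̂(s) = N(s)/N,   P̂(d) = N(d)/N.

The score of candidate d on input s₁…sₙ factors into per-symptom
likelihood-ratio operators op(sᵢ,d) = P̂(sᵢ|d)/P̂(sᵢ). This factored form
is algebraically identical to the classic Bayes quotient
Π P̂(sᵢ|d)·P̂(d)/Π P̂(sᵢ); the test suite checks the identity to 1e-12
relative on random models. Only diseases cooccurring with at least one
input symptom are scored (candidate restriction); symptoms never seen in
training are excluded from scoring and reported, since P̂(s) = 0 leaves
the operator undefined.

**Smoothing.** A pair with N(d,s) = 0 would zero the whole product, so the
conditional falls back to the Laplace form α/(N(d) + α·|V|), α = 1 by
default, with |V| the vocabulary size. Smoothing applies *only* to
non-cooccurring pairs; observed pairs use the unsmoothed MLE. Consequence
worth knowing: the smoothed pseudo-count is not scale-free, so duplicating
every record m times leaves all fully-observed scores bitwise unchanged
but shrinks the smoothed operators (more data = stronger evidence against
an unseen pair). The scale-invariance property holds exactly on the
observed-cooccurrence path and monotonically on the smoothed one; the
tests check precisely that.

**Main-symptom weighting.** gᵢ = w (default 2.0, configurable; meaningful
for w > 1) multiplies the operator of an input symptom in position
≤ n_main (default 3) when that symptom cooccurs with the candidate;
without cooccurrence the factor stays 1 — the smoothed operator is already
a strong demotion and is not additionally boosted. At w = 1 the weighted
and unweighted variants are bitwise identical. Because smoothing demotes a
non-cooccurring candidate by orders of magnitude while the boost is only a
small constant factor, weighting changes rankings rarely — exactly in the
mixed cases where top candidates differ in *which* main symptoms they
cooccur with. Its measured effect on hit accuracy is therefore small, and
can be zero on corpora dense enough that every candidate cooccurs with
every main symptom.

**Priors and the equal-probability variant.** Three prior modes:
empirical P̂(d); none (score = posterior-to-prior ratio, immune to class
imbalance in the prior); uniform. The uniform ("equal probability") mode
models an oversampled, class-balanced corpus analytically: prior 1/|D| and
marginal P̂(s) = (1/|D|)·Σ_d P̂(s|d), the exact limit of replicating each
class's records up to the least common multiple of the class counts
(`oversample_balanced` realizes that limit physically and the tests verify
the equivalence). The mixture is evaluated in exact rational arithmetic
and rounded to float once, so on an already balanced corpus it equals the
empirical marginal bitwise.

A consequence stated here so nobody rediscovers it the hard way: every
candidate is scored on the *same* input symptom list, so the marginal
Π 1/P̂(sᵢ) is a candidate-independent constant. Changing the marginal
(empirical → uniform mixture) or adding a constant prior (1/|D|) rescales
all scores equally and cannot change a ranking. Hence the no-prior and
equal-probability variants are ranking-equivalent, and differ from the
empirical-prior variant exactly by the P̂(d) factor. The eight variants
collapse to at most four distinct ranking behaviors (two prior families ×
weighting), plus the log/product distinction below. The variants are all
kept, because their *scores* differ (relevant when scores are thresholded
or displayed) and because the grid structure mirrors how this family of
algorithms is reported.

**Log form.** The product is computed exactly as written, so underflow on
very long symptom lists is possible; the log branch sums log(gᵢ·op) +
log(prior) instead and is the numerically safe form. Wherever no product
underflows to 0.0 the two rankings are identical (tested). The weighting
enters the log form multiplicatively inside the log — log(w·op) — never as
w·log(op). Although the log form is usually presented pairwise (classify
d₁ over d₂ when the log-ratio is positive), it is implemented as a
per-disease log score whose pairwise differences reproduce the pairwise
rule exactly, avoiding a tournament.

**Determinism.** Ties are broken by descending score then lexicographic
disease label. All randomness (fold assignment, corpus generation) flows
through explicit integer seeds.

## Corpus cleaning

Symptom strings are segmented on commas only — ASCII `,` and fullwidth
`，` — reflecting how the records are punctuated; no dictionary,
statistical or learned word segmentation, and no other punctuation splits.
Tokens are trimmed, deduplicated keeping first occurrence (presence is
binary; keeping the first occurrence preserves main-symptom positions) and
looked up in the synonym lexicon after whitespace/case folding; no fuzzy
matching. Unknown tokens are kept as raw terms by default, because the
intended use accepts natural-language symptom words rather than a closed
vocabulary; `drop_token` and `drop_record` policies are available. Rows
whose diagnosis field contains a comma are excluded as multi-disease
records (the comma is the only structure available for detecting them);
rows left without symptoms are excluded. Every exclusion and every
unmapped token is counted in the ingest report — unmatched input is the
main practical accuracy risk of this approach, so it is never silent.

## Evaluation protocol

Stratified k-fold cross-validation, default k = 3 (which also realizes a
2/3 train – 1/3 test ratio per fold; a `single_split` mode exists for
parity with plain holdout). Stratification deals each class's shuffled
records round-robin across folds with a rotating offset, so classes with
fewer than k records degrade gracefully instead of failing; a flag
disables it. All variants are evaluated on the same folds (paired
comparison), with one model fit per fold reused across variants since the
counts do not depend on the variant. Grid accuracy pools hits over all
test records (record-weighted); per-fold accuracies are reported
alongside. A test record with an empty candidate set counts as a miss and
is tallied separately.

## The synthetic generator

Each record draws a disease from a prevalence vector, then each symptom of
that disease's profile independently with its emission probability
(redrawing the all-absent outcome, which for realistic profiles is
vanishingly rare); present main symptoms are placed first in profile
order, the rest shuffled behind. The emission model deliberately matches
the classifier's conditional-independence assumption so that parameter
recovery has an exact target and the closed-form posterior
P(d | observed symptoms present) ∝ prevalence(d)·Π emission(d,s) is
available as an oracle. Record length is whatever the emissions produce;
there is no separate length distribution, which would break that closed
form.

Study shapes and their defaults:

- `make_spec` — the general corpus: 100 diseases, Zipf(1.0) prevalence
  (most-to-least common ratio 100:1), vocabulary of 300 symptom terms,
  3 main symptoms per disease with emission 0.6–0.95 (a main-symptom slot
  reuses an earlier disease's main with probability `overlap` = 0.3),
  4–10 secondary symptoms with emission 0.05–0.4 drawn from the full
  vocabulary.
- `separable_spec` — 20 equally prevalent diseases, each with 2 exclusive
  main symptoms at emission 0.9 plus 4 shared background symptoms at 0.3;
  near-perfect ranking is achievable, so it measures machinery, not
  statistics.
- `imbalanced_spec` — 20 diseases, geometric prevalence with a 50:1
  most-to-least ratio, all profiles (3 mains at 0.6–0.9, 5 secondaries at
  0.1–0.4) drawn from one 60-symptom pool, so profiles overlap heavily.
- the parameter-recovery shape: 20 diseases, 3 exclusive mains at
  emission 0.95 and 2 background symptoms at 0.05 — near-deterministic
  profiles chosen so that at 5,000 records (~250 per class, binomial
  sd ≈ 0.014) every fitted conditional is expected well inside the 0.05
  recovery band.

**What passing on synthetic data does and does not show.** Because the
generator satisfies the independence assumption exactly, the classifier is
near Bayes-optimal on these corpora and top-3 accuracies sit near the
ceiling; the grids mainly verify the machinery (counting, smoothing,
candidate logic, fold protocol), not real-world performance. Real corpora
violate independence (correlated symptoms), carry synonym noise and
unmatched vocabulary, and have much sparser cooccurrence structure —
accuracy there is an empirical question this package cannot answer from
simulation. The generator includes no symptom-correlation structure by
default and no natural-language noise. Relatedly, the large empirical
accuracy differences sometimes reported between ranking-equivalent
variants of this family (no-prior vs equal-probability) cannot arise here
by construction; within this implementation those variants differ in
score scale, numerical robustness and interpretation, not in ranking.

## Problem sizes used in the shipped runs

The acceptance script evaluates the grid on 12,000 records over 100
diseases (3-fold CV) and the imbalanced, separable and recovery analyses
on 5,000 records over 20 diseases each — sizes at which the binomial
uncertainty on a pooled accuracy is a few tenths of a percent, while the
whole script completes in seconds on one CPU.

## Known limitations

- The product form can underflow for inputs with many tens of symptoms;
  use the log variant there (this is its purpose).
- `oversample_balanced` is exact but can explode combinatorially (LCM of
  class counts); it guards with a size limit and exists for consistency
  testing, not production balancing.
- Weighting interacts with smoothing as described above; w is a clinical
  convention constant, not a fitted parameter, and no procedure is
  provided to estimate it.
- The candidate filter means a disease absent from training can never be
  predicted, and an input of entirely unseen symptoms yields an explicit
  `no_candidates` status rather than a guess.
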