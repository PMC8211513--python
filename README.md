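# dxrank

Ranked differential diagnosis from ordered symptom lists, with a family of
modified Naïve Bayes classifiers.

`dxrank` is built for corpora of the kind produced by clinical
record-keeping in Traditional Chinese Medicine (TCM) and similar settings:
each case is a single disease label plus a comma-separated, order-preserving
list of symptoms, where the first three symptoms entered are conventionally
the *main symptoms* — the ones the clinician considered most diagnostic.
Given a new symptom list, the tool returns the top-k (default top-3)
candidate diseases, the form in which such recommendations are consumed by
a clinician rather than as a single hard label.

## The model

All probabilities are record-level presence estimates from cooccurrence
counts: with N records, N(d) records labeled d, N(s) records containing
symptom s and N(d,s) records containing both,

    P̂(s|d) = N(d,s)/N(d),   P̂(s) = N(s)/N,   P̂(d) = N(d)/N.

The scoring unit is the **feature operator** — the likelihood ratio of one
symptom for one disease:

    op(s, d) = P̂(s|d) / P̂(s).

A candidate disease's score for input symptoms s₁…sₙ is

    score(d) = Π᷈ᵢ [ gᵢ · op(sᵢ, d) ] · prior(d)

where gᵢ = w (> 1, default 2) when sᵢ is a main symptom (position ≤ 3)
*and* cooccurs with d, else gᵢ = 1. Pairs never seen together get a
Laplace-smoothed conditional α/(N(d) + α·|V|) instead of the zero MLE, so
no candidate's score collapses. Candidates are the diseases cooccurring
with at least one input symptom.

Eight variants span {empirical prior, no prior, log form, equal
probability} × {weighted, unweighted}:

- **empirical** — multiply by P̂(d);
- **none** — drop the prior (the score is then the rate of change
  P(d|x)/P(d), which sidesteps prior imbalance);
- **log** — sum of logs of the same factors, the numerically safe branch
  against floating-point underflow on long symptom lists;
- **uniform** (equal probability) — prior 1/|D| and the symptom marginal a
  class-balanced, oversampled corpus would induce,
  P̂(s) = (1/|D|)·Σ_d P̂(s|d), computed analytically in exact rational
  arithmetic.

Evaluation follows the top-3 hit protocol: under stratified k-fold
cross-validation (default k = 3), a test record counts as a hit when its
true disease appears anywhere in the top-3 ranking.

Because real corpora of this kind are private, the package ships a
synthetic-corpus generator with known generative structure (Bernoulli
symptom emissions per disease, skewed prevalence, designated main symptoms
placed first) and a closed-form posterior oracle, so every algebraic and
behavioral property is testable. See `docs/methods.md` for what the
generator does and does not emulate.

## Worked example

Train on a tiny five-record corpus (`corpus.tsv`, TSV with columns
`disease`, `symptoms`, optional `source_id`):

```
disease   symptoms                        source_id
cough     cough, fever, wheeze            r1
cough     cough, night sweating           r2
insomnia  insomnia, palpitation, fever    r3
insomnia  insomnia, vertigo               r4
vertigo   vertigo, headache, fever        r5
```

```
$ dx train --records corpus.tsv --out model.json
model: 5 records, 3 diseases, 8 symptoms -> model.json

$ dx predict --model model.json --symptoms "fever, cough" \
    --prior uniform --weighted --w 2.0 --k 3
1. cough	3
2. vertigo	0.333333
3. insomnia	0.15
```

Reading the winner's score: both input symptoms are main symptoms (first
three positions) that cooccur with `cough`, so each operator is doubled.
The uniform-mixture marginals are P̂(fever) = 2/3 and P̂(cough) = 1/3,
giving (2 · ½÷⅔) · (2 · 1÷⅓) · ⅓ = 1.5 · 6 · ⅓ = **3**. `vertigo` never
cooccurs with the symptom "cough", so that factor falls back to the
Laplace-smoothed value — which is why its score is an order of magnitude
smaller — and the gap to `insomnia` reflects the remaining counts.

Simulate a corpus and run the full eight-variant comparison:

```
$ dx simulate --diseases 20 --vocab 120 --n 2000 --seed 17 --out sim.tsv
$ dx evaluate --records sim.tsv --k 3 --seed 17 --out-dir results/
             variant  accuracy  hits  n_test  n_no_candidate  ...
  empirical:weighted     1.000  2000    2000               0
       none:weighted     0.998  1996    2000               0
        log:weighted     1.000  2000    2000               0
    uniform:weighted     0.998  1996    2000               0
empirical:unweighted     1.000  2000    2000               0
     none:unweighted     0.998  1996    2000               0
      log:unweighted     1.000  2000    2000               0
  uniform:unweighted     0.998  1996    2000               0
```

Near-ceiling accuracies are expected here: the generator's emission model
matches the classifier's independence assumption, so the classifier is
close to Bayes-optimal on its own generative world (see
`docs/methods.md`). The grid writes `results/grid.tsv` (per-fold columns
included) and a `manifest.json` recording seed, fold count and the exact
variant configurations.

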