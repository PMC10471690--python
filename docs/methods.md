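# Methods

## The generation model

`qsynth` treats synthetic questionnaire generation as a chain of supervised
multiclass problems. The battery is six instruments with ordinal items:
SF-36 (36 items, answers 1–6), HAD (14, 0–3), SCL-90-R (90, 0–4), FIS8 (8,
0–4), FIS40 (40, 0–4) and PSQI (34 answer columns, 0–3) — 222 items, of
which SF-36 is the only real input and the other 186 are generated. The
core assumptions are:

1. **Answers are exchangeable across patients** given the questionnaire
   features; each question's answer is modelled independently given the
   features (no explicit within-questionnaire joint model — dependence
   between generated answers enters only through the shared features).
2. **Information flows along strongly correlated instruments.** A
   questionnaire is easiest to predict from the instruments whose subscales
   correlate with its own, which is what the cascade ordering optimises.
3. **Class imbalance is the dominant failure mode.** Ordinal answer
   categories are heavily skewed in clinical cohorts; unweighted training
   collapses onto modal answers and destroys the utility of rare-answer
   statistics. Every question model is therefore trained with weights
   `w_i = n / (classes × count_i)`.

### Subscale graph and ordering

Each of the 38 subscales is scored as the sum of its member items
(records with a missing questionnaire block score as missing). The graph
places an edge between two subscales when the absolute pairwise-complete
Pearson correlation is at least τ = 0.5 — the conventional cut between weak
and moderate correlation. τ is exposed; raising it can only remove edges.
Negative correlations count (|r| is thresholded): a strong inverse
relationship is as informative for prediction as a direct one.

Pairs with fewer than 3 complete shared records, or involving a constant
score, have undefined correlation and produce no edge (logged). Pairwise
deletion is the default because register counts differ per questionnaire;
a complete-case analysis can be obtained by pre-filtering the cohort to
`cohort.records_with(schema.names)`.

The cascade order is greedy: starting from SF-36, repeatedly append the
questionnaire j maximising the coverage of j's nodes by the union of all
already-selected questionnaires' nodes (a node is covered when adjacent to
any selected node). The union — rather than only the previously added
questionnaire — is used because the cascade concatenates *all* prior
questionnaires into the next step's features. Ties are broken by (1) more
covered nodes in absolute number, (2) fewer own nodes, (3) lexicographic
name; the candidate ranking of every round is logged. Questionnaires with
no external edges get coverage 0 and sort last.

### Cascade training

Step k trains one model per question of the k-th questionnaire on
`[real SF-36 ‖ synthetic prior blocks]`. Synthetic — not real — prior
blocks are used so that training features match what is available at
generation time (only SF-36); a `teacher_forcing` switch substitutes the
real prior blocks for ablation studies. Training records for a step are
those whose real input blocks *and* real target block are all present
(complete-case per step, no imputation), so usable records shrink down the
cascade; the per-step counts are recorded in the model provenance and shown
by `summary()`.

Question models with a single observed class become constant predictors
(with a warning); steps with fewer than 30 records (configurable) are an
error.

### Backends

The per-question model is pluggable behind a two-method contract
(`fit(X, y, class_weights, hyperparams, seed)`,
`predict_scores(X) -> scores over observed labels`):

* **linear** (default): standardised features + multinomial logistic
  regression with the class-weight dictionary. Deterministic, fast, and
  well calibrated — the reference backend for tests and batch generation.
* **mlp**: a numpy feed-forward softmax network — ReLU hidden layers,
  inverted dropout (rate 0.2) on the trailing `dropout_layers` hidden
  layers, Adam (lr 1e-3), class-weighted cross-entropy, early stopping on
  validation macro recall with best-weights restore. The validation split
  is a seeded 20% holdout; macro recall is monitored because the point of
  the class weights is rare-answer recall. Per-step default architectures
  (neurons 400/400/200/100 … 500/500/250/100, epochs 3000–4000, patience
  300–400) are shipped as `STEP_DEFAULT_HYPERPARAMS`; they are sized for
  cohorts of a few thousand records and should be shrunk for small data.
* **xgb**: gradient-boosted trees (xgboost) with per-sample weights derived
  from the class weights. Tree ensembles and networks perform comparably on
  this kind of structured data; the tree backend is cheaper to tune.
* **rounded**: ridge regression rounded half away from zero and clamped to
  the item's answer rank — the regression baseline against which the
  classification approach is compared. Its grand-total error is far larger
  than the classifiers' because regression shrinks toward the conditional
  mean and rounds away rare extreme answers.

Prediction defaults to **argmax** (deterministic: one synthetic battery per
SF-36 input, reproducible bitwise with the linear backend). **sample** mode
draws each answer from the backend's class scores with a seeded generator;
it is the distribution-preserving mode and the one used for marginal
fidelity evaluation, since argmax provably concentrates the generated
marginals onto high-posterior answers and under-represents rare ones even
when the model is perfectly calibrated.

### Validation metrics

* `classification_report`: per-label precision/recall/F1/support, accuracy,
  macro and support-weighted averages. F1 is the standard harmonic mean
  `2PR/(P+R)`; note for readers of the original formula sketch that the
  variant `TP/(TP+FN+FP)` omits the factor 2 and is *not* what is computed.
* Per-step report pooling: all (record, question) decisions of a step's
  target questionnaire are pooled into one label vector; accuracy is the
  exact-match rate and precision/recall/F1 are support-weighted label
  averages over the pooled confusion matrix. Pooling is the convention
  that matches counting "registers × questions" decisions.
* `mean_error`: `100 × (Σ synthetic − Σ real) / Σ real` on a questionnaire
  block; negative values mean the generator under-scores. Undefined (NaN,
  with a warning) when the real total is zero.
* `sum_ttest`: each question's answers are summed over records; the real
  and synthetic sum series (length = number of questions) are compared with
  a two-sided Welch t-test (a paired variant is available). Identical
  series give p = 1 by convention; two constant, different series give
  p = 0 with a warning. **Caveat:** the test treats questions as
  independent observations. On strongly inter-correlated questionnaires the
  per-question sums co-move and the test is markedly anticonservative (we
  measured ~77% null rejection at α = 0.05 on highly correlated synthetic
  batteries versus ~5% when items are independent). Its p-values should be
  read as a rough utility screen, not as calibrated inference; the
  calibration test in the suite therefore uses independent-item cohorts,
  where the test's assumptions hold.

## The synthetic cohort generator

`qsynth.simulate` replaces the (non-redistributable) hospital registry.
Per record, a latent trait vector over the 11 subscale subject areas is
drawn from N(0, R) with a planted correlation matrix R; item i with loading
λ has latent `u = λ·z_subject(i) + √(1−λ²)·ε` and is discretised into its
answer rank by equal-probability normal quantiles (per-item probability
overrides exist for imbalance experiments). Whole questionnaire blocks are
then dropped per record with per-questionnaire retention probabilities
proportional to the registry's available-forms counts (PSQI scarcest at
0.777, FIS8 0.816, the rest ≈0.93). Everything is reproducible bitwise
from the cohort spec's seed.

`default_registry_spec` plants the registry's qualitative structure: the
SF-36 core subjects are mutually correlated at 0.75; Anxiety/Depression
correlate at 0.85 with each other, 0.75/0.70 with Mental and 0.65 with
Emotional; Cognitive couples at 0.30 and Sleep quality at 0.15 with
everything. Loadings are 0.8 (SF-36, PSQI), 0.95 (HAD), 0.9 (FIS8), 0.85
(FIS40) and 0.34 (SCL-90-R), and the SCL-90-R discomfort-index item block
is tied to the Depression trait. This particular configuration is a
deliberate construction: because HAD's subject areas are a subset of
SCL-90-R's, a purely subject-level structure in which SF-36 reaches all of
HAD would also reach all of SCL-90-R, and the greedy order would pick the
larger questionnaire first. Down-weighting the SCL-90-R loading makes its
small discomfort-index subscale reachable only through HAD's stronger
loading (planted correlation ≈0.63 versus ≈0.44 from SF-36), and the weak
Cognitive trait leaves one FIS40 subscale uncovered so the fully covered
single-node FIS8 precedes FIS40. The constants were chosen by computing
the implied large-sample subscale correlations and centring the
edge/non-edge margins at roughly ±0.06 around the 0.5 threshold (about
three standard errors of a correlation at n = 2000); the recovered order
is stable across seeds at that size.

What the generator does **not** emulate: real marginal answer
distributions (uniform by default rather than clinically skewed),
within-questionnaire local dependence beyond shared traits, response
styles, item-level missingness (blocks are all-or-nothing, as in validated
registers), or any longitudinal structure. Passing tests on this fixture
demonstrate that the pipeline recovers planted statistical structure and
that its bookkeeping, determinism and calibration are correct — not that
generated data match real ME/CFS response distributions.

## Numerical and design choices

* All randomness flows through `numpy.random.default_rng` seeded per
  operation; per-question seeds are derived as `seed + 1000·step + item`.
* Correlations: pandas pairwise-complete Pearson, `min_periods=3`;
  diagonal forced to 1; NaN pairs yield no edge.
* Rounding for the regression backend is half away from zero
  (2.5 → 3), then clamping to the answer rank (4.2 on {0..3} → 3).
* Evaluation problem sizes: cohorts of 400–2000 records with a 1000-record
  holdout for fidelity, 400 replicates for t-test calibration, 100k-record
  oracle runs to define planted edges — sizes at which planted-structure
  recovery is stable while the whole suite stays fast on one CPU.
* The battery has 186 generated questions, hence 186 question models (14 +
  90 + 8 + 40 + 34); summaries that count "188 models" elsewhere conflate
  this with the final step's 188 input features.
* Class-weight arithmetic on the published example supports (66/886/807/562
  of n = 2321) gives 8.79, 0.65, 0.72 and 1.03; printed tables elsewhere
  show 8.80 and 0.66 for the first two — the formula as stated is
  implemented, and the ≤0.01 discrepancy is presumably upstream rounding.
* Subscale item memberships are not published for this battery; the
  bundled schema assigns contiguous blocks with the standard instruments'
  block sizes (e.g. SF-36 PF 10 items, SCL-90-R somatisation 12 items,
  FIS40 10/10/20) with component/total subscales as unions. A schema file
  (JSON/YAML) lets users substitute licensed instrument mappings.

## Known limitations

* Per-question conditional independence means higher-order joint statistics
  (e.g. answer co-occurrence within a generated questionnaire beyond what
  features explain) are not guaranteed to match.
* The sum-series t-test anticonservativeness described above.
* Argmax generation is biased toward modal answers by construction; use
  sampling mode when marginal or distributional fidelity matters.
* Real-registry performance figures cannot be reproduced or verified here;
  all quantitative claims in the test suite concern synthetic cohorts with
  known structure.
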