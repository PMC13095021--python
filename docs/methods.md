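# Methods

This note records the model, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## The two-step model

**Step 1 — clinical similarity.** Each patient's nine baseline variables are
encoded as one-hot blocks (with an explicit `missing` level per categorical)
plus z-scored continuous/ordinal values, and the row is rescaled to unit
Euclidean norm. Treatment line is ordinal and enters on its numeric rank
with lines ≥ 3 bucketed together. Missing continuous values are imputed with
the training-cohort median; all statistics (means, SDs, medians) are learned
on the training cohort and frozen for any later cohort.

The pairwise association encoder is one 2-layer projection network
(input → 64 → 32, ReLU, linear output) applied to both members of a pair —
weight sharing is structural, there is a single parameter set. The rescaled
cosine of the two projections is matched to the cutoff-rule pair label with
binary cross-entropy over balanced mini-batches of pairs (256 pairs/batch,
up to 50,000 pairs per epoch, 100 epochs, Adam at 10⁻³).

Censoring and the cutoff rule: *above* = observed PFS beyond 9.0 months
(event or censored, survival past the cutoff is established either way);
*below* = progression/death at or before the cutoff; patients censored at or
before the cutoff are ambiguous and appear in no labeled pair.

Two regularization choices matter and are deliberate defaults. Pair labels
are intrinsically noisy relative to the latent prognosis structure (survival
time scatters around its class median), and an unregularized 64×32 network
will drive the pair loss to ~0 by memorizing individual patients, which
destroys generalization to unseen cohorts. The trainer therefore (i) applies
weight decay 10⁻² and (ii) holds out 20% of the eligible patients as a
validation set and returns the epoch snapshot with the best validation pair
loss. On synthetic cohorts this raises the class purity of held-out graph
edges from ≈0.53 (chance is 0.5) to ≈0.80. Set `val_fraction=0` and
`weight_decay=0` to recover plain fixed-epoch training.

**Step 2 — hypergraph survival network.** The graph concatenates two named
hyperedge groups: one 2-node hyperedge per patient pair with similarity
≥ 0.5 (weight = similarity), and one (k+1)-node hyperedge per patient —
itself plus its k = 10 nearest neighbours in the standardized radiomics
space (weight 1, distance ties broken by lower index). Nodes left isolated
are re-attached to their nearest neighbour under the similarity matrix, or
given a pure self-column as a last resort (the only place a degree-1
hyperedge is tolerated). Both compositions are configurable.

Each convolution layer computes
σ(D_v^{-1/2} H W D_e^{-1} H^T D_v^{-1/2} X Θ) as the two-step node→edge→node
aggregation (hyperedge means, weighted node update); the implementation is
tested against the dense closed form at 10⁻⁹. Defaults: two layers
(128, 64), ReLU, dropout 0.5 in training mode, linear head to one scalar,
Adam at 10⁻³ with weight decay 5·10⁻⁴, 100 full-batch epochs. The reported
score is the negated head output so that higher scores mean better
predicted survival; the internal Cox risk is the un-negated head.

**Training objective.** The negative Breslow partial log-likelihood of the
Cox proportional-hazards model on PFS, full-batch and transductive (all
nodes take part in message passing; the likelihood runs over loss-mask
nodes). A partial likelihood was preferred over classifying a dichotomized
endpoint because it uses the complete censored time-to-event information;
the loss function is pluggable. Gradients are analytic and verified by
finite differences.

**Cross-validation and locking.** Five-fold transductive cross-validation
partitions patients; each fold's model trains its loss on the other folds'
nodes and is scored by held-out-fold C-index. `cross_validate` returns the
best-fold model; the *pipeline*, however, locks a model retrained on the
full training cohort and uses the CV only as the validation estimate — a
best-fold model has seen only 4/5 of the loss nodes and its selection by a
small validation fold is high-variance. External cohorts are scored by
building a fresh graph for that cohort with the locked encoder and the same
graph configuration, then running the locked network in evaluation mode.

## Evaluation machinery

* **Harrell's C** (scikit-survival): comparable pairs are those where the
  shorter observed time carries an event (at tied times, only
  event-vs-censored pairs compare); score ties earn 0.5. Percentile
  bootstrap over patients (default 1,000 replicates) gives the 95% CI.
  Orientation is explicit everywhere: higher score ⇒ longer survival.
* **KM / log-rank / Cox** via lifelines. lifelines handles tied event times
  with the Efron approximation, which coincides with Breslow on tie-free
  data; fit-accuracy tests use tie-free fixtures. Univariate screening
  retains covariates at Wald P < 0.05; multivariable control fits accept an
  optional ridge penalizer (the pipeline uses 0.1 for the wide radiomics
  block). Non-convergence and separation are flagged, not raised.
* **Cutpoint optimization** is an exhaustive search over ordered pairs of
  candidate cutpoints (midpoints of adjacent distinct scores, optionally
  thinned to a quantile-spaced subset) maximizing the three-group log-rank
  χ² subject to each group holding ≥ 10% of patients; ties resolve to the
  smallest cutpoints. The inner χ² is a vectorized k-group
  observed-minus-expected statistic, cross-checked against lifelines.
* **Fixed-proportion stratification** sizes ascending-score groups by
  cumulative-floor rounding with the last group absorbing the remainder.
* **Gower distance** averages per-variable dissimilarities (range-scaled
  absolute difference, rank-scaled ordinal difference, 0/1 categorical
  mismatch) over the variables observed in both patients; the ε-radius
  network connects pairs with d ≤ ε, boundary inclusive, default ε = 0.5.
  Agreement with R's `cluster::daisy` is covered by a test.
* **ICC(2,1)** (two-way random effects, absolute agreement, single rater)
  from classical mean squares filters radiomics features across replicate
  readings at threshold 0.75; features constant across patients in any
  reader are undefined and dropped. The variant and threshold are
  conventional choices, exposed in configuration.

## The synthetic-data generator

`generate_cohort` emulates the statistical structure of a multicenter NSCLC
immunotherapy cohort; its clinical marginals are fixed to a large training
cohort's demographics (80% male, 64% smokers, histology 51/34/15,
morphology 84/1/15, 92% combination therapy, treatment lines 63/26/11,
median age 63 (SD 9.4), median diameter 42 mm, median dNLR 2.7, median PFS
9.1 months, 8.5% censoring).

Mechanics: a latent two-level prognosis class (equiprobable) shifts a
*subset* of clinical variables — age, smoking, longest diameter, dNLR —
symmetrically (±1 SD on continuous scales, ±0.25 on probabilities), leaving
the other five variables class-neutral; marginals are preserved exactly by
the symmetry. The true log-hazard is

risk = 1.0 · (class = poor ? +1 : −1) + 0.8 · u,  u ~ N(0, 1),

where u is an idiosyncratic factor. Radiomics are block-correlated
Gaussians (6 blocks, ρ = 0.3, 120 features) whose first five features load
on the *standardized risk* with loading 0.5 — imaging features are noisy
proxies of overall tumour aggressiveness, so they correlate with the
clinical class as well. PFS is exponential with hazard ∝ exp(risk), rescaled
so the realized median equals 9.1 months; censoring is an independent 8.5%
Bernoulli with a uniform censoring time; OS adds a positive lognormal
increment whose median depends on the class. At n = 2,000 the true risk has
C ≈ 0.78 against the generated outcomes and a Cox fit on the true risk
recovers its coefficient of 1.

Why these effect sizes: (i) the class must be genuinely learnable from
clinical data (a logistic regression recovers it at ~96% accuracy) —
otherwise the supervised encoder has nothing to learn and the experiments
reduce to seed noise; (ii) not all baselines are prognostic — that is the
very premise of univariate screening, and it is what differentiates a
learned variable weighting from the equal-weight Gower distance; (iii)
radiomics loadings are modest so that node attributes alone do not exhaust
the risk — graph-based denoising then has measurable headroom, which is the
mechanism the two-step design relies on.

`generate_two_class_cohort` is an idealized variant for encoder validation:
class-conditional survival times place every patient unambiguously on one
side of the 9-month cutoff (the poor class progresses uniformly before it;
the good class survives past it, possibly censored late), and the clinical
separation is widened. Under exponential proportional hazards the
side-of-cutoff is irreducibly noisy given the class (P(T > c) = 2^(−c/median)
caps side predictability near 0.78 at realistic medians), so near-perfect
pair metrics are only a meaningful target in this aligned setting.

`generate_replicates` adds iid Gaussian reader noise to the radiomics table;
a unit-variance feature then has expected ICC = 1/(1 + σ²).

## What the synthetic experiments show — and what they do not

Passing tests demonstrate: the convolution and every survival statistic
agree with independent oracles; the encoder recovers latent two-class
structure from held-out clinical data; the full pipeline recovers enough of
a known generating risk (held-out C ≥ 0.65 against the true event times)
to beat a clinical-only Cox model; and the supervised graph beats the
unsupervised Gower graph under conditions where supervision has signal to
exploit. They do not demonstrate performance on real imaging cohorts: the
generator has Gaussian radiomics with a single linear risk factor, no
scanner or center effects, exponential survival, and independent censoring —
all simplifications real data will violate.

## Problem sizes and numerical details

Simulated experiments use 300 training and 150 held-out patients with 120
radiomics features, sizes at which every training run is a few seconds on
one CPU while leaving the statistics stable. All randomness flows through
`numpy.random.default_rng` seeds carried in the configuration dataclasses;
repeated seeded runs are byte-identical. Similarities are clipped to [0,1]
and cosines to [−1,1] before the arccos-free rescaling; the BCE clips
probabilities at 10⁻⁷; the partial likelihood is computed with a max-shift
for overflow safety; degenerate inputs (zero-norm encodings, zero latent
vectors, zero-degree nodes, all-censored cohorts, constant scores) raise
errors naming the offending patient or node.

## Known limitations

* The encoder's graph quality degrades gracefully but silently when the
  clinical variables carry little prognostic signal; inspect the held-out
  pair metrics before trusting the graph.
* The X-tile-style search is exhaustive over candidate pairs (O(m²) log-rank
  evaluations); use `max_candidates` for scores with many distinct values.
* Proportional hazards is assumed throughout the evaluation stack; strongly
  non-proportional cohorts will distort both the Cox controls and the
  training objective.
* The response AUC evaluates survival-trained scores against the response
  label; no classification head is trained.
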