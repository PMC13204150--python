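# Methods

`neuromimetic` implements a consolidated pipeline for two-class, imbalanced
biomedical feature tables — the motivating application is EEG-derived feature
tables for Alzheimer's-disease (AD) detection — consisting of five
train-then-transform feature extractors, seven population-metaheuristic
wrapper feature selectors (two of them hybrids), a zoo of hybrid boosted
classifiers, and a leakage-free repeated stratified cross-validation harness
over the full extractor × selector × classifier grid. This note records the
model choices, the parameters that matter, and the places where the design
was genuinely open.

## Scope and input model

The pipeline starts at the numeric feature-table level: a samples × features
matrix with binary labels (healthy = 0, AD = 1), read from CSV. Raw EEG
decoding, ICA artifact removal, and spectral feature engineering are out of
scope; whatever per-epoch representation produced the table is upstream of
this package. Labels are encoded {0, 1} internally; formula boundaries that
need signed (AdaBoost) or one-hot (WBLS) targets adapt locally.

## Synthetic data generator

The generator emulates the class structure of the reference EEG experiments:
two visual-task experiments with 1225 healthy vs. 325 AD epochs
(`experiment1`) and 1200 vs. 350 (`experiment2`). Features are
class-conditional Gaussians: `n_informative` features are equicorrelated
(coefficient `correlation`) with unit within-class SD and a between-class
mean shift of `effect_size` SD units; the remaining features are
class-independent N(0, `noise_sd`²). Defaults: 64 features, 8 informative,
effect size 1.0, correlation 0.3, noise SD 1.0 — desk-scale, but the
selectors face a genuine needle-in-haystack task.

What the generator does **not** emulate: temporal structure, channel
topography, heavy-tailed artifacts, non-Gaussian class shapes, and
between-subject heterogeneity of real EEG features. Tests passing on this
generator therefore establish that the algorithms are implemented correctly
and behave sensibly under mean-shift structure with class imbalance — not
that the pipeline reaches any particular accuracy on real recordings.

## Feature extraction

All extractors standardize columns internally (mean 0, population-SD 1,
fitted on training rows; constant columns map to zero). Fitted state is
never re-estimated at transform time.

- **PCA** — eigendecomposition of the population (1/n) covariance of
  standardized data; eigenvector signs fixed by making the
  largest-magnitude loading positive, so fits are deterministic. Default
  output dimension 10.
- **KPLS** — kernel partial least squares with a Gaussian kernel
  exp(−γ‖x−x′‖²). The training Gram is double-centered; latent directions
  come from NIPALS iterations on the centered Gram and centered targets with
  per-component deflation; a test kernel is centered with training
  statistics and projected as `Kt_c U (TᵀK_c U)⁻¹`, which reproduces the
  training scores exactly on the training rows. γ defaults to the median
  squared-distance heuristic; latent count defaults to 10. The published
  description of the centering and score formulas is typographically
  corrupt; the standard Rosipal-style construction is used and cross-checked
  against an ordinary-PLS oracle under a linear kernel.
- **Kriging** — the one design question with no published answer is how a
  geostatistical interpolator acts as a *feature extractor*. The realization
  here: each sample's p standardized feature values are read as observations
  of a 1-D random field at equispaced index locations in [0, 1] and kriged
  onto `output_dim` equispaced targets under the Gaussian covariance
  k(d) = σ²·exp(−d²/(2ℓ²)) with ℓ = 0.5 and σ² = 0.2 (the stated study
  parameters). Ordinary kriging (unbiasedness constraint) is used rather
  than simple kriging so the weights sum to 1 and a constant field is
  reproduced exactly — the "unbiased linear combination" reading. A diagonal
  nugget of 1e−8 keeps the very smooth Gaussian covariance solvable; the
  transform is a single precomputed (p × m) weight matrix. This realization
  is documented as the package's choice, not asserted as the original
  authors' intent.
- **Isomap** — symmetric k-NN graph (k = 10 by default) with Euclidean edge
  weights, all-pairs geodesics by Dijkstra, classical scaling of the
  double-centered squared geodesic matrix, and a Nyström out-of-sample
  extension (new points route through their k nearest training rows).
  A disconnected graph is repaired by adding the single shortest Euclidean
  edge between components (warned, never dropped) because downstream CV
  requires every sample embedded.
- **K-means distance features** — Lloyd iterations with greedy
  farthest-point seeding from the stage RNG, empty clusters re-seeded at the
  point farthest from its nearest centroid, iteration cap 300, k = 20 by
  default. The transform emits the k centroid distances (the only
  transform-like quantity in the published construction; hard indicators
  were the alternative). The recorded clustering-quality trace is the sum of
  within-cluster *distances*; because the mean update minimizes squared
  distance, this sum can in rare cases rise on an update step — such a step
  is rolled back and iteration stops, so the recorded trace is monotone
  non-increasing by construction.

## Wrapper feature selection

Selectors move a population of continuous positions in the box [−5, 5]^p
(symmetric around the transfer function's switch point) and score the binary
mask obtained by thresholding the sigmoid transfer at 0.5 (coordinate > 0).
The published studies run continuous optimizers on a discrete mask problem
without stating the mapping; the deterministic transfer rule is the standard
choice and is isolated in one function. An empty mask is repaired to the
single feature with the highest point-biserial |correlation| with the
labels (repairs are counted).

The wrapper fitness is the mean accuracy of a 5-nearest-neighbor classifier
over 3 stratified inner folds of the training portion, as a percentage.
The fitness function names no base classifier in the source description;
5-NN over 3 folds is cheap and deterministic, and the inner folds are frozen
per selector run so every mask is scored on identical splits. Fitness is
cached by mask, since the wrapper cost dominates runtime; the inner 5-NN is
a vectorized distance computation validated against scikit-learn's
estimator.

Per-algorithm notes (study-stated parameters in parentheses):

- **CSO** (pop 100, T 200, step α = 0.5, Lévy exponent λ = 1.5): Mantegna
  Lévy-flight proposals, greedy-accepted against a randomly chosen nest;
  a fraction p_a = 0.25 of the worst nests is re-drawn each iteration via
  the Heaviside-gated difference walk with a uniform step factor. The
  discovery probability "in [0, 1]" is drawn once per run.
- **RSO** (pop 100, T 200): best-guided update R = Q·x + W·(best − x),
  Q = A(1 − t/T) with A drawn once per run in [0, 1], W = 2·rand per
  dimension; proposal best − R, greedy-accepted.
- **CSO-RSO hybrid**: one shared population; each iteration proposes both
  the CSO Lévy move and the RSO best-guided move per agent and keeps the
  better of the two, greedily, then runs the cuckoo abandonment walk (the
  hybrid's stated parameter set includes the discovery probability). This
  costs about 2.25 evaluations per agent per iteration.
- **ZOA** (pop 50, T 100, C = 0.01): foraging toward the pioneer (best)
  zebra with J ∈ {1, 2}, then defense — either the time-shrinking
  self-perturbation (Ps ≤ 0.5) or a random-zebra-guided move; both phases
  greedy-accept.
- **GSA** (pop 100, T 200): masses normalized from fitness (flat population
  → uniform), attraction constant H(n) = H₀e^(−βn/T) with H₀ = 100, β = 20
  (the endpoints of the stated admissible range), ε = 1e−9. The
  acceleration is computed with the agent's own mass cancelled
  (a_i = Σ_j rand_j·H·M_j·(x_j−x_i)/(E_ij+ε)), avoiding 0/0 for the
  worst agent.
- **PSO** (pop 100, T 200, inertia θ = 0.5, cognitive b₁ = 0.2, social
  b₂ = 0.4): canonical velocity/position updates with per-dimension uniform
  draws and elitist gbest.
- **GSA-PSO hybrid**: velocity = θv + b₁c₁·a_i + b₂c₂·(gbest − x) — the
  gravitational acceleration occupies the cognitive slot, gbest attraction
  the social slot.

Velocity-based selectors initialize velocities uniformly in [−1, 1] (the
usual swarm convention); zero-velocity starts converge prematurely on
high-dimensional mask problems. Positions are clamped to the box after
every update. Every selector is elitist: the best-so-far fitness trace is
monotone non-decreasing, and T = 0 returns the best initial candidate.

## Classifiers

- **ELM** — random frozen input weights and biases uniform on [−1, 1],
  sigmoid activation, 100 hidden nodes; output weights solve the
  hidden-layer least squares with a small ridge (1e−6) for conditioning,
  against signed {−1, +1} targets.
- **AdaBoost core** — classic AdaBoost.M1 with {0, 1} class codes: uniform
  initial distribution, per-round proportional error ε_t, connection weight
  w_t = ½log((1−ε_t)/ε_t), multiplicative update D ∝ D·β_t^(1−e) with
  renormalization to the simplex, and prediction by thresholding the
  weighted vote at the class-code midpoint. A zero-error round caps the
  weight and stops; a persistent ε ≥ 0.5 round is discarded with a weight
  reset (logged). ELM bases see weight-resampled data (ELMs have no native
  sample weights); CART bases take the distribution directly as sample
  weights folded into the Gini proportions.
- **ELM-AdaBoost** — min-max normalization of inputs (per-column, constant
  columns to 0, unseen values clipped to [0, 1]) followed by 10 boosting
  rounds of ELMs.
- **CART / CART-AdaBoost** — exhaustive threshold search maximizing the
  weighted Gini gain at every node (depth cap 3 for boosting bases),
  majority-class leaves; an unsplittable node becomes a leaf.
- **WBLS** — linear random feature nodes (10 windows × 10 nodes), tanh
  enhancement nodes (100), ridge λ = 2⁻¹⁰, one-hot targets, and the
  closed-form weighted ridge solution W = (λI + UᵀVU)⁻¹UᵀVQ. The diagonal
  V = Z·M combines class-balance weights and optional per-class costs. The
  balance weight gives each minority-class sample 1/(class size) — unit
  total weight per minority class — and each majority-class sample
  ε/(class size) with ε = 0.5, shrinking the majority's total weight; ε = 1
  is classic balanced weighting and ε → 0 is the numerically stable limit
  of the published exponential down-weighting ε^(class size), which
  underflows as printed. This direction (minority samples outweigh majority
  samples per head) follows the stated intent of the construction; the
  literal constant-ε reading weights the classes backwards and makes the
  classifier collapse to majority-class prediction on the 1225/325 preset.
  Costs default to all ones (the
  published L×L cost matrix cannot left-multiply the residual
  dimensionally, so costs are realized per sample by class). Inputs are
  standardized internally so the tanh layer operates in range.
- **HWBLSA** — real-valued (probability-based) boosting of WBLS bases:
  stage scores h_l = (L−1)(log P_l − mean_l log P_l) (they sum to zero
  across classes), sample-weight update w ∝ w·exp(−(L−1)/L·yᵀlog P) with
  symmetric simplex label codes, probabilities floored at 1e−10 before
  logs, round weights α_m = ½ln((1−e)/e) + ln(L−1) recorded (at L = 2 the
  classic AdaBoost α), and final label argmax_l Σ_m h_l. Boosting weights
  reach the base WBLS through its diagonal sample-weight matrix. Rounds
  with error 0 or ≥ (L−1)/L stop the loop. Implemented for generic L,
  exercised at L = 2 and L = 3.
- **Soft voting** — equal-weight average of the class probabilities of
  multinomial logistic regression (500-iteration cap), a polynomial-kernel
  SVM with C = 2 (probability-calibrated via cross-validated calibration),
  a 250-tree random forest with depth cap 100, and 5-NN; a base that fails
  to train is excluded from the average with a logged warning.
- **Baselines** — standalone random forest, Gaussian naive Bayes (the
  continuous-feature reading of the unspecified "NBC" column), and a
  majority-class dummy for harness checks.

## Cross-validation protocol

Repeated stratified k-fold (k = 10, 5 repeats by default). Within each
fold: extractor fitted on training rows only; selector run on the
*transformed training portion*, its fitness using inner folds of that
portion only; classifier trained on the selected columns; test accuracy and
confusion counts recorded. Running the selector per fold is stricter than
the ambiguous published protocol (which may have selected once globally);
the optimistic variant is available behind `select_globally=True` so the
gap can be quantified. Accuracy is the headline metric; confusion counts
are stored so sensitivity/specificity can be derived without re-running.

All randomness flows through per-stage streams derived from the master seed
and a stage tag (SeedSequence spawning), so a full run is bit-reproducible
and any stage can be reproduced in isolation.

## Desk-scale problem sizes

The validation suite runs every algorithm at sizes a workstation handles
comfortably; these are the package's documented test conditions, not claims
about the reference study's scale:

- selector-recovery checks use 300-sample tables (180/120) with the
  generator defaults (64 features, 8 informative); the cuckoo/rat-swarm
  family runs at population 40 × 60 iterations and ZOA at 50 × 60 — these
  greedy local searchers saturate well within that budget — while the
  velocity-based family (GSA, PSO, GSA-PSO) runs at the full study budget
  of population 100 × 200 iterations, which its convergence behavior makes
  cheap under mask caching;
- the end-to-end grid check runs the experiment-1 preset (1550 samples) at
  effect size 1.5 over a reduced 2 × 2 × 2 grid with one repeat of 10-fold
  CV and selector budget 20 × 15 on the 10-dimensional extracted tables.

## Known limitations

- The kriging-as-extractor semantics is this package's interpretation of an
  under-specified construction (see above).
- On the synthetic needle-in-haystack task with the 5-NN wrapper fitness,
  plain cuckoo search is the strongest selector and the two hybrids do not
  out-score their parent algorithms in best wrapper fitness; ZOA (at its
  stated constant C = 0.01) shows the weakest feature recovery. Rankings of
  wrapper fitness on this mean-shift generator need not transfer to
  classification accuracy on real EEG features.
- Class-probability estimates of the boosted ensembles are uncalibrated
  scores, adequate for argmax decisions and soft voting, not for risk
  reporting.
- The CART implementation is exact but O(p · n log n) per node without the
  histogram approximations of production tree libraries; it is intended for
  the shallow boosted trees used here.
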