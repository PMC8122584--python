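# Methods

## The analysis

`omicsfuse` detects survival-linked cancer subtypes from three omic
layers measured on one patient cohort: mRNA expression, DNA methylation
and miRNA expression. The stages are:

1. **Normalisation.** Each feature is min-max scaled,
   `x_n = (x − x_min)/(x_max − x_min)`, per feature (column-wise). The
   per-feature axis is the only choice that bounds every input node of a
   sigmoid-output autoencoder, which the loss functions below require.
   Constant features map to all-zeros instead of raising: flat probes are
   routine in methylation and expression matrices and a zero column is a
   harmless input node.
2. **Feature selection.** Either the features of largest sample variance
   per omic (defaults 500 mRNA / 400 methylation / 100 miRNA, fused width
   1000), or univariate Cox screening: one proportional-hazards model per
   feature, fitted by Newton–Raphson on the Breslow partial likelihood,
   keeping features with Wald p < 0.05. No multiplicity correction is
   applied — the screen is a raw p cutoff by design. Constant and
   non-convergent features are skipped and reported, not fatal.
3. **Fusion.** Column-wise concatenation in omic order (mRNA,
   methylation, miRNA) after asserting a shared sample order.
4. **Embedding.** One of four autoencoder variants compresses the fused
   matrix through a bottleneck; the bottleneck activations are the
   patient embedding (the posterior mean for the variational model).
5. **Clustering.** Two fixed algorithm/similarity pairings over
   k = 3..6: PAM on Spearman correlation distance `d = 1 − ρ` (range
   [0, 2]), and k-means (k-means++, 10 restarts, seeded) on Euclidean
   distance. Silhouette width is computed with the same dissimilarity the
   clustering used; singleton clusters score 0.
6. **Survival validation.** Kaplan–Meier curves per cluster and the
   k-group log-rank test (hypergeometric moments per distinct event time,
   chi-square on k−1 df).
7. **Model selection.** For each k, count configurations (4 variants × 2
   pairings) whose mean silhouette exceeds 0.80; the optimal k maximises
   that count (ties to the smaller k, a deterministic convention). Among
   the above-bar configurations at the optimal k, the final model is the
   one with the smallest log-rank p (ties: higher silhouette, then
   variant order vanilla → denoising → sparse → variational, then
   PAM/Spearman before k-means/Euclidean). If nothing clears the bar the
   report flags "no confident k" and carries the best raw silhouette
   instead of silently resolving.

## Autoencoder variants

All four operate on [0, 1] inputs and share an Adam optimiser
(lr 1e-3, batch 16, 100 epochs by default; 50 epochs in the scaled-down
benchmarks below).

| variant | architecture | hidden / output | loss |
|---|---|---|---|
| vanilla | 1000-500-100-500-1000 | tanh / sigmoid | MSE |
| denoising | same | tanh / sigmoid | MSE vs clean input |
| sparse | same | tanh / sigmoid | BCE + L1(bottleneck) + L2(weights) |
| variational | 1000-500-250 → latent 100, mirrored decoder | ReLU / sigmoid | Bernoulli NLL + KL |

Notes on the open choices:

- **Corruption** (denoising) masks entries to zero independently with
  probability `noise_factor` (default 0.5). An additive-Gaussian mode
  (`corruption="gaussian"`, clipped to [0, 1]) is available behind a flag.
- **Sparsity**: the L1 penalty (0.01) attaches to bottleneck
  *activations*; the L2 penalty (0.01) attaches to *weights*.
- **Variational model**: "negative log-likelihood" with sigmoid outputs is
  implemented as the Bernoulli NLL (binary cross-entropy summed over
  features) — the only NLL consistent with sigmoid outputs on [0, 1]
  data. The decoder mirrors the encoder (100-250-500-1000). The embedding
  is the posterior mean μ, not a sample, so downstream clustering is
  deterministic. The KL weight ramps linearly from 0 to its full value
  over the first half of training (`kl_warmup=0.5`): without the warm-up
  the KL term wins the early race against reconstruction and the
  posterior collapses to the prior (we observed exactly this — constant μ
  across patients — at the default learning rate).
- There is no train/validation split: the representation is unsupervised
  and trained on all patients.
- The networks are plain dense layers on NumPy with manual
  backpropagation, trained in float32. At cohort scale (hundreds of
  patients × ~1000 features) a variant trains in seconds on one CPU, and
  keeping the arithmetic in-package makes seeded runs bitwise
  reproducible.

## The synthetic cohort generator

Real TCGA-style inputs are external downloads; the generator plants a
known truth instead so every stage has an acceptance surface.

- **Shapes.** Default: 3 subtypes × 50 patients; raw omic widths
  2500/2000/500 (about a seventh of a real cohort's mRNA/methylation
  dimensions), from which variance selection keeps the usual 500/400/100.
  Generating *raw* widths matters: selection is a real, signal-enriching
  step, exactly as in the full-scale workflow, rather than a no-op over
  pre-selected features.
- **Signal.** `signal_mode="signatures"` (default): the informative
  features (20% per omic) are split round-robin into disjoint per-subtype
  marker panels, elevated by `effect_size` (default 6) noise-SDs in their
  subtype. This mirrors how real subtypes carry distinct marker panels
  and gives each subtype its own cross-feature rank pattern — visible to
  both Euclidean and Spearman similarity. The alternative
  `signal_mode="ladder"` shifts every informative feature by
  `s × effect_size` for subtype *s*; it is mean-separable but
  rank-identical across non-zero subtypes and therefore invisible to
  scale-invariant (Spearman) similarity — useful for probing that failure
  mode, unsuitable as a default.
- **Geometries.** `"blobs"` (default) as above; `"lognormal"` plants the
  same blobs on the log scale and exponentiates (`x → exp(τ·x)`,
  τ = 2), giving the multiplicative, heavy-tailed marginals of raw
  expression data; `"shells"` places subtypes on concentric hyperspheres
  in the informative subspace (radius ∝ `effect_size·(s+1)/2` per-feature
  RMS). Purely radial structure is *not* recoverable by centroid/medoid
  clustering in any pointwise embedding — antipodes on one shell stay
  maximally distant — so shells exercise the generator and the failure
  mode, not subtype recovery.
- **Survival.** Per-subtype exponential event times (defaults 0.01,
  0.004, 0.001 events/day) with independent exponential censoring
  (5e-4/day); observed time = min(event, censoring). Memoryless, one
  parameter per subtype, with the censored fraction converging to
  `c/(h+c)`.
- **Not emulated:** platform-specific artifacts, batch effects,
  missingness, feature-feature correlation within a subtype, and
  probe-to-gene structure. Passing tests therefore demonstrate the
  machinery recovers *mean-separable, survival-linked* structure under
  realistic shapes and noise — not that it would denoise any particular
  real cohort.

## Benchmarks the tests pin down

- **Planted recovery** (10 seeds): 150 patients, effect 6, hazards
  0.01/0.004/0.001/day, 50 epochs. Each variant's PAM/Spearman arm must
  exceed silhouette 0.80 at k=3, the counting rule must return k=3, and
  the final model must reach ARI ≥ 0.9 against the planted labels with
  log-rank p < 0.01 — in ≥ 8 of 10 seeds.
- **Null calibration**: 1000 three-group log-rank replicates from one
  exponential reject at p < 0.05 at a rate in [0.035, 0.065]; Cox
  screening on 400 null features keeps ≈ 5% at α = 0.05 within
  Monte-Carlo error.
- **Nonlinear ordering**: on log-normal cohorts (log-effect 2, τ 2) the
  vanilla autoencoder's best clustering ARI is at least PCA's in the
  median over 10 seeds. On this benchmark linear projections degrade
  (PCA ARI ≈ 0.35–0.50) while the saturating encoder compresses the
  tails and recovers structure (ARI ≈ 0.65–0.75).
- **Determinism**: identical seeds serialize byte-identical reports.

Problem sizes in the suite (cohorts of 60–150 patients, raw widths up to
2500, 5–50 epochs) are chosen so the whole suite runs on a single CPU in
minutes while keeping every statistical check adequately powered.

## Numerical conventions

- Min-max scaling maps constant features to zeros; normalisation is
  idempotent on full-range inputs.
- Variance selection breaks ties by feature order and returns kept ids in
  the block's original order.
- Cox Newton iterations use step-halving to keep the partial likelihood
  non-decreasing; |β| > 500 or a singular information matrix is treated
  as non-convergence (feature skipped with a warning — monotone
  likelihoods from perfect separation do occur in screens).
- PAM is deterministic: BUILD initialisation, best-improvement SWAP,
  ties to the lowest index. k-means randomness is confined to the seeded
  k-means++ restarts.
- Spearman distance uses average ranks on ties; a constant latent vector
  is an error naming the sample (its ranks are undefined).
- PCA baseline: component count is the smallest explaining ≥ 0.90
  cumulative variance; component signs are fixed by making each
  component's largest-magnitude loading positive. Kernel PCA defaults to
  an RBF kernel with the median-pairwise-distance bandwidth heuristic;
  kernel and sparse PCA use 100 components, matching the autoencoder
  latent width.

## Known limitations

- The Cox screen fits one feature at a time; correlated features are
  all kept or dropped on their marginal association.
- PAM is O(k·n²) per SWAP pass — fine for cohorts of hundreds, not for
  tens of thousands of samples.
- The silhouette bar (0.80) and the p < 0.05 reporting threshold are
  conventions of the selection rule, not tuned quantities; on weak-signal
  cohorts the report's "no confident k" path is the expected outcome.
- With `signal_mode="ladder"` the Spearman/PAM arm cannot separate the
  non-zero subtypes (see above); this is a property of rank correlation,
  not a defect of the clustering.
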