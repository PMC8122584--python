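# omicsfuse

Autoencoder-based multi-omics fusion for survival-linked cancer subtype
detection.

Molecular subtypes of a cancer — patient subgroups with a shared
molecular profile and, ideally, distinct prognosis — rarely show up in a
single data layer. `omicsfuse` fuses three layers measured on the same
patients (mRNA expression, DNA methylation, miRNA expression) into one
compressed representation and asks whether patients cluster into groups
with genuinely different survival. It is aimed at computational
biologists who have per-omic feature tables plus clinical follow-up and
want a reproducible, testable subtyping pipeline.

## Method

Each omic is min-max scaled per feature, `x_n = (x − x_min)/(x_max −
x_min)`, reduced to its most informative features — largest variance
(500/400/100 per omic by default) or univariate Cox screening at
p < 0.05 — and concatenated into a fused matrix `X ∈ [0,1]^{n×1000}`.
Four autoencoder variants compress `X` through a bottleneck `h = f(x)`:

- **vanilla**: minimise `L(x, g(f(x)))` (MSE);
- **denoising**: minimise `L(x, g(f(x̃)))` with `x̃` the input whose
  entries were masked to zero with probability 0.5;
- **sparse**: BCE loss plus `Ω(h) = λ₁·Σ|h|` on bottleneck activations
  and an L2 weight penalty (λ₁ = λ₂ = 0.01);
- **variational**: Bernoulli reconstruction NLL plus
  `KL(N(μ, σ²) ‖ N(0, I))`, embedding = μ.

Patients are then clustered in the bottleneck space with two fixed
pairings — PAM on Spearman distance `d = 1 − ρ`, and k-means on
Euclidean distance — for k = 3..6. Every configuration is scored by mean
silhouette width `s = (b − a)/max(a, b)` and by the k-group log-rank
test on the resulting clusters. The subtype number is the k at which
most of the 8 configurations exceed silhouette 0.80, and the final model
is the above-bar configuration with the smallest log-rank p at that k.
PCA, kernel PCA and sparse PCA embeddings are available as baselines
through the same clustering and survival machinery.

A synthetic-cohort generator (`omicsfuse.synthetic`) plants known
subtypes — disjoint marker-panel signatures, optional log-normal or
concentric-shell geometries — with subtype-specific exponential survival
and right-censoring, so the whole pipeline is testable without external
data. See `docs/methods.md` for modelling details and conventions.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from omicsfuse import SimulationSpec, simulate_multiomics, run_all

spec = SimulationSpec(seed=1)          # 150 patients, 3 planted subtypes
dataset, truth = simulate_multiomics(spec)
report, embeddings = run_all(dataset, seed=1, epochs=50)

print(report.optimal_k, report.counts)
f = report.final
print(f.variant, f.pairing, round(f.mean_silhouette, 3), f.logrank_p)
print(adjusted_rand_score(truth.subtype_label, f.labels))
```

Output:

```
3 {3: 8, 4: 0, 5: 0, 6: 0}
variational pam/spearman 0.998 1.586e-22
1.0
```

Reading: all 8 autoencoder/clustering configurations exceeded the 0.80
silhouette bar at k = 3 (and none at other k), so the optimal subtype
number is 3. Among them the variational autoencoder with PAM/Spearman
had the smallest log-rank p (1.6e-22 — the three clusters have sharply
different survival), and its clusters match the planted subtypes exactly
(adjusted Rand index 1.0).

The same analysis is scriptable from a shell:

```sh
omicsfuse simulate --out cohort/ --seed 1
omicsfuse run --data cohort/ --out results/ --seed 1 --epochs 50
omicsfuse report --report results/
```

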