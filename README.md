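# ardkit

Identify and cluster **ageing-related diseases (ARDs)** — diseases whose rate
of first onset accumulates with chronological age — from aggregated
electronic-health-record onset counts.

The input is a per-disease table of first-diagnosis counts by integer age:
for each disease and age *x* in 21..84, the number of patients first recorded
with the disease at age *x* (*d_x*) and the number still at risk, i.e. with
no prior record (*l_x*). From this, two complementary, data-driven routes
lead to an ageing-relatedness classification:

1. **Curve clustering.** The age-specific rate of onset *q_x = d_x / l_x* is
   standardised to unit mass, *q̂_x = q_x / Σ_{i=21..84} q_i*, so curve
   *shapes* are comparable across diseases of very different frequency.
   Curves are clustered on Euclidean distance with a fully automated
   model-selection procedure: the hierarchical linkage is chosen by the
   cophenetic correlation coefficient, the number of clusters *k* by the
   Tibshirani gap statistic, and the clustering algorithm (hierarchical
   agglomerative vs k-means vs PAM vs spectral) by the Dunn validation
   index. Clusters with ≥ 3 diseases are "main" clusters, numbered from the
   oldest median onset age down; clusters with ≤ 2 diseases are outliers.
2. **Actuarial banding.** Each onset curve is fitted, on the log scale, with
   the Gompertz model *q_x = α e^{βx}* and the exponential-quadratic
   Gompertz–Makeham model *log q_x = log a + b·x + c·x²*. A negative
   senescent slope β means onset falls with age: very low likelihood of
   being ageing-related. Otherwise the adjusted R² of the Gompertz–Makeham
   fit is banded at 0.95 / 0.90 / 0.85 / 0.80 — the better the actuarial
   model fits, the higher the likelihood the disease is ageing-related.

Real linked primary-care/hospital EHR datasets of this kind are
access-restricted, so the package ships a **synthetic cohort generator**:
binomially sampled onset counts from five parametric hazard families
(late/mid-life exponential growth, linear rise, early peak then decline,
exponential decline) with known ground-truth family labels and
ageing-relatedness, making the entire pipeline testable end to end.

The package is aimed at epidemiologists and ageing researchers with
aggregated onset-count data who want a reproducible, criteria-based ARD
classification rather than an ad-hoc label.

## Worked example

```python
from ardkit import (SyntheticCohortConfig, generate_cohort,
                    run_pipeline, PipelineConfig)

counts, truth = generate_cohort(
    SyntheticCohortConfig(seed=1, n_diseases_per_family=8,
                          cohort_size_at_21=500_000))
result = run_pipeline(counts, None, PipelineConfig(k_max=10, n_refs=20),
                      seed=1, out_dir="demo")
print(open("demo/summary.txt").read())
```

```
ardkit pipeline summary
=======================
diseases analysed:       40
diseases clustered:      40
all-zero curves flagged: 0
selected algorithm:      hierarchical (linkage=average, k=5)
main clusters:           40 diseases in 5 clusters
outlier clusters:        0 diseases in 0 clusters

band counts:
  very_high                24
  very_low_beta_negative   16

cluster median onset ages:
  cluster 1: median 78.0y (IQR 78.0-78.0), n=8
  cluster 2: median 74.0y (IQR 74.0-74.0), n=8
  cluster 3: median 64.0y (IQR 64.0-64.0), n=8
  cluster 4: median 33.0y (IQR 33.0-33.0), n=8
  cluster 5: median 31.0y (IQR 31.0-31.0), n=8
```

Model selection lands on hierarchical agglomerative clustering with average
linkage and recovers the five generative families exactly (one cluster per
family). The three ageing-related families — late-exponential (cluster 1,
median onset 78y), mid-life exponential (cluster 2, 74y) and linear rise
(cluster 3, 64y) — are the 24 diseases banded `very_high` by the actuarial
route; the early-peak and declining families (clusters 4–5, onset in the
early 30s) all have β < 0 and land in `very_low_beta_negative`. The cluster
× band cross-tabulation (`result["crosstab_band"]`) shows the same
concordance cell by cell:

```
band       very_high  ...  very_low_beta_negative
Cluster 1          8  ...                       0
Cluster 2          8  ...                       0
Cluster 3          8  ...                       0
Cluster 4          0  ...                       8
Cluster 5          0  ...                       8
```

The same pipeline runs from the shell:

```bash
ardkit simulate --seed 1 --out data/
ardkit run --counts data/counts.csv --seed 1 --out results/
```

`ardkit rates`, `ardkit cluster` and `ardkit classify` expose the
individual stages; `docs/methods.md` documents the model, parameter
defaults and design decisions.

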