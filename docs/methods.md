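# Methods

## Single-sample network inference

A cohort-aggregated Pearson correlation matrix `N(G)` over all samples is
compared, per patient `S`, with the leave-one-out matrix `N(G−S)` computed
without that patient. The patient's raw network is

```
N(S) = W(S) · num · K · (N(G) − N(G−S)) + N(G−S),       num = n − 1
```

with balance factor `K` (default 0.10) and the genome-wide sample weight
`W(S) = (μ − min + x)/(max − min + x)`, where `μ` is the mean correlation
between patient `S` and every other patient, min/max range over all pairwise
patient-patient correlations, and `x = 0.01` guards the denominator. When
every pairwise correlation is equal, `W(S) = 1` by construction.

The raw weights are z-standardised per patient over the upper triangle of
that patient's matrix and edges with strictly `|z| > 2.58` are retained
(two-sided p = 0.01 under a normal reference; the critical value
`Φ⁻¹(0.995) = 2.5758` rounds to the conventional 2.58). Standardising per
patient — rather than per edge across patients — follows the convention of
single-sample interpolation methods: the reference population is the
patient's own edge-weight distribution. A consequence worth knowing: any
transformation that rescales all of a patient's weights uniformly is
invisible after thresholding; only *relative* reshaping of the weight
distribution changes a patient's network. A degenerate matrix (zero spread)
yields an empty network with a logged warning, never an error.

Retained edges store the signed interpolated weight `N(S)`, not the
z-score; feature extraction uses weights, distances use edge presence.
Inference is deterministic. Memory is bounded by one dense gene × gene
matrix; per-sample networks are written to disk one at a time by the CLI,
and a `--genes` flag restricts inference to a subset.

### Network QC

Density is `|edges| / C(n_genes, 2)`. The scale-free fit bins nonzero
binarized degrees into 20 log-spaced bins and regresses `log10 p(k)` on
`log10 k̄` over occupied bins; `R²` of that fit is reported, or a missing
marker when fewer than two bins are occupied (e.g. regular graphs). Bin
count is a parameter; 20 matches common weighted-network practice.

## Outcome-adjusted network distance

The base statistic is the Jaccard overlap `|Ei ∩ Ej| / |Ei ∪ Ej|` of two
edge sets (a similarity in [0, 1]; both-empty input yields a missing
marker, never 0/0). References are group-level networks: plain Pearson
correlation over the clinical-benefit (CB) or no-clinical-benefit (NCB)
samples, z-thresholded the same way. Intermediate-benefit (ICB) patients
contribute to neither reference. The per-patient result is
`(Nd_cb, Nd_ncb, ΔNd = Nd_cb − Nd_ncb)`.

By default a patient belonging to the group being aggregated is excluded
from that aggregation (hold-out), since including it leaks the patient into
its own reference; `holdout=False` reproduces the naive variant. The choice
matters: the group-level signal carried by ΔNd is weak relative to
patient-level variability (single-sample networks share a large
cohort-aggregate backbone), and in synthetic experiments at our frozen
conditions only the naive variant shows a consistent group direction. The
group references use plain group correlation, not the interpolation
machinery, which is defined for single-sample perturbations.

## Node and edge features

Each patient's network is split into positive- and negative-edge
subnetworks (negative weights stored as absolute values) and per-gene
weighted degree (connectivity) is computed in each; the two halves sum to
the per-gene sum of absolute incident weights. Edge features are the
per-patient weights of edges common to every network in the cohort.
Variance filters (top 5,000 genes / top 10,000 edges, unbiased `n−1`
variance, lexicographic tie-break) bound the screening burden.

### Survival screening

Every feature is screened with a univariate Cox proportional-hazards model
per endpoint (overall survival and progression-free survival), standardised
to mean 0 / sd 1 so hazard ratios are per-SD. Ties are handled with the
Breslow approximation and significance is a Wald test. A feature is
selected when p < α for *both* endpoints (α = 0.01 for genes and edges,
0.05 for pathway scores; raw p, no multiplicity correction — `adjust`
options exist but are off by default to match the screening convention).

The screen fits thousands of single-covariate models, so the Newton
iteration on the partial likelihood is implemented directly on arrays and
vectorised across features; `lifelines` fits the identical model and is the
independent cross-check in the test suite (agreement to ~1e-5 in
coefficient and SE). Numerical policies: constant features get p = 1 and
are never selected; rows with a missing feature value are dropped for that
feature only; a monotone likelihood (perfect concordance, no finite MLE) is
detected by a diverging coefficient and reported with the always-valid
score test at β = 0 instead of a meaningless Wald statistic; any other
non-convergence yields p = 1 with a diagnostic, never a crash.

## Pathway scores

Each gene set induces a subnetwork of each patient's network (genes absent
from the network are dropped at use time); weights are taken in absolute
value so positive and negative co-expression both contribute strength.
Scores per (patient, pathway):

* **entropy** `H = −Σ p_k log2 p_k`, `p_k = w_k / Σw` — 0 for a single
  edge, `log2 m` for m equally weighted edges; defined whenever ≥1 edge.
* **eigenvector score** — mean gene eigenvector centrality; computed per
  connected component from the principal eigenvector of the weighted
  adjacency, scaled so each component's largest entry is 1.
* **closeness score** — mean gene closeness with edge lengths `1/|w|`
  (stronger co-expression = shorter distance), each node scored within its
  reachable set.
* **betweenness score** — mean edge betweenness: shortest paths over
  unordered gene pairs through each edge, tie counts split.

The three centrality scores require at least `min_edges` edges (default 3);
thinner subnetworks yield missing markers rather than unstable numbers.
Entropy needs only one edge and is reported whenever defined. Missing
scores propagate as missing into screening and clustering (pairwise
deletion; mean imputation would bias entropy toward the cohort mean).
Invariances: entropy and the eigenvector score are unchanged under uniform
weight scaling; closeness scales linearly; betweenness path choices are
scale-free.

## Stratification and group statistics

Patients are clustered on the selected features by agglomerative clustering
with Ward linkage over cosine distances, cut at two clusters. Ward formally
assumes Euclidean geometry; applying it to cosine distances replicates the
convention of common clustermap tools, and `metric="euclidean"` is the pure
alternative. Features are standardised before the distance computation by
default (the clustermap convention leaves this unstated; both behaviours
are exposed). Cluster labels are deterministic — clusters are numbered by
the lexicographically smallest member id.

Clusters are compared by Kaplan–Meier curves with the two-group log-rank
test (via lifelines), by benefit-category composition with a Freeman–Halton
exact test for r × c tables (exhaustive enumeration of tables with the
observed margins, summing probabilities ≤ that of the observed table with
1e-12 relative slack; totals capped at 500), and by numeric covariates with
the Wilcoxon rank-sum test (exact for ≤25 untied observations per group,
normal approximation with tie correction otherwise). A median-split helper
divides patients on any scalar score (values ≥ median form the high group).

## Response prediction

CB patients are responders, NCB nonresponders; ICB patients are excluded.
Leave-one-out cross-validation with in-fold ANOVA-F selection (k swept over
10…100 in steps of 10, constant features ranked last, lexicographic
tie-break) feeds an L2 logistic regression with balanced class weights
(`w_c = n/(2 n_c)`), C = 1 by default, deterministic lbfgs solver
(tol 1e-6, ≤1000 iterations). Feature standardisation statistics are
recomputed inside every training fold. Reported metrics: accuracy, F1 with
responder positive, ROC AUC from decision scores; the best k is chosen by
accuracy (ties → smaller k), which reproduces the optimistic best-over-grid
convention — a deliberately leaky variant (selection on the full data) is
available only to demonstrate selection leakage and inflates accuracy on
null data. Across-study evaluation intersects feature spaces, selects and
standardises on the training cohort only, and reports test AUC. C can be
tuned by stratified 5-fold CV over 0.1…1.0 (ties → smallest C).

## Synthetic cohorts

The generator emulates a treatment-response cohort at desk scale
(default 100 samples × 500 genes) with the co-expression hallmarks the
pipeline targets. Design, and why it looks the way it does:

* **Latent severity.** Each patient carries a severity `ζ` from a bimodal
  mixture: a good/poor group label (Bernoulli, fraction 0.5) centres `ζ` at
  −1/+1 with within-group sd 0.5 — two latent outcome groups with
  patient-level heterogeneity, mirroring benefit categories that discretise
  a continuum.
* **Modules that reshape, not rescale.** A 100-gene disease module
  strengthens with severity (factor scale `e^{αζ/2}`, α = 1.6 at strong
  effect) while an equal-sized background module weakens
  correspondingly (`e^{−αζ/2}`). Because thresholding is per-patient and
  relative, only such reshaping of the weight distribution is visible to
  the inference; a uniform strengthening would be normalised away.
* **Banded loadings.** Within a module, gene i loads on a moving window of
  latent factors, giving a full gradient of pair correlations from
  `within_block_corr` (adjacent genes, default 0.5) down to zero — so part
  of every gene's edges sit near the retention threshold, where
  single-sample networks are most informative, and per-gene features
  average over many factors rather than a single module factor.
* **Negative coupling.** Background factors are anti-correlated with
  disease factors with per-patient strength `|ρ⁻| · Φ(ζ)` (ρ⁻ = −0.4),
  planting the stronger negative gene-gene associations of poor-outcome
  patients. The realised gene-level anti-correlation is attenuated by the
  residual variance (measured ≈ −0.10 for aligned pairs in the poor group
  vs ≈ −0.02 in good).
* **Survival.** Exponential times with log-hazard proportional to severity
  (proportional hazards by construction), scaled so the realised OS hazard
  ratio between group centres equals `hazard_ratio_poor` (default 10 —
  steep, matching benefit categories defined by early progression versus
  durable response); PFS runs at twice the OS baseline hazard with a 1.25×
  steeper slope. Independent exponential censoring (rate 1/3000 per day,
  ≈ 5–10% censoring at these hazards). With `effect_size="none"` both the
  reshaping and the hazard slope are zero: expression, grouping and
  survival are mutually independent — the calibration null.
* **Labels and gene sets.** CB = good, NCB = poor, with 20% of patients
  relabelled ICB at random; gene sets are 25-gene chunks of the disease
  module plus random decoy sets. Marginal gene means are identical across
  groups, so mean-based expression features carry no signal by design.

What the generator does *not* emulate: count noise, library-size and batch
effects, tumor purity, many weakly informative modules, or non-proportional
hazards. Passing tests on these cohorts show the pipeline recovers planted
co-expression signal under clean Gaussian conditions; they do not certify
performance on real RNA-seq.

### Measured behaviour at the frozen conditions

Single-sample interpolation at K = 0.1 perturbs the shared cohort backbone
only weakly: a patient's per-gene connectivity estimates its own module
coherence with correlation ≈ 0.4 to the latent severity — a ceiling set by
the patient's single expression draw, which every incident edge of a gene
shares. Consequently, at the frozen conditions supervised prediction from
edge features reaches ≈ 0.8 LOOCV accuracy and comfortably beats
expression-only models (whose features carry no mean signal), while
per-gene dual-endpoint screening recovers roughly half to two-thirds of
planted genes and unsupervised Ward/cosine clustering reaches an adjusted
Rand index of ≈ 0.3 against the latent groups. These are properties of the
method at these conditions, not implementation artifacts: inference matches
an independent brute-force recomputation to 1e-10 and the Cox screen
matches lifelines to 1e-5.

## Numerical and design choices

* Edge identity is the lexicographically ordered unordered pair; self-edges
  are forbidden everywhere.
* Zero-variance genes are dropped at load time with a warning (Pearson
  undefined); correlation routines refuse cohorts of fewer than 3 samples.
* Expression input is assumed log2-transformed; `log2_tpm_pseudocount`
  (CLI `--log2-tpm-pseudocount`) applies `log2(TPM + P)` for raw input.
* Edge-list round trips are byte-exact: floats are written with `repr`.
* Ties exactly at the z-threshold are excluded (strict inequality).
* The pipeline runner derives per-stage seeds as
  `(seed + CRC32(stage)) mod 2^31` and records config hash, seed and
  library versions in a manifest; re-running a config reproduces all
  outputs exactly.

## Limitations

* The adjusted-distance group signal is small relative to patient-level
  variability and, with hold-out references, undetectable at the synthetic
  conditions; treat ΔNd as a cohort-level read-out, not a per-patient
  classifier.
* Per-gene screening power is intrinsically limited by single-draw noise
  (see above); gene-level recovery should not be expected to approach 100%
  even under strong planted effects.
* The Freeman–Halton test enumerates exhaustively and is capped at a table
  total of 500.
* Cox screening is univariate by design; no multivariable adjustment,
  time-dependent covariates or competing risks.
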