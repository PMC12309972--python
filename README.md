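# ssnetkit

Sample-specific gene co-expression network analysis for treatment-response
cohorts: infer one network per patient from a bulk expression matrix, derive
network features (outcome-adjusted distances, signed gene connectivity,
common-edge weights, pathway topology scores), screen them against survival,
stratify patients, and predict clinical benefit.

## Who this is for

Computational biologists working with clinical trial cohorts (expression +
survival + response categories) who want per-patient network features rather
than cohort-level co-expression modules — for example to ask whether a
patient's co-expression wiring, not just their expression levels, predicts
response to immunotherapy.

## The model

For each patient *S* in a cohort of *n* samples, a sample-specific network is
obtained by weighted interpolation between the cohort-aggregated Pearson
correlation matrix and the leave-one-out matrix computed without that patient:

```
N_ij(S) = W(S) · num · K · ( N_ij(G) − N_ij(G−S) ) + N_ij(G−S)
```

where `num = n − 1`, `K` is a balance factor (default 0.10) and the
genome-wide sample weight

```
W(S) = ( μ_PCC(S,·) − min(PCC) + x ) / ( max(PCC) − min(PCC) + x )
```

(with `x = 0.01`) damps edge-count bias from unbalanced subpopulations;
`μ_PCC(S,·)` is the mean correlation between patient *S* and every other
patient, and `PCC` the set of all pairwise patient-patient correlations.
Each patient's raw weight matrix is z-standardised over its upper triangle
and edges with `|z| > 2.58` (two-sided p = 0.01) are retained, giving a
sparse signed network per patient.

Downstream features:

* **Adjusted network distance** — Jaccard overlap of a patient's edge set
  with clinical-benefit (CB) and no-clinical-benefit (NCB) aggregated
  networks: `Nd_cb`, `Nd_ncb` and `ΔNd = Nd_cb − Nd_ncb`.
* **Signed connectivity** — per-gene weighted degree, computed separately on
  positive- and negative-edge subnetworks.
* **Common-edge weights** — per-patient weights of edges present in every
  network of the cohort, variance-filtered to the top 10,000.
* **Pathway scores** — per (patient, pathway): Shannon entropy of the
  normalised edge-weight distribution (bits), and mean eigenvector /
  closeness / edge-betweenness centrality on the pathway-induced subnetwork
  with edge lengths 1/|w|.

Features are screened with univariate Cox proportional-hazards models and
kept when associated with both overall survival and progression-free
survival (p < 0.01 for genes/edges, p < 0.05 for pathways); selected
features feed Ward/cosine hierarchical clustering with Kaplan–Meier /
log-rank comparison, Freeman–Halton exact tests on cluster composition, and
leave-one-out cross-validated balanced logistic regression for CB-vs-NCB
prediction (ANOVA-F feature selection inside every fold).

A synthetic-cohort generator (`ssnetkit.synthetic`) provides
expression/clinical/gene-set triples with planted, severity-coupled network
structure so the entire pipeline is testable without any data download.

## Worked example

```python
import ssnetkit as sk

cohort = sk.generate_cohort(sk.SyntheticConfig(seed=0))
nets, qc = sk.infer_all_networks(cohort.expression)
print(f"mean density {qc['density'].mean():.4f}, "
      f"mean scale-free R2 {qc['scale_free_r2'].dropna().mean():.3f}")

conn = sk.connectivity_matrix(nets, cohort.expression.gene_ids, sign="positive")
from ssnetkit.features import screened_features
selected, screen = screened_features(conn, cohort.clinical, top_k=None, alpha=0.01)
print(f"{selected.shape[1]} of {conn.shape[1]} genes pass the dual OS+PFS screen")

from ssnetkit.ml import make_response_dataset, loocv_evaluate
edges = sk.edge_weight_matrix(nets)
_, best = loocv_evaluate(make_response_dataset(edges, cohort.clinical))
print(f"edge-feature LOOCV: accuracy {best.accuracy:.2f}, F1 {best.f1:.2f} at k={best.k}")
```

prints

```
mean density 0.0405, mean scale-free R2 0.388
93 of 500 genes pass the dual OS+PFS screen
edge-feature LOOCV: accuracy 0.88, F1 0.88 at k=20
```

The density (~4%) is the fraction of retained gene pairs per patient
network; the screened genes are those whose per-patient connectivity
predicts both survival endpoints; the LOOCV accuracy is honest (feature
selection re-run inside every training fold).

Command line equivalents:

```bash
ssnetkit simulate --seed 0 --out sim/
ssnetkit infer --expr sim/expr.tsv --k 0.10 --z 2.58 --out nets/
ssnetkit features --expr sim/expr.tsv --clinical sim/clin.csv --kind connectivity --out feat/
ssnetkit pathways --expr sim/expr.tsv --gmt sim/sets.gmt --out pscores.tsv
ssnetkit run --seed 0 --out run/        # full pipeline + manifest
```

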