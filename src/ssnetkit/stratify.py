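"""Patient stratification and survival comparison.

Samples are clustered on screened network features by agglomerative
clustering (Ward linkage over cosine distances, two clusters by default);
clusters are compared by Kaplan-Meier curves and the log-rank test, by
clinical-benefit composition with the Freeman-Halton exact test for r x c
contingency tables, and by numeric covariates with the Wilcoxon rank-sum
test.  A median-split helper divides patients on a scalar score instead of
a clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.special import gammaln

from .features import ENDPOINT_COLUMNS
from .io_formats import ClinicalTable


@dataclass
class ClusterAssignment:
    labels: pd.Series  # sample_id -> {1..n_clusters}
    linkage: str
    metric: str
    n_clusters: int


@dataclass
class SurvivalComparison:
    endpoint: str
    statistic: float
    p_value: float
    km_curves: dict[int, pd.DataFrame]  # cluster -> (time, at_risk, survival)
    zero_event_groups: list[int]


def hierarchical_cluster(
    fm: pd.DataFrame,
    n_clusters: int = 2,
    metric: str = "cosine",
    standardize: bool = True,
) -> ClusterAssignment:
    """Ward-linkage agglomerative clustering of samples on cosine distances.

    Ward linkage formally assumes Euclidean distances; applying it to cosine
    distances is a pragmatic convention shared by common clustermap tools
    (use ``metric='euclidean'`` for the pure variant).  Features are
    standardised (mean 0, sd 1) before the distance computation by default.
    Labels are deterministic: clusters are numbered 1..k by the
    lexicographically smallest sample id they contain.
    """
    if fm.shape[0] < n_clusters:
        raise ValueError(f"{fm.shape[0]} samples < {n_clusters} clusters")
    X = fm.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        X = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    d = pdist(X, metric=metric)
    link = hierarchy.linkage(d, method="ward")
    raw = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
    # deterministic relabeling by smallest member id
    order = sorted(set(raw), key=lambda c: min(s for s, r in zip(fm.index, raw) if r == c))
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels = pd.Series([remap[c] for c in raw], index=fm.index, name="cluster")
    return ClusterAssignment(labels=labels, linkage="ward", metric=metric, n_clusters=n_clusters)


def median_split(values: pd.Series) -> pd.Series:
    """Split on the median: values >= median -> group 2 ('high'), else 1."""
    med = values.median()
    return pd.Series(np.where(values >= med, 2, 1), index=values.index, name="cluster")


def logrank_comparison(
    clinical: ClinicalTable, labels: pd.Series, endpoint: str = "OS"
) -> SurvivalComparison:
    """Two-group log-rank test plus Kaplan-Meier step functions.

    A group with zero events is flagged (``zero_event_groups``) rather than
    raising.
    """
    tcol, ecol = ENDPOINT_COLUMNS[endpoint]
    clin = clinical.to_frame().loc[labels.index]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"log-rank comparison needs exactly 2 groups, got {len(groups)}")
    t1 = clin.loc[labels == groups[0], tcol]
    e1 = clin.loc[labels == groups[0], ecol]
    t2 = clin.loc[labels == groups[1], tcol]
    e2 = clin.loc[labels == groups[1], ecol]
    res = _ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
    curves = {}
    zero_events = []
    for g in groups:
        tt = clin.loc[labels == g, tcol]
        ee = clin.loc[labels == g, ecol]
        if ee.sum() == 0:
            zero_events.append(int(g))
        kmf = KaplanMeierFitter()
        kmf.fit(tt, ee)
        ev = kmf.event_table
        curves[int(g)] = pd.DataFrame(
            {
                "time": ev.index.to_numpy(dtype=float),
                "at_risk": ev["at_risk"].to_numpy(dtype=float),
                "survival": kmf.survival_function_["KM_estimate"].to_numpy(dtype=float),
            }
        )
    return SurvivalComparison(
        endpoint=endpoint,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        km_curves=curves,
        zero_event_groups=zero_events,
    )


# ---------------------------------------------------------------------------
# Freeman-Halton exact test


def _log_table_prob(table: np.ndarray, lr: np.ndarray, lc: np.ndarray, ln: float) -> float:
    # log P = sum log r_i! + sum log c_j! - log N! - sum log n_ij!
    return float(lr.sum() + lc.sum() - ln - gammaln(table + 1).sum())


def fisher_exact_rxc(table, max_total: int = 500) -> float:
    """Two-sided Freeman-Halton exact test for an r x c contingency table.

    The p-value sums the hypergeometric probabilities of every table with
    the observed margins whose probability is at most that of the observed
    table (with 1e-12 relative slack for float ties).  Exhaustive
    enumeration is used, so the grand total is capped at ``max_total``.
    """
    t = np.asarray(table)
    if t.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if not np.all(t == np.floor(t)) or np.any(t < 0):
            raise ValueError("table cells must be non-negative integers")
        t = t.astype(int)
    n = int(t.sum())
    if n == 0:
        raise ValueError("table is empty")
    if n > max_total:
        raise ValueError(f"total {n} exceeds exact-enumeration cap {max_total}")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    lr = gammaln(rows + 1)
    lc = gammaln(cols + 1)
    ln = gammaln(n + 1)
    log_obs = _log_table_prob(t, lr, lc, ln)
    cutoff = log_obs + 1e-12 + abs(log_obs) * 1e-12

    r, c = t.shape
    total_p = 0.0

    def rec(row: int, col: int, current: np.ndarray, row_left: np.ndarray, col_left: np.ndarray):
        nonlocal total_p
        if row == r - 1:
            # last row fully determined by column margins
            if np.all(col_left >= 0):
                current[row, :] = col_left
                lp = _log_table_prob(current, lr, lc, ln)
                if lp <= cutoff:
                    total_p += np.exp(lp)
            return
        if col == c - 1:
            v = row_left[row]
            if v < 0 or v > col_left[col]:
                return
            current[row, col] = v
            col_left[col] -= v
            rec(row + 1, 0, current, row_left, col_left)
            col_left[col] += v
            return
        hi = min(row_left[row], col_left[col])
        for v in range(hi + 1):
            current[row, col] = v
            row_left[row] -= v
            col_left[col] -= v
            rec(row, col + 1, current, row_left, col_left)
            row_left[row] += v
            col_left[col] += v

    rec(0, 0, np.zeros_like(t), rows.copy(), cols.copy())
    return float(min(total_p, 1.0))


# ---------------------------------------------------------------------------
# Rank-sum comparison


def group_compare(values: pd.Series, labels: pd.Series) -> float:
    """Two-sided Wilcoxon rank-sum p between the two label groups.

    Exact enumeration when both groups have <= 25 untied observations,
    otherwise the normal approximation with tie correction.  All-tied data
    returns p = 1.
    """
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("group_compare needs exactly two groups")
    a = values[labels == groups[0]].to_numpy(dtype=float)
    b = values[labels == groups[1]].to_numpy(dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >=2 values per group")
    if np.unique(np.concatenate([a, b])).size == 1:
        return 1.0
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (not has_ties and a.size <= 25 and b.size <= 25) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def cluster_composition(
    clinical: ClinicalTable, labels: pd.Series, by: str = "benefit"
) -> tuple[pd.DataFrame, float]:
    """Contingency table of cluster x category plus its exact p-value."""
    clin = clinical.to_frame().loc[labels.index]
    tab = pd.crosstab(labels, clin[by])
    p = fisher_exact_rxc(tab.to_numpy())
    return tab, p
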