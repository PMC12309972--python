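"""Node and edge feature matrices from sample networks, plus survival screens.

Two feature families are derived per patient: signed gene connectivity (the
weighted degree in the positive- or negative-edge subnetwork) and the
weights of edges common to every network in the cohort.  Features are then
filtered by across-sample variance (top 5,000 genes / top 10,000 edges by
default) and screened with univariate Cox models; a feature is selected
when it is significant for both overall survival and progression-free
survival at the configured alpha (default 0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import reduce

import numpy as np
import pandas as pd

from .cox import univariate_cox
from .io_formats import ClinicalTable
from .sweet import SampleNetwork

logger = logging.getLogger(__name__)

ENDPOINT_COLUMNS = {"OS": ("os_time", "os_event"), "PFS": ("pfs_time", "pfs_event")}


# ---------------------------------------------------------------------------
# Node features


def split_signed(net: SampleNetwork) -> tuple[SampleNetwork, SampleNetwork]:
    """Partition a network into positive- and negative-edge subnetworks.

    Negative-edge weights are stored as absolute values so both halves carry
    non-negative strengths.  Thresholding guarantees no zero-weight edges.
    """
    pos = {e: (w, z) for e, (w, z) in net.edges.items() if w > 0}
    neg = {e: (abs(w), z) for e, (w, z) in net.edges.items() if w < 0}
    return (
        SampleNetwork(net.sample_id, pos, net.n_genes),
        SampleNetwork(net.sample_id, neg, net.n_genes),
    )


def gene_connectivity(net: SampleNetwork, gene_ids: list[str] | None = None) -> pd.Series:
    """Weighted degree per gene: sum of incident edge weights (0 if isolated)."""
    conn: dict[str, float] = {}
    for (a, b), (w, _) in net.edges.items():
        if w < 0:
            raise ValueError("gene_connectivity expects a signed-split network")
        conn[a] = conn.get(a, 0.0) + w
        conn[b] = conn.get(b, 0.0) + w
    if gene_ids is None:
        gene_ids = sorted(conn)
    return pd.Series([conn.get(g, 0.0) for g in gene_ids], index=gene_ids, name=net.sample_id)


def connectivity_matrix(
    nets: dict[str, SampleNetwork], gene_ids: list[str], sign: str = "positive"
) -> pd.DataFrame:
    """Samples x genes connectivity matrix for one correlation sign."""
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    rows = []
    for sid, net in nets.items():
        pos, neg = split_signed(net)
        rows.append(gene_connectivity(pos if sign == "positive" else neg, gene_ids))
    return pd.DataFrame(rows, index=list(nets))


# ---------------------------------------------------------------------------
# Edge features


def common_edges(nets: list[SampleNetwork]) -> list[tuple[str, str]]:
    """Edges present in every network, in canonical sorted order."""
    if not nets:
        raise ValueError("need >=1 network")
    inter = reduce(lambda a, b: a & b, (n.edge_set() for n in nets))
    if not inter:
        logger.warning("no edges are common to all %d networks", len(nets))
    return sorted(inter)


def edge_weight_matrix(
    nets: dict[str, SampleNetwork], edges: list[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Samples x common-edges matrix of each sample's stored edge weight."""
    if edges is None:
        edges = common_edges(list(nets.values()))
    cols = [f"{a}|{b}" for a, b in edges]
    data = np.empty((len(nets), len(edges)))
    for i, net in enumerate(nets.values()):
        for j, e in enumerate(edges):
            data[i, j] = net.edges[e][0]
    return pd.DataFrame(data, index=list(nets), columns=cols)


# ---------------------------------------------------------------------------
# Variance filter


def top_variance_features(fm: pd.DataFrame, k: int) -> pd.DataFrame:
    """Keep the k features with largest across-sample variance (ddof=1).

    Ties are broken lexicographically by feature id so the result is
    deterministic.
    """
    if k > fm.shape[1]:
        raise ValueError(f"k={k} exceeds feature count {fm.shape[1]}")
    var = fm.var(axis=0, ddof=1)
    order = sorted(fm.columns, key=lambda c: (-var[c], c))
    return fm[order[:k]]


# ---------------------------------------------------------------------------
# Cox screen


@dataclass
class CoxScreenResult:
    feature_id: str
    coef: float
    hazard_ratio: float
    p_os: float
    p_pfs: float
    selected: bool


def cox_screen(
    fm: pd.DataFrame,
    clinical: ClinicalTable,
    alpha: float = 0.01,
    require_both: bool = True,
    endpoints: tuple[str, ...] = ("OS", "PFS"),
) -> pd.DataFrame:
    """Univariate Cox screen of every feature against OS and PFS.

    Each feature is standardised and fit one at a time (Breslow ties, Wald
    p).  ``selected`` requires p < alpha for both endpoints when
    ``require_both`` (the default), else for the first endpoint listed.
    Samples missing an endpoint are dropped from that endpoint's fits only.
    Returns a DataFrame indexed by feature id with columns coef,
    hazard_ratio, p_os, p_pfs, selected (coef/HR are from the OS fit when OS
    is screened).
    """
    clin = clinical.to_frame().loc[list(fm.index)]
    if len(fm.index) < 10:
        raise ValueError("cox_screen needs >=10 samples")
    pvals: dict[str, np.ndarray] = {}
    coefs: dict[str, np.ndarray] = {}
    for ep in endpoints:
        tcol, ecol = ENDPOINT_COLUMNS[ep]
        t = clin[tcol].to_numpy(dtype=float)
        e = clin[ecol].to_numpy(dtype=float)
        ok = np.isfinite(t) & np.isfinite(e)
        X = fm.to_numpy(dtype=float)[ok]
        fits = univariate_cox(X, t[ok], e[ok].astype(int))
        pvals[ep] = np.array([f.p for f in fits])
        coefs[ep] = np.array([f.coef for f in fits])
    first = endpoints[0]
    if require_both and len(endpoints) > 1:
        selected = np.all([pvals[ep] < alpha for ep in endpoints], axis=0)
    else:
        selected = pvals[first] < alpha
    out = pd.DataFrame(
        {
            "coef": coefs[first],
            "hazard_ratio": np.exp(coefs[first]),
            "p_os": pvals.get("OS", np.full(fm.shape[1], np.nan)),
            "p_pfs": pvals.get("PFS", np.full(fm.shape[1], np.nan)),
            "selected": selected,
        },
        index=pd.Index(fm.columns, name="feature_id"),
    )
    return out


def screened_features(
    fm: pd.DataFrame,
    clinical: ClinicalTable,
    top_k: int | None,
    alpha: float = 0.01,
    require_both: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Variance filter then dual-endpoint Cox screen; returns the selected
    feature submatrix and the full screen table."""
    if top_k is not None and top_k < fm.shape[1]:
        fm = top_variance_features(fm, top_k)
    screen = cox_screen(fm, clinical, alpha=alpha, require_both=require_both)
    keep = screen.index[screen["selected"]]
    return fm[list(keep)], screen
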