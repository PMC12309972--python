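"""Network distances between sample networks and outcome-aggregated networks.

The base quantity is the Jaccard overlap of two edge sets,
Nd = |Ei ∩ Ej| / |Ei ∪ Ej|, a similarity-valued score in [0, 1].  The
outcome-adjusted variant compares one patient's edge set against aggregated
networks built from the clinical-benefit (CB) and no-clinical-benefit (NCB)
groups, and reports Nd_cb, Nd_ncb and their difference ΔNd = Nd_cb - Nd_ncb.
Patients similar to the CB reference (high ΔNd) are expected to fare better.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import ClinicalTable, ExpressionMatrix
from .sweet import SampleNetwork, SweetParams, compute_pcc_matrix, zscore_threshold

EdgeSet = frozenset  # of canonically ordered (gene_a, gene_b) pairs


@dataclass
class DistanceResult:
    sample_id: str
    nd_cb: float | None
    nd_ncb: float | None
    delta_nd: float | None


def network_similarity(e_i: frozenset, e_j: frozenset) -> float | None:
    """Jaccard overlap of two edge sets; ``None`` when both are empty."""
    union = len(e_i | e_j)
    if union == 0:
        return None
    return len(e_i & e_j) / union


def aggregate_group_network(
    expr: ExpressionMatrix,
    group_sample_ids: list[str],
    params: SweetParams = SweetParams(),
    exclude: str | None = None,
) -> frozenset:
    """Edge set of a group-level network: plain group PCC + z-thresholding.

    ``exclude`` drops one sample (typically the patient being compared)
    from the aggregation so a patient is never part of its own reference.
    """
    ids = [s for s in group_sample_ids if s != exclude]
    if len(ids) < 3:
        raise ValueError(f"need >=3 samples to aggregate, got {len(ids)}")
    corr = compute_pcc_matrix(expr, ids)
    edges = zscore_threshold(corr.weights, corr.gene_ids, params, sample_id="<group>")
    return frozenset(edges)


def adjusted_distance(
    sample_id: str, sample_edges: frozenset, e_cb: frozenset, e_ncb: frozenset
) -> DistanceResult:
    nd_cb = network_similarity(sample_edges, e_cb)
    nd_ncb = network_similarity(sample_edges, e_ncb)
    delta = None if nd_cb is None or nd_ncb is None else nd_cb - nd_ncb
    return DistanceResult(sample_id=sample_id, nd_cb=nd_cb, nd_ncb=nd_ncb, delta_nd=delta)


def adjusted_distances(
    expr: ExpressionMatrix,
    nets: dict[str, SampleNetwork],
    clinical: ClinicalTable,
    params: SweetParams = SweetParams(),
    holdout: bool = True,
) -> pd.DataFrame:
    """Outcome-adjusted distances for every sample with a network.

    CB and NCB reference networks are aggregated from the respective benefit
    groups (ICB patients contribute to neither).  With ``holdout`` (default),
    a patient in the group being aggregated is excluded from that
    aggregation; ``holdout=False`` reproduces the naive variant.
    """
    groups = clinical.benefit_groups()
    cb_ids = [s for s in groups["CB"] if s in nets]
    ncb_ids = [s for s in groups["NCB"] if s in nets]
    base_cb = aggregate_group_network(expr, cb_ids, params)
    base_ncb = aggregate_group_network(expr, ncb_ids, params)
    rows = []
    for s, net in nets.items():
        e_cb, e_ncb = base_cb, base_ncb
        if holdout and s in cb_ids:
            e_cb = aggregate_group_network(expr, cb_ids, params, exclude=s)
        if holdout and s in ncb_ids:
            e_ncb = aggregate_group_network(expr, ncb_ids, params, exclude=s)
        res = adjusted_distance(s, net.edge_set(), e_cb, e_ncb)
        rows.append(
            {
                "sample_id": res.sample_id,
                "nd_cb": res.nd_cb,
                "nd_ncb": res.nd_ncb,
                "delta_nd": res.delta_nd,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def pairwise_similarity(nets: dict[str, SampleNetwork]) -> pd.DataFrame:
    """All-vs-all Jaccard similarity matrix (utility; not an endpoint)."""
    ids = list(nets)
    sets = {s: nets[s].edge_set() for s in ids}
    mat = pd.DataFrame(index=ids, columns=ids, dtype=float)
    for i, a in enumerate(ids):
        mat.loc[a, a] = 1.0
        for b in ids[i + 1 :]:
            v = network_similarity(sets[a], sets[b])
            mat.loc[a, b] = mat.loc[b, a] = float("nan") if v is None else v
    return mat
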