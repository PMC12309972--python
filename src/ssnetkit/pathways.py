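"""Sample-specific pathway subnetworks and topology scores.

For each (sample, pathway) pair the pathway's gene set induces a subnetwork
of that sample's co-expression network; edge weights are taken in absolute
value so positive and negative co-expression both contribute strength.
Four scores summarise the subnetwork:

* entropy (bits): Shannon entropy of the normalised edge-weight
  distribution, H = -sum p_k log2 p_k with p_k = w_k / sum(w) — low when a
  few edges dominate, log2(m) when all m edges are equally strong;
* eigenvector score: mean gene eigenvector centrality (per connected
  component, principal eigenvector of the weighted adjacency normalised so
  the largest entry is 1);
* closeness score: mean gene closeness centrality with edge lengths 1/|w|
  (stronger co-expression = shorter distance), computed within each node's
  reachable set for disconnected graphs;
* betweenness score: mean edge betweenness (number of shortest paths over
  unordered gene pairs through the edge, split across ties).

Pathways with fewer than ``min_edges`` edges in a sample yield missing
scores rather than unstable numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import GeneSetCollection
from .sweet import SampleNetwork

DEFAULT_MIN_EDGES = 3


@dataclass
class PathwayNetwork:
    """Induced pathway subnetwork with absolute edge weights."""

    pathway_name: str
    sample_id: str
    edges: dict[tuple[str, str], float]  # canonical pair -> |weight| > 0

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w, length=1.0 / w)
        return g


def extract_pathway_network(
    net: SampleNetwork, gene_set: set[str], pathway_name: str = ""
) -> PathwayNetwork:
    """Induced subgraph of a sample network on a pathway's genes.

    Genes absent from the network are dropped here (use time), and signed
    weights are converted to absolute values.
    """
    edges = {
        (a, b): abs(w)
        for (a, b), (w, _) in net.edges.items()
        if a in gene_set and b in gene_set
    }
    return PathwayNetwork(pathway_name=pathway_name, sample_id=net.sample_id, edges=edges)


# ---------------------------------------------------------------------------
# Scores


def pathway_entropy(pn: PathwayNetwork) -> float | None:
    """Shannon entropy (bits) of the edge-weight distribution; None if empty."""
    if pn.n_edges == 0:
        return None
    w = np.fromiter(pn.edges.values(), dtype=float)
    p = w / w.sum()
    return float(-(p * np.log2(p)).sum())


def eigenvector_score(pn: PathwayNetwork, min_edges: int = DEFAULT_MIN_EDGES) -> float | None:
    """Mean eigenvector centrality over pathway genes.

    Computed per connected component: the principal eigenvector of the
    component's weighted adjacency, taken non-negative and scaled so its
    largest entry is 1.
    """
    if pn.n_edges < min_edges:
        return None
    g = pn.to_graph()
    cents: list[float] = []
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        if len(nodes) == 1:
            cents.append(1.0)
            continue
        sub = g.subgraph(nodes)
        adj = nx.to_numpy_array(sub, nodelist=nodes, weight="weight")
        vals, vecs = np.linalg.eigh(adj)
        v = np.abs(vecs[:, -1])
        v = v / v.max()
        cents.extend(v.tolist())
    return float(np.mean(cents))


def closeness_score(pn: PathwayNetwork, min_edges: int = DEFAULT_MIN_EDGES) -> float | None:
    """Mean closeness centrality with edge lengths 1/|w|.

    Per node: (reachable - 1) / sum of shortest-path lengths to reachable
    nodes; unreachable nodes simply do not contribute to a node's sum.
    """
    if pn.n_edges < min_edges:
        return None
    g = pn.to_graph()
    vals = []
    for node in g.nodes:
        dist = nx.single_source_dijkstra_path_length(g, node, weight="length")
        total = sum(d for n, d in dist.items() if n != node)
        reachable = len(dist) - 1
        vals.append(reachable / total if total > 0 else 0.0)
    return float(np.mean(vals))


def betweenness_score(pn: PathwayNetwork, min_edges: int = DEFAULT_MIN_EDGES) -> float | None:
    """Mean edge betweenness: shortest paths (lengths 1/|w|) over unordered
    node pairs through each edge, with tie-splitting."""
    if pn.n_edges < min_edges:
        return None
    g = pn.to_graph()
    eb = nx.edge_betweenness_centrality(g, normalized=False, weight="length")
    return float(np.mean(list(eb.values())))


# ---------------------------------------------------------------------------
# Batch driver


def score_pathway(
    pn: PathwayNetwork, min_edges: int = DEFAULT_MIN_EDGES
) -> dict[str, float | None]:
    return {
        "entropy": pathway_entropy(pn),
        "eig_score": eigenvector_score(pn, min_edges),
        "closeness_score": closeness_score(pn, min_edges),
        "betweenness_score": betweenness_score(pn, min_edges),
        "n_edges": pn.n_edges,
    }


def score_all(
    nets: dict[str, SampleNetwork],
    gene_sets: GeneSetCollection,
    min_edges: int = DEFAULT_MIN_EDGES,
) -> pd.DataFrame:
    """One row per (sample, pathway) with the four scores (NaN = undefined)."""
    rows = []
    set_members = [(name, set(genes)) for name, _, genes in gene_sets]
    for sid, net in nets.items():
        for name, members in set_members:
            pn = extract_pathway_network(net, members, pathway_name=name)
            row = {"sample_id": sid, "pathway": name}
            row.update(
                {k: (math.nan if v is None else v) for k, v in score_pathway(pn, min_edges).items()}
            )
            rows.append(row)
    return pd.DataFrame(rows)


def pivot_scores(scores: pd.DataFrame, score: str) -> pd.DataFrame:
    """Samples x pathways matrix for one score kind (NaN where undefined)."""
    return scores.pivot(index="sample_id", columns="pathway", values=score)
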