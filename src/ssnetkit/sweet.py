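"""Single-sample co-expression network inference by weighted interpolation.

Each patient's network is obtained by comparing the cohort-aggregated
Pearson correlation matrix N(G) with the leave-one-out matrix N(G-S)
computed without that patient:

    N(S) = W(S) * num * K * (N(G) - N(G-S)) + N(G-S)

where ``num`` is the number of samples excluding the target, ``K`` is a
balance factor (default 10%) that rescales the differential correlation, and
W(S) is a genome-wide sample weight that neutralises edge-number bias from
unbalanced subpopulations:

    W(S) = (mu_PCC(S,P) - min(PCC_S) + x) / (max(PCC_S) - min(PCC_S) + x)

with mu_PCC(S,P) the mean sample-sample correlation between the target and
every other patient, PCC_S the set of all pairwise sample-sample
correlations and x a small division-safety constant (default 0.01).

Raw weights are then z-standardised per sample over the upper triangle and
edges with |z| above a two-sided threshold (default 2.58, p = 0.01) are
retained.  The module is fully deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SweetParams:
    """Tuning constants for single-sample network inference."""

    k: float = 0.10          # balance factor in (0, 1]
    x: float = 0.01          # division-safety constant in the sample weight
    z_threshold: float = 2.58  # two-sided edge-retention threshold

    def __post_init__(self) -> None:
        if not (0 < self.k <= 1):
            raise ValueError(f"balance factor K must be in (0, 1], got {self.k}")
        if self.x <= 0:
            raise ValueError(f"x must be > 0, got {self.x}")
        if self.z_threshold <= 0:
            raise ValueError(f"z_threshold must be > 0, got {self.z_threshold}")


@dataclass
class CorrelationNetwork:
    """Symmetric gene-gene Pearson correlation matrix (diagonal ignored)."""

    gene_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.gene_ids), len(self.gene_ids)):
            raise ValueError("weights must be square over gene_ids")
        self.weights = w


@dataclass
class SampleWeight:
    sample_id: str
    w: float
    mu: float
    pcc_min: float
    pcc_max: float


@dataclass
class SampleNetwork:
    """One patient's sparse signed network after interpolation + thresholding.

    ``edges`` maps canonically ordered gene pairs to (weight, z) where the
    weight is the interpolated correlation value N(S) (signed) and z is the
    per-sample standardised score that passed the threshold.
    """

    sample_id: str
    edges: dict[tuple[str, str], tuple[float, float]]
    n_genes: int

    def __post_init__(self) -> None:
        for (a, b) in self.edges:
            if a == b:
                raise ValueError(f"self-edge {a!r} in network {self.sample_id!r}")
            if a > b:
                raise ValueError(f"edge {(a, b)} not canonically ordered")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.edges)

    def genes_with_edges(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def degrees(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for a, b in self.edges:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        return deg


@dataclass
class NetworkQC:
    sample_id: str
    density: float
    scale_free_r2: float | None
    sample_weight: float | None = None


# ---------------------------------------------------------------------------
# Correlation machinery


def _check_variance(values: np.ndarray, gene_ids: list[str]) -> None:
    var = values.var(axis=1)
    bad = np.flatnonzero(var == 0)
    if bad.size:
        raise ValueError(f"zero-variance gene in correlation input: {gene_ids[bad[0]]!r}")


def compute_pcc_matrix(
    expr: ExpressionMatrix, sample_subset: list[str] | None = None
) -> CorrelationNetwork:
    """Pearson correlation matrix over gene pairs for a (subset of a) cohort."""
    sub = expr if sample_subset is None else expr.subset_samples(sample_subset)
    if sub.n_samples < 3:
        raise ValueError(f"need >=3 samples for correlations, got {sub.n_samples}")
    _check_variance(sub.values, sub.gene_ids)
    w = np.corrcoef(sub.values)
    np.clip(w, -1.0, 1.0, out=w)
    return CorrelationNetwork(list(sub.gene_ids), w)


def sample_pcc_matrix(expr: ExpressionMatrix) -> np.ndarray:
    """Sample-sample Pearson correlations over genome-wide expression vectors."""
    return np.clip(np.corrcoef(expr.values.T), -1.0, 1.0)


def compute_sample_weight(
    expr: ExpressionMatrix,
    target_sample: str,
    params: SweetParams = SweetParams(),
    _sample_pcc: np.ndarray | None = None,
) -> SampleWeight:
    if expr.n_samples < 3:
        raise ValueError("need >=3 samples to compute a sample weight")
    if target_sample not in expr.sample_ids:
        raise KeyError(f"sample {target_sample!r} not in cohort")
    pcc = sample_pcc_matrix(expr) if _sample_pcc is None else _sample_pcc
    i = expr.sample_ids.index(target_sample)
    others = np.delete(np.arange(expr.n_samples), i)
    mu = float(pcc[i, others].mean())
    iu = np.triu_indices(expr.n_samples, k=1)
    all_pairs = pcc[iu]
    lo, hi = float(all_pairs.min()), float(all_pairs.max())
    w = (mu - lo + params.x) / (hi - lo + params.x)
    return SampleWeight(sample_id=target_sample, w=w, mu=mu, pcc_min=lo, pcc_max=hi)


# ---------------------------------------------------------------------------
# Thresholding


def zscore_threshold(
    raw_weights: np.ndarray,
    gene_ids: list[str],
    params: SweetParams = SweetParams(),
    sample_id: str = "",
) -> dict[tuple[str, str], tuple[float, float]]:
    """Standardise a raw weight matrix over its upper triangle and keep
    edges with |z| strictly above the threshold.

    A degenerate matrix (zero spread) yields an empty edge set with a logged
    warning rather than an error.
    """
    n = len(gene_ids)
    iu = np.triu_indices(n, k=1)
    vals = np.asarray(raw_weights, dtype=float)[iu]
    mean = vals.mean()
    sd = vals.std(ddof=0)
    if sd == 0:
        logger.warning(
            "sample %s: all raw edge weights equal; degenerate (empty) network",
            sample_id or "<unnamed>",
        )
        return {}
    z = (vals - mean) / sd
    keep = np.abs(z) > params.z_threshold
    edges: dict[tuple[str, str], tuple[float, float]] = {}
    rows, cols = iu[0][keep], iu[1][keep]
    for r, c, w, zz in zip(rows, cols, vals[keep], z[keep]):
        a, b = gene_ids[r], gene_ids[c]
        if a > b:
            a, b = b, a
        edges[(a, b)] = (float(w), float(zz))
    return edges


# ---------------------------------------------------------------------------
# Single-sample inference


def interpolate(
    n_g: np.ndarray, n_g_minus_s: np.ndarray, w: float, num: int, k: float
) -> np.ndarray:
    """Entrywise N(S) = W * num * K * (N(G) - N(G-S)) + N(G-S)."""
    return w * num * k * (n_g - n_g_minus_s) + n_g_minus_s


def infer_sample_network(
    expr: ExpressionMatrix,
    target_sample: str,
    params: SweetParams = SweetParams(),
    _agg: CorrelationNetwork | None = None,
    _sample_pcc: np.ndarray | None = None,
) -> SampleNetwork:
    """Infer one patient's sparse signed network from the cohort matrix."""
    if expr.n_samples < 4:
        raise ValueError("need >=4 samples (leave-one-out keeps >=3)")
    agg = compute_pcc_matrix(expr) if _agg is None else _agg
    others = [s for s in expr.sample_ids if s != target_sample]
    if len(others) == expr.n_samples:
        raise KeyError(f"sample {target_sample!r} not in cohort")
    loo = compute_pcc_matrix(expr, others)
    sw = compute_sample_weight(expr, target_sample, params, _sample_pcc=_sample_pcc)
    num = expr.n_samples - 1
    raw = interpolate(agg.weights, loo.weights, sw.w, num, params.k)
    edges = zscore_threshold(raw, expr.gene_ids, params, sample_id=target_sample)
    return SampleNetwork(sample_id=target_sample, edges=edges, n_genes=expr.n_genes)


def infer_all_networks(
    expr: ExpressionMatrix, params: SweetParams = SweetParams()
) -> tuple[dict[str, SampleNetwork], pd.DataFrame]:
    """Infer networks for every sample; returns networks and a QC table.

    The aggregated matrix and the sample-sample correlation matrix are
    computed once and shared across samples.
    """
    agg = compute_pcc_matrix(expr)
    spcc = sample_pcc_matrix(expr)
    nets: dict[str, SampleNetwork] = {}
    qc_rows = []
    for s in expr.sample_ids:
        net = infer_sample_network(expr, s, params, _agg=agg, _sample_pcc=spcc)
        nets[s] = net
        sw = compute_sample_weight(expr, s, params, _sample_pcc=spcc)
        qc_rows.append(
            {
                "sample_id": s,
                "density": network_density(net),
                "scale_free_r2": scale_free_r2(net),
                "sample_weight": sw.w,
                "n_edges": net.n_edges,
            }
        )
    return nets, pd.DataFrame(qc_rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# QC


def network_density(net: SampleNetwork) -> float:
    if net.n_genes < 2:
        raise ValueError("density needs >=2 genes")
    return net.n_edges / (net.n_genes * (net.n_genes - 1) / 2)


def scale_free_r2(net: SampleNetwork, n_bins: int = 20) -> float | None:
    """R^2 of the log-log linear fit of the binarized degree distribution.

    Degrees come from the thresholded network.  Nonzero degrees are histogram-
    binned into ``n_bins`` log-spaced bins; for each occupied bin we regress
    log10(fraction of nodes) on log10(mean degree).  Returns ``None`` when
    fewer than two occupied bins exist (e.g. regular graphs).
    """
    degrees = np.array([d for d in net.degrees().values() if d > 0], dtype=float)
    return degree_distribution_r2(degrees, n_bins=n_bins)


def degree_distribution_r2(degrees: np.ndarray, n_bins: int = 20) -> float | None:
    degrees = np.asarray(degrees, dtype=float)
    degrees = degrees[degrees > 0]
    if degrees.size == 0:
        return None
    lo, hi = degrees.min(), degrees.max()
    if lo == hi:
        return None
    edges = np.logspace(math.log10(lo), math.log10(hi), n_bins + 1)
    edges[-1] *= 1 + 1e-12  # right-closed top bin
    idx = np.digitize(degrees, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        xs.append(math.log10(degrees[mask].mean()))
        ys.append(math.log10(mask.sum() / degrees.size))
    if len(xs) < 2:
        return None
    fit = stats.linregress(xs, ys)
    return float(fit.rvalue**2)
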