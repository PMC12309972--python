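"""End-to-end orchestration: simulate -> infer -> features/distances/pathways
-> stratify -> predict, with manifest logging and deterministic re-runs.

Every stage is a pure function of (inputs, config, seed); the single global
seed fans out to per-stage seeds via ``stage_seed``.  The manifest records
the config hash, seed and library versions so a run can be reproduced
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .distance import adjusted_distances
from .features import connectivity_matrix, edge_weight_matrix, screened_features
from .io_formats import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    read_clinical,
    read_expression,
    read_gmt,
    write_clinical,
    write_edge_list,
    write_expression,
    write_gmt,
)
from .ml import loocv_evaluate, make_response_dataset
from .pathways import pivot_scores, score_all
from .stratify import cluster_composition, hierarchical_cluster, logrank_comparison
from .sweet import SweetParams, infer_all_networks
from .synthetic import SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "sweet": {"k": 0.10, "x": 0.01, "z_threshold": 2.58},
    "screening": {
        "alpha_features": 0.01,
        "alpha_pathways": 0.05,
        "top_k_genes": 5000,
        "top_k_edges": 10000,
    },
    "pathways": {"min_edges": 3},
    "clustering": {"n_clusters": 2, "metric": "cosine", "standardize": True},
    "ml": {"k_grid": list(range(10, 101, 10)), "C": 1.0},
    "simulate": {},
}


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed: (seed + CRC32 of the stage name) mod 2^31."""
    return (int(seed) + zlib.crc32(stage.encode())) % (2**31)


def config_hash(cfg: dict[str, Any]) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def merged_config(user: dict[str, Any] | None) -> dict[str, Any]:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (user or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def write_manifest(out_dir: Path, cfg: dict[str, Any], extra: dict[str, Any] | None = None) -> None:
    import lifelines
    import networkx
    import scipy
    import sklearn

    manifest = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": cfg.get("seed"),
        "versions": {
            "ssnetkit": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "lifelines": lifelines.__version__,
            "networkx": networkx.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run_pipeline(
    cfg: dict[str, Any],
    out_dir: str | Path,
    expr: ExpressionMatrix | None = None,
    clinical: ClinicalTable | None = None,
    gene_sets: GeneSetCollection | None = None,
) -> dict[str, Any]:
    """Run every stage, writing per-stage outputs and a manifest.

    When no expression matrix is supplied, a synthetic cohort is generated
    from ``cfg['simulate']`` with the stage-derived seed.  Returns a summary
    dict (also written to ``summary.json``).
    """
    cfg = merged_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {}

    stage = "simulate"
    if expr is None:
        sim_kwargs = dict(cfg["simulate"])
        sim_kwargs.setdefault("seed", stage_seed(cfg["seed"], stage))
        scfg = SyntheticConfig(**sim_kwargs)
        cohort = generate_cohort(scfg)
        expr, clinical, gene_sets = cohort.expression, cohort.clinical, cohort.gene_sets
        write_expression(expr, out / "expr.tsv")
        write_clinical(clinical, out / "clin.csv")
        write_gmt(gene_sets, out / "sets.gmt")
        with open(out / "truth.json", "w") as fh:
            json.dump(
                {
                    "group": cohort.truth.group,
                    "planted_blocks": cohort.truth.planted_blocks,
                    "planted_pathways": cohort.truth.planted_pathways,
                },
                fh,
                indent=2,
            )
        summary["simulate"] = {"n_samples": expr.n_samples, "n_genes": expr.n_genes}
    if clinical is None:
        raise ValueError("clinical table required when expression is supplied")

    try:
        stage = "infer"
        params = SweetParams(
            k=cfg["sweet"]["k"], x=cfg["sweet"]["x"], z_threshold=cfg["sweet"]["z_threshold"]
        )
        nets, qc = infer_all_networks(expr, params)
        net_dir = out / "networks"
        net_dir.mkdir(exist_ok=True)
        for sid, net in nets.items():
            write_edge_list(net, net_dir / f"{sid}.tsv")
        qc.to_csv(out / "network_qc.tsv", sep="\t")
        summary["infer"] = {
            "mean_density": float(qc["density"].mean()),
            "mean_scale_free_r2": float(qc["scale_free_r2"].dropna().mean()),
        }

        stage = "distance"
        dist = adjusted_distances(expr, nets, clinical, params)
        dist.to_csv(out / "distances.tsv", sep="\t")
        summary["distance"] = {"mean_delta_nd": float(dist["delta_nd"].dropna().mean())}

        stage = "features"
        scr = cfg["screening"]
        conn = connectivity_matrix(nets, expr.gene_ids, sign="positive")
        sel_conn, conn_screen = screened_features(
            conn, clinical, top_k=scr["top_k_genes"], alpha=scr["alpha_features"]
        )
        conn_screen.to_csv(out / "connectivity_screen.tsv", sep="\t")
        edge_fm = edge_weight_matrix(nets)
        if edge_fm.shape[1] > 0:
            if edge_fm.shape[1] > scr["top_k_edges"]:
                from .features import top_variance_features

                edge_fm = top_variance_features(edge_fm, scr["top_k_edges"])
            sel_edges, edge_screen = screened_features(
                edge_fm, clinical, top_k=None, alpha=scr["alpha_features"]
            )
            edge_screen.to_csv(out / "edge_screen.tsv", sep="\t")
        else:
            sel_edges = edge_fm
        summary["features"] = {
            "n_selected_genes": int(sel_conn.shape[1]),
            "n_common_edges": int(edge_fm.shape[1]),
            "n_selected_edges": int(sel_edges.shape[1]),
        }

        stage = "pathways"
        if gene_sets is not None:
            scores = score_all(nets, gene_sets, min_edges=cfg["pathways"]["min_edges"])
            scores.to_csv(out / "pathway_scores.tsv", sep="\t", index=False)
            entropy_fm = pivot_scores(scores, "entropy")
            summary["pathways"] = {"n_pathways": int(entropy_fm.shape[1])}

        stage = "stratify"
        clus_cfg = cfg["clustering"]
        strat_fm = sel_conn if sel_conn.shape[1] >= 2 else conn
        assignment = hierarchical_cluster(
            strat_fm,
            n_clusters=clus_cfg["n_clusters"],
            metric=clus_cfg["metric"],
            standardize=clus_cfg["standardize"],
        )
        assignment.labels.to_csv(out / "clusters.tsv", sep="\t")
        strat_summary = {}
        for ep in ("OS", "PFS"):
            comp = logrank_comparison(clinical, assignment.labels, endpoint=ep)
            strat_summary[f"logrank_p_{ep.lower()}"] = comp.p_value
        tab, fisher_p = cluster_composition(clinical, assignment.labels)
        tab.to_csv(out / "cluster_composition.tsv", sep="\t")
        strat_summary["fisher_p_benefit"] = fisher_p
        summary["stratify"] = strat_summary

        stage = "predict"
        ml_cfg = cfg["ml"]
        ds = make_response_dataset(conn, clinical)
        _, best = loocv_evaluate(ds, k_grid=tuple(ml_cfg["k_grid"]), C=ml_cfg["C"])
        summary["predict"] = {
            "connectivity_loocv_accuracy": best.accuracy,
            "connectivity_loocv_f1": best.f1,
            "best_k": best.k,
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    write_manifest(out, cfg)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def load_inputs(
    expr_path: str | Path,
    clinical_path: str | Path | None = None,
    gmt_path: str | Path | None = None,
):
    expr = read_expression(expr_path)
    clinical = read_clinical(clinical_path) if clinical_path else None
    gene_sets = read_gmt(gmt_path) if gmt_path else None
    return expr, clinical, gene_sets
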