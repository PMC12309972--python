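"""Synthetic cohorts with outcome-coupled co-expression structure.

The generator emulates the study conditions the pipeline targets: a bulk
expression cohort (log2-TPM scale, treated as Gaussian) with correlated
gene modules and a latent, continuous per-sample *severity* that couples
network dysregulation to outcome.  Poor responders in real cohorts show
elevated connectivity and stronger negative gene-gene associations; here
that hallmark is planted explicitly:

* a *disease* module whose internal co-expression strengthens with a
  sample's severity, and a *background* module of equal size whose
  co-expression weakens correspondingly — so severity reshapes the
  relative edge-weight distribution rather than globally rescaling it
  (a global rescaling would be removed by the per-sample z-normalisation
  of the network inference and carry no signal);
* within each module, genes load on a moving-average window of latent
  factors, giving a gradient of pair correlations from strong (adjacent
  genes) to zero — so part of every gene's edges sit near the retention
  threshold, where single-sample networks are most informative;
* background factors are negatively coupled to disease factors with a
  per-sample strength that grows with severity, planting the stronger
  negative gene-gene associations of poor responders;
* severity is bimodal: a latent good/poor group (Bernoulli with
  ``frac_poor_outcome``) sets the severity centre at -1 or +1 and
  ``severity_within_sd`` adds within-group spread — two latent outcome
  groups with patient-level heterogeneity around them;
* survival is exponential with a log-hazard proportional to severity
  (proportional hazards by construction), scaled so the realised hazard
  ratio between the group centres equals ``hazard_ratio_poor``.  PFS runs
  at twice the OS baseline hazard with a steeper severity slope,
  mirroring benefit categories that are defined primarily through
  progression.
* benefit labels follow the groups (CB = good, NCB = poor) with a
  configurable ICB fraction reassigned at random; marginal gene means are
  identical across groups, so mean-based expression features carry no
  signal — the signal lives in the co-expression structure.

``effect_size`` scales both the severity spread and the log hazard ratio
(none = 0, weak = 0.375, strong = 1, following a 0.15 : 0.4 weak : strong
convention); with ``effect_size="none"`` expression and survival are
independent and the whole pipeline sees a calibrated null.  All randomness
flows from the single config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .io_formats import (
    ClinicalRecord,
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
)

EFFECT_SCALE = {"none": 0.0, "weak": 0.375, "strong": 1.0}


@dataclass(frozen=True)
class SyntheticConfig:
    n_samples: int = 100
    n_genes: int = 500
    n_blocks: int = 1          # disease modules (an equal number of background modules is added)
    block_size: int = 100
    within_block_corr: float = 0.5   # communality scale: adjacent-gene correlation in a module
    neg_block_corr: float = -0.4     # max disease-background factor anti-correlation
    effect_size: str = "strong"      # {"none", "weak", "strong"}
    severity_spread: float = 1.6     # log-scale gain of the module-strength multiplier at strong effect
    severity_within_sd: float = 0.5  # within-group spread of the latent severity
    frac_poor_outcome: float = 0.5
    baseline_hazard: float = 1.0 / 365.0  # OS events per day at severity 0; PFS baseline is 2x
    hazard_ratio_poor: float = 10.0  # realised OS hazard ratio poor vs good at strong effect
    pfs_slope_factor: float = 1.25   # PFS severity slope relative to OS
    censor_rate: float = 1.0 / 3000.0
    icb_fraction: float = 0.2
    planted_set_size: int = 25
    n_decoy_sets: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if 2 * self.block_size * self.n_blocks > self.n_genes:
            raise ValueError(
                "need n_genes >= 2 * n_blocks * block_size "
                "(disease + background modules)"
            )
        if self.effect_size not in EFFECT_SCALE:
            raise ValueError(f"effect_size must be one of {sorted(EFFECT_SCALE)}")
        if not (0 < self.within_block_corr < 1):
            raise ValueError("within_block_corr must be in (0, 1)")
        if not (-1 < self.neg_block_corr < 0):
            raise ValueError("neg_block_corr must be in (-1, 0)")
        for name in ("frac_poor_outcome", "icb_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("baseline_hazard", "hazard_ratio_poor", "censor_rate", "severity_spread"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_samples < 8:
            raise ValueError("n_samples must be >= 8")
        if self.block_size < 4:
            raise ValueError("block_size must be >= 4")


@dataclass
class SyntheticTruth:
    group: dict[str, str]  # sample_id -> {"good", "poor"}
    severity: dict[str, float]  # latent per-sample severity (standard normal scale)
    planted_blocks: list[list[str]]  # disease-module gene lists
    background_blocks: list[list[str]]
    planted_pathways: list[str]
    hazard_ratio_os: float
    hazard_ratio_pfs: float


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    gene_sets: GeneSetCollection
    truth: SyntheticTruth
    config: SyntheticConfig = field(repr=False, default=None)  # type: ignore[assignment]


def _fill_block(X, rows, factors, scale, comm, rng):
    """Banded moving-average loading: gene i loads on factors[i : i+w+1]."""
    bs = len(rows)
    w = factors.shape[0] - bs
    a = np.sqrt(comm / (w + 1))
    resid = np.sqrt(1 - comm)
    f = factors * scale[None, :]
    n = factors.shape[1]
    for k, i in enumerate(rows):
        X[i, :] = a * f[k : k + w + 1].sum(0) + resid * rng.standard_normal(n)


def generate_cohort(cfg: SyntheticConfig) -> SyntheticCohort:
    """Draw one cohort (expression, clinical, gene sets, ground truth)."""
    rng = np.random.default_rng(cfg.seed)
    n, bs = cfg.n_samples, cfg.block_size
    w = bs - 1  # full-gradient window
    eff = EFFECT_SCALE[cfg.effect_size]
    alpha = cfg.severity_spread * eff

    n_poor = int(round(cfg.frac_poor_outcome * n))
    poor = np.zeros(n, dtype=bool)
    poor[rng.choice(n, size=n_poor, replace=False)] = True
    # bimodal latent severity: group centre +/-1 plus within-group spread
    zeta = np.where(poor, 1.0, -1.0) + cfg.severity_within_sd * rng.standard_normal(n)
    s_dis = np.exp(alpha * zeta / 2)
    s_bg = np.exp(-alpha * zeta / 2)
    # per-sample anti-correlation between disease and background factors
    kappa = abs(cfg.neg_block_corr) * eff * stats.norm.cdf(zeta)

    X = rng.standard_normal((cfg.n_genes, n))
    comm = cfg.within_block_corr
    dis_blocks, bg_blocks = [], []
    for b in range(cfg.n_blocks):
        f = rng.standard_normal((bs + w, n))
        g_ind = rng.standard_normal((bs + w, n))
        g = -kappa[None, :] * f + np.sqrt(1 - kappa[None, :] ** 2) * g_ind
        dis_rows = list(range(2 * b * bs, (2 * b + 1) * bs))
        bg_rows = list(range((2 * b + 1) * bs, (2 * b + 2) * bs))
        _fill_block(X, dis_rows, f, s_dis, comm, rng)
        _fill_block(X, bg_rows, g, s_bg, comm, rng)
        dis_blocks.append(dis_rows)
        bg_blocks.append(bg_rows)

    width = len(str(cfg.n_samples))
    sample_ids = [f"S{i + 1:0{width}d}" for i in range(n)]
    gene_ids = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    expr = ExpressionMatrix(gene_ids, sample_ids, X)

    # group centres sit at zeta = -1 and +1, so a slope of log(HR)/2 per
    # severity unit realises the configured hazard ratio between centres
    slope_os = np.log(cfg.hazard_ratio_poor) / 2.0 * eff
    slope_pfs = slope_os * cfg.pfs_slope_factor
    records = []
    for j, sid in enumerate(sample_ids):
        h_os = cfg.baseline_hazard * np.exp(slope_os * zeta[j])
        h_pfs = 2.0 * cfg.baseline_hazard * np.exp(slope_pfs * zeta[j])
        os_true = rng.exponential(1.0 / h_os)
        pfs_true = rng.exponential(1.0 / h_pfs)
        cens_os = rng.exponential(1.0 / cfg.censor_rate)
        cens_pfs = rng.exponential(1.0 / cfg.censor_rate)
        records.append(
            ClinicalRecord(
                sample_id=sid,
                os_time=max(min(os_true, cens_os), 1e-3),
                os_event=int(os_true <= cens_os),
                pfs_time=max(min(pfs_true, cens_pfs), 1e-3),
                pfs_event=int(pfs_true <= cens_pfs),
                benefit="NCB" if poor[j] else "CB",
                arm="treated",
                site="primary",
            )
        )
    n_icb = int(round(cfg.icb_fraction * n))
    for j in rng.choice(n, size=n_icb, replace=False):
        records[j] = replace(records[j], benefit="ICB")
    clinical = ClinicalTable(records)

    planted_blocks = [[gene_ids[i] for i in rows] for rows in dis_blocks]
    background_blocks = [[gene_ids[i] for i in rows] for rows in bg_blocks]
    sets = []
    for b, genes in enumerate(planted_blocks):
        for c in range(0, len(genes), cfg.planted_set_size):
            chunk = genes[c : c + cfg.planted_set_size]
            if len(chunk) >= 4:
                sets.append(
                    (
                        f"PLANTED_B{b + 1}_{c // cfg.planted_set_size + 1}",
                        "planted disease-module gene set",
                        chunk,
                    )
                )
    for d in range(cfg.n_decoy_sets):
        members = rng.choice(cfg.n_genes, size=cfg.planted_set_size, replace=False)
        sets.append(
            (f"DECOY_{d + 1}", "random decoy gene set", [gene_ids[i] for i in sorted(members)])
        )
    gene_sets = GeneSetCollection(sets)

    hr_eff = float(cfg.hazard_ratio_poor**eff)
    truth = SyntheticTruth(
        group={sid: ("poor" if poor[j] else "good") for j, sid in enumerate(sample_ids)},
        severity={sid: float(zeta[j]) for j, sid in enumerate(sample_ids)},
        planted_blocks=planted_blocks,
        background_blocks=background_blocks,
        planted_pathways=[name for name, _, _ in sets if name.startswith("PLANTED")],
        hazard_ratio_os=hr_eff,
        hazard_ratio_pfs=float(hr_eff**cfg.pfs_slope_factor),
    )
    return SyntheticCohort(
        expression=expr, clinical=clinical, gene_sets=gene_sets, truth=truth, config=cfg
    )


def subsample_cohort(cohort: SyntheticCohort, n: int, seed: int) -> SyntheticCohort:
    """Uniform subsample of n samples without replacement (consistent across
    expression, clinical and truth)."""
    ids = cohort.expression.sample_ids
    if n > len(ids):
        raise ValueError(f"cannot subsample {n} from {len(ids)} samples")
    rng = np.random.default_rng(seed)
    keep = sorted(rng.choice(len(ids), size=n, replace=False))
    sub_ids = [ids[i] for i in keep]
    truth = SyntheticTruth(
        group={s: cohort.truth.group[s] for s in sub_ids},
        severity={s: cohort.truth.severity[s] for s in sub_ids},
        planted_blocks=cohort.truth.planted_blocks,
        background_blocks=cohort.truth.background_blocks,
        planted_pathways=cohort.truth.planted_pathways,
        hazard_ratio_os=cohort.truth.hazard_ratio_os,
        hazard_ratio_pfs=cohort.truth.hazard_ratio_pfs,
    )
    return SyntheticCohort(
        expression=cohort.expression.subset_samples(sub_ids),
        clinical=cohort.clinical.subset(sub_ids),
        gene_sets=cohort.gene_sets,
        truth=truth,
        config=cohort.config,
    )
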