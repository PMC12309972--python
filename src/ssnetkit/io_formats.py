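"""Readers/writers for the external formats the pipeline touches.

Expression matrices are genes x samples TSV (log2 TPM), clinical tables are
CSV, gene sets are GMT, and per-sample networks are edge-list TSV.  All
reader/writer pairs are lossless round trips on valid inputs; validation
failures raise :class:`FormatError` and never return partial objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BENEFIT_CATEGORIES = ("CB", "ICB", "NCB")


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


# ---------------------------------------------------------------------------
# Expression


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2-transformed TPM values.

    ``values`` has one row per gene and one column per sample.  Gene and
    sample ids are unique; all values are finite.  Pearson-based network
    inference additionally requires at least 3 samples and no zero-variance
    genes (enforced where correlations are computed, not here).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise FormatError(f"duplicate gene id: {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise FormatError(f"duplicate sample id: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite expression value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.sample_ids]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        idx = [self.sample_ids.index(s) for s in ids]
        return ExpressionMatrix(list(self.gene_ids), ids, self.values[:, idx])

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(gene_ids)
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in ids if g not in pos]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        idx = [pos[g] for g in ids]
        return ExpressionMatrix(ids, list(self.sample_ids), self.values[idx, :])


def _first_duplicate(items: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


def read_expression(
    path: str | Path,
    drop_zero_variance: bool = True,
    log2_tpm_pseudocount: float | None = None,
) -> ExpressionMatrix:
    """Read a genes x samples TSV (header = sample ids, first column = gene ids).

    Genes with zero variance across the cohort are dropped with a warning
    because Pearson correlation is undefined for them; pass
    ``drop_zero_variance=False`` to keep them.  ``log2_tpm_pseudocount``
    applies ``log2(x + P)`` for raw-TPM inputs; by default values are assumed
    already log2-transformed.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty expression file")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise FormatError(f"{path}: cannot parse expression TSV: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")
    dup = _first_duplicate([str(g) for g in df.index])
    if dup is not None:
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    dup = _first_duplicate([str(s) for s in df.columns])
    if dup is not None:
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce")
            if bad.isna().any():
                gene = df.index[int(np.argmax(bad.isna().to_numpy()))]
                raise FormatError(
                    f"{path}: non-numeric value at gene {gene!r}, sample {col!r}"
                ) from exc
        raise FormatError(f"{path}: non-numeric expression values") from exc
    if log2_tpm_pseudocount is not None:
        if np.any(values < 0):
            raise FormatError(f"{path}: negative TPM values cannot be log-transformed")
        values = np.log2(values + log2_tpm_pseudocount)
    em = ExpressionMatrix([str(g) for g in df.index], [str(s) for s in df.columns], values)
    if drop_zero_variance:
        var = em.values.var(axis=1)
        keep = var > 0
        if not keep.all():
            dropped = [g for g, k in zip(em.gene_ids, keep) if not k]
            logger.warning(
                "dropping %d zero-variance gene(s) at load: %s%s",
                len(dropped),
                ", ".join(dropped[:5]),
                "..." if len(dropped) > 5 else "",
            )
            em = ExpressionMatrix(
                [g for g, k in zip(em.gene_ids, keep) if k],
                em.sample_ids,
                em.values[keep],
            )
    return em


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(expr.sample_ids) + "\n")
        for g, row in zip(expr.gene_ids, expr.values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Clinical


@dataclass
class ClinicalRecord:
    sample_id: str
    os_time: float
    os_event: int
    pfs_time: float
    pfs_event: int
    benefit: str
    arm: str = ""
    site: str = ""
    covariates: Mapping[str, float] = field(default_factory=dict)


@dataclass
class ClinicalTable:
    """Per-sample survival endpoints and clinical-benefit category.

    ``benefit`` is one of CB (clinical benefit), ICB (intermediate) or NCB
    (no clinical benefit); OS/PFS are right-censored time-to-event pairs in
    days with event indicators in {0, 1}.
    """

    records: list[ClinicalRecord]

    def __post_init__(self) -> None:
        dup = _first_duplicate([r.sample_id for r in self.records])
        if dup is not None:
            raise FormatError(f"duplicate sample id in clinical table: {dup!r}")
        for r in self.records:
            if r.benefit not in BENEFIT_CATEGORIES:
                raise FormatError(
                    f"sample {r.sample_id!r}: benefit {r.benefit!r} not in "
                    f"{BENEFIT_CATEGORIES}"
                )
            for name, t in (("os_time", r.os_time), ("pfs_time", r.pfs_time)):
                if not np.isfinite(t) or t <= 0:
                    raise FormatError(f"sample {r.sample_id!r}: {name} must be > 0, got {t}")
            for name, e in (("os_event", r.os_event), ("pfs_event", r.pfs_event)):
                if e not in (0, 1):
                    raise FormatError(
                        f"sample {r.sample_id!r}: {name} must be 0 or 1, got {e}"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            d = {
                "sample_id": r.sample_id,
                "os_time": r.os_time,
                "os_event": r.os_event,
                "pfs_time": r.pfs_time,
                "pfs_event": r.pfs_event,
                "benefit": r.benefit,
                "arm": r.arm,
                "site": r.site,
            }
            d.update(r.covariates)
            rows.append(d)
        return pd.DataFrame(rows).set_index("sample_id")

    def subset(self, sample_ids: Iterable[str]) -> "ClinicalTable":
        wanted = list(sample_ids)
        by_id = {r.sample_id: r for r in self.records}
        missing = [s for s in wanted if s not in by_id]
        if missing:
            raise KeyError(f"samples not in clinical table: {missing[:5]}")
        return ClinicalTable([by_id[s] for s in wanted])

    def benefit_groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {c: [] for c in BENEFIT_CATEGORIES}
        for r in self.records:
            out[r.benefit].append(r.sample_id)
        return out


_CLIN_REQUIRED = ["sample_id", "os_time", "os_event", "pfs_time", "pfs_event", "benefit"]


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical CSV with the required named columns."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _CLIN_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing clinical columns: {missing}")
    extra = [
        c
        for c in df.columns
        if c not in _CLIN_REQUIRED + ["arm", "site"]
    ]
    records = []
    for _, row in df.iterrows():
        covs = {}
        for c in extra:
            v = pd.to_numeric(pd.Series([row[c]]), errors="coerce").iloc[0]
            if pd.notna(v):
                covs[c] = float(v)
        records.append(
            ClinicalRecord(
                sample_id=str(row["sample_id"]),
                os_time=float(row["os_time"]),
                os_event=int(row["os_event"]),
                pfs_time=float(row["pfs_time"]),
                pfs_event=int(row["pfs_event"]),
                benefit=str(row["benefit"]),
                arm=str(row.get("arm", "")) if pd.notna(row.get("arm", "")) else "",
                site=str(row.get("site", "")) if pd.notna(row.get("site", "")) else "",
                covariates=covs,
            )
        )
    return ClinicalTable(records)


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    clin.to_frame().reset_index().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT)


@dataclass
class GeneSetCollection:
    """Named gene sets as parsed from a GMT file.

    Genes absent from a later-supplied expression matrix are dropped at use
    time (when inducing pathway subnetworks), never at load time.
    """

    sets: list[tuple[str, str, list[str]]]  # (name, description, gene_ids)

    def __post_init__(self) -> None:
        dup = _first_duplicate([name for name, _, _ in self.sets])
        if dup is not None:
            raise FormatError(f"duplicate gene-set name: {dup!r}")
        for name, _, genes in self.sets:
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.sets]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def genes_of(self, name: str) -> set[str]:
        for n, _, genes in self.sets:
            if n == name:
                return set(genes)
        raise KeyError(name)


def read_gmt(path: str | Path) -> GeneSetCollection:
    path = Path(path)
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            sets.append((fields[0], fields[1], [g for g in fields[2:] if g]))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, desc, genes in collection:
            fh.write("\t".join([name, desc] + list(genes)) + "\n")


# ---------------------------------------------------------------------------
# Edge lists

EDGE_HEADER = "gene_a\tgene_b\tweight\tz_score"


def write_edge_list(network, path: str | Path) -> None:
    """Write a sample network as a TSV of canonical (gene_a < gene_b) edges.

    Floats are written with ``repr`` so that read -> write is byte-identical.
    """
    with open(path, "w") as fh:
        fh.write(EDGE_HEADER + "\n")
        for (a, b) in sorted(network.edges):
            w, z = network.edges[(a, b)]
            fh.write(f"{a}\t{b}\t{repr(float(w))}\t{repr(float(z))}\n")


def read_edge_list(path: str | Path, sample_id: str | None = None, n_genes: int | None = None):
    from .sweet import SampleNetwork  # local import to avoid a cycle

    path = Path(path)
    edges: dict[tuple[str, str], tuple[float, float]] = {}
    genes: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != EDGE_HEADER:
            raise FormatError(f"{path}: bad edge-list header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields")
            a, b, w, z = fields
            if a == b:
                raise FormatError(f"{path}:{lineno}: self-edge {a!r}")
            if a > b:
                raise FormatError(f"{path}:{lineno}: edge not in canonical order")
            key = (a, b)
            if key in edges:
                raise FormatError(f"{path}:{lineno}: duplicate edge {key}")
            edges[key] = (float(w), float(z))
            genes.update(key)
    if sample_id is None:
        sample_id = path.stem
    return SampleNetwork(
        sample_id=sample_id,
        edges=edges,
        n_genes=n_genes if n_genes is not None else len(genes),
    )
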