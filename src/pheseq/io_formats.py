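"""Dataset and configuration types, file readers/writers, and result export.

PheSeq consumes two aligned per-gene inputs: an association table mapping
gene identifiers to p-values from a sequence-analysis experiment, and an
embedding matrix mapping gene identifiers to fixed-length phenotype
description vectors.  Both are plain delimited text (tab by default, comma
accepted on read).  Genes that lack an embedding are retained with a
zero-imputed vector and a missing flag so that the background gene universe
stays intact for the comparison reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pheseq")

DEFAULT_P_EPS = 1e-300
DEFAULT_F_EPS = 1e-6


class FormatError(ValueError):
    """File-level structural problem (missing columns, ragged rows, empty file)."""


class ValidationError(ValueError):
    """Row- or value-level problem (duplicate gene, p-value out of range)."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved run configuration shared by both model variants.

    Parameters
    ----------
    mode
        ``"static"`` (fixed embeddings, Monte-Carlo MLE) or ``"dynamic"``
        (learnable VAE embeddings, MAP-MLE).
    learning_rate
        Gradient-ascent step size eta.
    mc_samples
        Number N of reparameterized Monte-Carlo draws per gene (dynamic).
    weight_decay
        L2 penalty lambda_w on encoder/decoder weights and biases (dynamic).
    embedding_dim
        Latent dimension K of the VAE posterior (dynamic only).
    lenient_alpha
        Fixed p-value cutoff of the lenient significance criterion.
    strict_fdr_q
        Benjamini-Hochberg level of the strict criterion.
    p_eps, f_eps
        Numerical floors for p-values and the latent score F.
    """

    mode: str = "static"
    seed: int = 0
    learning_rate: float = 0.05
    mc_samples: int = 4
    weight_decay: float = 1e-4
    max_iters: int = 3000
    tol: float = 1e-4
    embedding_dim: int = 16
    lenient_alpha: float = 0.05
    strict_fdr_q: float = 0.05
    p_eps: float = DEFAULT_P_EPS
    f_eps: float = DEFAULT_F_EPS
    gibbs_sweeps: int = 2
    posterior_sweeps: int = 50
    hidden_dim: int = 64

    def __post_init__(self) -> None:
        if self.mode not in ("static", "dynamic"):
            raise ValidationError(f"mode must be 'static' or 'dynamic', got {self.mode!r}")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.tol <= 0:
            raise ValidationError("tol must be positive")
        if not 0 < self.lenient_alpha < 1:
            raise ValidationError("lenient_alpha must lie in (0,1)")
        if not 0 < self.strict_fdr_q < 1:
            raise ValidationError("strict_fdr_q must lie in (0,1)")
        if self.mc_samples < 1:
            raise ValidationError("mc_samples must be a positive integer")
        if self.weight_decay < 0:
            raise ValidationError("weight_decay must be nonnegative")
        if self.max_iters < 1:
            raise ValidationError("max_iters must be a positive integer")
        if self.p_eps <= 0 or self.f_eps <= 0:
            raise ValidationError("p_eps and f_eps must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AssociationDataset:
    """Aligned per-gene observations: p-values and phenotype embeddings."""

    disease_id: str
    gene_ids: list[str]
    p_values: np.ndarray                 # shape (G,), clipped into [p_eps, 1]
    embeddings: np.ndarray | None = None  # shape (G, D) or None before attach
    missing_mask: np.ndarray | None = None  # True where the embedding was imputed
    source_label: str = ""
    p_eps: float = DEFAULT_P_EPS

    def __post_init__(self) -> None:
        self.p_values = np.asarray(self.p_values, dtype=float)
        if len(self.gene_ids) != len(set(self.gene_ids)):
            raise ValidationError("gene_ids must be unique")
        if len(self.gene_ids) < 1:
            raise ValidationError("dataset must contain at least one gene")
        if self.p_values.shape != (len(self.gene_ids),):
            raise ValidationError("p_values length must equal number of genes")
        self.p_values = clip_pvalues(self.p_values, self.p_eps)
        if self.embeddings is not None:
            self.embeddings = np.asarray(self.embeddings, dtype=float)
            if self.embeddings.shape[0] != len(self.gene_ids):
                raise ValidationError("embeddings row count must equal number of genes")
            if self.missing_mask is None:
                self.missing_mask = np.zeros(len(self.gene_ids), dtype=bool)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def embedding_dim(self) -> int | None:
        return None if self.embeddings is None else self.embeddings.shape[1]


@dataclass
class BenchmarkSet:
    """A benchmark gene list used for recall evaluation."""

    disease_id: str
    genes: set[str]
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("benchmark gene set must be non-empty")


def clip_pvalues(p: np.ndarray, p_eps: float = DEFAULT_P_EPS) -> np.ndarray:
    """Clip p-values into [p_eps, 1] so that log p is always finite."""
    return np.clip(np.asarray(p, dtype=float), p_eps, 1.0)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    return ","


def read_association_table(path: str | Path, p_eps: float = DEFAULT_P_EPS,
                           disease_id: str = "", source_label: str = "") -> AssociationDataset:
    """Read a gene/p-value table; embeddings are left unattached.

    The file must be tab- or comma-delimited with header columns
    ``gene_id`` and ``p_value``.  Duplicate genes and out-of-range or
    non-numeric p-values are rejected with the offending row named.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty file")
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    missing = {"gene_id", "p_value"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    genes = df["gene_id"].astype(str).tolist()
    dup = df["gene_id"][df["gene_id"].duplicated()].tolist()
    if dup:
        raise ValidationError(f"{path}: duplicate gene_id(s): {sorted(set(dup))}")
    pvals = np.empty(len(df), dtype=float)
    for i, raw in enumerate(df["p_value"]):
        try:
            v = float(raw)
        except (TypeError, ValueError):
            raise ValidationError(f"{path}: row {i + 1} (gene {genes[i]}): "
                                  f"non-numeric p-value {raw!r}") from None
        if not 0.0 <= v <= 1.0 or math.isnan(v):
            raise ValidationError(f"{path}: row {i + 1} (gene {genes[i]}): "
                                  f"p-value {v} outside [0, 1]")
        pvals[i] = v
    return AssociationDataset(disease_id=disease_id or path.stem, gene_ids=genes,
                              p_values=pvals, source_label=source_label, p_eps=p_eps)


def read_embedding_matrix(path: str | Path) -> tuple[dict[str, np.ndarray], int]:
    """Read a delimited embedding matrix: first column gene_id, then D numbers.

    Returns the gene -> vector map and the common dimension D.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty file")
    sep = _sniff_sep(path)
    emb: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(sep)
            gene, cells = parts[0], parts[1:]
            if dim is None:
                dim = len(cells)
                if dim == 0:
                    raise FormatError(f"{path}: no embedding columns")
            elif len(cells) != dim:
                raise FormatError(f"{path}: line {lineno}: expected {dim} values, "
                                  f"got {len(cells)} (ragged row)")
            vec = np.empty(dim)
            for j, cell in enumerate(cells):
                try:
                    vec[j] = float(cell)
                except ValueError:
                    raise ValidationError(
                        f"{path}: line {lineno}, column {header[j + 1] if j + 1 < len(header) else j + 1}: "
                        f"non-numeric value {cell!r}") from None
            emb[gene] = vec
    if dim is None:
        raise FormatError(f"{path}: no data rows")
    return emb, dim


def attach_embeddings(dataset: AssociationDataset,
                      emb: Mapping[str, np.ndarray]) -> AssociationDataset:
    """Attach embedding vectors to a dataset by gene id.

    Genes absent from the map receive the all-zero vector and a missing flag;
    they stay in the dataset so fitting and the comparison denominators see
    the full background universe.  Extra genes in the map are ignored.
    """
    dims = {len(np.asarray(v)) for v in emb.values()}
    if len(dims) > 1:
        raise ValidationError(f"embedding map has inconsistent dimensions: {sorted(dims)}")
    if not dims:
        raise ValidationError("embedding map is empty")
    dim = dims.pop()
    G = dataset.n_genes
    mat = np.zeros((G, dim))
    missing = np.zeros(G, dtype=bool)
    for i, g in enumerate(dataset.gene_ids):
        if g in emb:
            mat[i] = np.asarray(emb[g], dtype=float)
        else:
            missing[i] = True
    n_imputed = int(missing.sum())
    if n_imputed:
        logger.info("attach_embeddings: %d of %d genes lacked an embedding; "
                    "zero-imputed and flagged", n_imputed, G)
    extra = set(emb) - set(dataset.gene_ids)
    if extra:
        logger.info("attach_embeddings: %d embedding genes not in dataset; ignored", len(extra))
    return AssociationDataset(disease_id=dataset.disease_id, gene_ids=list(dataset.gene_ids),
                              p_values=dataset.p_values.copy(), embeddings=mat,
                              missing_mask=missing, source_label=dataset.source_label,
                              p_eps=dataset.p_eps)


def read_benchmark(path: str | Path, disease_id: str = "",
                   source_tag: str = "") -> BenchmarkSet:
    """Read a plain-text benchmark gene list: one symbol per line, '#' comments."""
    genes: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.add(line)
    return BenchmarkSet(disease_id=disease_id, genes=genes,
                        source_tag=source_tag or Path(path).stem)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_RESULT_COLUMNS = ["gene_id", "p_seq", "fused_posterior", "fused_p", "mean_F",
                   "alpha", "a", "b", "call_seq_strict", "call_seq_lenient", "call_fused"]


def write_results_table(results: Sequence, path: str | Path) -> None:
    """Write one row per gene in input order, tab-delimited, 12 significant digits."""
    rows = []
    for r in results:
        rows.append({
            "gene_id": r.gene_id,
            "p_seq": f"{r.p_seq:.12g}",
            "fused_posterior": f"{r.fused_posterior:.12g}",
            "fused_p": f"{r.fused_p:.12g}",
            "mean_F": f"{r.mean_F:.12g}",
            "alpha": f"{r.alpha:.12g}",
            "a": f"{r.a:.12g}",
            "b": f"{r.b:.12g}",
            "call_seq_strict": r.call_seq_strict,
            "call_seq_lenient": r.call_seq_lenient,
            "call_fused": r.call_fused,
        })
    df = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t")


def export_logp_scatter(results: Sequence, path: str | Path,
                        p_eps: float = DEFAULT_P_EPS) -> None:
    """Export per-gene -log10 p-values (sequence vs fused) for scatter layout."""
    rows = []
    for r in results:
        rows.append({
            "gene_id": r.gene_id,
            "neglog10_p_seq": f"{-math.log10(max(r.p_seq, p_eps)):.12g}",
            "neglog10_p_fused": f"{-math.log10(max(r.fused_p, p_eps)):.12g}",
            "evidence_count": r.evidence_count,
        })
    pd.DataFrame(rows, columns=["gene_id", "neglog10_p_seq", "neglog10_p_fused",
                                "evidence_count"]).to_csv(path, sep="\t", index=False)


def write_summary_json(summary, path: str | Path) -> None:
    """Serialize a SummaryReport (or any dataclass) to JSON."""
    if dataclasses.is_dataclass(summary) and not isinstance(summary, type):
        payload = dataclasses.asdict(summary)
    else:
        payload = dict(summary)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
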