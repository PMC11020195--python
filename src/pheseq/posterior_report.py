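"""Fused significance calling and comparison/recall reports.

The fitted model's per-gene posterior probability of association (the mean
posterior of the switch T) is turned into a fused p-value
``fused_p = 1 - fused_posterior``, so both threshold styles apply to the
sequence p-value and the fused p-value symmetrically:

* strict  — Benjamini-Hochberg step-up at level q, applied separately;
* lenient — a fixed nominal cutoff (default 0.05).

The summary report mirrors the single-omics-vs-fused comparison: counts and
background ratios of significant genes under each route, their overlap, and
the genes recalled by fusion alone; recall against a user-supplied benchmark
gene list is reported as hits plus a top-k cumulative curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import BenchmarkSet, RunConfig, ValidationError
from .static_pheseq import FittedModel

__all__ = ["GeneResult", "SummaryReport", "bh_fdr", "call_significance",
           "summarize", "recall_vs_benchmark", "build_gene_results"]


@dataclass
class GeneResult:
    gene_id: str
    p_seq: float
    fused_posterior: float
    mean_F: float
    alpha: float
    a: float
    b: float
    evidence_count: int = 0
    call_seq_strict: bool = False
    call_seq_lenient: bool = False
    call_fused: bool = False

    @property
    def fused_p(self) -> float:
        return 1.0 - self.fused_posterior


@dataclass
class SummaryReport:
    n_background: int
    n_fused_sig: int
    ratio_fused: float
    n_seq_sig: int
    ratio_seq: float
    n_overlap: int
    n_recalled: int
    seq_criterion: str
    recall_vs_benchmark: dict = field(default_factory=dict)
    top_k_curve: list = field(default_factory=list)


def bh_fdr(pvals, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up at level q; returns boolean calls.

    All p-values at or below the largest p(k) with p(k) <= q*k/m are called,
    so tied values are called together.  Empty input gives empty calls.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = q * np.arange(1, m + 1) / m
    passing = np.nonzero(sorted_p <= thresh)[0]
    if passing.size == 0:
        return np.zeros(m, dtype=bool)
    cutoff = sorted_p[passing[-1]]
    return p <= cutoff


def call_significance(results: list[GeneResult], config: RunConfig,
                      mode: str = "strict") -> list[GeneResult]:
    """Apply both sequence criteria and the chosen fused criterion in place.

    ``call_seq_strict`` is BH at ``strict_fdr_q`` on the sequence p-values;
    ``call_seq_lenient`` is the fixed ``lenient_alpha`` cutoff.  ``call_fused``
    follows the requested mode on the fused p-values.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    if not results:
        return results
    p_seq = np.array([r.p_seq for r in results])
    fused_p = np.array([r.fused_p for r in results])
    strict = bh_fdr(p_seq, config.strict_fdr_q)
    lenient = p_seq < config.lenient_alpha
    if mode == "strict":
        fused = bh_fdr(fused_p, config.strict_fdr_q)
    else:
        fused = fused_p < config.lenient_alpha
    for r, s, l, f in zip(results, strict, lenient, fused):
        r.call_seq_strict = bool(s)
        r.call_seq_lenient = bool(l)
        r.call_fused = bool(f)
    return results


def summarize(results: list[GeneResult], seq_criterion: str = "strict") -> SummaryReport:
    """Count fused vs sequence calls, their overlap, and fusion-only recalls."""
    if seq_criterion not in ("strict", "lenient"):
        raise ValueError("seq_criterion must be 'strict' or 'lenient'")
    n = len(results)
    fused = {r.gene_id for r in results if r.call_fused}
    attr = "call_seq_strict" if seq_criterion == "strict" else "call_seq_lenient"
    seq = {r.gene_id for r in results if getattr(r, attr)}
    overlap = fused & seq
    return SummaryReport(
        n_background=n,
        n_fused_sig=len(fused), ratio_fused=len(fused) / n if n else 0.0,
        n_seq_sig=len(seq), ratio_seq=len(seq) / n if n else 0.0,
        n_overlap=len(overlap), n_recalled=len(fused) - len(overlap),
        seq_criterion=seq_criterion)


def _ranked(results: list[GeneResult]) -> list[GeneResult]:
    # descending fused posterior; ties by ascending sequence p, then gene id
    return sorted(results, key=lambda r: (-r.fused_posterior, r.p_seq, r.gene_id))


def recall_vs_benchmark(results: list[GeneResult], benchmark: BenchmarkSet,
                        k_list: list[int] | None = None):
    """Benchmark recall of the fused calls plus a top-k cumulative hit curve.

    Returns (hits, recall_fraction, curve) where curve pairs each k with the
    number of benchmark genes among the k highest-ranked genes.
    """
    if not benchmark.genes:
        raise ValidationError("benchmark gene set is empty")
    called = {r.gene_id for r in results if r.call_fused}
    hits = len(called & benchmark.genes)
    recall = hits / len(benchmark.genes)
    ranked_ids = [r.gene_id for r in _ranked(results)]
    if k_list is None:
        k_list = [10, 20, 50]
    curve = []
    for k in sorted(k_list):
        top = set(ranked_ids[:k])
        curve.append((k, len(top & benchmark.genes)))
    return hits, recall, curve


def build_gene_results(model: FittedModel, p_values: np.ndarray | None = None,
                       evidence_counts=None) -> list[GeneResult]:
    """Assemble per-gene results from a fitted model.

    ``p_values`` defaults to none and must be supplied when the model
    archive is loaded without its dataset; fitting callers pass
    ``dataset.p_values`` directly.
    """
    if p_values is None:
        raise ValueError("p_values are required to build gene results")
    G = len(model.gene_ids)
    ev = np.zeros(G, dtype=int) if evidence_counts is None else np.asarray(evidence_counts)
    results = []
    for i, g in enumerate(model.gene_ids):
        results.append(GeneResult(
            gene_id=g, p_seq=float(p_values[i]),
            fused_posterior=float(model.mean_posterior_T[i]),
            mean_F=float(model.mean_F[i]),
            alpha=float(model.params.alpha[i]),
            a=float(model.params.a[i]), b=float(model.params.b[i]),
            evidence_count=int(ev[i])))
    return results
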