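"""Synthetic datasets with the statistical structure the fusion model assumes.

The generator reproduces, at the vector level, the data congruence the
method relies on: a minority of genes is truly associated; their p-values
follow the significant Beta(alpha, 1) component while the rest are uniform;
and embeddings of associated genes cluster apart from those of
non-associated genes.  Cluster centers sit at +/- (separation/2) along a
random unit direction, so their Euclidean distance equals ``separation``
and the per-dimension Gaussian noise has standard deviation ``noise_sd``.

``inject_discordance`` then breaks the congruence for chosen fractions of
genes — significance without a matching description, or a strong
description without strong sequence evidence — to exercise the recall
narrative of the fused calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import AssociationDataset, ValidationError
from .pvalue_mixture import sample_p

__all__ = ["SimulationTruth", "simulate_dataset", "inject_discordance"]


@dataclass
class SimulationTruth:
    T_true: np.ndarray
    alpha_true: float
    m1: np.ndarray
    m0: np.ndarray
    noise_sd: float
    frac_assoc: float
    seed: int
    discordant_p_only: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    discordant_emb_only: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    @property
    def separation(self) -> float:
        return float(np.linalg.norm(self.m1 - self.m0))


def simulate_dataset(G: int = 2000, D: int = 32, frac_assoc: float = 0.1,
                     alpha_true: float = 0.1, separation: float = 3.0,
                     noise_sd: float = 1.0, seed: int = 0,
                     disease_id: str = "synthetic"):
    """Generate an aligned p-value/embedding dataset plus its ground truth.

    Per gene: T ~ Bernoulli(frac_assoc); p via the mixture sampler; the
    embedding ~ N(m_T, noise_sd^2 I_D) with cluster centers m1, m0 at
    Euclidean distance ``separation``.
    """
    if G < 10:
        raise ValidationError("G must be at least 10")
    if not 0 < frac_assoc < 1:
        raise ValidationError("frac_assoc must lie in (0, 1)")
    if not 0 < alpha_true < 1:
        raise ValidationError("alpha_true must lie in (0, 1)")
    if separation < 0 or noise_sd <= 0:
        raise ValidationError("separation must be >= 0 and noise_sd > 0")
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal(D)
    direction /= np.linalg.norm(direction)
    m1 = (separation / 2.0) * direction
    m0 = -m1
    T = (rng.uniform(size=G) < frac_assoc).astype(int)
    p = sample_p(T, alpha_true, rng)
    emb = np.where(T[:, None] == 1, m1, m0) + noise_sd * rng.standard_normal((G, D))
    gene_ids = [f"G{i:05d}" for i in range(G)]
    dataset = AssociationDataset(disease_id=disease_id, gene_ids=gene_ids,
                                 p_values=p, embeddings=emb,
                                 source_label="simulate_dataset")
    truth = SimulationTruth(T_true=T, alpha_true=alpha_true, m1=m1, m0=m0,
                            noise_sd=noise_sd, frac_assoc=frac_assoc, seed=seed)
    return dataset, truth


def inject_discordance(dataset: AssociationDataset, truth: SimulationTruth,
                       frac_p_only: float, frac_emb_only: float,
                       rng: np.random.Generator):
    """Break p-value/embedding congruence for chosen gene fractions.

    A fraction ``frac_p_only`` of truly associated genes keep their
    significant p-value but have the embedding resampled from the null
    cluster; a fraction ``frac_emb_only`` of null genes get a
    significant-cluster embedding paired with a merely lenient p-value
    (uniform draw rescaled below 0.05).  Modified indices are recorded in
    the returned truth.  Returns a new (dataset, truth) pair.
    """
    if not (0 <= frac_p_only < 1 and 0 <= frac_emb_only < 1
            and frac_p_only + frac_emb_only < 1):
        raise ValidationError("fractions must lie in [0,1) and sum below 1")
    p = dataset.p_values.copy()
    emb = dataset.embeddings.copy()
    D = emb.shape[1]
    idx1 = np.nonzero(truth.T_true == 1)[0]
    idx0 = np.nonzero(truth.T_true == 0)[0]
    n_p_only = int(round(frac_p_only * idx1.size))
    n_emb_only = int(round(frac_emb_only * idx0.size))
    p_only = rng.choice(idx1, size=n_p_only, replace=False) if n_p_only else np.zeros(0, dtype=int)
    emb_only = rng.choice(idx0, size=n_emb_only, replace=False) if n_emb_only else np.zeros(0, dtype=int)
    if n_p_only:
        emb[p_only] = truth.m0 + truth.noise_sd * rng.standard_normal((n_p_only, D))
    if n_emb_only:
        emb[emb_only] = truth.m1 + truth.noise_sd * rng.standard_normal((n_emb_only, D))
        p[emb_only] = 0.05 * rng.uniform(size=n_emb_only)
    new_dataset = AssociationDataset(
        disease_id=dataset.disease_id, gene_ids=list(dataset.gene_ids),
        p_values=p, embeddings=emb, missing_mask=dataset.missing_mask,
        source_label=dataset.source_label + "+discordance", p_eps=dataset.p_eps)
    new_truth = SimulationTruth(
        T_true=truth.T_true.copy(), alpha_true=truth.alpha_true,
        m1=truth.m1, m0=truth.m0, noise_sd=truth.noise_sd,
        frac_assoc=truth.frac_assoc, seed=truth.seed,
        discordant_p_only=np.sort(p_only), discordant_emb_only=np.sort(emb_only))
    return new_dataset, new_truth
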