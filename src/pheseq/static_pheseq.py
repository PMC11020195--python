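"""Monte-Carlo maximum-likelihood fitting with fixed embeddings.

The probabilistic graphical model couples, per gene g, an association score
F_g ~ Beta(a_g, b_g), a switch T_g ~ Bernoulli(F_g), and the observed
p-value P_g ~ T_g * Beta(alpha_g, 1) + (1 - T_g) * U(0, 1).  The per-gene
parameters (alpha_g, a_g, b_g) are produced by the perception network Phi
from the gene's fixed embedding, so phenotypically similar genes share
statistical strength.

Fitting alternates: sample the latent pair (T, F) from its conditional
distribution by Gibbs sweeps, evaluate the single-sample gradient of the
joint log-probability with respect to (alpha, a, b), and chain it through
Phi for one gradient-ascent step.  The Beta-normalizer gradients use the
digamma-difference form, which is algebraically identical to the Gamma-ratio
expressions but numerically stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, psi

from .io_formats import AssociationDataset, RunConfig
from .perception import (PerceptionNetworkParams, PerGeneParameters, VAEParams,
                         MLPParams, phi_backward, phi_forward, phi_forward_cache,
                         phi_init)
from .pvalue_mixture import posterior_T

__all__ = ["LatentState", "FittedModel", "log_joint_static", "sample_latents",
           "grad_static", "step_phi", "fit_static", "posterior_summaries",
           "save_model", "load_model"]


@dataclass
class LatentState:
    """One Monte-Carlo draw of the per-gene latents (T, F)."""

    F: np.ndarray  # in (f_eps, 1 - f_eps)
    T: np.ndarray  # 0/1 integers


@dataclass
class FittedModel:
    """Fit output: final parameters, posterior summaries and the trace."""

    mode: str
    gene_ids: list
    phi: PerceptionNetworkParams
    params: PerGeneParameters
    mean_posterior_T: np.ndarray
    mean_F: np.ndarray
    trace: list
    config: RunConfig
    vae: VAEParams | None = None
    converged_at: int | None = None


def log_joint_static(P: np.ndarray, T: np.ndarray, F: np.ndarray,
                     params: PerGeneParameters) -> float:
    """Joint log-probability of (P, T, F) given per-gene (alpha, a, b).

    Sum over genes of
    ``T log alpha + T (alpha - 1) log P + log B(a,b)^-1
    + (T + a - 1) log F + (b - T) log(1 - F)``.
    """
    P = np.asarray(P, dtype=float)
    T = np.asarray(T, dtype=float)
    F = np.asarray(F, dtype=float)
    al, a, b = params.alpha, params.a, params.b
    terms = (T * np.log(al) + T * (al - 1.0) * np.log(P)
             + gammaln(a + b) - gammaln(a) - gammaln(b)
             + (T + a - 1.0) * np.log(F) + (b - T) * np.log1p(-F))
    return float(terms.sum())


def sample_latents(params: PerGeneParameters, P: np.ndarray,
                   rng: np.random.Generator, gibbs_sweeps: int = 2,
                   f_eps: float = 1e-6) -> LatentState:
    """Draw (T, F) by Gibbs sweeps of the exact conditionals.

    F initializes from its Beta(a, b) prior; each sweep then draws
    T ~ Bernoulli(posterior_T(P, alpha, F)) and refreshes
    F ~ Beta(a + T, b + 1 - T).  The returned F is clipped away from {0, 1}.
    """
    a, b = params.a, params.b
    F = rng.beta(a, b)
    T = np.zeros_like(F, dtype=int)
    for _ in range(gibbs_sweeps):
        tau = posterior_T(P, params.alpha, F, f_eps)
        T = (rng.uniform(size=tau.shape) < tau).astype(int)
        F = rng.beta(a + T, b + 1 - T)
    return LatentState(F=np.clip(F, f_eps, 1.0 - f_eps), T=T)


def grad_static(P: np.ndarray, latents: LatentState,
                params: PerGeneParameters):
    """Per-gene single-sample gradients of the joint log-probability.

    Returns the triple (d/d alpha, d/d a, d/d b):

        d_alpha = T * (log P + 1 / alpha)
        d_a     = psi(a + b) - psi(a) + log F
        d_b     = psi(a + b) - psi(b) + log(1 - F)
    """
    P = np.asarray(P, dtype=float)
    T = latents.T.astype(float)
    F = latents.F
    al, a, b = params.alpha, params.a, params.b
    g_alpha = T * (np.log(P) + 1.0 / al)
    g_a = psi(a + b) - psi(a) + np.log(F)
    g_b = psi(a + b) - psi(b) + np.log1p(-F)
    return g_alpha, g_a, g_b


def step_phi(grads, Z: np.ndarray, phi: PerceptionNetworkParams,
             eta: float) -> PerGeneParameters:
    """One gradient-ascent step on Phi; returns the recomputed parameters.

    The per-gene gradient triple is chained through the output heads and the
    network; the weight update uses the gene-averaged gradient so the step
    size is invariant to the number of genes.  Phi is updated in place.
    """
    g_alpha, g_a, g_b = grads
    if not (np.all(np.isfinite(g_alpha)) and np.all(np.isfinite(g_a))
            and np.all(np.isfinite(g_b))):
        raise FloatingPointError("non-finite gradient entering step_phi")
    _, raw, cache = phi_forward_cache(Z, phi)
    _, dW, db = phi_backward(phi, raw, cache, g_alpha, g_a, g_b)
    G = Z.shape[0]
    for l in range(len(phi.net.weights)):
        phi.net.weights[l] += eta * dW[l] / G
        phi.net.biases[l] += eta * db[l] / G
    return phi_forward(Z, phi)


def posterior_summaries(params: PerGeneParameters, P: np.ndarray,
                        rng: np.random.Generator, sweeps: int = 50,
                        f_eps: float = 1e-6):
    """Posterior means of T and F under frozen parameters.

    Runs `sweeps` Gibbs sweeps and averages the *conditional* probability
    of T = 1 (Rao-Blackwellized) and the sampled F.
    """
    a, b = params.a, params.b
    F = rng.beta(a, b)
    tau_acc = np.zeros_like(F)
    f_acc = np.zeros_like(F)
    for _ in range(sweeps):
        tau = posterior_T(P, params.alpha, F, f_eps)
        tau_acc += tau
        T = (rng.uniform(size=tau.shape) < tau).astype(int)
        F = np.clip(rng.beta(a + T, b + 1 - T), f_eps, 1.0 - f_eps)
        f_acc += F
    return tau_acc / sweeps, f_acc / sweeps


def _convergence_tracker(tol: float, window: int = 5):
    """Stateful check: True once the max parameter change stays < tol
    for `window` consecutive iterations."""
    state = {"prev": None, "count": 0}

    def update(stacked: np.ndarray) -> bool:
        if state["prev"] is not None:
            delta = float(np.abs(stacked - state["prev"]).max())
            state["count"] = state["count"] + 1 if delta < tol else 0
        state["prev"] = stacked.copy()
        return state["count"] >= window

    return update


def fit_static(dataset: AssociationDataset, config: RunConfig) -> FittedModel:
    """Fit the fixed-embedding variant by Monte-Carlo gradient ascent.

    Each iteration: map embeddings through Phi, draw one latent sample by
    Gibbs sweeps, evaluate the gradient triple, and take one ascent step on
    Phi.  Stops at ``max_iters`` or when the largest change of any per-gene
    (alpha, a, b) stays below ``tol`` for 5 consecutive iterations.
    Posterior summaries then average 50 frozen-parameter Gibbs sweeps.
    """
    if dataset.embeddings is None:
        raise ValueError("embeddings must be attached before fitting")
    rng = np.random.default_rng(config.seed)
    Z = dataset.embeddings
    P = dataset.p_values
    phi = phi_init(rng, Z.shape[1], config.hidden_dim, config.f_eps)
    params = phi_forward(Z, phi)
    trace: list[float] = []
    converged = _convergence_tracker(config.tol)
    converged_at = None
    for t in range(config.max_iters):
        latents = sample_latents(params, P, rng, config.gibbs_sweeps, config.f_eps)
        obj = log_joint_static(P, latents.T, latents.F, params)
        if not np.isfinite(obj):
            raise FloatingPointError(
                f"objective diverged at iteration {t}; trace: {trace[-5:]}")
        trace.append(obj)
        grads = grad_static(P, latents, params)
        params = step_phi(grads, Z, phi, config.learning_rate)
        if converged(params.stack()):
            converged_at = t + 1
            break
    mean_tau, mean_F = posterior_summaries(
        params, P, rng, config.posterior_sweeps, config.f_eps)
    return FittedModel(mode="static", gene_ids=list(dataset.gene_ids), phi=phi,
                       params=params, mean_posterior_T=mean_tau, mean_F=mean_F,
                       trace=trace, config=config, converged_at=converged_at)


# ---------------------------------------------------------------------------
# model archive
# ---------------------------------------------------------------------------

_ARCHIVE_VERSION = 1


def _pack_mlp(prefix: str, net: MLPParams, payload: dict) -> None:
    payload[f"{prefix}_nlayers"] = np.array(len(net.weights))
    for l, (w, b) in enumerate(zip(net.weights, net.biases)):
        payload[f"{prefix}_w{l}"] = w
        payload[f"{prefix}_b{l}"] = b


def _unpack_mlp(prefix: str, data) -> MLPParams:
    n = int(data[f"{prefix}_nlayers"])
    return MLPParams([data[f"{prefix}_w{l}"] for l in range(n)],
                     [data[f"{prefix}_b{l}"] for l in range(n)])


def save_model(model: FittedModel, path) -> None:
    """Serialize a FittedModel to a versioned .npz archive with config echo."""
    payload: dict = {
        "version": np.array(_ARCHIVE_VERSION),
        "mode": np.array(model.mode),
        "gene_ids": np.array(model.gene_ids, dtype=object),
        "alpha": model.params.alpha, "a": model.params.a, "b": model.params.b,
        "mean_posterior_T": model.mean_posterior_T,
        "mean_F": model.mean_F,
        "trace": np.asarray(model.trace, dtype=float),
        "config_json": np.array(json.dumps(model.config.to_dict())),
        "converged_at": np.array(-1 if model.converged_at is None
                                 else model.converged_at),
        "phi_f_eps": np.array(model.phi.f_eps),
    }
    _pack_mlp("phi", model.phi.net, payload)
    if model.vae is not None:
        payload["latent_dim"] = np.array(model.vae.latent_dim)
        _pack_mlp("enc", model.vae.encoder, payload)
        _pack_mlp("dec", model.vae.decoder, payload)
    np.savez(path, **payload)


def load_model(path) -> FittedModel:
    """Load a FittedModel archive; rejects unknown archive versions."""
    data = np.load(path, allow_pickle=True)
    version = int(data["version"])
    if version != _ARCHIVE_VERSION:
        raise ValueError(f"model archive version {version} not supported "
                         f"(expected {_ARCHIVE_VERSION})")
    config = RunConfig.from_dict(json.loads(str(data["config_json"])))
    phi = PerceptionNetworkParams(net=_unpack_mlp("phi", data),
                                  f_eps=float(data["phi_f_eps"]))
    vae = None
    if "latent_dim" in data:
        vae = VAEParams(encoder=_unpack_mlp("enc", data),
                        decoder=_unpack_mlp("dec", data),
                        latent_dim=int(data["latent_dim"]))
    conv = int(data["converged_at"])
    return FittedModel(
        mode=str(data["mode"]), gene_ids=[str(g) for g in data["gene_ids"]],
        phi=phi,
        params=PerGeneParameters(alpha=data["alpha"], a=data["a"], b=data["b"]),
        mean_posterior_T=data["mean_posterior_T"], mean_F=data["mean_F"],
        trace=list(data["trace"]), config=config, vae=vae,
        converged_at=None if conv < 0 else conv)
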