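"""Deep-learning perception module: the parameter network Phi and the VAE.

Two small multilayer perceptrons carry the perception task:

* the parameter network Phi maps a gene's embedding to its per-gene mixture
  parameters (alpha, a, b) through constrained output heads, so that
  0 < alpha < 1 and a, b > 1 always hold (the closed-form F-update
  (T + a - 1) / (a + b - 1) then always lands strictly inside (0, 1));
* in the dynamic variant, a VAE encoder maps the raw description vector L
  to an isotropic Gaussian posterior q(Z|L) = N(mu, sigma * I_K) with a
  scalar variance sigma, and a decoder maps Z back to a Gaussian
  reconstruction of L with unit observation variance.

All forward passes cache intermediates and every gradient used in training
is assembled analytically (plain reverse-mode chain rule); the test suite
checks each against central finite differences.  Everything is float64.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MLPParams", "PerceptionNetworkParams", "VAEParams", "EncoderOutput",
    "PerGeneParameters", "mlp_init", "mlp_forward", "mlp_backward",
    "phi_init", "phi_forward", "phi_forward_cache", "phi_backward",
    "vae_init", "encode", "encode_cache", "encoder_backward",
    "decode_mean", "decode_loglik", "decoder_backward",
    "reparameterize", "kl_isotropic", "kl_grads", "combine_meta_embeddings",
]

# output-head constraints.  alpha is confined to (1e-4, 0.5): as alpha -> 1
# the significant Beta(alpha, 1) component becomes indistinguishable from the
# uniform branch and the sampled latent chain drifts (null genes' switch
# frequency self-reinforces).  Both a and b exceed 1 + f_eps so the Beta(a, b)
# score prior is interior-unimodal: the closed-form MAP update
# F = (T + a - 1) / (a + b - 1) is then always the interior argmax; with
# a < 1 it hits the boundary, F gets clipped to f_eps, and log F feedback
# collapses the score for every gene.
_ALPHA_LO = 1e-4
_ALPHA_HI = 0.5

_SIGMA_MIN = 1e-6


def _sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softplus(x):
    return np.logaddexp(0.0, x)


# ---------------------------------------------------------------------------
# generic MLP with tanh hidden layers and a linear output layer
# ---------------------------------------------------------------------------

@dataclass
class MLPParams:
    weights: list  # list of (d_in, d_out) arrays
    biases: list   # list of (d_out,) arrays

    def copy(self) -> "MLPParams":
        return MLPParams([w.copy() for w in self.weights],
                         [b.copy() for b in self.biases])

    def sq_norm(self) -> float:
        return float(sum((w ** 2).sum() for w in self.weights)
                     + sum((b ** 2).sum() for b in self.biases))


def mlp_init(rng: np.random.Generator, dims: list[int]) -> MLPParams:
    """Glorot-uniform initialization for layer sizes dims[0] -> ... -> dims[-1]."""
    weights, biases = [], []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        lim = np.sqrt(6.0 / (d_in + d_out))
        weights.append(rng.uniform(-lim, lim, size=(d_in, d_out)))
        biases.append(np.zeros(d_out))
    return MLPParams(weights, biases)


def mlp_forward(params: MLPParams, X: np.ndarray):
    """Forward pass on a (G, d_in) batch; returns (out, cache)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    acts = [X]
    h = X
    n = len(params.weights)
    for l, (W, b) in enumerate(zip(params.weights, params.biases)):
        z = h @ W + b
        h = z if l == n - 1 else np.tanh(z)
        acts.append(h)
    if not np.all(np.isfinite(h)):
        bad = np.where(~np.isfinite(h).all(axis=1))[0]
        raise FloatingPointError(f"non-finite activations at row index {bad[0]}")
    return h, acts


def mlp_backward(params: MLPParams, cache: list, dout: np.ndarray):
    """Backprop dout (G, d_out) through the cached forward pass.

    Returns (dX, dweights, dbiases); gradients are sums over the batch.
    """
    n = len(params.weights)
    dW = [None] * n
    db = [None] * n
    delta = np.atleast_2d(dout)
    for l in range(n - 1, -1, -1):
        h_in = cache[l]
        dW[l] = h_in.T @ delta
        db[l] = delta.sum(axis=0)
        delta = delta @ params.weights[l].T
        if l > 0:  # through the tanh of the previous layer's output
            delta = delta * (1.0 - cache[l] ** 2)
    return delta, dW, db


# ---------------------------------------------------------------------------
# parameter network Phi: embedding -> (alpha, a, b)
# ---------------------------------------------------------------------------

@dataclass
class PerGeneParameters:
    """Per-gene mixture parameters produced by Phi.

    alpha in (0,1) is the significant-branch Beta shape; (a, b) parameterize
    the Beta prior of the association score F, with a + b > 1 guaranteed.
    """

    alpha: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))

    def stack(self) -> np.ndarray:
        return np.stack([self.alpha, self.a, self.b])


@dataclass
class PerceptionNetworkParams:
    net: MLPParams
    f_eps: float = 1e-6


def phi_init(rng: np.random.Generator, input_dim: int, hidden_dim: int = 64,
             f_eps: float = 1e-6) -> PerceptionNetworkParams:
    """Two tanh hidden layers of width hidden_dim, three linear output heads."""
    return PerceptionNetworkParams(
        net=mlp_init(rng, [input_dim, hidden_dim, hidden_dim, 3]), f_eps=f_eps)


def _heads_forward(raw: np.ndarray, f_eps: float) -> PerGeneParameters:
    alpha = _ALPHA_LO + (_ALPHA_HI - _ALPHA_LO) * _sigmoid(raw[:, 0])
    a = _softplus(raw[:, 1]) + 1.0 + f_eps
    b = _softplus(raw[:, 2]) + 1.0 + f_eps
    return PerGeneParameters(alpha=alpha, a=a, b=b)


def phi_forward(Z: np.ndarray, phi: PerceptionNetworkParams) -> PerGeneParameters:
    """Map per-gene embeddings Z (G, K) to per-gene (alpha, a, b)."""
    raw, _ = mlp_forward(phi.net, Z)
    return _heads_forward(raw, phi.f_eps)


def phi_forward_cache(Z: np.ndarray, phi: PerceptionNetworkParams):
    raw, cache = mlp_forward(phi.net, Z)
    return _heads_forward(raw, phi.f_eps), raw, cache


def phi_backward(phi: PerceptionNetworkParams, raw: np.ndarray, cache: list,
                 g_alpha: np.ndarray, g_a: np.ndarray, g_b: np.ndarray):
    """Chain per-gene gradients w.r.t. (alpha, a, b) back through the heads.

    Returns (dZ, dweights, dbiases) of the scalar objective
    sum_g [g_alpha*alpha_g + g_a*a_g + g_b*b_g] linearized at the cache.
    """
    s0 = _sigmoid(raw[:, 0])
    dh = np.empty_like(raw)
    dh[:, 0] = g_alpha * (_ALPHA_HI - _ALPHA_LO) * s0 * (1.0 - s0)
    dh[:, 1] = g_a * _sigmoid(raw[:, 1])   # softplus' = sigmoid
    dh[:, 2] = g_b * _sigmoid(raw[:, 2])
    return mlp_backward(phi.net, cache, dh)


# ---------------------------------------------------------------------------
# VAE encoder / decoder
# ---------------------------------------------------------------------------

@dataclass
class VAEParams:
    encoder: MLPParams  # D -> hidden -> K + 1 (mu vector, raw variance scalar)
    decoder: MLPParams  # K -> hidden -> D (reconstruction mean)
    latent_dim: int

    def sq_norm(self) -> float:
        return self.encoder.sq_norm() + self.decoder.sq_norm()


@dataclass
class EncoderOutput:
    mu: np.ndarray     # (G, K)
    sigma: np.ndarray  # (G,) isotropic posterior variance, > 0


def vae_init(rng: np.random.Generator, data_dim: int, latent_dim: int,
             hidden_dim: int = 64) -> VAEParams:
    enc = mlp_init(rng, [data_dim, hidden_dim, hidden_dim, latent_dim + 1])
    dec = mlp_init(rng, [latent_dim, hidden_dim, hidden_dim, data_dim])
    return VAEParams(encoder=enc, decoder=dec, latent_dim=latent_dim)


def encode(L: np.ndarray, theta: VAEParams) -> EncoderOutput:
    out, _ = mlp_forward(theta.encoder, L)
    K = theta.latent_dim
    return EncoderOutput(mu=out[:, :K], sigma=_softplus(out[:, K]) + _SIGMA_MIN)


def encode_cache(L: np.ndarray, theta: VAEParams):
    out, cache = mlp_forward(theta.encoder, L)
    K = theta.latent_dim
    return EncoderOutput(mu=out[:, :K], sigma=_softplus(out[:, K]) + _SIGMA_MIN), out, cache


def encoder_backward(theta: VAEParams, raw: np.ndarray, cache: list,
                     d_mu: np.ndarray, d_sigma: np.ndarray):
    """Backprop gradients w.r.t. (mu, sigma) into encoder weight gradients."""
    K = theta.latent_dim
    dout = np.zeros_like(raw)
    dout[:, :K] = d_mu
    dout[:, K] = d_sigma * _sigmoid(raw[:, K])  # through the softplus
    _, dW, db = mlp_backward(theta.encoder, cache, dout)
    return dW, db


def decode_mean(Z: np.ndarray, theta: VAEParams):
    """Decoder reconstruction mean m(Z); returns (mean, cache)."""
    return mlp_forward(theta.decoder, Z)


def decode_loglik(L: np.ndarray, Z: np.ndarray, theta: VAEParams) -> np.ndarray:
    """Per-gene Gaussian log-likelihood log p(L|Z) with unit observation variance.

    Equals -0.5 * ||L - m(Z)||^2 - (D/2) * log(2 pi).
    """
    L = np.atleast_2d(np.asarray(L, dtype=float))
    m, _ = decode_mean(Z, theta)
    D = L.shape[1]
    resid = L - m
    return -0.5 * (resid ** 2).sum(axis=1) - 0.5 * D * np.log(2.0 * np.pi)


def decoder_backward(L: np.ndarray, Z: np.ndarray, theta: VAEParams):
    """Gradients of sum_g log p(L_g|Z_g) w.r.t. Z and the decoder parameters.

    Returns (dZ, dweights, dbiases).  dloglik/dm = (L - m), then chain
    through the decoder.
    """
    L = np.atleast_2d(np.asarray(L, dtype=float))
    m, cache = decode_mean(Z, theta)
    dout = L - m
    return mlp_backward(theta.decoder, cache, dout)


# ---------------------------------------------------------------------------
# reparameterization and KL
# ---------------------------------------------------------------------------

def reparameterize(mu: np.ndarray, sigma, eps: np.ndarray) -> np.ndarray:
    """Location-scale sample Z = mu + sqrt(sigma) * eps, sigma the variance."""
    sigma = np.asarray(sigma, dtype=float)
    return mu + np.sqrt(sigma)[..., None] * eps if sigma.ndim == 1 else mu + np.sqrt(sigma) * eps


def kl_isotropic(mu: np.ndarray, sigma) -> np.ndarray:
    """KL( N(mu, sigma*I_K) || N(0, I_K) ) for a scalar variance sigma.

    Equals 0.5 * (||mu||^2 + K * (sigma - 1 - log sigma)); its negative
    sigma-derivative is K * (1 - sigma) / (2 * sigma).
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    sigma = np.asarray(sigma, dtype=float)
    K = mu.shape[1]
    return 0.5 * ((mu ** 2).sum(axis=1) + K * (sigma - 1.0 - np.log(sigma)))


def kl_grads(mu: np.ndarray, sigma):
    """Gradients of -KL w.r.t. mu and sigma: (-mu, K*(1-sigma)/(2*sigma))."""
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    sigma = np.asarray(sigma, dtype=float)
    K = mu.shape[1]
    return -mu, K * (1.0 - sigma) / (2.0 * sigma)


# ---------------------------------------------------------------------------
# meta-embedding combination
# ---------------------------------------------------------------------------

def combine_meta_embeddings(modalities: list, weights=None) -> np.ndarray:
    """Convex combination of same-length embedding vectors from modalities.

    Weights default to uniform; they must be nonnegative and sum to 1.
    """
    if not modalities:
        raise ValueError("need at least one modality")
    arrs = [np.asarray(m, dtype=float) for m in modalities]
    shapes = {a.shape for a in arrs}
    if len(shapes) > 1:
        raise ValueError(f"modality length mismatch: {sorted(shapes)}")
    if weights is None:
        weights = np.full(len(arrs), 1.0 / len(arrs))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(arrs),):
        raise ValueError("one weight per modality required")
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must be nonnegative and sum to 1")
    return sum(w * a for w, a in zip(weights, arrs))
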