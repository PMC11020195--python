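"""MAP-MLE fitting with learnable VAE embeddings (block coordinate ascent).

The dynamic variant replaces the fixed embedding input of the static model
with a latent code Z_g learned jointly: an encoder produces the variational
posterior q(Z_g|L_g) = N(mu_g, sigma_g I_K), a decoder scores the
reconstruction log p(L_g|Z_g), and Phi consumes sampled Z rather than the
raw description vector.  One outer iteration performs, in fixed order:

1. encode L -> (mu, sigma); the posterior mode mu is the MAP point
   estimate of Z used by the inference blocks;
2. Phi(mu) -> per-gene (alpha, a, b);
3. latent refresh: T ~ its exact conditional, then the closed-form MAP
   update F <- (T + a - 1) / (a + b - 1);
4. ascend the VAE parameters theta through the pathwise Monte-Carlo
   gradients of the per-gene objective, which average over N
   reparameterized draws Z = mu + sqrt(sigma) * eps (with L2 weight
   decay lambda_w);
5. ascend Phi through the same gradient triple as the static variant,
   evaluated at the MAP point mu with a conditional draw of F.

Reparameterized sampling serves the expectations of the variational
objective; the discrete/score blocks consume the MAP embedding, keeping
the switch inference sharp even when the scalar posterior variance sigma
stays near its prior value.

The per-gene Monte-Carlo objective averaged over N reparameterized draws is

    (1/N) sum_n [ log p(L|Z^(n)) + log Beta(F; a(Z^(n)), b(Z^(n))) ]
    - KL( q(Z|L) || N(0, I_K) )

whose mu/sigma gradients combine the pathwise terms with the analytic KL
derivatives (-mu and K (1 - sigma) / (2 sigma)).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, psi

from .io_formats import AssociationDataset, RunConfig
from .perception import (EncoderOutput, VAEParams, decode_loglik,
                         decoder_backward, encode_cache, encoder_backward,
                         kl_grads, kl_isotropic, phi_backward, phi_forward,
                         phi_forward_cache, phi_init, reparameterize, vae_init)
from .pvalue_mixture import posterior_T
from .static_pheseq import (FittedModel, LatentState, PerGeneParameters,
                            _convergence_tracker, grad_static,
                            log_joint_static, posterior_summaries, step_phi)

__all__ = ["map_update_F", "beta_logpdf", "mc_objective", "grad_mu_sigma",
           "elbo", "log_joint_dynamic", "fit_dynamic"]


def map_update_F(T, a, b, f_eps: float = 1e-6):
    """Closed-form MAP update of the association score F given the switch T.

    Maximizes the F-dependent terms ``(T + a - 1) log F + (b - T) log(1-F)``
    at F = (T + a - 1) / (a + b - 1), clipped into (f_eps, 1 - f_eps).
    Requires a + b > 1.
    """
    T = np.asarray(T, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a + b <= 1.0):
        raise ValueError("map_update_F requires a + b > 1")
    F = np.atleast_1d((T + a - 1.0) / (a + b - 1.0))
    return np.clip(F, f_eps, 1.0 - f_eps)


def beta_logpdf(F, a, b):
    """Log-density of Beta(a, b) at F — the score prior log p(F|Z)."""
    F = np.asarray(F, dtype=float)
    return (gammaln(a + b) - gammaln(a) - gammaln(b)
            + (a - 1.0) * np.log(F) + (b - 1.0) * np.log1p(-F))


def _draw_eps(rng: np.random.Generator, N: int, G: int, K: int) -> np.ndarray:
    return rng.standard_normal(size=(N, G, K))


def mc_objective(L: np.ndarray, F: np.ndarray, enc: EncoderOutput,
                 eps: np.ndarray, phi, theta: VAEParams) -> float:
    """Monte-Carlo objective of the Z-dependent terms with frozen noise.

    ``eps`` has shape (N, G, K); each draw n uses Z^(n) = mu + sqrt(sigma)*eps_n.
    Returns the scalar sum over genes.
    """
    N = eps.shape[0]
    total = np.zeros(L.shape[0] if L.ndim > 1 else 1)
    for n in range(N):
        Z = reparameterize(enc.mu, enc.sigma, eps[n])
        params = phi_forward(Z, phi)
        total += decode_loglik(L, Z, theta) + beta_logpdf(F, params.a, params.b)
    total = total / N - kl_isotropic(enc.mu, enc.sigma)
    return float(total.sum())


def grad_mu_sigma(L: np.ndarray, F: np.ndarray, enc: EncoderOutput,
                  eps: np.ndarray, phi, theta: VAEParams,
                  collect_weight_grads: bool = False):
    """Pathwise gradients of the Monte-Carlo objective w.r.t. (mu, sigma).

    For each frozen draw, the gradient w.r.t. Z combines the decoder
    reconstruction term and the score-prior term chained through Phi's
    (a, b) heads; it maps to mu one-to-one and to sigma through
    d Z / d sigma = eps / (2 sqrt(sigma)).  The analytic KL derivatives
    (-mu, K (1 - sigma) / (2 sigma)) are added.

    With ``collect_weight_grads`` the decoder-weight gradients (averaged
    over draws, summed over genes) are returned as well.
    """
    N, G, K = eps.shape
    dmu = np.zeros_like(enc.mu)
    dsig = np.zeros_like(enc.sigma)
    dec_dW = dec_db = None
    sqrt_sig = np.sqrt(enc.sigma)
    for n in range(N):
        Z = reparameterize(enc.mu, enc.sigma, eps[n])
        # decoder reconstruction pathway
        dZ_dec, dW, db = decoder_backward(L, Z, theta)
        # score-prior pathway through Phi's (a, b) heads
        params, raw, cache = phi_forward_cache(Z, phi)
        g_a = psi(params.a + params.b) - psi(params.a) + np.log(F)
        g_b = psi(params.a + params.b) - psi(params.b) + np.log1p(-F)
        dZ_phi, _, _ = phi_backward(phi, raw, cache,
                                    np.zeros_like(g_a), g_a, g_b)
        dZ = dZ_dec + dZ_phi
        dmu += dZ / N
        dsig += (dZ * eps[n]).sum(axis=1) / (2.0 * sqrt_sig) / N
        if collect_weight_grads:
            if dec_dW is None:
                dec_dW = [w / N for w in dW]
                dec_db = [b / N for b in db]
            else:
                for l in range(len(dW)):
                    dec_dW[l] += dW[l] / N
                    dec_db[l] += db[l] / N
    kmu, ksig = kl_grads(enc.mu, enc.sigma)
    dmu += kmu
    dsig += ksig
    if collect_weight_grads:
        return dmu, dsig, dec_dW, dec_db
    return dmu, dsig


def elbo(dataset: AssociationDataset, params: PerGeneParameters,
         theta: VAEParams, latents: LatentState, enc: EncoderOutput,
         eps: np.ndarray, f_eps: float = 1e-6) -> float:
    """Monte-Carlo evidence lower bound at the given latent state.

    Assembles E_q[log p(P|T) + log p(T|F) + log p(F|Z) + log p(L|Z)]
    - KL(q(Z|L) || N(0,I)) - E_q[log q(T)], with the given (T, F) treated
    as the current variational state: q(T) is the exact Bernoulli
    conditional and q(F) a point mass (zero entropy contribution).
    """
    P, L = dataset.p_values, dataset.embeddings
    T = latents.T.astype(float)
    F = np.clip(latents.F, f_eps, 1.0 - f_eps)
    N = eps.shape[0]
    mc = np.zeros(dataset.n_genes)
    for n in range(N):
        Z = reparameterize(enc.mu, enc.sigma, eps[n])
        mc += decode_loglik(L, Z, theta)
    # log p(F|Z) is evaluated at the current per-gene (a, b)
    terms = (T * np.log(params.alpha) + T * (params.alpha - 1.0) * np.log(P)
             + T * np.log(F) + (1.0 - T) * np.log1p(-F)
             + beta_logpdf(F, params.a, params.b)
             + mc / N
             - kl_isotropic(enc.mu, enc.sigma))
    tau = posterior_T(P, params.alpha, F, f_eps)
    tau = np.clip(tau, 1e-12, 1.0 - 1e-12)
    log_qT = T * np.log(tau) + (1.0 - T) * np.log1p(-tau)
    value = float((terms - log_qT).sum())
    if not np.isfinite(value):
        bad = np.where(~np.isfinite(terms - log_qT))[0]
        raise FloatingPointError(f"non-finite ELBO contribution at gene index {bad[0]}")
    return value


def log_joint_dynamic(P, T, F, Z, L, params: PerGeneParameters,
                      theta: VAEParams) -> float:
    """Joint log-probability of (P, T, F, Z, L): the static joint plus the
    decoder likelihood and the standard-normal prior on Z."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    K = Z.shape[1]
    log_pz = -0.5 * (Z ** 2).sum(axis=1) - 0.5 * K * np.log(2.0 * np.pi)
    extra = float((decode_loglik(L, Z, theta) + log_pz).sum())
    return log_joint_static(P, T, F, params) + extra


def fit_dynamic(dataset: AssociationDataset, config: RunConfig) -> FittedModel:
    """Fit the learnable-embedding variant by block coordinate ascent.

    See the module docstring for the per-iteration block order.  Stops at
    ``max_iters`` or when the largest change of any per-gene (alpha, a, b)
    stays below ``tol`` for 5 consecutive iterations; posterior summaries
    then average 50 frozen-parameter Gibbs sweeps, exactly as in the static
    variant.
    """
    if dataset.embeddings is None:
        raise ValueError("embeddings must be attached before fitting")
    rng = np.random.default_rng(config.seed)
    L = dataset.embeddings
    P = dataset.p_values
    G, D = L.shape
    K = config.embedding_dim
    theta = vae_init(rng, D, K, config.hidden_dim)
    phi = phi_init(rng, K, config.hidden_dim, config.f_eps)
    eta, lam, N = config.learning_rate, config.weight_decay, config.mc_samples

    enc = encode_cache(L, theta)[0]
    params = phi_forward(enc.mu, phi)
    F = np.clip(params.a / (params.a + params.b), config.f_eps, 1 - config.f_eps)

    trace: list[float] = []
    converged = _convergence_tracker(config.tol)
    converged_at = None
    for t in range(config.max_iters):
        # (1) encode; mu is the MAP embedding for the inference blocks
        enc, enc_raw, enc_cache = encode_cache(L, theta)
        Z = enc.mu
        # (2) perception
        params = phi_forward(Z, phi)
        # (3) latent refresh: exact-conditional T, closed-form MAP F
        tau = posterior_T(P, params.alpha, F, config.f_eps)
        T = (rng.uniform(size=G) < tau).astype(int)
        F = map_update_F(T, params.a, params.b, config.f_eps)
        latents = LatentState(F=F, T=T)
        obj = log_joint_dynamic(P, T, F, Z, L, params, theta)
        if not np.isfinite(obj):
            raise FloatingPointError(
                f"objective diverged at iteration {t}; trace: {trace[-5:]}")
        trace.append(obj)
        # (4) theta step: pathwise gradients with fresh frozen noise
        eps = _draw_eps(rng, N, G, K)
        dmu, dsig, dec_dW, dec_db = grad_mu_sigma(
            L, F, enc, eps, phi, theta, collect_weight_grads=True)
        enc_dW, enc_db = encoder_backward(theta, enc_raw, enc_cache, dmu, dsig)
        # decay applied as its exact flow exp(-eta*lam), stable for any lam
        decay = np.exp(-eta * lam)
        for l in range(len(theta.encoder.weights)):
            theta.encoder.weights[l] = decay * theta.encoder.weights[l] + eta * enc_dW[l] / G
            theta.encoder.biases[l] = decay * theta.encoder.biases[l] + eta * enc_db[l] / G
        for l in range(len(theta.decoder.weights)):
            theta.decoder.weights[l] = decay * theta.decoder.weights[l] + eta * dec_dW[l] / G
            theta.decoder.biases[l] = decay * theta.decoder.biases[l] + eta * dec_db[l] / G
        # (5) Phi step: the gradient triple chained through Phi at Z.  The
        # score entering this Monte-Carlo gradient is a *draw* from the
        # exact conditional Beta(a + T, b + 1 - T), not the MAP point:
        # evaluating the Beta-prior gradient at a point value makes the
        # (a, b) maximum-likelihood problem degenerate (concentration grows
        # without bound and log F diverges at the clip boundary).
        F_star = np.clip(rng.beta(params.a + T, params.b + 1 - T),
                         config.f_eps, 1.0 - config.f_eps)
        grads = grad_static(P, LatentState(F=F_star, T=T), params)
        params = step_phi(grads, Z, phi, eta)
        if converged(params.stack()):
            converged_at = t + 1
            break

    # posterior summaries at the encoder mean
    enc = encode_cache(L, theta)[0]
    params = phi_forward(enc.mu, phi)
    mean_tau, mean_F = posterior_summaries(
        params, P, rng, config.posterior_sweeps, config.f_eps)
    return FittedModel(mode="dynamic", gene_ids=list(dataset.gene_ids), phi=phi,
                       params=params, mean_posterior_T=mean_tau, mean_F=mean_F,
                       trace=trace, config=config, vae=theta,
                       converged_at=converged_at)
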