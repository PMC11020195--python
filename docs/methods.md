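# Methods

## Generative model

Each gene–disease pair *g* carries two observations: a p-value `P_g` from a
single sequence analysis, clipped into `[p_eps, 1]` with `p_eps = 1e-300`
so `log P_g` is finite, and a phenotype-description embedding (a
fixed-length real vector). Two latent variables couple them: an
association score `F_g ∈ (0,1)` with a `Beta(a_g, b_g)` prior, and a
binary switch `T_g ~ Bernoulli(F_g)`. The p-value follows the two-groups
beta–uniform mixture

    P_g | T_g  ~  T_g · Beta(α_g, 1) + (1 − T_g) · U(0, 1),

whose significant component has density `α p^(α−1)` with `α < 1`. The
per-gene parameters `(α_g, a_g, b_g)` are produced by a perception network
Φ from the gene's embedding, which is what makes this a fusion model:
genes with similar descriptions receive similar mixture parameters, so
phenotype evidence modulates how much the p-value is believed.

All switch posteriors are computed in log space with max-subtraction
(`α p^(α−1)` reaches ~1e270 at the clip floor), and `F` is clipped to
`[f_eps, 1 − f_eps]`, `f_eps = 1e-6`, before any `log F` appears.

## Perception network and its constraints

Φ is a two-hidden-layer tanh MLP (width 64, Glorot-uniform init from the
run seed) with three constrained heads:

* `α = 1e-4 + (0.5 − 1e-4) · logistic(h)` — confined to (1e-4, 0.5);
* `a = softplus(h) + 1 + f_eps` and `b = softplus(h) + 1 + f_eps` — both
  strictly above 1.

Both caps are identifiability/stability constraints that we found
necessary, not cosmetic choices:

* As `α → 1` the significant component becomes indistinguishable from the
  uniform branch. Under sampled-latent training this is an attractor: null
  genes occasionally draw `T = 1`, the resulting gradient pushes their α
  upward, which makes their switch posterior collapse onto `F` and the
  latent chain drifts (a Pólya-urn-like runaway we observed as recovery
  degrading with training time). Capping α at 0.5 keeps the significant
  branch a genuinely decreasing density; values of α fitted on truly
  associated genes land near the simulation's 0.1 regardless.
* With `a < 1` the MAP update `F ← (T + a − 1)/(a + b − 1)` lands on the
  boundary 0 whenever `T = 0`; the clipped value `f_eps` then contributes
  `log F ≈ −13.8` to the `(a, b)` gradients, driving `a` further down — an
  absorbing collapse of the whole score field. Keeping `a, b > 1` makes
  the `Beta(a, b)` prior interior-unimodal, so the closed-form update is
  always the interior argmax.

## Static variant (Monte-Carlo MLE)

Per iteration: `(α, a, b) = Φ(Z)`; one latent sample per gene from two
Gibbs sweeps of the exact conditionals (`T ~ Bernoulli(posterior)` then
`F ~ Beta(a + T, b + 1 − T)`, initialized from the `Beta(a, b)` prior);
the single-sample gradient triple

    ∇α = T (log P + 1/α),
    ∇a = Ψ(a+b) − Ψ(a) + log F,
    ∇b = Ψ(a+b) − Ψ(b) + log(1 − F)

(digamma-difference form of the Beta-normalizer derivatives, numerically
stable and algebraically identical to the Gamma-ratio form) is chained
through Φ's heads and layers, and Φ takes one ascent step. The weight
update uses the gene-averaged gradient so the step size is invariant to
the number of genes; with the sum convention the same optimization is
recovered by rescaling the learning rate by G.

Defaults: learning rate 0.05, up to 3000 iterations, convergence when the
largest change of any per-gene `(α, a, b)` stays below `tol = 1e-4` for 5
consecutive iterations. These were chosen for reliable convergence of the
training objective at the default problem scale (2000 genes fit in ~30 s
on one CPU); all are config-overridable.

Posterior summaries are computed after fitting with frozen parameters: 50
Gibbs sweeps, averaging the *conditional* switch probability
(Rao-Blackwellized) and the sampled `F`. The fused p-value is
`1 − mean posterior`, a probability of non-association on [0, 1] — chosen
because the model emits posterior probabilities rather than tail
statistics, and this transform is monotone in the evidence and usable with
both thresholding conventions.

## Dynamic variant (MAP-MLE with a learnable embedding)

The raw description vector `L_g` is encoded by a VAE into an isotropic
Gaussian posterior `q(Z_g|L_g) = N(μ_g, σ_g I_K)` with a *scalar* variance
σ_g — the only reading under which the analytic KL gradient term
`K(1 − σ)/(2σ)` is exactly the σ-derivative of the Gaussian KL. The
encoder and decoder are two-hidden-layer tanh MLPs (width 64); the decoder
defines `log p(L|Z)` as a Gaussian reconstruction with unit observation
variance. Reparameterized samples are `Z = μ + sqrt(σ) · ε` (σ is a
variance; a location–scale sampler requires the scale `sqrt(σ)`).

One outer iteration, in fixed order:

1. encode `L → (μ, σ)`; the mode μ is the MAP point estimate of Z;
2. `Φ(μ) → (α, a, b)`;
3. latent refresh: `T` sampled from its exact conditional, then the
   closed-form MAP update `F ← (T + a − 1)/(a + b − 1)`;
4. ascend the VAE parameters through the pathwise Monte-Carlo gradients of
   `(1/N) Σ_n [log p(L|Z⁽ⁿ⁾) + log Beta(F; a(Z⁽ⁿ⁾), b(Z⁽ⁿ⁾))] − KL`,
   N = 4 frozen draws, plus L2 weight decay `λ_w = 1e-4` applied as its
   exact flow `exp(−η λ_w)` (stable for any λ_w);
5. ascend Φ with the static gradient triple evaluated at μ, with `F*`
   drawn from the conditional `Beta(a + T, b + 1 − T)`.

Two numerical decisions in this loop deserve justification:

* **MAP evaluation of the discrete blocks.** The expectations of the
  variational objective use reparameterized draws, but the switch
  inference and the Φ gradient consume the posterior mode μ. With a scalar
  isotropic σ the KL keeps σ near its prior value, so sampled Z carries
  noise comparable to the cluster separation itself; training Φ on such
  samples blurs the class boundary (recovery stalls around 0.80 balanced
  accuracy), while evaluating at the MAP embedding reaches ~0.95. This is
  the point-estimate half of the MAP-MLE solver, applied consistently.
* **Sampled F in the Φ step.** The Monte-Carlo gradient is defined at
  latents drawn from the variational state. Plugging the MAP point value
  of F into the `(a, b)` gradients instead makes the Beta maximum-
  likelihood problem degenerate — the prior chases a point mass, its
  concentration grows without bound, and at the clip boundary `log F`
  diverges (we observed population-wide collapse). Drawing `F*` from its
  exact conditional restores the spread the MLE needs, exactly as in the
  static variant.

Posterior summaries are computed as in the static variant, with Φ
evaluated at the final encoder means. Latent dimension defaults to
K = 16.

## Significance calling and reports

Strict calls are Benjamini–Hochberg at `q = 0.05` (step-up; ties called
together), applied separately to the sequence and fused p-values; lenient
calls use the fixed cutoff 0.05 (`p < 0.05`; the cutoff is configurable —
0.005 is a common stricter alternative for the same style). The summary
report counts significant genes under each route, their ratios over the
background universe, the overlap, and the genes *recalled* by fusion only
(`n_recalled = n_fused − overlap` by construction). Benchmark recall ranks
genes by descending fused posterior with deterministic tie-breaks
(ascending sequence p, then gene id) and reports hits plus a top-k
cumulative curve.

Genes lacking an embedding are zero-imputed and flagged rather than
dropped, keeping the background denominators intact; the zero vector is a
neutral input to the network, and the flag is retained in the dataset for
downstream filtering.

## Synthetic data

The generator reproduces the structure the model assumes, at the vector
level: `T ~ Bernoulli(frac_assoc)`; `P` from the mixture
(`Beta(alpha_true, 1)` via inverse CDF `u^(1/α)`); embeddings from two
isotropic Gaussian clusters whose centers sit at `±(separation/2)` along a
random unit direction (center distance = `separation`, per-dimension noise
`noise_sd`). Defaults: G = 2000 genes, D = 32 dimensions,
`frac_assoc = 0.1`, `alpha_true = 0.1`, `separation = 3`, `noise_sd = 1` —
a desk-scale cohort on which the Bayes-optimal classifier (known here
because the generative model is known) attains ≈ 0.94 balanced accuracy,
leaving genuine headroom above the 0.9 recovery bar while a p-value-only
rule reaches only ≈ 0.80.

`inject_discordance` deliberately breaks the p-value/embedding congruence:
a fraction of truly associated genes keep their significant p-value but
get a null-cluster embedding (significance without description), and a
fraction of null genes get a significant-cluster embedding paired with a
merely lenient p-value (uniform below 0.05). The discordance experiment
uses fractions 0.2 and 0.1 respectively with the static fit.

What the generator does *not* emulate: literature/annotation noise,
embedding heteroscedasticity, correlated evidence between genes (LD,
co-citation), non-Gaussian embedding geometry, and p-value miscalibration
of the upstream analysis. Passing recovery tests on this generator shows
the inference machinery works when the model's assumptions hold; it does
not certify performance on real corpora, where embedding quality and
p-value calibration dominate.

## Known limitations

* Per-gene mixture-shape α is only weakly identified for any single gene;
  it is effectively a property of embedding neighborhoods. Interpret the
  per-gene α as a smoothed field, not a gene-level estimate.
* The training objective is a single-sample Monte-Carlo estimate; traces
  fluctuate, and the convergence check (parameter stability over a
  5-iteration window) can trigger late on flat plateaus. Windowed means of
  the objective are non-decreasing within Monte-Carlo noise until then.
* The dynamic variant's (a, b) concentrations grow slowly with continued
  training (the Beta prior sharpens around the polarized scores); ranking
  quality is insensitive to this, but absolute posterior values saturate
  toward 0/1 with very long runs.
* One disease per fit; no amortization across diseases.
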