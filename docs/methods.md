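# Methods

## Model

`difflik` works with score-based diffusion models built on the
variance-exploding (VE) SDE

    dx_t = g(t) dw_t,        g(t) = sigma0 (sigma1/sigma0)^t,     t in [0, 1],

with zero drift and an exponential diffusion coefficient (defaults
sigma0 = 0.1, sigma1 = 70).  Because the drift vanishes, the forward
perturbation kernel started at a point x0 is Gaussian with variance

    sigma2(t) = int_0^t g(s)^2 ds
              = sigma0^2 [(sigma1/sigma0)^(2t) - 1] / (2 ln(sigma1/sigma0)).

We use this exact integral, not the common approximation
`sigma0^2 (sigma1/sigma0)^(2t)`: the two differ by the factor
`2 ln(sigma1/sigma0)` (about 13 for the default schedule), which changes both
the forward kernel at small t and the size of the accumulated noise at t = 1.
With the defaults, `sigma2(1) ~ 374` (std ~ 19.3).

Generation uses the reverse SDE
`dx = -g^2 s(x,t) dt + g dw̄` (Euler–Maruyama, uniform grid, noise in every
step including the last; a noise-free final step is available as a switch) and
the deterministic probability-flow ODE `dx/dt = -g^2 s(x,t) / 2`, which shares
the SDE's marginal distributions.

## Likelihood recovery

`log p(x, t)` is a state function on joint space-time, so its change along
any path from data (t = 0) to noise (t = 1) is the line integral of its
spatiotemporal gradient.  The spatial gradient is the score; the temporal
derivative follows from the Fokker–Planck equation of the zero-drift SDE:

    d log p / dt = g^2/2 Tr(grad s) + g^2/2 ||s||^2.

Given the prior log-density at the t = 1 endpoint,

    log p0(x0) = log p1(x1) - int_0^1 [ s . dx/dt + g^2/2 Tr(grad s) + g^2/2 ||s||^2 ] dt.

Two integrators implement this:

* **diffusion-path** (`diff_likelihood`): the composite trapezoid rule over
  the nodes of a sampled trajectory, exactly one trapezoid per node pair —
  second order in the step, no extra score evaluations beyond the nodes.
* **flow-path** (`flow_likelihood`): along the probability-flow ODE the
  substitution `dx/dt = -g^2 s / 2` makes the work term cancel the score-norm
  term, leaving the divergence-only integrand `g^2/2 Tr(grad s)`.  Path and
  integrand are solved jointly with adaptive RK45.

The classical work integral `-beta^-1 int s . dx` (no Fokker–Planck term) is
kept as `naive_work_integral`, a documented negative control: it assumes an
energy independent of t and is systematically wrong along diffusion paths
(RMS error about 170x the full integrand's in the analytic-score benchmark).

Energies use the Boltzmann convention `log p = -beta E - log Z` with beta = 1
and the reference log Z fixed to 0, so `E = -log p`.

## Prior at t = 1

The likelihood identity needs `log p(x1, 1)`.  The library default is the VE
point-mass prior `N(0, sigma2(1) I)`.  For the benchmark schedule this is a
poor stand-in for the true t = 1 marginal: the accumulated noise std (~19) is
*smaller* than the data spread (std ~30), so the marginal at t = 1 is still
visibly trimodal (its Kolmogorov–Smirnov distance to any single Gaussian is
~0.038).  Two better choices are used where they are available:

* **analytic-score workflows** use the exact t = 1 marginal of the mixture
  (closed form under the VE kernel), making the identity exact — this is what
  allows oracle tests at 1e-3 absolute accuracy in log-density;
* **learned-model workflows** use the *empirical prior*
  `p1 = (1/N) sum_i N(x_i, sigma2(1) I)` over the training set — exactly the
  t = 1 marginal implied by denoising score matching, computable at inference
  time from the training data alone.  It supplies both the starting noise
  samples of the reverse SDE and the `log p1` endpoint term.  For speed the
  60,000 equal-weight kernels are merged into <= 2048 narrow bins keyed by
  within-bin means; centering merged kernels on the bin mean cancels the
  first-order error and leaves a log-density error below 1e-5.

All randomness flows through explicit `numpy` generators; experiment seeds
are split into independent data/training/sampling streams with
`SeedSequence.spawn`, so every run is bit-for-bit reproducible from one
integer.

## Score fields

A score field is anything with `__call__(x, t)` and `divergence(x, t)`
(batched).  Two implementations ship:

**Analytic oracle.**  For an isotropic Gaussian mixture the VE kernel acts by
convolution, so every marginal is again a mixture with inflated component
variances `b_i^2 + sigma2(t)`; density, score and score divergence are closed
forms (log-sum-exp throughout — sigma2 spans four orders of magnitude).  The
oracle supports t = 0 exactly.

**Learned model.**  A tanh MLP (default 3 hidden layers of width 128) takes
`x / x_scale` and a Gaussian-Fourier embedding of the *noise-level
coordinate* `u = log(sigma(t)/sigma_ref) / log(sigma(1)/sigma_ref)` and
predicts the noise `eps_hat`; the exposed score is `-eps_hat / sigma(t)`.
Conditioning on log sigma rather than raw t gives the network uniform
resolution across noise levels — with raw t the low-noise regime collapses
into a vanishing interval and the recovered likelihoods degrade markedly.
Derivatives are computed analytically in closed form: reverse-mode for
parameter gradients, forward-mode for the exact spatial Jacobian trace the
integrands need (one extra pass per spatial dimension; for the n <= 8
use-cases of this package the exact trace is cheaper and better-conditioned
than stochastic trace estimation).  tanh keeps the field twice
differentiable.

Training is denoising score matching with the sigma^2 weighting, under which
the objective is plain noise prediction `E ||eps_hat - z||^2 / 2`.  Noise
levels are stratified log-uniformly between sigma(t_min) and sigma(1),
matching the conditioning coordinate.  Optimization: Adam (lr 1e-3, cosine
decay, batch 512, 30,000 steps) with an exponential moving average of the
weights (decay 0.999) as the final model.  Most of the DSM objective is
irreducible noise (the zero score already achieves n/2 = 0.5), so training
quality is judged by score-field probes and end-to-end recovery, not by the
loss value.

## Benchmark and what it shows

The validation target is a 1D trimodal mixture: means (-30, 0, 40), stds
(8, 5, 10), weights (0.4, 0.3, 0.3); 60,000 training points; 10,000 samples
generated with 1,000 reverse-diffusion steps.  The synthetic-data generator
*is* the analytic oracle, so every recovered quantity has an exact reference.
These data are clean i.i.d. draws from a smooth density — the benchmark
exercises the integrators and the training loop, not robustness to the
finite, biased, high-dimensional data of real applications (e.g. protein
structures), and a passing suite shows correctness of the machinery, not that
a particular protein model's learned energies are trustworthy.

Numerical/engineering choices, all declared in `difflik.constants` or the
config dataclasses:

* flow ODE tolerances rtol 1e-6 / atol 1e-8 (oracle work); the learned-model
  experiment relaxes to 1e-5 / 1e-6 since solver error is then far below
  model error;
* oracle flow-recovery error budget: 1e-3 absolute in log-density;
* t_min = 1e-4 for learned scores (sigma(t_min) ~ 1e-3; networks are not
  trained below it), 0 for the analytic oracle;
* trapezoid rule only on sampled paths, one segment per node pair, matching
  the score evaluations already available from inference;
* reverse-SDE time grid uniform; 1,000 steps in the benchmark;
* probability conservation is checked by Riemann integration of
  `exp(log p0)` on a fine grid spanning the mixture's support.

Scaled-down problem sizes used by the test suite (30,000 training points,
12,000 optimization steps, 500 diffusion steps, likelihoods on 2,000 samples
with the sampling check on 10,000) are the package's chosen smoke-test scale;
the acceptance script runs the full study.

## Known limitations

* Path independence holds only for exact (conservative, Fokker–Planck
  consistent) scores.  Learned scores are not guaranteed to be either, so
  diffusion- and flow-path likelihoods genuinely disagree on trained models;
  the package reports the discrepancy (per-sample results carry the path
  kind) and never asserts it away.
* The learned-model correlation and KS numbers are stochastic: they vary at
  the percent level with data/training/sampling seeds and mildly with
  architecture choices the benchmark's description does not pin down.
* Only variance-exploding, zero-drift diffusion in flat R^n is supported: no
  variance-preserving schedules, no Riemannian/SE(3) manifolds.
* The exact divergence costs one forward-mode pass per dimension; beyond
  n ~ 10 a Hutchinson estimator would be preferable, and is not implemented.
* The empirical-prior kernel compression is 1D; in higher dimensions the
  prior falls back to the uncompressed kernel sum (or the Gaussian prior).
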