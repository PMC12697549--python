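# difflik

Extract log-likelihoods — equivalently *learned energies* — from score-based
diffusion models by integrating the spatiotemporal gradient of the marginal
log-density along a path from data to noise.

## The problem

A score-based diffusion model never learns the data density `p0(x)` directly.
It learns the *score* `s(x, t) = ∇ₓ log p(x, t)` of the marginals of a
noising SDE, which is all that reverse-time sampling needs.  But for physical
systems — docked protein complexes, folded structures — `−log p0(x0)` is
proportional to a free energy (`p0 = e^{−βE}/Z`), so recovering the model's
likelihood turns a generative model into a scoring function.

Since `log p(x, t)` is a state function on joint space-time, its change along
any path from `(x0, 0)` to `(x1, 1)` is a line integral.  The spatial part of
the gradient is the score; the temporal part follows from the Fokker–Planck
equation of the variance-exploding SDE `dx = g(t) dw`:

    ∂ log p/∂t = ½ g² Tr ∇ₓs + ½ g² ‖s‖²,

giving

    log p0(x0) = log p1(x1) − ∫₀¹ [ s · dx/dt + ½ g² Tr ∇ₓs + ½ g² ‖s‖² ] dt.

`difflik` evaluates this integral two ways:

* **diffusion path** — trapezoid rule over the nodes of a sampled
  reverse-diffusion trajectory, reusing the scores computed during inference
  (`diff_likelihood`);
* **flow path** — along the probability-flow ODE `dx/dt = −½ g² s`, where the
  work and score-norm terms cancel and an adaptive solver integrates the
  divergence-only integrand `½ g² Tr ∇ₓs` (`flow_likelihood`).

The classical work integral `−β⁻¹∫ s·dx` (which wrongly assumes a
time-independent energy) ships as a negative control, and everything is
validated end-to-end on a 1D trimodal Gaussian mixture for which scores,
marginals and likelihoods are available in closed form.  The engine is
dimension-agnostic over Rⁿ; any object with `__call__(x, t)` and
`divergence(x, t)` can serve as the score field.

## Worked example

Recover likelihoods with the exact mixture score (the oracle setting — no
training involved):

```python
import numpy as np
from difflik import (
    DiffusionSpec, NoiseSchedule, flow_likelihood, nll_to_energy, trimodal_mixture,
)
from difflik.gmm import AnalyticMixtureScore

schedule = NoiseSchedule(sigma0=0.1, sigma1=70.0, t_min=0.0)
mixture = trimodal_mixture()                       # modes at -30, 0, 40
score = AnalyticMixtureScore(mixture, schedule)    # exact s(x,t) and its divergence
spec = DiffusionSpec(schedule, dimension=1, n_steps=1000)

x0 = np.array([[-30.0], [0.0], [15.0], [40.0]])
log_p1 = mixture.marginal_at_t(schedule, 1.0).log_density
result = flow_likelihood(x0, score, spec, log_p1=log_p1)

for x, lp, truth in zip(x0[:, 0], result.log_p0, mixture.log_density(x0)):
    print(f"x0={x:6.1f}  log p0={lp:8.4f}  true={truth:8.4f}  "
          f"learned energy={nll_to_energy(lp).energy:7.4f}")
```

```
x0= -30.0  log p0= -3.9147  true= -3.9147  learned energy= 3.9147
x0=   0.0  log p0= -3.7314  true= -3.7314  learned energy= 3.7314
x0=  15.0  log p0= -7.1412  true= -7.1412  learned energy= 7.1412
x0=  40.0  log p0= -4.4255  true= -4.4255  learned energy= 4.4255
```

The flow integral reproduces the true log-density to display precision
(errors are below 1e-3 across the mixture's support); the energies are the
corresponding β=1 Boltzmann energies, highest where the density is lowest
(x0=15, between modes).  The full study — train a score network by denoising
score matching on 60,000 mixture samples, generate 10,000 samples by
1,000-step reverse diffusion, recover their likelihoods along both paths and
compare with ground truth — runs with:

```sh
difflik experiment --outdir results/ --seed 0
```

which reports the sampling Kolmogorov–Smirnov distance and the Pearson
correlations of recovered vs true probabilities for both integrators, and
writes per-sample tables (`recovery.csv`, `trajectories.csv`, `report.json`).
`difflik train` and `difflik likelihood` expose the training and scoring
steps separately; see `--help`.

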