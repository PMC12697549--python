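"""Exact Gaussian-mixture machinery: data generator and analytic oracle.

For an isotropic Gaussian mixture ``p0 = sum_i w_i N(mu_i, b_i^2 I)`` the
variance-exploding forward kernel acts by convolution, so every marginal
``p(. , t)`` is again a Gaussian mixture with the same weights and means and
inflated component variances ``b_i^2 + sigma2(t)``.  Density, score and
score divergence of every marginal are therefore available in closed form,
which makes the mixture both the synthetic-data generator and the brute-force
oracle for the likelihood integrators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml
from scipy.special import logsumexp
from scipy.stats import norm

from difflik.score import as_batch
from difflik.sde import NoiseSchedule, marginal_variance

__all__ = ["GaussianMixture", "trimodal_mixture", "AnalyticMixtureScore"]


@dataclass(frozen=True)
class GaussianMixture:
    """Isotropic Gaussian mixture over R^n.

    Parameters
    ----------
    weights : array (K,)
        Mixture weights on the simplex (non-negative, sum to 1).
    means : array (K, n)
        Component means; 1D inputs of shape (K,) are promoted to (K, 1).
    stds : array (K,)
        Per-component isotropic standard deviations, strictly positive.
    """

    weights: np.ndarray
    means: np.ndarray
    stds: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        mu = np.asarray(self.means, dtype=float)
        if mu.ndim == 1:
            mu = mu.reshape(-1, 1)
        b = np.asarray(self.stds, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be non-negative and sum to 1")
        if np.any(b <= 0):
            raise ValueError("stds must be strictly positive")
        if not (len(w) == len(mu) == len(b)):
            raise ValueError("weights, means, stds must have equal length")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", mu)
        object.__setattr__(self, "stds", b)

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def dimension(self) -> int:
        return self.means.shape[1]

    # ---- moments -------------------------------------------------------
    @property
    def mean(self) -> np.ndarray:
        return self.weights @ self.means

    @property
    def variance(self) -> float:
        """Total variance (per-coordinate trace average for n>1)."""
        mu = self.mean
        second = self.weights @ (
            self.stds**2 * self.dimension + np.sum(self.means**2, axis=1)
        )
        return float((second - np.sum(mu**2)) / self.dimension)

    # ---- densities -----------------------------------------------------
    def _log_component_densities(self, x: np.ndarray) -> np.ndarray:
        # x: (m, n) -> (m, K)
        n = self.dimension
        d2 = np.sum((x[:, None, :] - self.means[None, :, :]) ** 2, axis=2)
        v = self.stds**2
        return -0.5 * d2 / v - 0.5 * n * np.log(2.0 * np.pi * v)

    def log_density(self, x) -> np.ndarray:
        """log p(x) via log-sum-exp over components; shape (m,) or scalar."""
        xb, single = as_batch(x)
        lp = logsumexp(self._log_component_densities(xb) + np.log(self.weights), axis=1)
        return float(lp[0]) if single else lp

    def density(self, x) -> np.ndarray:
        return np.exp(self.log_density(x))

    def cdf(self, x) -> np.ndarray:
        """Mixture CDF (1D only)."""
        if self.dimension != 1:
            raise ValueError("cdf is defined for 1D mixtures")
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.sum(
            self.weights * norm.cdf((x[:, None] - self.means[:, 0]) / self.stds), axis=1
        )
        return out if out.size > 1 else float(out[0])

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        """Posterior component probabilities, log-space stable; (m, K)."""
        lc = self._log_component_densities(x) + np.log(self.weights)
        return np.exp(lc - logsumexp(lc, axis=1, keepdims=True))

    def score(self, x) -> np.ndarray:
        """grad_x log p(x): responsibility-weighted sum of -(x - mu_i)/b_i^2."""
        xb, single = as_batch(x)
        r = self.responsibilities(xb)  # (m, K)
        comp = -(xb[:, None, :] - self.means[None, :, :]) / (self.stds**2)[None, :, None]
        s = np.sum(r[:, :, None] * comp, axis=1)
        return s[0] if single else s

    def score_divergence(self, x) -> np.ndarray:
        """Tr grad_x score in closed form.

        With per-component scores ``g_i = -(x - mu_i)/b_i^2`` and
        responsibilities ``r_i``:  div s = sum_i r_i (||g_i||^2 - n/b_i^2)
        - ||s||^2.
        """
        xb, single = as_batch(x)
        n = self.dimension
        r = self.responsibilities(xb)
        comp = -(xb[:, None, :] - self.means[None, :, :]) / (self.stds**2)[None, :, None]
        s = np.sum(r[:, :, None] * comp, axis=1)
        g2 = np.sum(comp**2, axis=2)  # (m, K)
        div = np.sum(r * (g2 - n / self.stds**2), axis=1) - np.sum(s**2, axis=1)
        return float(div[0]) if single else div

    # ---- sampling ------------------------------------------------------
    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n i.i.d. points, shape (n, dim): component by weight, then Gaussian."""
        if n < 1:
            raise ValueError("n must be >= 1")
        comp = rng.choice(self.n_components, size=n, p=self.weights)
        z = rng.standard_normal((n, self.dimension))
        return self.means[comp] + self.stds[comp, None] * z

    # ---- diffusion marginals ------------------------------------------
    def marginal_at_t(self, schedule: NoiseSchedule, t: float) -> "GaussianMixture":
        """Marginal p(., t) under the VE kernel: stds -> sqrt(b_i^2 + sigma2(t))."""
        v = marginal_variance(schedule, t)
        return GaussianMixture(self.weights, self.means, np.sqrt(self.stds**2 + v))

    # ---- serialization -------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "stds": self.stds.tolist(),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "GaussianMixture":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(payload["weights"], payload["means"], payload["stds"])


def trimodal_mixture() -> GaussianMixture:
    """The trimodal 1D benchmark mixture used throughout validation.

    Three well-separated modes: means (-30, 0, 40), stds (8, 5, 10),
    weights (0.4, 0.3, 0.3).
    """
    return GaussianMixture(
        weights=np.array([0.4, 0.3, 0.3]),
        means=np.array([-30.0, 0.0, 40.0]),
        stds=np.array([8.0, 5.0, 10.0]),
    )


class AnalyticMixtureScore:
    """Exact score field of a mixture's diffusion marginals.

    Realizes ``s(x, t) = grad_x log p(x, t)`` and its divergence in closed
    form, valid on the full interval t in [0, 1] (no lower cutoff needed).
    Serves as the oracle against which learned scores and both likelihood
    integrators are tested.
    """

    kind = "analytic"

    def __init__(self, gmm: GaussianMixture, schedule: NoiseSchedule):
        self.gmm = gmm
        self.schedule = schedule

    def _marginal(self, t: float) -> GaussianMixture:
        return self.gmm.marginal_at_t(self.schedule, float(t))

    def __call__(self, x, t) -> np.ndarray:
        xb, _ = as_batch(x)
        t = np.asarray(t, dtype=float)
        if t.ndim == 0:
            return self._marginal(float(t)).score(xb)
        out = np.empty_like(xb)
        for tv in np.unique(t):
            mask = t == tv
            out[mask] = self._marginal(float(tv)).score(xb[mask])
        return out

    def divergence(self, x, t) -> np.ndarray:
        xb, _ = as_batch(x)
        t = np.asarray(t, dtype=float)
        if t.ndim == 0:
            return np.atleast_1d(self._marginal(float(t)).score_divergence(xb))
        out = np.empty(xb.shape[0])
        for tv in np.unique(t):
            mask = t == tv
            out[mask] = self._marginal(float(tv)).score_divergence(xb[mask])
        return out

    def log_marginal_density(self, x, t) -> np.ndarray:
        return self._marginal(float(t)).log_density(x)
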