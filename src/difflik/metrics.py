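"""Validation metrics: KS distance, Pearson correlation, KDE, binned means."""

from __future__ import annotations

import numpy as np
from scipy.stats import gaussian_kde

__all__ = ["ks_distance", "pearson_r", "kde_estimate", "binned_mean"]


def ks_distance(samples, cdf) -> float:
    """Two-sided Kolmogorov–Smirnov distance of samples to a reference CDF.

    ``sup_x |F_emp(x) - F(x)|`` with the empirical CDF evaluated from both
    sides at each sorted sample (the standard two-sided convention).
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = len(x)
    if n == 0:
        raise ValueError("need at least one sample")
    f = np.asarray(cdf(x), dtype=float)
    d_plus = np.max(np.arange(1, n + 1) / n - f)
    d_minus = np.max(f - np.arange(0, n) / n)
    return float(max(d_plus, d_minus))


def pearson_r(a, b) -> float:
    """Sample Pearson correlation coefficient."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need two equal-length sequences of length >= 2")
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if denom == 0.0:
        raise ValueError("correlation undefined: zero variance input")
    return float(np.clip(np.sum(a * b) / denom, -1.0, 1.0))


def kde_estimate(samples, grid, bandwidth="auto") -> np.ndarray:
    """Gaussian kernel density estimate on a grid.

    ``bandwidth="auto"`` uses Scott's rule; a numeric bandwidth is interpreted
    as the absolute kernel standard deviation.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if len(samples) == 0:
        raise ValueError("need at least one sample")
    grid = np.asarray(grid, dtype=float)
    if len(samples) == 1:
        bw = 1.0 if bandwidth == "auto" else float(bandwidth)
        return np.exp(-0.5 * ((grid - samples[0]) / bw) ** 2) / (bw * np.sqrt(2 * np.pi))
    if bandwidth == "auto":
        kde = gaussian_kde(samples)
    else:
        kde = gaussian_kde(samples, bw_method=float(bandwidth) / samples.std(ddof=1))
    return kde(grid)


def binned_mean(x, y, n_bins: int):
    """Mean of y in equal-width bins over the range of x; empty bins omitted.

    Returns (bin_centers, bin_means).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=y, minlength=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    return centers[keep], sums[keep] / counts[keep]
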