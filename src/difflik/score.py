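"""Score-field contract shared by analytic oracles and learned networks.

A *score field* is any object approximating ``s(x, t) = grad_x log p(x, t)``
for the marginals of a diffusion process.  The likelihood integrators only
need two capabilities: pointwise evaluation and the divergence (trace of the
spatial Jacobian), both batched over points.
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np


@runtime_checkable
class ScoreField(Protocol):
    """Callable approximation of the marginal score with divergence support.

    Conventions
    -----------
    ``x`` has shape ``(m, n)`` (``m`` points in ``R^n``); ``t`` is a scalar or
    an array broadcastable to ``(m,)``.  ``__call__`` returns shape ``(m, n)``
    and ``divergence`` returns shape ``(m,)``.
    """

    #: "analytic" for closed-form oracles, "learned" for trained networks.
    kind: str

    def __call__(self, x: np.ndarray, t) -> np.ndarray: ...

    def divergence(self, x: np.ndarray, t) -> np.ndarray: ...


def as_batch(x) -> tuple[np.ndarray, bool]:
    """Coerce a point or batch of points to shape ``(m, n)``.

    Returns the 2D array and whether the input was a single point (so callers
    can squeeze results back).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 0:
        return x.reshape(1, 1), True
    if x.ndim == 1:
        return x.reshape(1, -1), True
    if x.ndim == 2:
        return x, False
    raise ValueError(f"expected point(s) of shape (n,) or (m, n), got {x.shape}")


class ZeroScore:
    """The identically-zero score field (score-free baseline)."""

    kind = "analytic"

    def __call__(self, x, t):
        x, _ = as_batch(x)
        return np.zeros_like(x)

    def divergence(self, x, t):
        x, _ = as_batch(x)
        return np.zeros(x.shape[0])
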