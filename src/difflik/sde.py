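"""Variance-exploding diffusion SDE: schedule, kernel, samplers.

The forward process is ``dx = g(t) dw`` (zero drift) with the exponential
diffusion coefficient ``g(t) = sigma0 * (sigma1/sigma0)**t`` on t in [0, 1].
Because the drift vanishes, the forward perturbation kernel started at ``x0``
is Gaussian, ``q(x_t, t | x0) = N(x0, sigma2(t) I)`` with
``sigma2(t) = int_0^t g(s)^2 ds`` available in closed form.

Reverse-time generation uses the reverse SDE
``dx = -g(t)^2 s(x, t) dt + g(t) dw_bar`` discretized with Euler–Maruyama,
and the deterministic probability-flow ODE ``dx/dt = -g(t)^2 s(x, t) / 2``
which shares the SDE's marginals.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp

from difflik.constants import DEFAULT_T_MIN, FLOW_ATOL, FLOW_RTOL
from difflik.score import ScoreField, as_batch

__all__ = [
    "NoiseSchedule",
    "DiffusionSpec",
    "Trajectory",
    "g_of_t",
    "marginal_variance",
    "perturb_forward",
    "sample_reverse_sde",
    "solve_flow_ode",
    "FlowSolverError",
]


@dataclass(frozen=True)
class NoiseSchedule:
    """Exponential noise schedule of a variance-exploding SDE.

    Parameters
    ----------
    sigma0, sigma1
        Diffusion coefficient at t=0 and t=1; ``sigma1 > sigma0 > 0`` so that
        ``g`` increases strictly over the unit interval.
    t_min
        Lower integration cutoff in [0, 1).  Learned scores are typically only
        trusted down to a small positive time; analytic oracles support 0.
    """

    sigma0: float = 0.1
    sigma1: float = 70.0
    t_min: float = DEFAULT_T_MIN
    t_max: float = 1.0

    def __post_init__(self):
        if not (self.sigma1 > self.sigma0 > 0):
            raise ValueError("require sigma1 > sigma0 > 0")
        if not (0.0 <= self.t_min < 1.0):
            raise ValueError("t_min must lie in [0, 1)")
        if self.t_max != 1.0:
            raise ValueError("t_max is fixed at 1")

    # ratio sigma1/sigma0 appears in every closed form
    @property
    def _ratio(self) -> float:
        return self.sigma1 / self.sigma0

    def g(self, t):
        return g_of_t(self, t)

    def sigma2(self, t):
        return marginal_variance(self, t)

    def sigma(self, t):
        return np.sqrt(marginal_variance(self, t))


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0) or np.any(t > 1.0):
        raise ValueError(f"diffusion time must lie in [0, 1], got {t}")
    return t


def g_of_t(schedule: NoiseSchedule, t):
    """Diffusion coefficient ``g(t) = sigma0 * (sigma1/sigma0)**t``."""
    t = _check_time(t)
    return schedule.sigma0 * schedule._ratio**t


def marginal_variance(schedule: NoiseSchedule, t):
    """Accumulated perturbation variance ``sigma2(t) = int_0^t g(s)^2 ds``.

    For the exponential schedule the integral is exact:
    ``sigma0^2 * ((sigma1/sigma0)**(2t) - 1) / (2 ln(sigma1/sigma0))``.
    This is the variance of the forward kernel (the expm1 form keeps it
    accurate near t=0, where the common ``sigma0^2 r^{2t}`` approximation is
    off by a factor of ``2 ln r``).
    """
    t = _check_time(t)
    log_r = np.log(schedule._ratio)
    return schedule.sigma0**2 * np.expm1(2.0 * t * log_r) / (2.0 * log_r)


def time_of_variance(schedule: NoiseSchedule, v):
    """Inverse of :func:`marginal_variance`: the time t with sigma2(t) = v."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("variance must be non-negative")
    log_r = np.log(schedule._ratio)
    return np.log1p(2.0 * v * log_r / schedule.sigma0**2) / (2.0 * log_r)


def perturb_forward(x0, t, schedule: NoiseSchedule, rng: np.random.Generator):
    """Draw ``x_t ~ q(. , t | x0) = N(x0, sigma2(t) I)`` from the forward kernel."""
    x0 = np.asarray(x0, dtype=float)
    sd = np.sqrt(marginal_variance(schedule, t))
    return x0 + sd * rng.standard_normal(x0.shape)


@dataclass(frozen=True)
class DiffusionSpec:
    """Fully-specified diffusion process (schedule + dimension + grid + prior).

    The drift is identically zero (variance-exploding convention).  The time
    grid for the reverse-SDE sampler is uniform with ``n_steps + 1`` nodes on
    ``[t_min, 1]``.  The prior defaults to the zero-mean VE Gaussian
    ``N(0, sigma2(1) I)``; ``prior_mean`` / ``prior_var`` allow a
    moment-matched prior when the data spread is not negligible against the
    accumulated noise.
    """

    schedule: NoiseSchedule = field(default_factory=NoiseSchedule)
    dimension: int = 1
    n_steps: int = 1000
    prior_mean: float = 0.0
    prior_var: float | None = None

    def __post_init__(self):
        if self.dimension < 1 or self.n_steps < 1:
            raise ValueError("dimension and n_steps must be positive")
        if self.prior_var is not None and self.prior_var <= 0:
            raise ValueError("prior_var must be positive")

    @property
    def effective_prior_var(self) -> float:
        if self.prior_var is not None:
            return float(self.prior_var)
        return float(marginal_variance(self.schedule, 1.0))

    def time_grid(self, descending: bool = True) -> np.ndarray:
        grid = np.linspace(self.schedule.t_min, 1.0, self.n_steps + 1)
        return grid[::-1].copy() if descending else grid

    def sample_prior(self, n_samples: int, rng: np.random.Generator) -> np.ndarray:
        sd = np.sqrt(self.effective_prior_var)
        return self.prior_mean + sd * rng.standard_normal((n_samples, self.dimension))


@dataclass
class Trajectory:
    """Ordered path ``(t_i, x_i)`` through diffusion space.

    ``points`` has shape ``(k, n)`` for a single path or ``(k, m, n)`` for a
    batch of m paths sharing the same time grid.  ``times`` must be strictly
    monotone (ascending or descending) with at least two nodes.
    """

    times: np.ndarray
    points: np.ndarray
    origin: Literal["reverse_sde", "flow_ode", "forward_kernel"]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("a trajectory needs at least two time nodes")
        dt = np.diff(self.times)
        if not (np.all(dt > 0) or np.all(dt < 0)):
            raise ValueError("trajectory times must be strictly monotone")
        if self.points.shape[0] != len(self.times):
            raise ValueError("times and points length mismatch")
        if self.points.ndim not in (2, 3):
            raise ValueError("points must have shape (k, n) or (k, m, n)")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def is_batched(self) -> bool:
        return self.points.ndim == 3

    @property
    def dimension(self) -> int:
        return self.points.shape[-1]

    def ascending(self) -> "Trajectory":
        """Return an equivalent trajectory with times increasing."""
        if self.times[1] > self.times[0]:
            return self
        return Trajectory(self.times[::-1].copy(), self.points[::-1].copy(), self.origin)

    def endpoint(self, t: float) -> np.ndarray:
        """Point(s) at whichever end of the path is closer to time ``t``."""
        idx = 0 if abs(self.times[0] - t) <= abs(self.times[-1] - t) else -1
        return self.points[idx]

    def to_csv(self, path_or_buf) -> None:
        """Write a single path as CSV with columns step, t, x_1..x_n."""
        import pandas as pd

        if self.is_batched:
            raise ValueError("CSV export is defined for single paths only")
        cols = {"step": np.arange(len(self)), "t": self.times}
        for j in range(self.dimension):
            cols[f"x_{j + 1}"] = self.points[:, j]
        pd.DataFrame(cols).to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, origin="reverse_sde") -> "Trajectory":
        import pandas as pd

        df = pd.read_csv(path_or_buf)
        xcols = [c for c in df.columns if c.startswith("x_")]
        return cls(df["t"].to_numpy(), df[xcols].to_numpy(), origin)


def _score_checked(score: ScoreField, x: np.ndarray, t: float, step: int) -> np.ndarray:
    s = score(x, t)
    if not np.all(np.isfinite(s)):
        raise FloatingPointError(
            f"non-finite score at step {step} (t={t:.6g}); "
            "check the score field's supported time range"
        )
    return s


def sample_reverse_sde(
    score: ScoreField,
    spec: DiffusionSpec,
    x1: np.ndarray,
    rng: np.random.Generator,
    noise_last_step: bool = True,
) -> Trajectory:
    """Euler–Maruyama integration of the reverse SDE from t=1 down to t_min.

    Per step of size ``dt > 0`` (time decreasing) the update is

        x <- x + g(t)^2 s(x, t) dt + g(t) sqrt(dt) z,   z ~ N(0, I),

    i.e. the score drift pushes samples toward high-density regions while the
    reverse-time Wiener term re-injects noise.  ``x1`` is the starting noise
    sample, shape ``(n,)`` or ``(m, n)``; the returned trajectory contains all
    ``n_steps + 1`` nodes with times descending from 1 to ``t_min``.

    ``noise_last_step=False`` makes the final step purely deterministic, a
    common denoising variant; the default keeps plain Euler–Maruyama.
    """
    x, single = as_batch(x1)
    if x.shape[1] != spec.dimension:
        raise ValueError(f"x1 dimension {x.shape[1]} != spec dimension {spec.dimension}")
    times = spec.time_grid(descending=True)
    points = np.empty((len(times),) + x.shape)
    points[0] = x
    sched = spec.schedule
    for i in range(len(times) - 1):
        t = times[i]
        dt = times[i] - times[i + 1]  # positive
        g = float(g_of_t(sched, t))
        s = _score_checked(score, x, t, i)
        x = x + g * g * s * dt
        if noise_last_step or i < len(times) - 2:
            x = x + g * np.sqrt(dt) * rng.standard_normal(x.shape)
        points[i + 1] = x
    if single:
        points = points[:, 0, :]
    return Trajectory(times, points, origin="reverse_sde")


class FlowSolverError(RuntimeError):
    """Probability-flow ODE solver failure; carries the last valid time."""

    def __init__(self, message: str, last_t: float):
        super().__init__(f"{message} (last valid t={last_t:.6g})")
        self.last_t = last_t


def _flow_rhs(score: ScoreField, schedule: NoiseSchedule, n: int):
    def rhs(t, y):
        x = y.reshape(-1, n)
        g2 = float(g_of_t(schedule, np.clip(t, 0.0, 1.0))) ** 2
        return (-0.5 * g2 * score(x, np.clip(t, 0.0, 1.0))).ravel()

    return rhs


def solve_flow_ode(
    score: ScoreField,
    spec: DiffusionSpec,
    x0: np.ndarray,
    direction: str = "0to1",
    rtol: float = FLOW_RTOL,
    atol: float = FLOW_ATOL,
    t_eval: np.ndarray | None = None,
) -> Trajectory:
    """Solve the probability-flow ODE ``dx/dt = -g(t)^2 s(x, t) / 2``.

    The flow shares the SDE's marginal distributions but is deterministic, so
    it maps data points to noise points (direction "0to1", starting at
    ``x0`` at ``t_min``) or back ("1to0").  Solved with adaptive RK45;
    the returned trajectory holds the solver's accepted nodes (or ``t_eval``).
    """
    x, single = as_batch(x0)
    if x.shape[1] != spec.dimension:
        raise ValueError(f"x0 dimension {x.shape[1]} != spec dimension {spec.dimension}")
    t0, t1 = (spec.schedule.t_min, 1.0) if direction == "0to1" else (1.0, spec.schedule.t_min)
    sol = solve_ivp(
        _flow_rhs(score, spec.schedule, spec.dimension),
        (t0, t1),
        x.ravel(),
        method="RK45",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise FlowSolverError(f"flow ODE solver failed: {sol.message}", float(sol.t[-1]))
    points = sol.y.T.reshape(len(sol.t), x.shape[0], spec.dimension)
    if single:
        points = points[:, 0, :]
    return Trajectory(sol.t, points, origin="flow_ode")
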