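"""Denoising score matching: train a score approximator on samples.

The network never sees the marginal score directly.  For each data point
``x0`` a time ``t`` and a perturbed point ``x_t = x0 + sigma(t) z`` are drawn
from the forward kernel, and the network is regressed onto the *conditional*
score ``grad log q(x_t | x0) = -z / sigma(t)``; in expectation over the data
this recovers the marginal score.  With the variance weighting
``lambda(t) = sigma(t)^2`` the objective reduces to noise prediction,
``E || eps_hat(x_t, t) - z ||^2 / 2``, which keeps targets O(1) across a noise
scale spanning four orders of magnitude.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from difflik.nn import MLP, Adam, GaussianFourierFeatures
from difflik.score import ScoreField, as_batch
from difflik.sde import NoiseSchedule, marginal_variance, time_of_variance

__all__ = ["TrainConfig", "LearnedScore", "dsm_loss", "train_score_model",
           "TrainingDivergedError"]


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the score model and its optimization.

    Defaults follow common small-scale practice for score models: Adam with
    cosine learning-rate decay, noise levels stratified log-uniformly between
    sigma(t_min) and sigma(1), sigma^2 loss weighting (implicit in the
    noise-prediction objective), and an exponential moving average of the
    weights for the final model.
    """

    n_steps: int = 30_000
    batch_size: int = 512
    learning_rate: float = 1e-3
    lr_decay: str = "cosine"  # "cosine" or "none"
    hidden: int = 128
    n_hidden_layers: int = 3
    time_embed_dim: int = 64
    fourier_scale: float = 8.0
    ema_decay: float = 0.999  # 0 disables weight averaging
    seed: int = 0

    def __post_init__(self):
        if min(self.n_steps, self.batch_size, self.hidden, self.n_hidden_layers,
               self.time_embed_dim) <= 0 or self.learning_rate <= 0:
            raise ValueError("all counts and the learning rate must be positive")
        if not (0.0 <= self.ema_decay < 1.0):
            raise ValueError("ema_decay must lie in [0, 1)")
        if self.lr_decay not in ("cosine", "none"):
            raise ValueError("lr_decay must be 'cosine' or 'none'")


class LearnedScore:
    """Score field backed by a trained noise-prediction MLP.

    The network outputs ``eps_hat(x, t)``; the exposed score is
    ``s(x, t) = -eps_hat / sigma(t)``.  Spatial derivatives (for the
    divergence) are exact forward-mode derivatives through the network, one
    pass per spatial coordinate.
    """

    kind = "learned"

    def __init__(self, mlp: MLP, fourier: GaussianFourierFeatures,
                 schedule: NoiseSchedule, dimension: int, x_scale: float,
                 config: TrainConfig | None = None,
                 loss_history: np.ndarray | None = None):
        self.mlp = mlp
        self.fourier = fourier
        self.schedule = schedule
        self.dimension = dimension
        self.x_scale = float(x_scale)
        self.config = config
        self.loss_history = loss_history

    # -- feature assembly ------------------------------------------------
    def _time_coord(self, t: np.ndarray) -> np.ndarray:
        """Noise-level coordinate: normalized log sigma(t).

        sigma spans four orders of magnitude; conditioning on log sigma gives
        the network uniform resolution across noise levels, whereas raw t
        squeezes the low-noise regime into a vanishing interval.
        """
        t_ref = max(self.schedule.t_min, 1e-5)
        s_ref = np.sqrt(marginal_variance(self.schedule, t_ref))
        s_one = np.sqrt(marginal_variance(self.schedule, 1.0))
        sig = np.sqrt(np.maximum(marginal_variance(self.schedule, t), s_ref**2 * 1e-12))
        return np.log(sig / s_ref) / np.log(s_one / s_ref)

    def _features(self, x: np.ndarray, t: np.ndarray) -> np.ndarray:
        return np.concatenate(
            [x / self.x_scale, self.fourier.embed(self._time_coord(t))], axis=1
        )

    def _sigma(self, t: np.ndarray) -> np.ndarray:
        sig = np.sqrt(marginal_variance(self.schedule, t))
        if np.any(sig == 0.0):
            raise ValueError("learned score undefined at sigma(t)=0; use t >= t_min > 0")
        return sig

    def _broadcast_t(self, x: np.ndarray, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.broadcast_to(t, (x.shape[0],)).astype(float)

    def eps(self, x, t) -> np.ndarray:
        xb, single = as_batch(x)
        tb = self._broadcast_t(xb, t)
        out = self.mlp.forward(self._features(xb, tb))
        return out[0] if single else out

    def __call__(self, x, t) -> np.ndarray:
        xb, single = as_batch(x)
        tb = self._broadcast_t(xb, t)
        s = -self.mlp.forward(self._features(xb, tb)) / self._sigma(tb)[:, None]
        return s[0] if single else s

    def score_and_divergence(self, x, t) -> tuple[np.ndarray, np.ndarray]:
        """One cached forward pass plus one JVP per spatial coordinate."""
        xb, _ = as_batch(x)
        tb = self._broadcast_t(xb, t)
        feats = self._features(xb, tb)
        out, cache = self.mlp.forward(feats, want_cache=True)
        sig = self._sigma(tb)
        s = -out / sig[:, None]
        div_eps = np.zeros(xb.shape[0])
        for j in range(self.dimension):
            da = np.zeros_like(feats)
            da[:, j] = 1.0 / self.x_scale
            div_eps += self.mlp.input_jvp(cache, da)[:, j]
        return s, -div_eps / sig

    def divergence(self, x, t) -> np.ndarray:
        return self.score_and_divergence(x, t)[1]

    # -- checkpointing ---------------------------------------------------
    def save(self, directory) -> None:
        """Write weights (npz) plus a JSON sidecar with every regeneration input."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = self.mlp.get_params()
        arrays["fourier_freqs"] = self.fourier.freqs
        np.savez(directory / "weights.npz", **arrays)
        sidecar = {
            "dimension": self.dimension,
            "x_scale": self.x_scale,
            "mlp_sizes": self.mlp.sizes,
            "schedule": {"sigma0": self.schedule.sigma0,
                         "sigma1": self.schedule.sigma1,
                         "t_min": self.schedule.t_min},
            "config": asdict(self.config) if self.config else None,
            "final_loss": (float(self.loss_history[-1])
                           if self.loss_history is not None else None),
        }
        (directory / "checkpoint.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory) -> "LearnedScore":
        directory = Path(directory)
        sidecar = json.loads((directory / "checkpoint.json").read_text())
        arrays = np.load(directory / "weights.npz")
        rng = np.random.default_rng(0)
        fourier = GaussianFourierFeatures(2 * len(arrays["fourier_freqs"]), 1.0, rng)
        fourier.freqs = arrays["fourier_freqs"]
        mlp = MLP(sidecar["mlp_sizes"], rng)
        mlp.set_params({k: arrays[k] for k in arrays.files if k != "fourier_freqs"})
        schedule = NoiseSchedule(**sidecar["schedule"])
        cfg = TrainConfig(**sidecar["config"]) if sidecar["config"] else None
        return cls(mlp, fourier, schedule, sidecar["dimension"],
                   sidecar["x_scale"], config=cfg)


def _draw_dsm_batch(x0: np.ndarray, schedule: NoiseSchedule,
                    rng: np.random.Generator, t_min: float):
    m = x0.shape[0]
    t = rng.uniform(t_min, 1.0, size=m)
    sig = np.sqrt(marginal_variance(schedule, t))
    if np.any(sig == 0.0):
        raise ValueError("sigma(t)=0 in DSM batch; raise the time cutoff above 0")
    z = rng.standard_normal(x0.shape)
    xt = x0 + sig[:, None] * z
    return t, sig, z, xt


def dsm_loss(score: ScoreField, x0_batch: np.ndarray, schedule: NoiseSchedule,
             rng: np.random.Generator, t_min: float | None = None) -> float:
    """Monte-Carlo denoising score-matching loss of an arbitrary score field.

    Uses the sigma^2-weighted objective
    ``mean over batch of || sigma(t) s(x_t, t) + z ||^2 / 2``; a perfect
    conditional score scores 0, the zero score scores n/2 in expectation.
    """
    x0, _ = as_batch(x0_batch)
    if x0.shape[0] == 0:
        raise ValueError("empty batch")
    if t_min is None:
        t_min = schedule.t_min
    t, sig, z, xt = _draw_dsm_batch(x0, schedule, rng, t_min)
    resid = sig[:, None] * score(xt, t) + z
    return float(0.5 * np.mean(np.sum(resid**2, axis=1)))


def train_score_model(data: np.ndarray, schedule: NoiseSchedule,
                      config: TrainConfig = TrainConfig()) -> LearnedScore:
    """Fit a noise-prediction MLP to samples by stochastic gradient descent.

    ``data`` has shape (N,) or (N, n).  Returns a :class:`LearnedScore`;
    training is deterministic given ``config.seed``.  The spatial input scale
    is set from the data so that network inputs stay O(1) across the whole
    noise range.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    if data.ndim != 2:
        raise ValueError("data must have shape (N,) or (N, n)")
    n_data, dim = data.shape
    rng = np.random.default_rng(config.seed)

    x_scale = float(np.sqrt(np.var(data) + marginal_variance(schedule, 1.0)))
    fourier = GaussianFourierFeatures(config.time_embed_dim, config.fourier_scale, rng)
    sizes = ([dim + config.time_embed_dim]
             + [config.hidden] * config.n_hidden_layers + [dim])
    mlp = MLP(sizes, rng)
    opt = Adam(mlp.Ws + mlp.bs, lr=config.learning_rate)

    t_min = max(schedule.t_min, 1e-5)  # sigma(t) must stay positive in training
    sig_lo = float(np.sqrt(marginal_variance(schedule, t_min)))
    sig_hi = float(np.sqrt(marginal_variance(schedule, 1.0)))
    model = LearnedScore(mlp, fourier, schedule, dim, x_scale, config=config)
    ema = ([p.copy() for p in opt.params] if config.ema_decay > 0 else None)
    losses = np.empty(config.n_steps)
    strata = (np.arange(config.batch_size) + 0.0) / config.batch_size
    for step in range(config.n_steps):
        if config.lr_decay == "cosine":
            opt.lr = config.learning_rate * 0.5 * (
                1.0 + np.cos(np.pi * step / config.n_steps))
        idx = rng.integers(0, n_data, size=config.batch_size)
        x0 = data[idx]
        # noise levels stratified uniformly in log sigma between sigma(t_min)
        # and sigma(1) -- matching the network's noise-level conditioning --
        # then mapped back to times through the schedule inverse
        u = (strata + rng.uniform(0, 1.0 / config.batch_size, config.batch_size))
        sig = sig_lo * (sig_hi / sig_lo) ** u
        t = time_of_variance(schedule, sig**2)
        z = rng.standard_normal(x0.shape)
        xt = x0 + sig[:, None] * z
        feats = model._features(xt, t)
        out, cache = mlp.forward(feats, want_cache=True)
        resid = out - z  # noise-prediction residual
        loss = 0.5 * np.mean(np.sum(resid**2, axis=1))
        if not np.isfinite(loss):
            raise TrainingDivergedError(f"non-finite loss at step {step}")
        losses[step] = loss
        dWs, dbs = mlp.backward(cache, resid / config.batch_size)
        opt.step(dWs + dbs)
        if ema is not None:
            d = config.ema_decay
            for e, p in zip(ema, opt.params):
                e *= d
                e += (1 - d) * p
    if ema is not None:
        k = len(mlp.Ws)
        mlp.Ws = ema[:k]
        mlp.bs = ema[k:]
    model.loss_history = losses
    return model
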