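import numpy as np
import pytest

from difflik import (
    ExperimentConfig,
    NoiseSchedule,
    TrainConfig,
    run_gmm_experiment,
    train_score_model,
    trimodal_mixture,
)
from difflik.gmm import AnalyticMixtureScore, GaussianMixture


@pytest.fixture(scope="session")
def schedule():
    """Benchmark schedule with exact-time support (analytic oracle, t_min=0)."""
    return NoiseSchedule(sigma0=0.1, sigma1=70.0, t_min=0.0)


@pytest.fixture(scope="session")
def schedule_cut():
    """Benchmark schedule with the learned-score time cutoff."""
    return NoiseSchedule(sigma0=0.1, sigma1=70.0, t_min=1e-4)


@pytest.fixture(scope="session")
def mixture():
    return trimodal_mixture()


@pytest.fixture(scope="session")
def oracle_score(mixture, schedule):
    return AnalyticMixtureScore(mixture, schedule)


@pytest.fixture(scope="session")
def single_gaussian():
    return GaussianMixture(weights=[1.0], means=[[3.0]], stds=[5.0])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_trained_model(schedule_cut):
    """A quickly trained 1D score model for unit-level checks."""
    gmm = trimodal_mixture()
    data = gmm.sample(10_000, np.random.default_rng(42))
    cfg = TrainConfig(n_steps=3000, hidden=64, batch_size=256, seed=3)
    return train_score_model(data[:, 0], schedule_cut, cfg)


@pytest.fixture(scope="session")
def learned_report():
    """Moderate-scale end-to-end benchmark run shared by the slower tests.

    Scaled down from the full study (30k training points, 12k optimization
    steps, 500 diffusion steps; likelihoods on 2,000 samples, the sampling
    check on 10,000) to keep the suite fast while staying in the regime where
    the trained model recovers the mixture well.
    """
    cfg = ExperimentConfig(
        n_train=30_000,
        n_samples=10_000,
        n_likelihood=2_000,
        n_steps=500,
        train=TrainConfig(n_steps=12_000),
        seed=7,
    )
    return run_gmm_experiment(cfg)


@pytest.fixture(scope="session")
def oracle_report():
    """Analytic-score benchmark run (no training) shared by the slower tests."""
    cfg = ExperimentConfig(
        n_train=1_000,
        n_samples=2_000,
        n_steps=500,
        score="analytic",
        t_min=0.0,
        seed=7,
    )
    return run_gmm_experiment(cfg)
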