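"""Path-integral likelihood recovery: oracle equivalence and controls."""

import numpy as np
import pytest
from scipy.integrate import quad

from difflik import (
    DiffusionSpec,
    Trajectory,
    diff_likelihood,
    flow_likelihood,
    fp_time_derivative,
    marginal_variance,
    naive_work_integral,
    nll_to_energy,
    perturb_forward,
    prior_log_density,
    sample_reverse_sde,
    solve_flow_ode,
)
from difflik.constants import FLOW_ORACLE_ATOL
from difflik.gmm import AnalyticMixtureScore, GaussianMixture
from difflik.likelihood import EmpiricalPrior
from difflik.metrics import pearson_r
from difflik import trimodal_mixture
from difflik.score import ZeroScore


class TestPriorLogDensity:
    def test_gaussian_peak_value(self, schedule):
        v1 = marginal_variance(schedule, 1.0)
        assert prior_log_density(np.zeros(1), schedule) == pytest.approx(
            -0.5 * np.log(2 * np.pi * v1)
        )

    def test_decreasing_in_radius_and_normalized(self, schedule):
        xs = np.linspace(0, 100, 11)[:, None]
        vals = prior_log_density(xs, schedule)
        assert np.all(np.diff(vals) < 0)
        total, _ = quad(lambda x: np.exp(prior_log_density(np.array([x]), schedule)),
                        -300, 300, limit=200)
        assert total == pytest.approx(1.0, abs=1e-8)


class TestFpTimeDerivative:
    def test_single_gaussian_closed_form(self, schedule):
        # d/dt log N(x; mu, v(t)) with dv/dt = g^2 equals g^2/2 (-1/v + (x-mu)^2/v^2)
        g = GaussianMixture(weights=[1.0], means=[2.0], stds=[3.0])
        score = AnalyticMixtureScore(g, schedule)
        for x, t in [(2.0, 0.3), (7.0, 0.8), (-1.0, 0.05)]:
            v = 9.0 + marginal_variance(schedule, t)
            g2 = (0.1 * 700.0**t) ** 2
            expected = 0.5 * g2 * (-1.0 / v + (x - 2.0) ** 2 / v**2)
            got = fp_time_derivative(score, schedule, np.array([x]), t)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_matches_time_finite_difference(self, mixture, oracle_score, schedule, rng):
        xs = rng.uniform(-50, 60, size=8)
        for x in xs:
            t, h = 0.45, 1e-6
            fd = (
                mixture.marginal_at_t(schedule, t + h).log_density(x)
                - mixture.marginal_at_t(schedule, t - h).log_density(x)
            ) / (2 * h)
            got = fp_time_derivative(oracle_score, schedule, np.array([x]), t)
            assert got == pytest.approx(fd, abs=1e-5)

    def test_pure_curvature_at_mode_is_negative(self, schedule):
        g = GaussianMixture(weights=[1.0], means=[0.0], stds=[4.0])
        score = AnalyticMixtureScore(g, schedule)
        assert fp_time_derivative(score, schedule, np.zeros(1), 0.5) < 0

    def test_requires_divergence_capability(self, schedule):
        assert fp_time_derivative(ZeroScore(), schedule, np.zeros(1), 0.5) == 0.0
        with pytest.raises(TypeError):
            fp_time_derivative(lambda x, t: x, schedule, np.zeros(1), 0.5)


class TestDiffLikelihood:
    def test_degenerate_two_node_trapezoid(self, schedule):
        # constant integrand over one segment: sum = integrand * dt exactly
        g = GaussianMixture(weights=[1.0], means=[0.0], stds=[3.0])
        score = AnalyticMixtureScore(g, schedule)
        t0, t1 = 0.2, 0.4
        x = np.array([[1.5], [1.5]])  # no displacement: work term vanishes
        traj = Trajectory([t0, t1], x, "forward_kernel")
        res = diff_likelihood(traj, score, schedule, log_p1=0.0)
        expected = 0.5 * (
            fp_time_derivative(score, schedule, x[0], t0)
            + fp_time_derivative(score, schedule, x[1], t1)
        ) * (t1 - t0)
        assert res.path_integral == pytest.approx(expected, rel=1e-12)
        assert res.term_work == pytest.approx(0.0, abs=1e-15)
        assert res.log_p0 == pytest.approx(-res.path_integral)

    def test_oracle_diffusion_recovery_correlates_with_truth(self, mixture, oracle_score,
                                                             schedule):
        spec = DiffusionSpec(schedule, 1, n_steps=1000)
        rng = np.random.default_rng(21)
        m1 = mixture.marginal_at_t(schedule, 1.0)
        x1 = m1.sample(500, rng)
        traj = sample_reverse_sde(oracle_score, spec, x1, rng)
        res = diff_likelihood(traj, oracle_score, schedule, log_p1=m1.log_density)
        x0 = traj.ascending().points[0]
        r = pearson_r(np.exp(res.log_p0), mixture.density(x0))
        assert r >= 0.97

    def test_refinement_halves_error_quadratically(self, mixture, oracle_score, schedule):
        # trapezoid on the same smooth flow path: error drops ~4x per refinement
        spec = DiffusionSpec(schedule, 1, n_steps=64)
        x0 = np.array([12.0])
        m1 = mixture.marginal_at_t(schedule, 1.0)
        vals = {}
        for n in (64, 128, 256):
            t_eval = np.linspace(schedule.t_min, 1.0, n + 1)
            path = solve_flow_ode(oracle_score, spec, x0, t_eval=t_eval,
                                  rtol=1e-11, atol=1e-13)
            res = diff_likelihood(path, oracle_score, schedule, log_p1=m1.log_density)
            vals[n] = res.log_p0
        coarse = abs(vals[64] - vals[128])
        fine = abs(vals[128] - vals[256])
        assert fine < coarse  # converging
        assert fine == pytest.approx(coarse / 4.0, rel=0.5)  # ~second order

    def test_short_or_nonmonotone_trajectories_rejected(self, oracle_score, schedule):
        with pytest.raises(ValueError):
            Trajectory([0.5], [[1.0]], "reverse_sde")
        with pytest.raises(ValueError):
            Trajectory([0.1, 0.8, 0.4], [[0.0], [1.0], [2.0]], "reverse_sde")


class TestFlowLikelihood:
    def test_oracle_equivalence_on_probe_points(self, mixture, oracle_score, schedule):
        spec = DiffusionSpec(schedule, 1, n_steps=100)
        probes = np.linspace(-55.0, 70.0, 40)[:, None]
        m1 = mixture.marginal_at_t(schedule, 1.0)
        res = flow_likelihood(probes, oracle_score, spec, log_p1=m1.log_density)
        err = np.abs(res.log_p0 - mixture.log_density(probes))
        assert err.max() <= FLOW_ORACLE_ATOL

    def test_single_gaussian_exact_recovery(self, schedule):
        g = GaussianMixture(weights=[1.0], means=[3.0], stds=[5.0])
        score = AnalyticMixtureScore(g, schedule)
        spec = DiffusionSpec(schedule, 1, n_steps=100)
        x0 = np.array([7.0])
        res = flow_likelihood(x0, score, spec,
                              log_p1=g.marginal_at_t(schedule, 1.0).log_density,
                              rtol=1e-10, atol=1e-12)
        assert res.log_p0 == pytest.approx(float(g.log_density(x0)), abs=1e-6)
        # endpoint follows the linear-SDE closed form
        v = lambda t: 25.0 + marginal_variance(schedule, t)  # noqa: E731
        traj = solve_flow_ode(score, spec, x0, rtol=1e-10, atol=1e-12)
        expected_end = 3.0 + (7.0 - 3.0) * np.sqrt(v(1.0) / v(0.0))
        assert traj.points[-1][0] == pytest.approx(expected_end, abs=1e-6)

    def test_work_and_score_norm_cancel_on_flow_path(self, mixture, oracle_score, schedule):
        # evaluate the FULL integrand discretely on a flow trajectory: the
        # work term must cancel the score-norm term, leaving the divergence
        spec = DiffusionSpec(schedule, 1, n_steps=100)
        t_eval = np.linspace(schedule.t_min, 1.0, 2001)
        path = solve_flow_ode(oracle_score, spec, np.array([-25.0]), t_eval=t_eval,
                              rtol=1e-10, atol=1e-12)
        res = diff_likelihood(path, oracle_score, schedule, log_p1=0.0)
        assert abs(res.term_work + res.term_score_norm) < 1e-3 * abs(res.term_divergence)

    def test_path_independence_with_exact_score(self, mixture, oracle_score, schedule):
        # diffusion-path and flow-path integrals agree for a conservative,
        # Fokker-Planck-consistent (exact) score
        spec = DiffusionSpec(schedule, 1, n_steps=2000)
        m1 = mixture.marginal_at_t(schedule, 1.0)
        x0 = np.array([[-30.0], [0.0], [40.0], [15.0]])
        rng = np.random.default_rng(3)
        flow = flow_likelihood(x0, oracle_score, spec, log_p1=m1.log_density)
        # forward-kernel path: straight noising of x0 with the schedule
        times = spec.time_grid(descending=False)
        sig = np.sqrt(marginal_variance(schedule, times))
        z = rng.standard_normal((x0.shape[0], 1))
        pts = x0[None, :, :] + sig[:, None, None] * z[None, :, :]
        fwd = Trajectory(times, pts, "forward_kernel")
        diff = diff_likelihood(fwd, oracle_score, schedule, log_p1=m1.log_density)
        np.testing.assert_allclose(diff.log_p0, flow.log_p0, atol=0.05)

    def test_batched_and_single_results_agree(self, mixture, oracle_score, schedule):
        spec = DiffusionSpec(schedule, 1, n_steps=100)
        batch = flow_likelihood(np.array([[1.0], [2.0]]), oracle_score, spec)
        one = flow_likelihood(np.array([1.0]), oracle_score, spec)
        # adaptive steps differ between the coupled systems; agreement
        # is to solver tolerance, not bitwise
        assert batch.log_p0[0] == pytest.approx(one.log_p0, abs=1e-5)


class TestNaiveWorkIntegral:
    def test_zero_score_gives_zero(self, schedule):
        traj = Trajectory([0.0, 0.5, 1.0], [[0.0], [4.0], [9.0]], "reverse_sde")
        assert naive_work_integral(traj, ZeroScore()) == 0.0

    def test_time_independent_field_reduces_to_density_difference(self, mixture, schedule):
        # frozen t=0 score field: work integral telescopes to the log-density gap
        class Frozen:
            kind = "analytic"

            def __call__(self, x, t):
                return mixture.score(x)

            def divergence(self, x, t):
                return mixture.score_divergence(x)

        a, b = -10.0, 25.0
        xs = np.linspace(a, b, 4001)[:, None]
        traj = Trajectory(np.linspace(0.0, 1.0, 4001), xs, "reverse_sde")
        got = naive_work_integral(traj, Frozen(), beta=1.0)
        expected = -(mixture.log_density(b) - mixture.log_density(a))
        assert got == pytest.approx(expected, abs=1e-4)

    def test_worse_than_full_integrand_on_same_paths(self, mixture, oracle_score, schedule):
        # the spatial-only work integral ignores d log p/dt and loses accuracy
        spec = DiffusionSpec(schedule, 1, n_steps=100)
        probes = np.linspace(-50.0, 65.0, 30)[:, None]
        m1 = mixture.marginal_at_t(schedule, 1.0)
        t_eval = np.linspace(schedule.t_min, 1.0, 501)
        path = solve_flow_ode(oracle_score, spec, probes, t_eval=t_eval)
        lp1 = m1.log_density(path.points[-1])
        full = diff_likelihood(path, oracle_score, schedule, log_p1=lp1)
        naive_logp0 = lp1 + naive_work_integral(path, oracle_score)
        truth = mixture.log_density(probes)
        rms_full = np.sqrt(np.mean((full.log_p0 - truth) ** 2))
        rms_naive = np.sqrt(np.mean((naive_logp0 - truth) ** 2))
        assert rms_naive > rms_full

    def test_beta_validation(self, schedule):
        traj = Trajectory([0.0, 1.0], [[0.0], [1.0]], "reverse_sde")
        with pytest.raises(ValueError):
            naive_work_integral(traj, ZeroScore(), beta=0.0)


class TestEnergyView:
    def test_zero_log_p_zero_energy(self):
        assert nll_to_energy(0.0).energy == 0.0

    def test_beta_linearity_and_round_trip(self):
        e1 = nll_to_energy(-3.0, beta=1.0)
        e2 = nll_to_energy(-3.0, beta=2.0)
        assert e2.energy == pytest.approx(e1.energy / 2.0)
        assert np.exp(-e2.beta * e2.energy) == pytest.approx(np.exp(-3.0), rel=1e-12)

    def test_rejects_nonpositive_beta(self):
        with pytest.raises(ValueError):
            nll_to_energy(1.0, beta=-1.0)


class TestEmpiricalPrior:
    def test_matches_equal_weight_mixture_on_tiny_data(self, schedule):
        data = np.array([-2.0, 0.5, 3.0])
        prior = EmpiricalPrior(data, schedule)
        v1 = marginal_variance(schedule, 1.0)
        ref = GaussianMixture(weights=np.full(3, 1 / 3), means=data,
                              stds=np.full(3, np.sqrt(v1)))
        xs = np.linspace(-60, 60, 7)[:, None]
        np.testing.assert_allclose(prior.log_density(xs), ref.log_density(xs), rtol=1e-12)

    def test_samples_have_convolved_variance(self, schedule, rng):
        data = trimodal_mixture().sample(2000, rng)
        prior = EmpiricalPrior(data, schedule)
        draws = prior.sample(40_000, rng)
        expected = data.var() + marginal_variance(schedule, 1.0)
        assert abs(draws.var() - expected) / expected < 0.05
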