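"""Inference tests: bi-Gaussian fitting, Tikhonov/GCV, bootstrap, populations."""

import numpy as np
import pytest

from domeq import (
    BackgroundModel,
    BiGaussianModel,
    DeerTrace,
    DistanceGrid,
    PathwayModel,
    bootstrap_ci,
    extract_populations,
    fit_bigaussian,
    simulate_trace,
    tikhonov_solve,
)
from domeq.forward import dipolar_kernel
from domeq.infer import _second_difference, gcv_select, gcv_score_unconstrained


def make_trace(model, time, noise=0.0, seed=None, lam=0.4, kappa=0.1, d=1.0):
    return simulate_trace(model, PathwayModel.four_pulse(lam),
                          BackgroundModel(kappa, d), time, noise_sigma=noise, seed=seed)


class TestBiGaussianFit:
    @pytest.mark.parametrize("r1,p1,r2", [
        (22.0, 0.68, 45.0),   # apo-like equilibrium
        (22.0, 0.50, 45.0),   # ligand-shifted equilibrium
        (24.0, 0.70, 45.0),   # alternative label pair
    ])
    def test_noiseless_round_trip(self, grid, time_axis, r1, p1, r2):
        truth = BiGaussianModel(r1, 1.5, p1, r2, 8.0)
        fit = fit_bigaussian(make_trace(truth, time_axis), grid, seed=1)
        assert fit.model.p1 == pytest.approx(p1, abs=0.01)
        assert fit.model.r1 == pytest.approx(r1, abs=0.2)
        assert fit.model.r2 == pytest.approx(r2, abs=0.5)

    def test_single_gaussian_degenerate_second_component(self, grid, time_axis):
        truth = BiGaussianModel(30.0, 2.0, 1.0, 60.0, 2.0)
        fit = fit_bigaussian(make_trace(truth, time_axis), grid, seed=1)
        assert min(fit.model.p1, fit.model.p2) <= 0.02 or \
            abs(fit.model.r1 - fit.model.r2) < 1.0

    def test_noisy_replicates_population_mean(self, grid):
        """Mean recovered compact population over noisy replicates stays
        within 0.02 of the ground truth (sigma = 0.005)."""
        time = np.linspace(0.0, 2.5, 251)
        truth = BiGaussianModel(22.0, 1.5, 0.7, 45.0, 8.0)
        p1s = []
        for seed in range(1, 101):
            trace = make_trace(truth, time, noise=0.005, seed=seed)
            fit = fit_bigaussian(trace, grid, n_starts=3, seed=seed)
            p1s.append(fit.model.p1)
        assert np.mean(p1s) == pytest.approx(0.7, abs=0.02)
        assert np.std(p1s) < 0.1

    def test_self_consistency_over_parameter_grid(self, grid, time_axis):
        """Noiseless round trips across the physically relevant parameter
        range recover populations within 0.01 and centers within 0.2 A."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            p1 = rng.uniform(0.3, 0.9)
            r1 = rng.uniform(20.0, 30.0)
            r2 = rng.uniform(38.0, 55.0)
            truth = BiGaussianModel(r1, 1.5, p1, r2, 8.0)
            fit = fit_bigaussian(make_trace(truth, time_axis), grid, seed=3)
            assert fit.model.p1 == pytest.approx(p1, abs=0.01)
            assert fit.model.r1 == pytest.approx(r1, abs=0.2)
            assert fit.model.r2 == pytest.approx(r2, abs=0.5)

    def test_rejects_tiny_or_constant_traces(self, grid):
        with pytest.raises(ValueError, match="8 data points"):
            fit_bigaussian(DeerTrace(np.arange(5.0), np.ones(5) + np.arange(5) * 0.1), grid)
        with pytest.raises(ValueError, match="constant"):
            fit_bigaussian(DeerTrace(np.arange(20.0), np.ones(20)), grid)


class TestTikhonov:
    def test_known_truth_mode_recovery(self, grid, time_axis):
        truth = BiGaussianModel(30.0, 2.0, 1.0, 60.0, 2.0)
        trace = make_trace(truth, time_axis)
        sol = gcv_select(trace, grid)
        assert abs(sol.distribution.mode() - 30.0) <= grid.step

    def test_large_alpha_limit_is_smoothest(self, grid, time_axis):
        truth = BiGaussianModel(30.0, 2.0, 1.0, 60.0, 2.0)
        trace = make_trace(truth, time_axis)
        p = tikhonov_solve(trace, grid, alpha=1e6)
        curvature = _second_difference(grid.n_points) @ p.density
        assert np.max(np.abs(curvature)) < 1e-4 * np.max(p.density)

    def test_discrepancy_at_gcv_alpha(self, grid, time_axis):
        """The regularized solution reproduces the trace to within ~1.2x
        the noise level at the GCV-selected alpha."""
        sigma = 0.005
        truth = BiGaussianModel(22.0, 1.5, 0.7, 45.0, 8.0)
        trace = make_trace(truth, time_axis, noise=sigma, seed=2)
        fit = fit_bigaussian(trace, grid, seed=0)
        sol = gcv_select(trace, grid, fit=fit)
        lam = fit.pathways.pathways[0][0]
        bg = np.exp(-fit.background.kappa * np.abs(time_axis) ** fit.background.d)
        kernel_w = dipolar_kernel(grid, time_axis) * grid.trapezoid_weights[None, :]
        reconstructed = (1 - lam + lam * (kernel_w @ sol.distribution.density)) * bg
        rms = np.sqrt(np.mean((reconstructed - trace.signal) ** 2))
        assert rms <= 1.2 * sigma

    def test_rejects_nonpositive_alpha(self, grid, apo_trace):
        with pytest.raises(ValueError):
            tikhonov_solve(apo_trace, grid, alpha=0.0)


class TestGcv:
    def test_pure_noise_selects_heavy_smoothing(self, grid):
        rng = np.random.default_rng(4)
        time = np.linspace(0.0, 2.5, 151)
        signal = 0.5 + rng.normal(0.0, 0.01, size=len(time))
        trace = DeerTrace(time, signal, noise_sigma=0.01,
                          pathway_model=PathwayModel.four_pulse(0.5),
                          background=BackgroundModel(0.0, 1.0))
        alphas = np.logspace(-3, 3, 25)
        with pytest.warns(UserWarning):
            sol = gcv_select(trace, grid, alpha_grid=alphas)
        assert sol.alpha >= alphas[-2] or sol.alpha_on_boundary

    def test_noiseless_selects_light_smoothing(self, grid, time_axis):
        truth = BiGaussianModel(30.0, 2.0, 1.0, 60.0, 2.0)
        trace = make_trace(truth, time_axis)
        alphas = np.logspace(-3, 3, 25)
        sol = gcv_select(trace, grid, alpha_grid=alphas)
        assert sol.alpha <= np.median(alphas)

    def test_matches_brute_force_leave_one_out(self):
        """On a small toy inversion the unconstrained GCV score agrees
        with brute-force leave-one-out refitting: exactly via the linear-
        smoother identity on one realization, and within 5% on the mean
        over noise realizations."""
        toy_grid = DistanceGrid(15.0, 60.0, 16)
        time = np.linspace(0.4, 1.2, 30)
        alpha = 1.0
        model = BiGaussianModel(25.0, 2.0, 1.0, 50.0, 5.0)
        kernel_w = dipolar_kernel(toy_grid, time) * toy_grid.trapezoid_weights[None, :]
        l2 = _second_difference(toy_grid.n_points)
        reg = kernel_w.T @ kernel_w + alpha**2 * (l2.T @ l2)
        h = kernel_w @ np.linalg.solve(reg, kernel_w.T)
        hii = np.diag(h)

        def trace_for(seed):
            return simulate_trace(model, PathwayModel.four_pulse(1.0),
                                  BackgroundModel(0.0, 1.0), time,
                                  noise_sigma=0.05, seed=seed, grid=toy_grid)

        # exact LOO identity: refit without point i == e_i / (1 - H_ii)
        d0 = trace_for(0).signal
        brute = np.empty(len(time))
        for i in range(len(time)):
            mask = np.ones(len(time), dtype=bool)
            mask[i] = False
            reg_i = kernel_w[mask].T @ kernel_w[mask] + alpha**2 * (l2.T @ l2)
            p_i = np.linalg.solve(reg_i, kernel_w[mask].T @ d0[mask])
            brute[i] = d0[i] - kernel_w[i] @ p_i
        shortcut = (d0 - h @ d0) / (1.0 - hii)
        assert np.allclose(brute, shortcut, atol=1e-8)

        gcvs, loos = [], []
        for seed in range(40):
            tr = trace_for(seed)
            e = tr.signal - h @ tr.signal
            n = len(time)
            gcvs.append(n * np.sum(e**2) / np.trace(np.eye(n) - h) ** 2)
            loos.append(np.mean((e / (1.0 - hii)) ** 2))
            if seed == 0:
                score = gcv_score_unconstrained(tr, toy_grid, alpha)
                assert score == pytest.approx(gcvs[0], rel=1e-10)
        assert np.mean(gcvs) == pytest.approx(np.mean(loos), rel=0.05)


class TestBootstrap:
    def test_zero_noise_gives_tight_intervals(self, grid, apo_trace):
        fit = fit_bigaussian(apo_trace, grid, seed=1)
        fit = bootstrap_ci(apo_trace, fit, n_samples=20, seed=0, grid=grid)
        lo, hi = fit.ci95["p1"]
        assert hi - lo <= 1e-3

    def test_seed_reproducibility(self, grid, time_axis):
        truth = BiGaussianModel(22.0, 1.5, 0.7, 45.0, 8.0)
        trace = make_trace(truth, time_axis, noise=0.005, seed=9)
        fit = fit_bigaussian(trace, grid, seed=0)
        a = bootstrap_ci(trace, fit, n_samples=50, seed=5, grid=grid)
        b = bootstrap_ci(trace, fit, n_samples=50, seed=5, grid=grid)
        c = bootstrap_ci(trace, fit, n_samples=50, seed=6, grid=grid)
        assert a.ci95 == b.ci95
        assert a.ci95 != c.ci95

    def test_rejects_too_few_samples(self, grid, apo_trace):
        fit = fit_bigaussian(apo_trace, grid, seed=1)
        with pytest.raises(ValueError):
            bootstrap_ci(apo_trace, fit, n_samples=10, seed=0, grid=grid)


class TestExtractPopulations:
    def test_auto_split_on_canonical_mixture(self, grid):
        dist = BiGaussianModel(22.0, 1.5, 0.7, 45.0, 8.0).density(grid)
        p_c, p_e = extract_populations(dist, split="auto")
        assert p_c == pytest.approx(0.70, abs=0.01)
        assert p_c + p_e == 1.0

    def test_bigaussian_passthrough(self):
        m = BiGaussianModel(22.0, 1.5, 0.68, 45.0, 8.0)
        assert extract_populations(m) == (0.68, pytest.approx(0.32))

    def test_all_density_below_split(self, grid):
        dist = BiGaussianModel(20.0, 1.0, 1.0, 25.0, 1.0).density(grid)
        p_c, p_e = extract_populations(dist, split=70.0)
        assert (p_c, p_e) == (1.0, 0.0)

    def test_unimodal_auto_raises(self, grid):
        dist = BiGaussianModel(30.0, 3.0, 1.0, 60.0, 3.0).density(grid)
        with pytest.raises(ValueError, match="unimodal"):
            extract_populations(dist, split="auto")

    def test_populations_sum_to_one_exactly(self, grid):
        rng = np.random.default_rng(3)
        for _ in range(10):
            dist = BiGaussianModel(rng.uniform(18, 30), rng.uniform(1, 3),
                                   rng.uniform(0.1, 0.9), rng.uniform(40, 60),
                                   rng.uniform(4, 10)).density(grid)
            p_c, p_e = extract_populations(dist, split=35.0)
            assert p_c + p_e == 1.0
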