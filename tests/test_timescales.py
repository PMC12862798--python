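"""Ensemble averaging, preprocessing, max-ent fitting, dynamical content."""

import numpy as np
import pytest

import contactdyn as cd
from contactdyn.timescales import (
    extension_level,
    find_peaks_log,
    gaussian_lowpass,
    log_resample,
    refine_linear,
    _weights,
)

from conftest import scaled_response_spec


def _series(values_list, dt=1.0, name=(1, 4)):
    out = []
    for i, v in enumerate(values_list):
        v = np.asarray(v, dtype=float)
        out.append(
            cd.DistanceSeries(
                contact=(cd.ResidueLabel(name[0]), cd.ResidueLabel(name[1])),
                trajectory_id=f"t{i}",
                times=np.arange(v.size) * dt,
                values=v,
            )
        )
    return out


class TestEnsembleAverage:
    def test_identical_trajectories_zero_sem(self):
        resp = cd.ensemble_average(_series([np.ones(5) * 2, np.ones(5) * 2]))
        np.testing.assert_allclose(resp.sem, 0.0)

    def test_two_point_mean_and_sem(self):
        resp = cd.ensemble_average(_series([[1.0, 1.0], [3.0, 3.0]]))
        assert resp.mean[0] == pytest.approx(2.0)
        assert resp.sem[0] == pytest.approx(1.0)  # std(ddof=1)/sqrt(2) = sqrt(2)/sqrt(2)

    def test_mixed_lengths_drop_n_traj(self):
        """Short runs end: the trajectory count per point drops accordingly."""
        short = [np.ones(10)] * 9
        long = [np.ones(100)] * 3
        resp = cd.ensemble_average(_series(short + long))
        assert resp.n_traj[0] == 12
        assert resp.n_traj[-1] == 3
        assert resp.n_traj[9] == 12 and resp.n_traj[10] == 3

    def test_single_trajectory_sem_zero(self):
        resp = cd.ensemble_average(_series([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(resp.sem, 0.0)

    def test_mixed_features_rejected(self):
        a = _series([[1.0, 2.0]])
        b = _series([[1.0, 2.0]], name=(2, 6))
        with pytest.raises(ValueError, match="mix"):
            cd.ensemble_average(a + b)


class TestTauGrid:
    def test_four_decades_at_ten_per_decade(self):
        grid = cd.build_tau_grid(1.0, 10_000.0, per_decade=10)
        assert grid.n == 41
        assert grid.taus[0] == pytest.approx(1.0)
        assert grid.taus[-1] == pytest.approx(10_000.0)

    def test_constant_ratio(self):
        grid = cd.build_tau_grid(0.1, 10_000.0, per_decade=10)
        np.testing.assert_allclose(grid.taus[1:] / grid.taus[:-1], 10**0.1, rtol=1e-12)

    def test_extension_decade(self):
        grid = cd.build_tau_grid(1.0, 100.0, per_decade=10, extend_decades=1)
        assert grid.taus[-1] == pytest.approx(1000.0)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            cd.build_tau_grid(10.0, 1.0)


class TestPreprocess:
    def test_constants_are_fixed_points(self):
        t = np.arange(60) * 0.5
        resp = cd.ResponseEnsemble("x", t, np.full(60, 1.7), np.zeros(60), np.full(60, 5))
        pre = cd.preprocess(resp)
        np.testing.assert_allclose(pre.mean, 1.7, rtol=1e-12)
        # and of a second application (already log-spaced constant data)
        pre2 = cd.preprocess(pre)
        np.testing.assert_allclose(pre2.mean, 1.7, rtol=1e-12)

    def test_interpolation_sample_count(self):
        """10 frames with factor 4 -> 9 gaps x 4 + 1 = 37 samples."""
        t_fine, v = refine_linear(np.arange(10.0), np.arange(10.0) ** 2, 4)
        assert t_fine.size == 37
        # linearity between original nodes
        assert v[2] == pytest.approx(0.5 * (0 + 1))

    def test_log_resample_density(self):
        t = np.linspace(0.1, 1000.0, 50_000)
        t_log, v = log_resample(t, np.ones_like(t), 750)
        assert t_log.size == pytest.approx(4 * 750 + 1, abs=2)
        ratios = t_log[1:] / t_log[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)

    def test_gaussian_filter_equals_direct_convolution(self):
        """Direct summation with a normalized sigma=6 kernel is the oracle."""
        rng = np.random.default_rng(0)
        v = np.exp(-np.arange(400) / 80.0) + 0.05 * rng.normal(size=400)
        sigma = 6.0
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        kernel = np.exp(-0.5 * (x / sigma) ** 2)
        kernel /= kernel.sum()
        padded = np.concatenate([np.full(radius, v[0]), v, np.full(radius, v[-1])])
        direct = np.array(
            [np.sum(padded[i : i + 2 * radius + 1] * kernel[::-1]) for i in range(v.size)]
        )
        np.testing.assert_allclose(gaussian_lowpass(v, sigma), direct, atol=1e-12)

    def test_extension_value_is_last_half_decade_mean(self):
        t = np.geomspace(1.0, 1000.0, 300)
        v = np.where(t >= 1000 / np.sqrt(10), 2.0, 5.0)
        assert extension_level(t, v) == pytest.approx(2.0)
        # full chain: the appended tail sits at the half-decade average
        tu = np.linspace(0.0, 1000.0, 2001)
        resp = cd.ResponseEnsemble(
            "x", tu, np.full(tu.size, 3.3), np.zeros(tu.size), np.ones(tu.size, dtype=int)
        )
        pre = cd.preprocess(resp)
        assert pre.times[-1] == pytest.approx(10_000.0, rel=1e-3)
        np.testing.assert_allclose(pre.mean[-100:], 3.3, rtol=1e-12)

    def test_too_few_frames_rejected(self):
        resp = cd.ResponseEnsemble("x", [0.0], [1.0], [0.0], [1])
        with pytest.raises(ValueError):
            cd.preprocess(resp)


class TestMaxEntFit:
    def test_single_exponential_recovery(self):
        """Noiseless on-grid decay: mass concentrates at the true tau."""
        grid = cd.build_tau_grid(2.0, 1000.0, per_decade=10)
        tau_true = grid.taus[14]
        t = np.geomspace(0.25, 2000.0, 3000)
        mean = np.exp(-t / tau_true)
        resp = cd.ResponseEnsemble("x", t, mean, np.zeros_like(t), np.ones_like(t, dtype=int))
        cfg = cd.MaxEntConfig(lam=1e-4, weight_mode="uniform", max_iter=50_000)
        spec = cd.maxent_fit(resp, grid, cfg)
        mass = np.abs(spec.amplitudes)
        near = np.abs(np.log10(grid.taus / tau_true)) <= 0.1 + 1e-9  # +/- one grid step
        assert mass[near].sum() / mass.sum() >= 0.9
        rms = np.sqrt(np.mean((spec.reconstruct(t) - mean) ** 2))
        assert rms < 0.01

    def test_flat_data_gives_empty_spectrum(self):
        grid = cd.build_tau_grid(2.0, 1000.0, per_decade=10)
        t = np.linspace(0.0, 2000.0, 500)
        resp = cd.ResponseEnsemble("x", t, np.full(t.size, 2.5), np.zeros_like(t), np.ones_like(t, dtype=int))
        cfg = cd.MaxEntConfig(entropy_prior=0.05)
        pre = cd.preprocess(resp, cfg)
        spec = cd.maxent_fit(pre, grid, cfg)
        assert np.all(np.abs(spec.amplitudes) <= 0.05 * 1e-2)
        assert spec.offset == pytest.approx(2.5, abs=1e-3)

    def test_rise_and_fall_two_component_scenario(self):
        """A distance that rises at ~30 ns and falls back at ~800 ns."""
        spec_gen = scaled_response_spec(components=((30.0, -0.3), (800.0, 0.25)))
        series, truth = cd.generate_response_ensemble(spec_gen, seed=2)
        resp = cd.ensemble_average(series)
        cfg = cd.MaxEntConfig()
        pre = cd.preprocess(resp, cfg)
        grid = cd.build_tau_grid(2.0, 10_000.0, per_decade=10)
        fit = cd.maxent_fit(pre, grid, cfg)
        peaks = find_peaks_log(grid.taus, np.abs(fit.amplitudes), 0.05)
        for tau_true, amp_true in truth["components"]:
            half_decade = [
                (t, h) for t, h in peaks if tau_true / 10**0.5 <= t <= tau_true * 10**0.5
            ]
            assert half_decade, f"no peak within half a decade of {tau_true} ns"
            k = np.argmin(np.abs(grid.taus - half_decade[0][0]))
            assert np.sign(fit.amplitudes[k]) == np.sign(amp_true)

    def test_objective_trace_monotone(self):
        spec_gen = scaled_response_spec()
        series, _ = cd.generate_response_ensemble(spec_gen, seed=0)
        resp = cd.ensemble_average(series)
        cfg = cd.MaxEntConfig()
        pre = cd.preprocess(resp, cfg)
        grid = cd.build_tau_grid(2.0, 10_000.0, per_decade=10)
        fit = cd.maxent_fit(pre, grid, cfg)
        trace = fit.objective_trace
        assert trace.size > 1
        assert np.all(np.diff(trace) <= 1e-10)

    def test_amplitude_linearity_under_data_scaling(self):
        """Scaling data and prior by c scales the amplitudes by c."""
        spec_gen = scaled_response_spec(noise_sd=0.0, n_traj=1, long_traj_fraction=1.0)
        series, _ = cd.generate_response_ensemble(spec_gen, seed=0)
        resp = cd.ensemble_average(series)
        grid = cd.build_tau_grid(2.0, 10_000.0, per_decade=10)
        base_cfg = cd.MaxEntConfig(lam=1.0, weight_mode="uniform", entropy_prior=0.05)
        pre = cd.preprocess(resp, base_cfg)
        ref = cd.maxent_fit(pre, grid, base_cfg)
        for c in (0.5, 2.0):
            scaled = cd.ResponseEnsemble(
                "x", pre.times, c * pre.mean, pre.sem, pre.n_traj
            )
            cfg_c = cd.MaxEntConfig(lam=1.0, weight_mode="uniform", entropy_prior=0.05 * c)
            fit_c = cd.maxent_fit(scaled, grid, cfg_c)
            np.testing.assert_allclose(fit_c.amplitudes, c * ref.amplitudes, atol=2e-4)

    def test_non_finite_data_rejected(self):
        grid = cd.build_tau_grid(1.0, 100.0)
        t = np.geomspace(1, 100, 50)
        m = np.ones(50)
        m[3] = np.nan
        resp = cd.ResponseEnsemble("x", t, np.ones(50), np.zeros(50), np.ones(50, dtype=int))
        resp.mean = m  # bypass constructor check to exercise the fit's own guard
        with pytest.raises(ValueError):
            cd.maxent_fit(resp, grid)


class TestDynamicalContent:
    def _spectrum(self, grid, amps, feature="1_4"):
        return cd.RelaxationSpectrum(
            feature=feature, grid=grid, amplitudes=amps, offset=0.0,
            chi2=0.0, entropy=0.0, lam=0.0, prior=1.0,
        )

    def test_single_term_hand_value(self):
        grid = cd.build_tau_grid(1.0, 100.0, per_decade=2)
        amps = np.zeros(grid.n)
        amps[2] = 2.0
        profile = cd.dynamical_content([self._spectrum(grid, amps)])
        assert profile.total[2] == pytest.approx(4.0)
        assert profile.total.sum() == pytest.approx(4.0)

    def test_decomposition_sums_to_total_exactly(self):
        grid = cd.build_tau_grid(1.0, 1000.0, per_decade=5)
        rng = np.random.default_rng(0)
        spectra = [
            self._spectrum(grid, rng.normal(size=grid.n), feature=f"f{j}") for j in range(9)
        ]
        partition = {f"f{j}": j % 3 for j in range(6)}  # f6..f8 unassigned -> noise
        profile = cd.dynamical_content(spectra, partition)
        summed = sum(profile.per_cluster.values())
        np.testing.assert_array_equal(summed, profile.total)

    def test_cluster_profiles_peak_at_planted_taus(self):
        grid = cd.build_tau_grid(1.0, 10_000.0, per_decade=10)
        planted = {"a": 10.0, "b": 200.0, "c": 3000.0}
        spectra, partition = [], {}
        for cid, tau in planted.items():
            k = np.argmin(np.abs(grid.taus - tau))
            for j in range(3):
                amps = np.zeros(grid.n)
                amps[k] = 1.0 + 0.1 * j
                name = f"{cid}{j}"
                spectra.append(self._spectrum(grid, amps, feature=name))
                partition[name] = cid
        profile = cd.dynamical_content(spectra, partition)
        for cid, tau in planted.items():
            peak_tau = grid.taus[np.argmax(profile.per_cluster[cid])]
            assert abs(np.log10(peak_tau / tau)) <= 0.5

    def test_mixed_grids_rejected(self):
        g1 = cd.build_tau_grid(1.0, 100.0, per_decade=2)
        g2 = cd.build_tau_grid(1.0, 1000.0, per_decade=2)
        with pytest.raises(ValueError):
            cd.dynamical_content(
                [self._spectrum(g1, np.zeros(g1.n)), self._spectrum(g2, np.zeros(g2.n))]
            )


class TestPowerLaw:
    def test_exact_alpha_half(self):
        t = np.geomspace(1.0, 1000.0, 300)
        resp = cd.ResponseEnsemble("x", t, t**0.5, np.zeros_like(t), np.ones_like(t, dtype=int))
        fit = cd.powerlaw_fit(resp, (1.0, 1000.0))
        assert fit.alpha == pytest.approx(0.5, abs=1e-6)

    def test_exact_alpha_and_prefactor(self):
        t = np.geomspace(1.0, 1000.0, 300)
        resp = cd.ResponseEnsemble("x", t, 3.0 * t**0.3, np.zeros_like(t), np.ones_like(t, dtype=int))
        fit = cd.powerlaw_fit(resp, (1.0, 1000.0))
        assert fit.alpha == pytest.approx(0.3, abs=1e-6)
        assert fit.prefactor == pytest.approx(3.0, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0)

    def test_noisy_replicates_recover_alpha(self):
        rng = np.random.default_rng(1)
        t = np.geomspace(10.0, 10_000.0, 400)
        alphas = []
        for _ in range(100):
            y = 2.0 * t**0.4
            y = y * (1 + 0.01 * rng.normal(size=t.size))
            resp = cd.ResponseEnsemble("x", t, y, np.zeros_like(t), np.ones_like(t, dtype=int))
            alphas.append(cd.powerlaw_fit(resp, (10.0, 10_000.0)).alpha)
        assert np.mean(alphas) == pytest.approx(0.4, abs=0.02)

    def test_window_validation(self):
        t = np.geomspace(1.0, 100.0, 100)
        resp = cd.ResponseEnsemble("x", t, t**0.5, np.zeros_like(t), np.ones_like(t, dtype=int))
        with pytest.raises(ValueError, match="decade"):
            cd.powerlaw_fit(resp, (10.0, 50.0))

    def test_nonpositive_values_name_the_mode(self):
        t = np.geomspace(1.0, 100.0, 100)
        resp = cd.ResponseEnsemble("x", t, t**0.5 - 5.0, np.zeros_like(t), np.ones_like(t, dtype=int))
        with pytest.raises(ValueError, match="raw"):
            cd.powerlaw_fit(resp, (1.0, 100.0), baseline="raw")


@pytest.fixture(scope="module")
def prepared():
    series, _ = cd.generate_response_ensemble(scaled_response_spec(), seed=3)
    resp = cd.ensemble_average(series)
    cfg = cd.MaxEntConfig()
    return cd.preprocess(resp, cfg), cfg


class TestLambdaScan:

    def test_chi2_monotone_in_lambda(self, prepared):
        pre, cfg = prepared
        grid = cd.build_tau_grid(2.0, 10_000.0, per_decade=10)
        rows = cd.lambda_scan(pre, grid, [50.0, 100.0, 200.0], cfg)
        chi2 = [r["chi2"] for r in rows]
        assert chi2[1] >= chi2[0] - 1e-12
        assert chi2[2] >= chi2[1] - 1e-12

    def test_lambda_to_zero_matches_least_squares(self, prepared):
        """Direct least squares on the same exponential basis is the oracle.

        Compared on a coarse (3/decade) grid where the unregularized
        problem is well conditioned and its minimum meaningful.
        """
        pre, _ = prepared
        cfg = cd.MaxEntConfig(lam=1e-9, weight_mode="uniform", max_iter=50_000)
        grid = cd.build_tau_grid(2.0, 10_000.0, per_decade=3)
        fit = cd.maxent_fit(pre, grid, cfg)
        A = np.column_stack(
            [np.exp(-np.outer(pre.times, 1.0 / grid.taus)), np.ones(pre.times.size)]
        )
        coef, *_ = np.linalg.lstsq(A, pre.mean, rcond=None)
        chi2_ls = float(np.mean((A @ coef - pre.mean) ** 2))
        assert fit.chi2 <= chi2_ls * 1.01

    def test_unsorted_lambdas_rejected(self, prepared):
        pre, cfg = prepared
        grid = cd.build_tau_grid(2.0, 10_000.0, per_decade=5)
        with pytest.raises(ValueError):
            cd.lambda_scan(pre, grid, [100.0, 50.0], cfg)
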