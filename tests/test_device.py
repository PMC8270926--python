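"""Device-curve fitting, variability model, and modulator tests."""

import numpy as np
import pytest

from dexat.device import (
    ConductanceTrace,
    DEXATFit,
    ModulatorParams,
    asymmetric_nonlinearity,
    degrade_adaptive_params,
    double_exponential,
    endurance_window,
    extract_variability,
    fit_dexat,
    inject_neuron_variability,
    modulator_behavioral_sim,
    preprocess_ltd,
    read_trace_csv,
    simulate_variability,
    synthetic_ltd_trace,
    synthetic_ltp_trace,
    write_trace_csv,
)
from dexat.neurons import DEXATParams, LIFParams
from dexat.network import simulate


class TestPreprocess:
    def test_two_point_trace_is_straight_line(self):
        tr = ConductanceTrace(x=[0.0, 1.0], g=[1e-3, 1e-5], direction="LTD")
        t, y = preprocess_ltd(tr, delta_t=0.25)
        np.testing.assert_allclose(y, np.linspace(1.0, 0.0, 5), atol=1e-12)

    def test_normalization_bounds_and_idempotence(self):
        tr = synthetic_ltd_trace(n_pulses=30)
        t, y = preprocess_ltd(tr, delta_t=5.0)
        assert y.min() == 0.0 and y.max() == 1.0
        # feeding the output back through changes nothing
        tr2 = ConductanceTrace(x=t, g=y + 1e-6, direction="LTD")
        t2, y2 = preprocess_ltd(tr2, delta_t=5.0)
        np.testing.assert_allclose(y2, y, atol=1e-9)

    def test_upsample_exact_at_knots(self):
        # linear interpolation reproduces the sampled values at the knots
        tr = synthetic_ltd_trace(n_pulses=20, pulse_duration=20.0)
        t, y = preprocess_ltd(tr, delta_t=5.0, pulse_duration=20.0)
        g = tr.g
        norm = (g - g.min()) / (g.max() - g.min())
        knots = (np.arange(20) * 20 / 5).astype(int)
        np.testing.assert_allclose(y[knots], norm, atol=1e-12)

    def test_constant_trace_rejected(self):
        tr = ConductanceTrace(x=[0, 1, 2], g=[1.0, 1.0, 1.0], direction="LTD")
        with pytest.raises(ValueError, match="constant"):
            preprocess_ltd(tr, delta_t=0.5)


class TestFitDexat:
    def test_noiseless_parameter_recovery(self):
        t = np.arange(0.0, 1200.0, 1.0)
        y = double_exponential(t, 30.0, 300.0, 0.5, 0.5)
        fit = fit_dexat(t, y)
        assert fit.converged
        assert fit.tau_a1 == pytest.approx(30.0, rel=0.01)
        assert fit.tau_a2 == pytest.approx(300.0, rel=0.01)
        assert fit.beta1 == pytest.approx(0.5, rel=0.01)
        assert fit.beta2 == pytest.approx(0.5, rel=0.01)

    def test_single_exponential_collapses(self):
        t = np.arange(0.0, 600.0, 1.0)
        y = double_exponential(t, 100.0, 100.0, 0.0, 1.0)
        fit = fit_dexat(t, y)
        # degenerate input: either one amplitude vanishes or the taus merge
        assert (min(fit.beta1, fit.beta2) < 0.02
                or fit.tau_a2 / fit.tau_a1 < 1.5)
        assert fit.goodness < 1e-4

    def test_roundtrip_within_reported_residual(self):
        tr = synthetic_ltd_trace(noise=0.02, seed=4)
        t, y = preprocess_ltd(tr, delta_t=5.0, pulse_duration=20.0)
        fit = fit_dexat(t, y)
        resid = np.linalg.norm(fit.curve(t) - y)
        assert resid <= fit.goodness * (1 + 1e-9)

    def test_increasing_curve_rejected(self):
        t = np.arange(100.0)
        with pytest.raises(ValueError, match="decreasing"):
            fit_dexat(t, t / 100.0)

    def test_neuron_params_handoff(self, tmp_path):
        fit = DEXATFit(tau_a1=30.0, tau_a2=300.0, beta1=0.5, beta2=0.5,
                       baseline=0.0, goodness=0.0)
        p = fit.to_neuron_params(LIFParams(delta_t=1.0))
        # a single spike must reproduce the fitted amplitudes
        assert p.beta1 * (1 - p.rho1) == pytest.approx(0.5)
        assert p.beta2 * (1 - p.rho2) == pytest.approx(0.5)
        fit.to_yaml(tmp_path / "fit.yaml")
        assert DEXATFit.from_yaml(tmp_path / "fit.yaml") == fit


class TestANL:
    def test_mirrored_pair_is_symmetric_zero(self):
        ltd = synthetic_ltd_trace()
        ltp = synthetic_ltp_trace(mirror_of=ltd)
        d = preprocess_ltd(ltd, delta_t=5.0, pulse_duration=20.0)
        tr_p = ConductanceTrace(x=ltp.x, g=ltp.g[::-1], direction="LTD")
        p = preprocess_ltd(tr_p, delta_t=5.0, pulse_duration=20.0)
        p = (p[0], p[1][::-1])  # undo the flip: normalized rising curve
        assert asymmetric_nonlinearity(p, d) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_perturbation(self):
        ltd = synthetic_ltd_trace()
        t, y = preprocess_ltd(ltd, delta_t=5.0, pulse_duration=20.0)
        vals = []
        for eps in (0.0, 0.05, 0.1, 0.2):
            y_p = np.clip(y[::-1] + eps * np.sin(np.linspace(0, 3, y.size)), 0, 1)
            vals.append(asymmetric_nonlinearity((t, y_p), (t, y)))
        assert vals == sorted(vals)

    def test_bounded_on_random_pairs(self, rng):
        for _ in range(20):
            a = np.sort(rng.random(30))[::-1]
            b = np.sort(rng.random(25))
            a = (a - a.min()) / np.ptp(a)
            b = (b - b.min()) / np.ptp(b)
            v = asymmetric_nonlinearity((np.arange(25.0), b), (np.arange(30.0), a))
            assert 0.0 <= v <= 1.0


class TestVariability:
    def test_identical_traces_give_zero(self):
        mu = np.linspace(1.0, 0.3, 50)
        prof = extract_variability(np.tile(mu, (10, 1)))
        assert prof.eta_r == pytest.approx(0.0, abs=1e-12)

    def test_sigma_matches_two_pass_oracle(self, rng):
        traces = 1.0 + 0.1 * rng.standard_normal((20, 30))
        prof = extract_variability(traces)
        for i in range(30):
            col = traces[:, i]
            mean = col.sum() / 20
            var = ((col - mean) ** 2).sum() / 19
            assert prof.sigma[i] == pytest.approx(np.sqrt(var), rel=1e-12)
            assert prof.eta[i] == pytest.approx(np.sqrt(var) / mean, rel=1e-12)

    def test_roundtrip_recovers_eta_r(self):
        # consistency loop: simulate at eta_r = 0.30, extract within 5%
        mu = 0.3 + 0.9 * np.exp(-np.arange(200) / 60.0)
        traces = simulate_variability(mu, eta_r=0.30, n=100, seed=2)
        prof = extract_variability(traces)
        assert prof.eta_r == pytest.approx(0.30, rel=0.05)

    def test_zero_eta_reproduces_mu_exactly(self):
        mu = np.linspace(1.0, 0.2, 40)
        traces = simulate_variability(mu, eta_r=0.0, n=5, seed=0)
        assert np.array_equal(traces, np.tile(mu, (5, 1)))

    def test_sample_moments_recover_inputs(self):
        mu = np.full(20, 0.8)
        n = 10_000
        traces = simulate_variability(mu, eta_r=0.2, n=n, seed=1)
        # CLT: per-timestep sample mean within 3 sigma/sqrt(n)
        assert np.all(np.abs(traces.mean(0) - 0.8) < 3 * 0.16 / np.sqrt(n))
        cv = traces.std(0, ddof=1) / traces.mean(0)
        assert np.median(cv) == pytest.approx(0.2, rel=0.05)

    def test_requires_multiple_traces_and_nonzero_mean(self):
        with pytest.raises(ValueError):
            extract_variability(np.ones((1, 10)))
        bad = np.vstack([np.ones(5), -np.ones(5)])
        with pytest.raises(ValueError, match="nonzero"):
            extract_variability(bad)


class TestInjection:
    def test_zero_eta_matches_noiseless_simulation(self, small_config,
                                                   small_weights, rng):
        x = (rng.random((60, small_config.n_input)) < 0.3).astype(float)
        clean = simulate(small_config, small_weights, x)
        noisy = inject_neuron_variability(small_config, small_weights, x,
                                          eta_r=0.0, seed=3)
        assert np.array_equal(clean.spikes, noisy.spikes)
        np.testing.assert_array_equal(clean.thresholds, noisy.thresholds)

    def test_fixed_seed_is_reproducible(self, small_config, small_weights, rng):
        x = (rng.random((60, small_config.n_input)) < 0.3).astype(float)
        a = inject_neuron_variability(small_config, small_weights, x, 0.3, seed=5)
        b = inject_neuron_variability(small_config, small_weights, x, 0.3, seed=5)
        assert np.array_equal(a.spikes, b.spikes)
        c = inject_neuron_variability(small_config, small_weights, x, 0.3, seed=6)
        assert not np.array_equal(a.thresholds, c.thresholds)

    def test_noise_only_touches_adaptive_thresholds(self, small_config,
                                                    small_weights, rng):
        x = (rng.random((40, small_config.n_input)) < 0.3).astype(float)
        noisy = inject_neuron_variability(small_config, small_weights, x,
                                          eta_r=0.2, seed=1)
        clean = simulate(small_config, small_weights, x)
        assert not np.array_equal(noisy.thresholds, clean.thresholds)
        # perturbed thresholds stay above the clip floor
        assert noisy.thresholds.min() >= 0.01 * small_config.adaptive.b_j0 - 1e-12


class TestModulator:
    def test_no_spikes_flat_at_baseline(self):
        t, v = modulator_behavioral_sim(np.array([]), t_end=200.0)
        assert np.allclose(v, v[0])

    def test_shorter_interval_raises_second_peak(self):
        # adaptation coupling: a quick second spike meets a weaker HRS and
        # reaches a higher threshold peak
        p = ModulatorParams()
        _, v_short = modulator_behavioral_sim(np.array([50.0, 80.0]), p,
                                              t_end=400.0)
        _, v_long = modulator_behavioral_sim(np.array([50.0, 650.0]), p,
                                             t_end=1000.0)
        peak_short = v_short[81:200].max()
        peak_long = v_long[651:800].max()
        assert peak_short > peak_long

    def test_default_peak_to_floor_ratio_is_five(self):
        p = ModulatorParams()
        ratio = p.v_th(np.array([p.g_max]))[0] / p.v_th(np.array([p.g_min]))[0]
        assert ratio == pytest.approx(5.0, rel=1e-6)

    def test_unsorted_spikes_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            modulator_behavioral_sim(np.array([10.0, 5.0]))


class TestEndurance:
    def test_window_monotone_in_cycles(self):
        for mode in ("linear", "exponential"):
            w = [endurance_window(c, mode=mode, rate=1e-5) for c in
                 (0, 1e4, 1e5, 1e6)]
            assert w[0] == 1.0
            assert all(a >= b for a, b in zip(w, w[1:]))
            assert w[-1] >= 0.1

    def test_degradation_shrinks_threshold_dynamic_range(self, lif):
        p = DEXATParams(lif=lif)
        ranges = []
        for w in (1.0, 0.7, 0.4, 0.1):
            q = degrade_adaptive_params(p, w)
            # dynamic range of the threshold transient after one spike
            jump = (q.beta1 * (1 - q.rho1) + q.beta2 * (1 - q.rho2)) / lif.delta_t
            ranges.append(jump)
        assert all(a > b for a, b in zip(ranges, ranges[1:]))


def test_trace_csv_roundtrip(tmp_path):
    tr = synthetic_ltd_trace(n_pulses=15, noise=0.03, seed=9)
    path = tmp_path / "ltd.csv"
    write_trace_csv(tr, path)
    back = read_trace_csv(path, direction="LTD")
    np.testing.assert_allclose(back.x, tr.x)
    np.testing.assert_allclose(back.g, tr.g)
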