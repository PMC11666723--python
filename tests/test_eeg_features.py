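import numpy as np
import pytest
from scipy import signal as sps

from uapipe import eeg_features as ef
from uapipe.errors import ConfigurationError
from uapipe.task_synth import (EffectConfig, EpochedSignal, GroupEffects,
                               _aperiodic_noise, generate_session_design,
                               simulate_eeg)


def make_epochs(data, srate=250.0, t0=-1.0, channels=None, alignment="stimulus"):
    data = np.asarray(data, dtype=float)
    channels = channels or [f"ch{i}" for i in range(data.shape[0])]
    times = t0 + np.arange(data.shape[1]) / srate
    return EpochedSignal(data=data, srate=srate, times=times,
                         alignment=alignment, channels=channels)


# ---------------------------------------------------------------------------
# brute-force sample-entropy oracle (independent triple-loop implementation)
# ---------------------------------------------------------------------------

def brute_force_counts(segments, m, r):
    templates = []
    for seg in segments:
        seg = np.asarray(seg, float)
        for i in range(len(seg) - m):
            templates.append(seg[i:i + m + 1])
    a = b = 0
    for i in range(len(templates)):
        for j in range(i + 1, len(templates)):
            ti, tj = templates[i], templates[j]
            if max(abs(ti[k] - tj[k]) for k in range(m)) <= r:
                b += 1
                if abs(ti[m] - tj[m]) <= r:
                    a += 1
    return a, b


class TestMorletPower:
    def test_pure_sinusoid_peak_frequency(self):
        t = np.arange(0, 4, 1 / 250)
        sig = np.sin(2 * np.pi * 10 * t)
        epochs = make_epochs(np.tile(sig[None, :, None], (3, 1, 2)), t0=0.0)
        tf = ef.morlet_power(epochs, np.arange(2, 16), log_transform=False)
        mid = tf.power.shape[2] // 2
        assert (tf.freqs[np.argmax(tf.power[:, :, mid], axis=1)] == 10).all()

    def test_amplitude_doubling_quadruples_power(self):
        t = np.arange(0, 4, 1 / 250)
        base = np.sin(2 * np.pi * 8 * t)
        e1 = make_epochs(base[None, :, None], t0=0.0)
        e2 = make_epochs(2 * base[None, :, None], t0=0.0)
        p1 = ef.morlet_power(e1, np.array([8.0]), log_transform=False)
        p2 = ef.morlet_power(e2, np.array([8.0]), log_transform=False)
        mid = p1.power.shape[2] // 2
        assert p2.power[0, 0, mid] == pytest.approx(4 * p1.power[0, 0, mid], rel=1e-6)

    def test_chirp_ridge_tracks_instantaneous_frequency(self):
        srate = 250.0
        t = np.arange(0, 8, 1 / srate)
        f0, f1 = 4.0, 14.0
        sig = sps.chirp(t, f0=f0, t1=t[-1], f1=f1)
        epochs = make_epochs(sig[None, :, None], srate=srate, t0=0.0)
        tf = ef.morlet_power(epochs, np.arange(2, 17, 0.5), log_transform=False)
        inst = f0 + (f1 - f0) * tf.times / t[-1]
        sel = tf.valid.all(axis=0)
        ridge = tf.freqs[np.argmax(tf.power[0][:, sel], axis=0)]
        assert np.max(np.abs(ridge - inst[sel])) <= 1.0

    def test_log_transform_applied_per_trial(self):
        rng = np.random.default_rng(0)
        data = np.exp(rng.standard_normal((1, 1000, 8)))
        epochs = make_epochs(data, t0=0.0)
        lin = ef.morlet_power(epochs, np.array([10.0]), log_transform=False,
                              average=False)
        log = ef.morlet_power(epochs, np.array([10.0]), log_transform=True)
        # mean of per-trial logs, not log of mean power
        assert np.allclose(log.power, np.log10(lin.power).mean(axis=3))

    def test_nyquist_guard(self):
        epochs = make_epochs(np.zeros((1, 500, 1)))
        with pytest.raises(ConfigurationError):
            ef.morlet_power(epochs, np.array([200.0]))

    def test_parseval_monotonicity(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((2, 1000, 4))
        freqs = np.arange(4, 20, 2.0)
        p_small = ef.morlet_power(make_epochs(base), freqs, log_transform=False)
        p_big = ef.morlet_power(make_epochs(3 * base), freqs, log_transform=False)
        assert p_big.power.sum() > p_small.power.sum()


class TestCppSlope:
    def test_linear_ramp_exact(self):
        srate = 250.0
        times = np.arange(-1.0, 0.5, 1 / srate)
        k = 7.5
        data = np.tile(k * times, (2, 1))[:, :, None]
        epochs = make_epochs(data, t0=-1.0, alignment="response")
        est = ef.cpp_slope(epochs, channels=("ch0", "ch1"), lowpass=None)
        assert est.value == pytest.approx(k, rel=1e-9)

    def test_flat_trace(self):
        data = np.full((2, 375, 3), 1.25)
        epochs = make_epochs(data, t0=-1.0, alignment="response")
        est = ef.cpp_slope(epochs, channels=("ch0", "ch1"), lowpass=None)
        assert est.value == pytest.approx(0.0, abs=1e-12)
        assert est.threshold == pytest.approx(1.25)

    def test_window_outside_epoch_raises(self):
        epochs = make_epochs(np.zeros((1, 100, 1)), t0=-0.2)
        with pytest.raises(ConfigurationError, match="outside epoch"):
            ef.cpp_slope(epochs, channels=("ch0",), slope_window=(-1.0, -0.5),
                         lowpass=None)

    def test_planted_load_ordering(self, effects):
        design = generate_session_design(n_runs=1, seed=12)
        out = simulate_eeg(design, effects, seed=12, group="young")
        resp = out["response"]
        loads = resp.trial_info["load"].to_numpy()
        slopes = []
        for load in (1, 2, 3, 4):
            sel = loads == load
            sub = EpochedSignal(resp.data[:, :, sel], srate=resp.srate,
                                times=resp.times, alignment="response",
                                channels=resp.channels)
            slopes.append(ef.cpp_slope(sub).value)
        # planted: 18 - 3*(load-1), decreasing
        assert all(a > b for a, b in zip(slopes, slopes[1:]))
        ge = effects.group("young")
        for load, s in zip((1, 2, 3, 4), slopes):
            assert s == pytest.approx(ge.at_load("cpp_slope", load), abs=2.0)


class TestMuBeta:
    def test_planted_lateralization(self, effects):
        design = generate_session_design(n_runs=1, seed=13)
        out = simulate_eeg(design, effects, seed=13, group="young")
        resp = out["response"]
        est, curves = ef.mubeta_slope(resp, resp.trial_info["response_side"].to_numpy())
        pre = curves["times"] < -0.2
        assert curves["contra"][pre].mean() < curves["ipsi"][pre].mean()

    def test_no_lateralization_null(self):
        rng = np.random.default_rng(3)
        t = np.arange(-1.0, 0.5, 1 / 250)
        wave = np.sin(2 * np.pi * 20 * t)
        data = wave[None, :, None] + 0.1 * rng.standard_normal((4, t.size, 40))
        epochs = make_epochs(data, t0=-1.0, channels=["C3", "CP3", "C4", "CP4"],
                             alignment="response")
        sides = np.array(["left", "right"] * 20)
        _, curves = ef.mubeta_slope(epochs, sides)
        diff = curves["contra"] - curves["ipsi"]
        assert abs(diff.mean()) < 0.05 * curves["ipsi"].mean()

    def test_missing_side_dropped_with_warning(self):
        data = np.random.default_rng(0).standard_normal((4, 375, 6))
        epochs = make_epochs(data, t0=-1.0, channels=["C3", "CP3", "C4", "CP4"],
                             alignment="response")
        sides = np.array(["left", "right", None, "left", "right", None])
        with pytest.warns(UserWarning, match="missing response side"):
            ef.mubeta_slope(epochs, sides)


class TestSSVEP:
    def _epochs(self, extra=None, srate=250.0, n_trials=8, amp30=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(-1.0, 3.0, 1 / srate)
        data = np.zeros((2, t.size, n_trials))
        if amp30:
            data += amp30 * np.sin(2 * np.pi * 30 * t)[None, :, None]
        if extra is not None:
            data += extra(rng, t, n_trials)
        return make_epochs(data, srate=srate, t0=-1.0)

    def test_pure_entrained_component_positive(self):
        epochs = self._epochs(amp30=2.0)
        times, val = ef.ssvep_amplitude(epochs, baseline=None)
        assert val.mean() > 0

    def test_flat_broadband_cancels(self):
        def white(rng, t, n):
            return rng.standard_normal((2, t.size, n))
        epochs = self._epochs(extra=white, n_trials=30)
        times, val = ef.ssvep_amplitude(epochs, baseline=None)
        # sideband subtraction removes the flat background
        def pow30(rng_=None):
            return None
        raw = self._epochs(amp30=2.0)
        _, ref = ef.ssvep_amplitude(raw, baseline=None)
        assert abs(val.mean()) < 0.05 * ref.mean()

    def test_one_over_f_background_cancels(self):
        def pink(rng, t, n):
            out = np.empty((2, t.size, n))
            for c in range(2):
                for i in range(n):
                    out[c, :, i] = _aperiodic_noise(rng, t.size, 250.0, 1.5)
            return out
        epochs = self._epochs(extra=pink, n_trials=30)
        _, val = ef.ssvep_amplitude(epochs, baseline=None)
        raw = self._epochs(amp30=1.0)
        _, ref = ef.ssvep_amplitude(raw, baseline=None)
        assert abs(val.mean()) < 0.1 * ref.mean()

    def test_sideband_outside_nyquist_raises(self):
        epochs = self._epochs(amp30=1.0)
        with pytest.raises(ConfigurationError):
            ef.ssvep_amplitude(epochs, f0=124.0, sidebands=(122.0, 126.0))


class TestSampleEntropy:
    def test_alternating_sequence_zero_entropy(self):
        seq = np.tile([1.0, -1.0], 150)
        epochs = make_epochs(seq[None, :, None], t0=0.0)
        out = ef.sample_entropy_timeresolved(epochs, r=0.1, alpha_notch=None,
                                             window=0.5, step=0.5)
        assert not out.undefined.all()
        assert np.nanmax(np.abs(out.entropy)) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_counts_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        segments = [rng.standard_normal(rng.integers(20, 60))
                    for _ in range(rng.integers(2, 5))]
        r = 0.5 * np.concatenate(segments).std()
        a, b = ef.sample_entropy_counts(segments, 2, r)
        a2, b2 = brute_force_counts(segments, 2, r)
        assert (a, b) == (a2, b2)

    def test_noise_more_irregular_than_sinusoid(self):
        rng = np.random.default_rng(4)
        t = np.arange(0, 2, 1 / 250)
        sine = np.sqrt(2) * np.sin(2 * np.pi * 5 * t)
        noise = rng.standard_normal(t.size)
        e_sine = ef.sample_entropy_timeresolved(
            make_epochs(sine[None, :, None], t0=0.0), alpha_notch=None,
            window=1.0, step=1.0)
        e_noise = ef.sample_entropy_timeresolved(
            make_epochs(noise[None, :, None], t0=0.0), alpha_notch=None,
            window=1.0, step=1.0)
        assert np.nanmean(e_noise.entropy) > np.nanmean(e_sine.entropy)

    def test_constant_input_flagged_undefined(self):
        epochs = make_epochs(np.ones((1, 500, 2)), t0=0.0)
        out = ef.sample_entropy_timeresolved(epochs, alpha_notch=None)
        assert out.undefined.all()
        assert np.isnan(out.entropy).all()

    def test_pooled_across_trials(self):
        # two trials each too short alone for many matches still give counts
        rng = np.random.default_rng(5)
        data = rng.standard_normal((1, 130, 4))
        epochs = make_epochs(data, t0=0.0)
        out = ef.sample_entropy_timeresolved(epochs, alpha_notch=None,
                                             window=0.5, step=0.5)
        assert np.isfinite(out.entropy).any()


class TestAperiodicFit:
    def test_exact_power_law(self):
        freqs = np.arange(2, 80.5, 0.5)
        psd = 10.0 * freqs ** -2.0
        fit = ef.aperiodic_fit(freqs, psd)
        assert fit.exponent == pytest.approx(2.0, abs=0.01)
        assert fit.offset == pytest.approx(1.0, abs=0.01)

    def test_power_law_plus_peak(self):
        freqs = np.arange(2, 80.5, 0.5)
        psd = freqs ** -1.5 + 0.5 * np.exp(-((freqs - 10) ** 2) / (2 * 1.5 ** 2))
        fit = ef.aperiodic_fit(freqs, psd)
        assert fit.exponent == pytest.approx(1.5, abs=0.05)
        assert any(abs(p["center"] - 10) < 2 for p in fit.peaks)

    def test_white_noise_flat(self):
        rng = np.random.default_rng(6)
        sig = rng.standard_normal((30, 1000))
        freqs, psd = ef.spectral_psd(sig, 250.0)
        fit = ef.aperiodic_fit(freqs, psd)
        assert abs(fit.exponent) < 0.05

    @pytest.mark.parametrize("expo", [0.5, 1.0, 1.5, 2.0, 2.5])
    def test_recovery_grid_with_peaks(self, expo):
        rng = np.random.default_rng(int(expo * 10))
        t = np.arange(1000) / 250.0
        sigs = np.stack([_aperiodic_noise(rng, 1000, 250.0, expo)
                         for _ in range(40)])
        sigs += np.sin(2 * np.pi * 10 * t)[None, :]
        freqs, psd = ef.spectral_psd(sigs, 250.0)
        fit = ef.aperiodic_fit(freqs, psd)
        assert fit.exponent == pytest.approx(expo, abs=0.05)

    def test_negative_psd_rejected(self):
        with pytest.raises(ConfigurationError):
            ef.aperiodic_fit(np.arange(2, 40, 0.5), -np.ones(76))

    def test_too_few_points_raises(self):
        freqs = np.arange(2, 5.5, 0.5)
        with pytest.raises(ConfigurationError):
            ef.aperiodic_fit(freqs, freqs ** -1.0)


class TestFilterContract:
    def test_zero_phase_symmetry(self):
        # a symmetric input stays symmetric under the zero-phase low-pass
        n = 501
        x = np.exp(-((np.arange(n) - n // 2) ** 2) / 200.0)
        y = ef._zero_phase_lowpass(x[None, :], 250.0, 8.0)[0]
        assert np.allclose(y, y[::-1], atol=1e-10)
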