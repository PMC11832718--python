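"""Complex demodulation, AM/ITPC profiles, band power, topography, ERSP."""

import numpy as np
import pytest

import assr_entrain as ae
from assr_entrain.demod import (DemodSettings, DemodulatedEpochs,
                                amplitude_modulation, assr_bandpower,
                                complex_demodulate, ersp, ersp_image, itpc,
                                modulation_profile, topography_40hz)
from assr_entrain.mcgf import McgfParams, mcgf_eval
from assr_entrain.preprocess import EpochedData


def make_component(data, fs=250.0):
    data = np.asarray(data, float)
    if data.ndim == 2:
        data = data[:, None, :]
    return EpochedData(data=data, fs=fs, t0_index=250, window=(-1.0, 6.0),
                       baseline_window=(-0.5, -0.25), channel_labels=("RESS",))


def make_demod(data, fs=250.0):
    n = np.asarray(data).shape[-1]
    t = (np.arange(n) - n // 7) / fs
    return DemodulatedEpochs(data=np.asarray(data, complex), times=t, fs=fs,
                             baseline_window=(t[0], t[n // 14]))


TIMES = (np.arange(1750) - 250) / 250.0


class TestComplexDemodulate:
    def test_constant_envelope_amplitude_and_phase(self):
        a, phi0 = 2.0, np.pi / 4
        x = a * np.cos(2 * np.pi * 40 * TIMES + phi0)
        dm = complex_demodulate(make_component(x[None, :]))
        mid = slice(500, 1250)
        amp = 2 * np.abs(dm.data[0, mid])
        assert amp.min() > 1.98 and amp.max() < 2.02
        phases = np.angle(dm.data[0, mid])
        assert np.max(np.abs(phases - phi0)) < 0.02

    def test_zero_in_zero_out(self):
        dm = complex_demodulate(make_component(np.zeros((3, 1750))))
        assert np.all(dm.data == 0.0)

    def test_out_of_band_tone_rejected(self):
        # 38 Hz shifts to 2 Hz, the lowpass stopband edge: strongly attenuated
        x = np.cos(2 * np.pi * 38.0 * TIMES)
        dm = complex_demodulate(make_component(x[None, :]))
        mid = slice(500, 1250)
        assert np.max(2 * np.abs(dm.data[0, mid])) < 0.1

    def test_envelope_consistency_for_mcgf_signal(self):
        # the recovered envelope tracks the true MCGF envelope to within 5%
        # of its peak away from the epoch edges
        for mu in (0.3, 0.6):
            p = McgfParams(A=1.0, d=1.0, mu=mu, sigma=0.15, alpha=0.1)
            env = np.where(TIMES >= 0, mcgf_eval(TIMES, p), 0.0)
            x = env * np.cos(2 * np.pi * 40 * TIMES + 0.3)
            dm = complex_demodulate(make_component(x[None, :]))
            est = 2 * np.abs(dm.data[0])
            mask = (TIMES > -0.5) & (TIMES < 5.496)
            err = np.max(np.abs(est[mask] - env[mask])) / env.max()
            assert err < 0.05

    def test_nyquist_validation(self):
        comp = make_component(np.zeros((1, 175)), fs=50.0)
        with pytest.raises(ValueError):
            complex_demodulate(comp, DemodSettings())


class TestAmplitudeModulation:
    def test_constant_envelope_self_subtracts(self):
        dm = make_demod(np.full((4, 1400), 0.5 + 0.0j))
        am, baseline = amplitude_modulation(dm)
        np.testing.assert_allclose(am, 0.0, atol=1e-12)
        assert baseline == pytest.approx(1.0)

    def test_step_envelope_recovers_amplitude(self):
        data = np.zeros((4, 1400), complex)
        data[:, 400:] = 1.5 / 2  # envelope a = 1.5 outside the baseline
        am, _ = amplitude_modulation(make_demod(data))
        assert am[800] == pytest.approx(1.5)

    def test_trial_mean_of_envelopes(self):
        a_k = np.array([0.5, 1.0, 2.0, 4.0])
        data = (a_k[:, None] / 2) * np.ones((4, 1400))
        dm = make_demod(data.astype(complex))
        pre = amplitude_modulation(dm)[0] + amplitude_modulation(dm)[1]
        np.testing.assert_allclose(pre, a_k.mean(), rtol=1e-12)

    def test_positive_before_baseline_subtraction(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal((10, 1400)) + 1j * rng.standard_normal((10, 1400))
        am, baseline = amplitude_modulation(make_demod(z))
        assert np.all(am + baseline >= 0.0)


class TestItpc:
    def test_identical_phases_give_unity(self):
        z = np.exp(1j * 0.7) * np.ones((40, 1400)) * 0.3
        pre = itpc(make_demod(z))[0] + itpc(make_demod(z))[1]
        np.testing.assert_allclose(pre, 1.0, atol=1e-12)

    def test_antiphase_pair_gives_zero(self):
        z = np.stack([np.ones(1400), -np.ones(1400)]).astype(complex)
        pre = itpc(make_demod(z))[0] + itpc(make_demod(z))[1]
        np.testing.assert_allclose(pre, 0.0, atol=1e-12)

    def test_uniform_phases_match_rayleigh_mean(self):
        # resultant length of K uniform phasors has mean ~ sqrt(pi / (4 K))
        K, reps = 40, 10_000
        rng = np.random.default_rng(1)
        phases = rng.uniform(0, 2 * np.pi, size=(reps, K))
        resultant = np.abs(np.exp(1j * phases).mean(axis=1))
        expected = np.sqrt(np.pi / (4 * K))
        se = resultant.std(ddof=1) / np.sqrt(reps)
        assert abs(resultant.mean() - expected) < 2 * se + 1e-3

    def test_bounded_for_arbitrary_inputs(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            z = rng.standard_normal((8, 200)) + 1j * rng.standard_normal((8, 200))
            series, baseline = itpc(make_demod(z))
            pre = series + baseline
            valid = np.isfinite(pre)
            assert np.all(pre[valid] >= -1e-12) and np.all(pre[valid] <= 1 + 1e-12)

    def test_zero_modulus_samples_flagged_missing(self):
        z = np.ones((3, 1400), complex)
        z[:, 700] = 0.0
        series, _ = itpc(make_demod(z))
        assert np.isnan(series[700])
        assert np.isfinite(series[600])

    def test_needs_two_trials(self):
        with pytest.raises(ValueError):
            itpc(make_demod(np.ones((1, 1400), complex)))


class TestBandpowerAndTopography:
    def test_sine_power_parseval(self):
        for a in (1.0, 2.0):
            x = a * np.sin(2 * np.pi * 40 * TIMES)
            p = assr_bandpower(make_component(x[None, :]))
            assert p == pytest.approx(a**2 / 2, rel=0.02)

    def test_out_of_band_noise_ignored(self):
        rng = np.random.default_rng(3)
        x = np.sin(2 * np.pi * 40 * TIMES)
        interference = (0.8 * np.sin(2 * np.pi * 10 * TIMES + 1.0)
                        + 0.5 * np.sin(2 * np.pi * 60 * TIMES))
        p = assr_bandpower(make_component((x + interference)[None, :]))
        assert p == pytest.approx(0.5, rel=0.05)

    def test_topography_localizes_source(self):
        data = np.zeros((3, 4, 1750))
        data[:, 2, :] = np.sin(2 * np.pi * 40 * TIMES)
        ep = EpochedData(data=data, fs=250.0, t0_index=250, window=(-1, 6),
                         baseline_window=(-0.5, -0.25),
                         channel_labels=("a", "b", "c", "d"))
        topo = topography_40hz(ep)
        assert np.argmax(topo.value) == 2
        assert topo.value[2] > 100 * max(topo.value[0], 1e-15)

    def test_topography_equivariant_under_channel_permutation(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((3, 4, 1750))
        ep = EpochedData(data=data, fs=250.0, t0_index=250, window=(-1, 6),
                         baseline_window=(-0.5, -0.25),
                         channel_labels=("a", "b", "c", "d"))
        perm = [2, 0, 3, 1]
        ep_perm = EpochedData(data=data[:, perm, :], fs=250.0, t0_index=250,
                              window=(-1, 6), baseline_window=(-0.5, -0.25),
                              channel_labels=tuple("cadb"))
        np.testing.assert_allclose(topography_40hz(ep_perm).value,
                                   topography_40hz(ep).value[perm], rtol=1e-12)

    def test_diffuse_profile_spreads_power(self, timeline):
        def gini(v):
            v = np.sort(v)
            n = v.size
            return (2 * np.arange(1, n + 1) - n - 1) @ v / (n * v.sum())

        ginis = {}
        for group in ("highCog", "lowCog"):
            cfg = ae.group_preset(group, seed=5)
            ep = ae.simulate_assr_epochs(cfg, timeline)
            ginis[group] = gini(topography_40hz(ep).value)
        # focal temporal (highCog) concentrates power; diffuse spreads it
        assert ginis["lowCog"] < ginis["highCog"]


class TestErsp:
    def test_single_and_identical_trials(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((1, 10, 20)) + 1j * rng.standard_normal((1, 10, 20))
        np.testing.assert_allclose(ersp(x), np.abs(x[0]) ** 2, rtol=1e-12)
        stacked = np.repeat(x, 5, axis=0)
        np.testing.assert_allclose(ersp(stacked), ersp(x), rtol=1e-12)

    def test_sign_invariance_and_nonnegativity(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((4, 10, 20))
        np.testing.assert_allclose(ersp(np.concatenate([x, -x])), ersp(x), rtol=1e-12)
        assert np.all(ersp(x) >= 0.0)
        with pytest.raises(ValueError):
            ersp(np.zeros((0, 3, 3)))

    def test_image_shape_and_40hz_row_scales_with_power(self):
        def map_at_40(a):
            x = a * np.sin(2 * np.pi * 40 * TIMES)
            freqs, times, m = ersp_image(make_component(x[None, :]),
                                         out_shape=None)
            row = np.argmin(np.abs(freqs - 40.0))
            stim = (times > 0) & (times < 6)
            return m[row, stim].sum()

        # ERSP integrates to band power up to a constant transform factor:
        # the ratio must be invariant to amplitude
        r1 = map_at_40(1.0) / assr_bandpower(
            make_component(np.sin(2 * np.pi * 40 * TIMES)[None, :]))
        r2 = map_at_40(2.0) / assr_bandpower(
            make_component(2 * np.sin(2 * np.pi * 40 * TIMES)[None, :]))
        assert r2 == pytest.approx(r1, rel=1e-6)

    def test_resampled_grid(self):
        x = np.sin(2 * np.pi * 40 * TIMES)
        freqs, times, m = ersp_image(make_component(x[None, :]))
        assert m.shape == (224, 224)
        assert len(freqs) == 224 and len(times) == 224


class TestProfilePlumbing:
    def test_modulation_profile_fields(self, clean_component):
        dm = complex_demodulate(ae.ress_analysis(
            _two_channel(clean_component)).component)
        profile = modulation_profile(dm)
        assert profile.K == 40
        assert profile.t.shape == profile.am.shape == profile.itpc.shape
        # phase jitter 0, no noise: in-stimulus ITPC (pre-baseline) is 1
        mid = (profile.t > 1.0) & (profile.t < 5.0)
        np.testing.assert_allclose(profile.itpc[mid] + profile.itpc_baseline,
                                   1.0, atol=1e-9)


def _two_channel(component):
    """Duplicate a 1-channel epoch container into two channels so that RESS
    preconditions hold."""
    from dataclasses import replace

    data = np.concatenate([component.data, 0.5 * component.data], axis=1)
    return replace(component, data=data, channel_labels=("a", "b"))
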