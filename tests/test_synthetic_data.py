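import numpy as np
import pytest
from dataclasses import replace

from esgdenoise.metrics_screen import band_power, kr2, screen_convergence, welch_psd
from esgdenoise.synthetic_data import (SyntheticSpec, calibrate_gain,
                                       default_beat_model, gen_background,
                                       gen_ecg_artifact, gen_rr_series,
                                       inject_divergence, preset,
                                       synthesize_recording)
from conftest import FS


class TestRrSeries:
    def test_zero_hr_sd_gives_constant_rr(self):
        spec = SyntheticSpec(duration=60.0, hr_sd=0.0, seed=1)
        r = gen_rr_series(spec)
        rr = np.diff(r) / FS
        assert np.allclose(rr, 60.0 / 82.0, atol=1e-3)

    def test_realized_rate_near_target(self):
        spec = SyntheticSpec(duration=600.0, seed=2)
        r = gen_rr_series(spec)
        bpm = 60.0 / (np.diff(r) / FS)
        assert 79.0 <= np.mean(bpm) <= 85.0

    def test_zero_duration_empty(self):
        assert gen_rr_series(SyntheticSpec(duration=0.0, seed=3)).size == 0


class TestArtifact:
    def test_beat_peaks_on_r_times(self):
        spec = SyntheticSpec(duration=30.0, seed=4, qrs_jitter=0.0,
                             beat_gain_sd=0.0)
        rng = np.random.default_rng(4)
        r = gen_rr_series(spec, rng)
        art = gen_ecg_artifact(default_beat_model(), r, spec, rng)
        for rr in r[1:-1]:
            local = art[rr - 100:rr + 101]
            assert abs(int(np.argmax(np.abs(local))) - 100) <= 1

    def test_linear_in_amplitudes(self):
        spec = SyntheticSpec(duration=20.0, seed=5)
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
        r = gen_rr_series(spec)
        m = default_beat_model()
        a1 = gen_ecg_artifact(m, r, spec, rng1)
        import copy
        m2 = copy.deepcopy(m)
        m2.a = m2.a * 2.0
        a2 = gen_ecg_artifact(m2, r, spec, rng2)
        assert np.allclose(a2, 2.0 * a1, atol=1e-12)

    def test_width_jitter_produces_width_cv(self):
        """Half-height QRS widths vary with cv ~ qrs_jitter."""
        spec = SyntheticSpec(duration=120.0, seed=6, qrs_jitter=0.1,
                             beat_gain_sd=0.0, hr_sd=0.0)
        rng = np.random.default_rng(6)
        r = gen_rr_series(spec, rng)
        art = gen_ecg_artifact(default_beat_model(), r, spec, rng)
        widths = []
        for rr in r[1:-1]:
            seg = art[rr - 200:rr + 201]
            peak = seg[200]
            above = np.nonzero(seg >= 0.5 * peak)[0]
            widths.append(above[-1] - above[0])
        cv = np.std(widths) / np.mean(widths)
        assert abs(cv - 0.1) <= 0.03


class TestBackground:
    def test_band_limited_and_scaled(self):
        spec = SyntheticSpec(duration=60.0, seed=7, noise_sd=2.0)
        bg = gen_background(spec)
        assert abs(float(np.std(bg)) - 2.0) <= 0.04
        est = welch_psd(bg, FS)
        total = band_power(est, (0.0, FS / 2))
        outside = total - band_power(est, (10.0, 500.0))
        assert outside <= 0.05 * total
        assert abs(kr2(bg)) <= 0.1


class TestSynthesize:
    def test_zero_gain_recording_equals_clean(self):
        spec = SyntheticSpec(duration=30.0, seed=8, artifact_gain=0.0,
                             n_channels=2)
        rec, truth = synthesize_recording(spec)
        assert np.array_equal(rec.data, truth.clean)
        assert abs(kr2(rec.data[0])) < 0.15

    def test_conservation_exact(self):
        spec = SyntheticSpec(duration=30.0, seed=9, n_channels=3,
                             line_amp=1.0)
        rec, truth = synthesize_recording(spec)
        assert np.array_equal(truth.clean + truth.artifact, rec.data)

    def test_full_determinism(self):
        spec = SyntheticSpec(duration=20.0, seed=10, n_channels=2)
        r1, t1 = synthesize_recording(spec)
        r2, t2 = synthesize_recording(spec)
        assert np.array_equal(r1.data, r2.data)
        assert np.array_equal(t1.r_indices, t2.r_indices)


class TestCalibration:
    def test_zero_target_zero_gain(self):
        assert calibrate_gain(0.0, SyntheticSpec(duration=30.0, seed=11)) == 0.0

    def test_kr2_monotone_in_gain(self):
        spec = SyntheticSpec(duration=40.0, seed=12)
        rng = np.random.default_rng(12)
        r = gen_rr_series(spec, rng)
        art = gen_ecg_artifact(default_beat_model(), r, spec, rng)
        bg = gen_background(spec, rng)
        vals = [kr2(bg + g * art) for g in (0.0, 2.0, 5.0, 10.0, 20.0)]
        assert np.all(np.diff(vals) > -0.05)

    def test_self_validation_on_independent_seed(self):
        spec = SyntheticSpec(duration=75.0, seed=13, n_channels=1,
                             gain_profile_span=0.0)
        gain = calibrate_gain(2.0, spec)
        check = replace(spec, seed=spec.seed + 100, artifact_gain=gain)
        rec, _ = synthesize_recording(check)
        from esgdenoise.preprocess import PreprocessConfig, bandpass_filter
        y = bandpass_filter(rec.data[0], FS, PreprocessConfig())
        assert 1.6 <= kr2(y) <= 2.4

    def test_preset_contamination_levels(self):
        """bp-like mixtures land at KR2 ~ 2, lp-like at ~ 7.5."""
        from esgdenoise.preprocess import PreprocessConfig, bandpass_filter
        for name, lo, hi in (("bp", 1.0, 3.0), ("lp", 5.0, 10.0)):
            spec = preset(name, seed=14, duration=75.0, n_channels=2)
            rec, _ = synthesize_recording(spec)
            vals = [kr2(bandpass_filter(rec.data[c], FS, PreprocessConfig()))
                    for c in range(2)]
            assert lo <= np.mean(vals) <= hi


class TestInjectDivergence:
    def test_injected_channel_reaches_mv_range(self):
        spec = SyntheticSpec(duration=20.0, seed=15, n_channels=3)
        rec, truth = synthesize_recording(spec)
        out = inject_divergence(rec, 1, rng=15)
        assert np.max(np.abs(out.data[1])) >= 10_000.0
        assert np.array_equal(out.data[0], rec.data[0])
        assert np.array_equal(out.data[2], rec.data[2])

    def test_screen_flags_only_injected_channel(self):
        spec = SyntheticSpec(duration=40.0, seed=16, n_channels=8,
                             artifact_gain=8.0)
        rec, truth = synthesize_recording(spec)
        refpop = np.array([kr2(rec.data[c]) for c in range(8)])
        out = inject_divergence(rec, 5, rng=16)
        # emulate denoiser outputs: artifact removed everywhere except the
        # divergent channel, whose excursions survive
        den = np.array([kr2(truth.clean[c]) if c != 5 else kr2(out.data[5])
                        for c in range(8)])
        flags, _ = screen_convergence(den, refpop)
        assert flags[5]
        assert flags.sum() == 1
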