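import numpy as np
import pytest

from esgdenoise.rpeaks import BeatAnnotations
from esgdenoise.template_denoise import (TemplateConfig, ats_denoise,
                                         build_beat_template,
                                         segment_template, ts_denoise)
from conftest import FS, make_artifact_train


def periodic_train(beat, n_beats=60, spacing=1500, gains=None):
    half = (beat.size - 1) // 2
    r = np.arange(1000, 1000 + n_beats * spacing, spacing)
    x = np.zeros(r[-1] + half + 1000)
    gains = np.ones(n_beats) if gains is None else gains
    for g, rr in zip(gains, r):
        x[rr - half:rr + half + 1] += g * beat
    return x, BeatAnnotations(r_indices=r, fs=FS)


def window_power(y, ann, half):
    return sum(float(np.sum(y[r - half:r + half + 1] ** 2))
               for r in ann.r_indices
               if r - half >= 0 and r + half + 1 <= y.size)


class TestBeatTemplate:
    def test_identical_beats_give_exact_template(self, clean_beat):
        x, ann = periodic_train(clean_beat)
        tpl = build_beat_template(x, ann, 30)
        assert np.allclose(tpl.samples, clean_beat, atol=1e-12)
        assert tpl.n_averaged == 40

    def test_edge_beat_uses_first_40(self, clean_beat):
        x, ann = periodic_train(clean_beat, n_beats=60)
        tpl0 = build_beat_template(x, ann, 0)
        assert tpl0.n_averaged == 40

    def test_averaging_variance_law(self, clean_beat):
        """Template noise sd ~ sigma/sqrt(40) for beats = truth + N(0, s^2)."""
        rng = np.random.default_rng(11)
        sigma = 0.5
        x, ann = periodic_train(clean_beat, n_beats=40)
        x = x + rng.standard_normal(x.size) * sigma
        tpl = build_beat_template(x, ann, 20)
        resid_sd = float(np.std(tpl.samples - clean_beat))
        expected = sigma / np.sqrt(40)
        assert abs(resid_sd - expected) <= 0.3 * expected


class TestSegmentation:
    def test_partition_identity_and_qrs_length(self, clean_beat):
        x, ann = periodic_train(clean_beat)
        tpl = build_beat_template(x, ann, 30)
        seg = segment_template(tpl)
        assert np.array_equal(seg.concatenate(), tpl.samples)
        assert seg.qrs_seg.size == round(0.12 * FS) + 1

    def test_out_of_range_boundary_raises(self, clean_beat):
        x, ann = periodic_train(clean_beat)
        tpl = build_beat_template(x, ann, 30)
        with pytest.raises(ValueError):
            segment_template(tpl, (-60.0, 300.0))


class TestTsDenoise:
    def test_exact_cancellation_of_identical_beats(self, clean_beat):
        x, ann = periodic_train(clean_beat, gains=np.full(60, 5.0))
        y = ts_denoise(x, ann)
        half = int(0.2 * FS)
        assert window_power(y, ann, half) <= 1e-10 * window_power(x, ann, half)

    def test_per_beat_gain_recovery(self, clean_beat):
        # 40 beats: every template averages the same set, and normalising
        # the gains to mean 1 makes that template the clean beat itself
        rng = np.random.default_rng(12)
        gains = rng.uniform(0.5, 2.0, 40)
        gains *= 40 / gains.sum()
        x, ann = periodic_train(clean_beat, n_beats=40, gains=gains)
        y, details = ts_denoise(x, ann, return_details=True)
        fitted = {d["beat"]: d["gain"] for d in details}
        for i, g in enumerate(gains):
            assert abs(fitted[i] - g) <= 1e-6
        half = int(0.2 * FS)
        assert window_power(y, ann, half) <= 1e-10 * window_power(x, ann, half)

    def test_background_only_nearly_untouched(self):
        from esgdenoise.metrics_screen import cross_correlation
        rng = np.random.default_rng(13)
        x = rng.standard_normal(int(40 * FS))
        fake = BeatAnnotations(
            r_indices=np.arange(1000, x.size - 1000, 1500), fs=FS)
        y = ts_denoise(x, fake)
        assert cross_correlation(x, y) >= 99.0

    def test_repeat_application_shrinks_change(self, clean_beat):
        """Second pass changes the signal less than the first."""
        rng = np.random.default_rng(14)
        art, ann, _ = make_artifact_train(duration=30.0, gain=5.0, seed=14,
                                          qrs_jitter=0.05, beat_gain_sd=0.1)
        x = art + rng.standard_normal(art.size) * 0.5
        y1 = ts_denoise(x, ann)
        y2 = ts_denoise(y1, ann)
        assert np.sum((y2 - y1) ** 2) < np.sum((y1 - x) ** 2)


class TestAtsDenoise:
    def test_selects_true_qrs_scale(self, clean_beat, beat_model):
        """A beat with an on-grid stretched QRS is matched at that scale."""
        true_scale = 1.06
        half = (clean_beat.size - 1) // 2
        # stretched beat: resample the clean beat about R by 1/scale
        src = half + (np.arange(clean_beat.size) - half) / true_scale
        stretched = np.interp(src, np.arange(clean_beat.size), clean_beat)
        x, ann = periodic_train(clean_beat, n_beats=41)
        mid = ann.r_indices[20]
        x[mid - half:mid + half + 1] = stretched
        _, details = ats_denoise(x, ann, return_details=True)
        by_beat = {d["beat"]: d for d in details}
        assert by_beat[20]["scale"] == pytest.approx(true_scale)
        # unmodified beats keep scale 1 (tie-break prefers 1.0)
        assert by_beat[10]["scale"] == pytest.approx(1.0)

    def test_identical_beats_match_ts(self, clean_beat):
        x, ann = periodic_train(clean_beat, gains=np.full(60, 3.0))
        yts = ts_denoise(x, ann)
        yats = ats_denoise(x, ann)
        assert np.max(np.abs(yats - yts)) <= 1e-9 * np.max(np.abs(x))

    def test_ats_beats_ts_under_width_jitter(self):
        """With +/-10 % QRS width jitter ATS residuals dominate TS's."""
        art, ann, _ = make_artifact_train(duration=60.0, gain=5.0, seed=15,
                                          qrs_jitter=0.10)
        _, dts = ts_denoise(art, ann, return_details=True)
        yts = ts_denoise(art, ann)
        yats, dats = ats_denoise(art, ann, return_details=True)
        half = int(0.2 * FS)
        assert (window_power(yats, ann, half)
                <= window_power(yts, ann, half))
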