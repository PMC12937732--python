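import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from esgdenoise.metrics_screen import (aggregate_metrics, band_power,
                                       compute_metric_set, cross_correlation,
                                       delta_kr2, format_count, kr2,
                                       relative_error, screen_convergence,
                                       snr, spectral_distortion, welch_psd)
from conftest import FS


@pytest.fixture(scope="module")
def ref():
    rng = np.random.default_rng(61)
    from esgdenoise.preprocess import PreprocessConfig, bandpass_filter
    return bandpass_filter(rng.standard_normal(int(30 * FS)), FS,
                           PreprocessConfig())


class TestWelch:
    def test_sinusoid_peak_location(self):
        t = np.arange(int(10 * FS)) / FS
        est = welch_psd(np.sin(2 * np.pi * 100 * t), FS)
        assert est.freqs[int(np.argmax(est.psd))] == pytest.approx(100.0, abs=0.5)

    def test_parseval(self):
        rng = np.random.default_rng(62)
        x = 3.0 * rng.standard_normal(int(30 * FS))
        est = welch_psd(x, FS)
        total = np.trapezoid(est.psd, est.freqs)
        assert total == pytest.approx(9.0, rel=0.10)

    def test_zero_signal(self):
        est = welch_psd(np.zeros(int(5 * FS)), FS)
        assert np.all(est.psd == 0.0)


class TestRelativeError:
    def test_identity_scaling_and_null(self, ref):
        assert relative_error(ref, ref, FS) == 0.0
        assert relative_error(ref, np.zeros_like(ref), FS) == pytest.approx(1.0)
        assert relative_error(ref, 2.0 * ref, FS) == pytest.approx(9.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_error(np.zeros(int(5 * FS)), np.ones(int(5 * FS)), FS)


class TestSnr:
    def test_known_noise_ratios(self, ref):
        rng = np.random.default_rng(63)
        e = rng.standard_normal(ref.size)
        e *= np.std(ref) / np.std(e)
        assert snr(ref, ref + e) == pytest.approx(0.0, abs=0.05)
        assert snr(ref, ref + e / np.sqrt(10)) == pytest.approx(10.0, abs=0.05)

    def test_identical_signals_capped(self, ref):
        assert snr(ref, ref) == 120.0


class TestCrossCorrelation:
    def test_sign_and_orthogonality(self, ref):
        assert cross_correlation(ref, ref) == pytest.approx(100.0)
        assert cross_correlation(ref, -ref) == pytest.approx(-100.0)
        t = np.arange(int(4 * FS)) / FS
        s, c = np.sin(2 * np.pi * 10 * t), np.cos(2 * np.pi * 10 * t)
        assert abs(cross_correlation(s, c)) < 1e-6

    def test_zero_signal_rejected(self, ref):
        with pytest.raises(ValueError):
            cross_correlation(ref, np.zeros_like(ref))


class TestSpectralDistortion:
    def test_identity_and_quadratic_scaling(self, ref):
        for band in ((0.0, 20.0), (20.0, 200.0)):
            assert spectral_distortion(ref, ref, FS, band) == pytest.approx(100.0)
            assert spectral_distortion(ref, 0.5 * ref, FS, band) == \
                pytest.approx(25.0)


class TestKr2:
    def test_reference_distributions(self):
        rng = np.random.default_rng(64)
        n = 240000
        assert abs(kr2(rng.standard_normal(n))) <= 0.03
        assert kr2(rng.uniform(0, 1, n)) == pytest.approx(-1.01, abs=0.02)
        lap = np.log(20) / np.log(2) - 2.91
        assert kr2(rng.laplace(0, 1, n)) == pytest.approx(lap, abs=0.05)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(a=st.floats(0.01, 100.0), b=st.floats(-50.0, 50.0))
    def test_location_scale_invariance(self, a, b):
        y = np.random.default_rng(65).laplace(0, 1, 5000)
        assert kr2(a * y + b) == pytest.approx(kr2(y), abs=1e-9)

    def test_degenerate_iqr_rejected(self):
        with pytest.raises(ValueError):
            kr2(np.ones(1000))


class TestDeltaKr2:
    def test_identities(self):
        assert delta_kr2(2.0, 0.0) == -1.0
        assert delta_kr2(-1.5, 1.5) == 0.0
        assert delta_kr2(0.7, -1.4) == pytest.approx(1.0)

    def test_near_zero_reference_flagged(self):
        with pytest.raises(ValueError):
            delta_kr2(1e-12, 1.0)


class TestScreen:
    def test_hand_computed_thresholds(self):
        refpop = np.array([1.0, 2.0, 3.0, 4.0])
        flags, thr = screen_convergence(np.array([3.0, 0.5, -2.0]), refpop)
        assert thr.upper == pytest.approx(2.5)
        assert thr.lower == pytest.approx(-1.45)
        assert flags.tolist() == [True, False, True]

    def test_inside_band_not_flagged(self):
        refpop = np.linspace(0.5, 4.0, 50)
        den = np.full(10, 0.1)
        flags, _ = screen_convergence(den, refpop)
        assert not flags.any()

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            screen_convergence(np.array([]), np.array([1.0]))


class TestAggregation:
    def _cases(self):
        rows = []
        for matrix, n, k in (("64-BP", 896, 6), ("32-BP", 448, 3),
                             ("32-LP", 448, 3)):
            for i in range(n):
                rows.append({"matrix": matrix, "algorithm": "eks2",
                             "RE": 0.5, "SNR": 1.0, "CC": 50.0,
                             "SD_low": 10.0, "SD_high": 50.0, "KR2": 0.5,
                             "dKR2": -0.5, "null": False,
                             "flagged": i < k})
        return pd.DataFrame(rows)

    def test_table3_style_percentages(self):
        _, counts = aggregate_metrics(self._cases())
        by = counts.set_index("matrix")
        for m in ("64-BP", "32-BP", "32-LP", "Total"):
            assert format_count(int(by.loc[m, "errors"]),
                                int(by.loc[m, "cases"])).endswith("(0.67%)")

    def test_flagged_cases_excluded_after(self):
        df = self._cases()
        summary, _ = aggregate_metrics(df)
        row = summary[(summary.matrix == "64-BP") & (summary.metric == "RE")]
        assert int(row["n_before"].iloc[0]) == 896
        assert int(row["n_after"].iloc[0]) == 890

    def test_identical_trials_have_zero_trial_variance(self):
        df = self._cases()
        summary, _ = aggregate_metrics(df)
        assert np.allclose(summary["sd_before"].fillna(0.0), 0.0)


class TestMetricSetIdentity:
    def test_identity_algorithm_scores_optimal(self, ref):
        ms = compute_metric_set(ref, ref.copy(), FS)
        assert ms.re == 0.0
        assert ms.cc_pct == pytest.approx(100.0)
        assert ms.sd_low_pct == pytest.approx(100.0)
        assert ms.sd_high_pct == pytest.approx(100.0)
        assert ms.delta_kr2 == 0.0
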