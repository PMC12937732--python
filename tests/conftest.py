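"""Shared fixtures: small seeded synthetic signals and benchmark runs."""

from __future__ import annotations

import numpy as np
import pytest

from esgdenoise.pipeline import BenchmarkConfig, run_benchmark
from esgdenoise.preprocess import PreprocessConfig, preprocess_channel, trim_analysis_segment
from esgdenoise.rpeaks import BeatAnnotations, detect_r_peaks, realign_r_peaks
from esgdenoise.synthetic_data import (SyntheticSpec, default_beat_model,
                                       gen_background, gen_ecg_artifact,
                                       gen_rr_series, preset,
                                       synthesize_recording)

FS = 2000.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def beat_model():
    """Canonical unit-peak five-wave beat model."""
    return default_beat_model()


@pytest.fixture(scope="session")
def clean_beat(beat_model):
    """Noise-free beat window (+/-200 ms) sampled from the model."""
    half = int(0.2 * FS)
    phase = np.arange(-half, half + 1) / FS * beat_model.omega
    return beat_model.evaluate(phase)


def make_artifact_train(duration=30.0, gain=5.0, seed=0, qrs_jitter=0.0,
                        beat_gain_sd=0.0, hr_sd=0.0):
    """Quasiperiodic artifact trace + true annotations, no background."""
    spec = SyntheticSpec(duration=duration, seed=seed, qrs_jitter=qrs_jitter,
                         beat_gain_sd=beat_gain_sd, hr_sd=hr_sd)
    rng = np.random.default_rng(seed)
    r = gen_rr_series(spec, rng)
    model = default_beat_model(2 * np.pi * spec.hr_mean / 60.0)
    art = gen_ecg_artifact(model, r, spec, rng) * gain
    return art, BeatAnnotations(r_indices=r, fs=FS), spec


@pytest.fixture(scope="session")
def bp_channel():
    """One preprocessed brachial-like contaminated channel with annotations.

    Returns (y0, ann, truth_clean, truth_artifact) over the 60 s analysis
    segment of a 75 s synthetic trial.
    """
    spec = preset("bp", seed=0, duration=75.0, n_channels=2)
    rec, truth = synthesize_recording(spec)
    pp = PreprocessConfig(segment_len=60.0)
    seg = trim_analysis_segment(rec, pp)
    i0 = int(pp.trim_start * FS)
    i1 = i0 + int(pp.segment_len * FS)
    y0 = preprocess_channel(seg.data[1], FS, pp)
    ann = realign_r_peaks(y0, detect_r_peaks(y0, FS))
    return y0, ann, truth.clean[1][i0:i1], truth.artifact[1][i0:i1]


@pytest.fixture(scope="session")
def ordering_result():
    """Desk-scale benchmark over both contamination presets, all algorithms.

    75 s trials (15 s lead-in + 60 s analysis), 6 channels per matrix.
    """
    cfg = BenchmarkConfig(presets=("bp", "lp"), seed=0, n_channels=6,
                          duration=75.0,
                          preprocess=PreprocessConfig(segment_len=60.0))
    return run_benchmark(cfg)
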