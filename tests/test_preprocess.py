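"""Signal-level contracts of the pre-processing chain."""

import numpy as np
import pandas as pd
import pytest

from ecogmap import (PipelineConfig, PreprocessError, common_average_reference,
                     detect_noisy_electrodes, downsample, epoch_trials,
                     remove_line_noise)
from ecogmap.preprocess import EpochSet

from conftest import make_recording


def _rms(x):
    return float(np.sqrt(np.mean(np.asarray(x, dtype=np.float64) ** 2)))


def _epochs_from_signal(sig, rate=2048.0, time_zero=None):
    sig = np.asarray(sig, dtype=np.float32)[None, None, :]
    n = sig.shape[-1]
    return EpochSet("T", float(rate), sig, time_zero or n // 2,
                    np.array([n]), [0], ["active"],
                    [{"sound": 0.0, "letter": 1.5, "button": 2.5}])


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def test_epoch_spans_sound_minus_1s_to_button_plus_1s():
    rec = make_recording(events=[(0, "sound", 4096),
                                 (0, "letter", int(3.5 * 2048)),
                                 (0, "button", int(5.0 * 2048))],
                         conditions={0: "active"})
    # sound at 2 s, button at 5 s -> epoch [1 s, 6 s) = samples [2048, 12288)
    eps = epoch_trials(rec)
    assert eps.time_zero == 2048
    assert eps.lengths[0] == 12288 - 2048
    np.testing.assert_array_equal(eps.data[0, :, :100],
                                  rec.traces[:, 2048:2148])


def test_epoch_capped_at_8_seconds():
    rate = 2048
    rec = make_recording(duration=20.0,
                         events=[(0, "sound", 2 * rate),
                                 (0, "letter", 4 * rate),
                                 (0, "button", 11 * rate)],
                         conditions={0: "active"})
    eps = epoch_trials(rec)
    assert eps.lengths[0] == 8 * rate


def test_trial_with_insufficient_pre_window_is_dropped():
    rate = 2048
    rec = make_recording(duration=20.0,
                         events=[(0, "sound", rate // 2),
                                 (0, "letter", 2 * rate),
                                 (0, "button", 3 * rate),
                                 (1, "sound", 6 * rate),
                                 (1, "letter", 8 * rate),
                                 (1, "button", 9 * rate)],
                         conditions={0: "active", 1: "active"})
    eps = epoch_trials(rec)
    assert eps.n_trials == 1 and eps.n_dropped == 1
    assert eps.trial_ids == [1]


def test_passive_epoch_uses_fixed_post_window():
    rate = 2048
    rec = make_recording(duration=20.0,
                         events=[(0, "sound", 4 * rate)],
                         conditions={0: "passive"})
    eps = epoch_trials(rec)
    cfg = PipelineConfig()
    assert eps.lengths[0] == int(round((1.0 + cfg.passive_epoch_end) * rate))
    assert eps.event_latencies[0] == {"sound": 0.0}


def test_no_usable_trials_raises():
    rate = 2048
    rec = make_recording(duration=5.0,
                         events=[(0, "sound", rate // 4)],
                         conditions={0: "passive"})
    with pytest.raises(PreprocessError, match="no usable trials"):
        epoch_trials(rec)


# ---------------------------------------------------------------------------
# line-noise removal
# ---------------------------------------------------------------------------

def test_notch_kills_line_tone_and_passes_neighbors():
    rate = 2048.0
    t = np.arange(int(8 * rate)) / rate
    tone50 = np.sin(2 * np.pi * 50.0 * t)
    out = remove_line_noise(_epochs_from_signal(tone50, rate)).data
    assert _rms(out) < 0.03 * _rms(tone50)
    tone30 = np.sin(2 * np.pi * 30.0 * t)
    out30 = remove_line_noise(_epochs_from_signal(tone30, rate)).data
    assert abs(_rms(out30) - _rms(tone30)) < 0.05 * _rms(tone30)


def test_notch_of_zero_signal_is_zero():
    out = remove_line_noise(_epochs_from_signal(np.zeros(4096))).data
    np.testing.assert_allclose(out, 0.0, atol=1e-7)


def test_notch_frequency_above_nyquist_rejected():
    eps = _epochs_from_signal(np.zeros(4096), rate=500.0)
    with pytest.raises(PreprocessError, match="Nyquist"):
        remove_line_noise(eps, freqs=(50.0, 300.0))


# ---------------------------------------------------------------------------
# downsampling
# ---------------------------------------------------------------------------

def test_downsample_length_2048_to_500():
    eps = _epochs_from_signal(np.zeros(8 * 2048), rate=2048.0)
    out = downsample(eps, to_rate=500)
    assert out.data.shape[-1] == 4000
    assert out.rate == 500.0
    assert out.lengths[0] == 4000


def test_downsample_preserves_passband_and_rejects_above_nyquist():
    rate = 2048.0
    t = np.arange(int(4 * rate)) / rate
    tone100 = np.sin(2 * np.pi * 100.0 * t)
    out = downsample(_epochs_from_signal(tone100, rate), to_rate=500).data
    mid = out[..., 500:-500]
    assert abs(_rms(mid) - _rms(tone100)) < 0.05 * _rms(tone100)
    tone240 = np.sin(2 * np.pi * 240.0 * t)  # transition band of the filter
    out240 = downsample(_epochs_from_signal(tone240, rate), to_rate=500).data
    assert _rms(out240[..., 500:-500]) < 0.8 * _rms(tone240)
    tone350 = np.sin(2 * np.pi * 350.0 * t)  # above the new Nyquist
    out350 = downsample(_epochs_from_signal(tone350, rate), to_rate=500).data
    assert _rms(out350[..., 500:-500]) < 0.05 * _rms(tone350)


def test_downsample_requires_lower_rate():
    eps = _epochs_from_signal(np.zeros(4096), rate=500.0)
    with pytest.raises(PreprocessError):
        downsample(eps, to_rate=500)


# ---------------------------------------------------------------------------
# noisy-electrode detection and re-referencing
# ---------------------------------------------------------------------------

def _multi_epochs(data, rate=500.0):
    data = np.asarray(data, dtype=np.float64)
    n = data.shape[-1]
    return EpochSet("T", rate, data, n // 2, np.array([n] * data.shape[0]),
                    list(range(data.shape[0])),
                    ["active"] * data.shape[0],
                    [{"sound": 0.0}] * data.shape[0])


def test_noisy_detection_flags_scaled_outlier_only():
    rng = np.random.default_rng(0)
    data = rng.standard_normal((3, 64, 1000))
    eps = _multi_epochs(data)
    assert not detect_noisy_electrodes(eps, k=5.0).any()
    data2 = data.copy()
    data2[:, 17, :] *= 100.0
    flags = detect_noisy_electrodes(_multi_epochs(data2), k=5.0)
    assert flags[17] and flags.sum() == 1
    assert not detect_noisy_electrodes(_multi_epochs(data2), k=np.inf).any()


def test_noisy_detection_needs_four_electrodes():
    rng = np.random.default_rng(0)
    eps = _multi_epochs(rng.standard_normal((2, 3, 100)))
    with pytest.raises(PreprocessError):
        detect_noisy_electrodes(eps)


def test_car_zeroes_equal_traces_and_centers_mean():
    rng = np.random.default_rng(1)
    base = rng.standard_normal((2, 1, 500))
    data = np.repeat(base, 2, axis=1)
    out = common_average_reference(_multi_epochs(data))
    np.testing.assert_allclose(out.data, 0.0, atol=1e-12)
    data6 = rng.standard_normal((2, 6, 500))
    out6 = common_average_reference(_multi_epochs(data6))
    np.testing.assert_allclose(out6.data.mean(axis=1), 0.0, atol=1e-12)


def test_car_excluded_electrode_does_not_shift_others():
    rng = np.random.default_rng(2)
    data = rng.standard_normal((1, 5, 400))
    spoiled = data.copy()
    spoiled[:, 0, :] += 1e4        # wild outlier electrode
    excl = np.array([True, False, False, False, False])
    ref_clean = common_average_reference(_multi_epochs(data), excl)
    ref_spoiled = common_average_reference(_multi_epochs(spoiled), excl)
    np.testing.assert_allclose(ref_clean.data[:, 1:], ref_spoiled.data[:, 1:])
    # the excluded electrode is itself still re-referenced
    np.testing.assert_allclose(
        ref_spoiled.data[:, 0],
        spoiled[:, 0] - spoiled[:, 1:].mean(axis=1))


def test_car_requires_two_clean_electrodes():
    eps = _multi_epochs(np.zeros((1, 3, 100)))
    with pytest.raises(PreprocessError):
        common_average_reference(eps, np.array([True, True, False]))
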