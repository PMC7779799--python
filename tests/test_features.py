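"""Spectral feature extraction: envelopes, TFRs, alignment, matrices."""

import numpy as np
import pytest

from ecogmap import (BandEnvelope, DegenerateBaselineError, FeatureError,
                     PipelineConfig, band_envelope, build_feature_matrix,
                     compute_tfr, concatenate_segments, event_align,
                     normalize_power)
from ecogmap.preprocess import EpochSet


def _epochs(data, rate=500.0, time_zero=None, conditions=None,
            latencies=None):
    data = np.asarray(data, dtype=np.float64)
    n_tr, _, n = data.shape
    tz = n // 2 if time_zero is None else time_zero
    return EpochSet(
        "T", rate, data, tz, np.array([n] * n_tr), list(range(n_tr)),
        conditions or ["active"] * n_tr,
        latencies or [{"sound": 0.0, "letter": 1.0, "button": 1.8}] * n_tr)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_normalized_change_arithmetic():
    times = np.linspace(-1.0, 1.0, 201)
    B = 4.0
    power = np.full((1, 1, 201), B)
    np.testing.assert_allclose(normalize_power(power, times), 0.0)
    double = power.copy()
    double[..., times >= 0] = 2.0 * B
    np.testing.assert_allclose(
        normalize_power(double, times)[..., times >= 0], 1.0)
    half = power.copy()
    half[..., times >= 0] = 0.5 * B
    out = normalize_power(half, times)
    np.testing.assert_allclose(out[..., times >= 0], -0.5)


def test_symmetric_normalization_mode():
    times = np.linspace(-1.0, 1.0, 201)
    power = np.full((1, 1, 201), 2.0)
    out = normalize_power(3 * power, times, mode="symmetric")
    np.testing.assert_allclose(out, 0.0)  # P == B everywhere


def test_degenerate_baseline_raises():
    times = np.linspace(-1.0, 1.0, 201)
    power = np.zeros((1, 2, 201))
    with pytest.raises(DegenerateBaselineError):
        normalize_power(power, times)


def test_baseline_outside_epoch_raises():
    times = np.linspace(0.5, 1.0, 50)
    with pytest.raises(FeatureError, match="baseline"):
        normalize_power(np.ones((1, 1, 50)), times)


# ---------------------------------------------------------------------------
# band envelopes
# ---------------------------------------------------------------------------

def test_alpha_envelope_of_10hz_tone_is_flat_unit():
    rate = 500.0
    t = np.arange(int(4 * rate)) / rate - 2.0
    sig = np.sin(2 * np.pi * 10.0 * t)
    # add a DC-ish pedestal so baseline normalization has a positive baseline
    eps = _epochs(sig[None, None, :], rate)
    env = band_envelope(eps, (8.0, 12.0), "alpha")
    # normalized change should be ~0 (envelope constant = baseline)
    core = env.data[..., 300:-300]
    assert np.abs(core).max() < 0.08
    # raw analytic-signal magnitude of the tone is ~1 away from edges
    from scipy.signal import butter, hilbert, sosfiltfilt
    sos = butter(4, [8, 12], btype="bandpass", fs=rate, output="sos")
    mag = np.abs(hilbert(sosfiltfilt(sos, sig)))
    assert np.allclose(mag[300:-300], 1.0, atol=0.05)


def test_gamma_envelope_of_10hz_tone_is_negligible():
    rate = 500.0
    t = np.arange(int(4 * rate)) / rate
    rng = np.random.default_rng(0)
    sig = np.sin(2 * np.pi * 10.0 * t) + 0.01 * rng.standard_normal(len(t))
    from scipy.signal import butter, hilbert, sosfiltfilt
    sos = butter(4, [55, 200], btype="bandpass", fs=rate, output="sos")
    mag = np.abs(hilbert(sosfiltfilt(sos, sig)))
    assert mag[300:-300].mean() < 0.05


def test_envelope_tracks_amplitude_step():
    rate = 500.0
    n = int(4 * rate)
    t = np.arange(n) / rate - 2.0
    amp = np.where(t < 0.5, 1.0, 2.0)
    sig = amp * np.sin(2 * np.pi * 10.0 * t)
    eps = _epochs(sig[None, None, :], rate)
    env = band_envelope(eps, (8.0, 12.0), "alpha")
    # (P - B)/B with B ~ 1 -> post-step value ~ 1.0 (2x amplitude)
    pre = env.data[0, 0, (t > -0.5) & (t < 0.2)]
    post = env.data[0, 0, (t > 0.8) & (t < 1.4)]  # settled, away from edges
    assert np.abs(pre).max() < 0.15
    assert np.abs(post - 1.0).max() < 0.15


def test_band_outside_nyquist_rejected():
    eps = _epochs(np.zeros((1, 1, 1000)), rate=100.0)
    with pytest.raises(FeatureError, match="Nyquist"):
        band_envelope(eps, (55.0, 200.0))


# ---------------------------------------------------------------------------
# time-frequency maps
# ---------------------------------------------------------------------------

def test_tfr_peaks_at_tone_frequency():
    rate = 500.0
    n = int(4 * rate)
    t = np.arange(n) / rate - 2.0
    rng = np.random.default_rng(1)
    # tone present only post-stimulus: the normalized change then peaks at
    # the tone frequency (a baseline tone would bias the ratio at neighbors)
    sig = (np.sin(2 * np.pi * 40.0 * t) * (t >= 0)
           + 0.2 * rng.standard_normal(n))
    tfr = compute_tfr(_epochs(sig[None, None, :], rate))
    post = (tfr.times > 0.3) & (tfr.times < 1.5)
    profile = np.nanmean(tfr.power_change[0][:, post], axis=1)
    assert tfr.freqs[np.nanargmax(profile)] == pytest.approx(40.0, abs=2.0)


def test_tfr_masks_edges_at_low_frequency():
    rate = 500.0
    tfr = compute_tfr(_epochs(np.random.default_rng(0)
                              .standard_normal((1, 1, 2000)) + 5.0, rate))
    # 6 Hz window = 7/6 s; the first sample cannot host a centered window
    assert np.isnan(tfr.power_change[0, 0, 0])
    mid = np.searchsorted(tfr.times, 0.0)
    assert np.isfinite(tfr.power_change[0, 0, mid])


def test_tfr_requires_seven_cycles_of_lowest_frequency():
    with pytest.raises(FeatureError, match="cycles"):
        compute_tfr(_epochs(np.ones((1, 1, 400)), rate=500.0))


def test_tfr_null_normalization_stationary(config):
    """For baseline-stationary noise the normalized change is small and,
    in particular, statistically identical between disjoint post-stimulus
    windows (only the short-baseline ratio bias remains, which is shared)."""
    rate = 500.0
    rng = np.random.default_rng(7)
    data = rng.standard_normal((16, 2, 2000)) + 10.0
    tfr = compute_tfr(_epochs(data, rate))
    sel = (tfr.freqs >= 60) & (tfr.freqs <= 200)
    early = (tfr.times > 0.0) & (tfr.times < 0.5)
    late = (tfr.times > 0.5) & (tfr.times < 1.0)
    m_early = np.nanmean(tfr.power_change[:, sel][:, :, early])
    m_late = np.nanmean(tfr.power_change[:, sel][:, :, late])
    assert abs(m_early) < 0.15 and abs(m_late) < 0.15
    assert abs(m_early - m_late) < 0.05


# ---------------------------------------------------------------------------
# event alignment and feature matrices
# ---------------------------------------------------------------------------

def _envelope_from(data, rate=500.0):
    n = data.shape[-1]
    times = (np.arange(n) - n // 2) / rate
    return BandEnvelope("x", np.asarray(data, float), times, rate)


def test_event_align_passive_trials_skip_letter_button():
    rate = 500.0
    data = np.ones((3, 2, 3000))
    eps = _epochs(data, rate,
                  conditions=["active", "passive", "active"],
                  latencies=[{"sound": 0.0, "letter": 1.0, "button": 1.8},
                             {"sound": 0.0},
                             {"sound": 0.0, "letter": 1.1, "button": 1.9}])
    segs = event_align(_envelope_from(data), eps)
    assert sorted(segs) == ["button", "letter", "sound"]
    assert segs["sound"].data.shape[0] == 3
    assert segs["letter"].trial_index.tolist() == [0, 2]
    assert segs["button"].trial_index.tolist() == [0, 2]


def test_event_align_window_lengths(config):
    rate = 500.0
    data = np.ones((2, 1, 3000))
    eps = _epochs(data, rate)
    segs = event_align(_envelope_from(data), eps)
    assert segs["sound"].data.shape[-1] == int(round(1.5 * rate))
    assert segs["letter"].data.shape[-1] == int(round(0.9 * rate))


def test_feature_modes_on_constant_envelope(config):
    rate = 500.0
    c = 0.37
    data = np.full((4, 3, 3000), c)
    eps = _epochs(data, rate)
    envs = {"gamma": _envelope_from(data)}
    for mode in ("whole_trial", "per_event", "window_0_900ms", "sliding"):
        feats = build_feature_matrix(envs, eps, mode=mode, config=config)
        vals = feats.drop(columns="condition").to_numpy(dtype=float)
        np.testing.assert_allclose(vals, c, atol=1e-12)


def test_sliding_window_count():
    rate = 500.0
    data = np.ones((2, 1, 3000))
    eps = _epochs(data, rate)
    segs = event_align(_envelope_from(data), eps,
                       windows={"sound": (-0.5, 1.0)})
    cat, _, _ = concatenate_segments(segs, order=("sound",))
    w, s = 50, 25  # 100 ms / 50 ms at 500 Hz
    expected = (cat.shape[-1] - w) // s + 1
    assert expected == 29


def test_features_invariant_to_trial_order(config):
    rng = np.random.default_rng(3)
    data = rng.standard_normal((6, 4, 3000)) * 0.1 + 1.0
    eps = _epochs(data, 500.0)
    perm = rng.permutation(6)
    eps_shuf = _epochs(data[perm], 500.0)
    f1 = build_feature_matrix({"g": _envelope_from(data)}, eps,
                              mode="whole_trial", config=config)
    f2 = build_feature_matrix({"g": _envelope_from(data[perm])}, eps_shuf,
                              mode="whole_trial", config=config)
    np.testing.assert_allclose(f1["g"], f2["g"], atol=1e-12)


def test_per_event_mode_rejected_for_passive(config):
    data = np.ones((2, 1, 3000))
    eps = _epochs(data, 500.0, conditions=["passive", "passive"],
                  latencies=[{"sound": 0.0}] * 2)
    with pytest.raises(FeatureError, match="per_event"):
        build_feature_matrix({"g": _envelope_from(data)}, eps,
                             mode="per_event", condition="passive",
                             config=config)


def test_band_and_tfr_estimators_agree(tiny_epochsets, config):
    """Band-averaged TFR change and the Hilbert-envelope change estimate the
    same quantity; their electrode profiles should correlate strongly."""
    eps = tiny_epochsets[0]
    from ecogmap import band_envelope as be
    sub = EpochSet(eps.patient_id, eps.rate, eps.data[:6, :4], eps.time_zero,
                   eps.lengths[:6], eps.trial_ids[:6], eps.conditions[:6],
                   eps.event_latencies[:6])
    tfr = compute_tfr(sub, config)
    lo, hi = config.bands["gamma"]
    sel = (tfr.freqs >= lo) & (tfr.freqs <= hi)
    post = (tfr.times > 0.0) & (tfr.times < 1.0)
    tfr_prof = np.nanmean(tfr.power_change[:, sel][:, :, post], axis=(1, 2))
    env = be(sub, (lo, hi), "gamma", config)
    esel = (env.times > 0.0) & (env.times < 1.0)
    env_prof = env.data[..., esel].mean(axis=(0, 2))
    r = np.corrcoef(tfr_prof, env_prof)[0, 1]
    assert r > 0.9
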