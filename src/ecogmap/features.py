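"""Spectral features: time-frequency maps, band-limited Hilbert envelopes,
baseline normalization, event alignment, and band-feature matrices.

Power is expressed throughout as the *normalized change* relative to the
pre-stimulus baseline (-0.7 to -0.1 s before sound onset): ``(P - B)/B``
with ``B`` the per-trial, per-electrode (and per-frequency) baseline mean,
computed before any trial averaging.  A symmetric alternative
``(P - B)/(P + B)`` is available through ``PipelineConfig.normalization``.

Band envelopes use a zero-phase (two-pass) 4th-order Butterworth band-pass at
the band edges followed by the analytic-signal magnitude; epochs are
mirror-padded by 0.5 s to suppress filter and Hilbert edge transients.
Time-frequency maps use sliding Hanning windows of 7 cycles per frequency at
a 10 ms step; time points whose window is not fully supported by the epoch
are masked rather than zero-padded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .config import PipelineConfig
from .preprocess import EpochSet

logger = logging.getLogger("ecogmap")


class FeatureError(ValueError):
    """Invalid feature-extraction request."""


class DegenerateBaselineError(FeatureError):
    """Baseline power is non-positive or non-finite for some electrode."""


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_power(power: np.ndarray, times: np.ndarray,
                    baseline_window: tuple[float, float] = (-0.7, -0.1),
                    mode: str = "relative") -> np.ndarray:
    """Baseline-normalize a power time course along its last axis.

    ``power`` has shape ``(..., electrodes, time)`` (any leading axes);
    baseline is averaged over ``baseline_window`` (half-open, seconds, same
    clock as ``times``) separately for every leading index, ignoring masked
    (NaN) samples.  ``mode="relative"`` gives ``(P - B)/B``; ``"symmetric"``
    gives ``(P - B)/(P + B)``.
    """
    times = np.asarray(times)
    sel = (times >= baseline_window[0]) & (times < baseline_window[1])
    if not sel.any():
        raise FeatureError(
            f"baseline window {baseline_window} lies outside the epoch "
            f"(times {times[0]:.3f}..{times[-1]:.3f} s)")
    with np.errstate(invalid="ignore"):
        base = np.nanmean(power[..., sel], axis=-1, keepdims=True)
    bad = ~np.isfinite(base) | (base <= 0)
    if bad.any():
        idx = np.argwhere(bad)[0]
        raise DegenerateBaselineError(
            f"non-positive baseline power at index {tuple(int(i) for i in idx[:-1])} "
            f"(electrode axis is the second-to-last)")
    if mode == "relative":
        return power / base - 1.0
    if mode == "symmetric":
        return (power - base) / (power + base)
    raise FeatureError(f"unknown normalization mode {mode!r}")


# ---------------------------------------------------------------------------
# band envelopes
# ---------------------------------------------------------------------------

@dataclass
class BandEnvelope:
    """Per-trial baseline-normalized band power change.

    ``data`` is ``trials x electrodes x time`` at the epoch set's rate;
    ``times`` is seconds relative to sound onset.
    """

    band: str
    data: np.ndarray
    times: np.ndarray
    rate: float


def band_envelope(epochs: EpochSet, band: tuple[float, float],
                  band_name: str = "", config: PipelineConfig | None = None,
                  pad_seconds: float = 0.5) -> BandEnvelope:
    """Band-pass (zero-phase Butterworth, order 4), rectify via the analytic
    signal, and baseline-normalize per trial."""
    if config is None:
        config = PipelineConfig()
    lo, hi = band
    nyq = epochs.rate / 2.0
    if not 0.0 < lo < hi < nyq:
        raise FeatureError(
            f"band ({lo}, {hi}) Hz outside (0, Nyquist={nyq}) Hz")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=epochs.rate,
                        output="sos")
    n = epochs.data.shape[-1]
    pad = min(n - 1, int(round(pad_seconds * epochs.rate)))
    x = np.concatenate([epochs.data[..., pad:0:-1], epochs.data,
                        epochs.data[..., -2:-2 - pad:-1]], axis=-1)
    x = signal.sosfiltfilt(sos, x, axis=-1)
    env = np.abs(signal.hilbert(x, axis=-1))[..., pad:pad + n]
    env = normalize_power(env, epochs.times, config.baseline_window,
                          mode=config.normalization)
    return BandEnvelope(band=band_name or f"{lo:g}-{hi:g}Hz", data=env,
                        times=epochs.times, rate=epochs.rate)


# ---------------------------------------------------------------------------
# time-frequency maps
# ---------------------------------------------------------------------------

@dataclass
class TFR:
    """Trial-averaged baseline-normalized time-frequency map.

    ``power_change`` is ``electrodes x frequencies x times``; samples whose
    analysis window is unsupported are NaN.
    """

    power_change: np.ndarray
    freqs: np.ndarray
    times: np.ndarray


def compute_tfr(epochs: EpochSet, config: PipelineConfig | None = None,
                trials: np.ndarray | None = None) -> TFR:
    """Sliding Hanning-window spectrogram, 7 cycles per frequency, 2 Hz
    frequency steps and 10 ms time steps, baseline-normalized per trial and
    averaged over trials."""
    if config is None:
        config = PipelineConfig()
    f0, f1 = config.tfr_freq_range
    freqs = np.arange(f0, f1 + 1e-9, config.tfr_freq_step)
    n = epochs.data.shape[-1]
    min_len_s = config.tfr_cycles / freqs[0]
    if n / epochs.rate < min_len_s:
        raise FeatureError(
            f"epoch ({n / epochs.rate:.3f} s) shorter than {config.tfr_cycles} "
            f"cycles of the lowest frequency ({min_len_s:.3f} s)")
    step = max(1, int(round(config.tfr_time_step * epochs.rate)))
    centers = np.arange(0, n, step)
    times = (centers - epochs.time_zero) / epochs.rate
    data = epochs.data if trials is None else epochs.data[trials]
    n_tr, n_el = data.shape[0], data.shape[1]
    power = np.full((n_tr, n_el, len(freqs), len(centers)), np.nan)
    for fi, f in enumerate(freqs):
        win_len = int(round(config.tfr_cycles / f * epochs.rate))
        half = win_len // 2
        valid = (centers - half >= 0) & (centers - half + win_len <= n)
        if not valid.any():
            continue
        win = signal.windows.hann(win_len, sym=False)
        kern = win * np.exp(-2j * np.pi * f * np.arange(win_len) / epochs.rate)
        kern /= win.sum()
        starts = centers[valid] - half
        frames = np.lib.stride_tricks.sliding_window_view(
            data, win_len, axis=-1)[..., starts, :]
        coef = frames @ kern
        power[:, :, fi, valid] = (np.abs(coef) ** 2)
    power = normalize_power(power, times, config.baseline_window,
                            mode=config.normalization)
    with np.errstate(invalid="ignore"):
        avg = np.nanmean(power, axis=0)
    return TFR(power_change=avg, freqs=freqs, times=times)


# ---------------------------------------------------------------------------
# event alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignedSegment:
    """One event-aligned cut: ``data`` is ``kept-trials x electrodes x time``
    with ``times`` in seconds relative to the event onset."""

    event: str
    times: np.ndarray
    data: np.ndarray
    trial_index: np.ndarray  # indices into the source trial axis


def event_align(envelope: BandEnvelope, epochs: EpochSet,
                windows: dict[str, tuple[float, float]] | None = None,
                trials: np.ndarray | None = None,
                config: PipelineConfig | None = None,
                ) -> dict[str, AlignedSegment]:
    """Re-cut a per-trial time course around each event at its per-trial
    latency.  Passive trials contribute only to the sound segment; trials
    whose window exceeds their epoch are excluded from that segment."""
    if config is None:
        config = PipelineConfig()
    if windows is None:
        windows = config.event_windows
    if trials is None:
        trials = np.arange(epochs.n_trials)
    rate = envelope.rate
    out: dict[str, AlignedSegment] = {}
    for event, (w0, w1) in windows.items():
        n_win = int(round((w1 - w0) * rate))
        rel_times = w0 + np.arange(n_win) / rate
        kept, slabs = [], []
        n_skipped = 0
        for t in trials:
            lat = epochs.event_latencies[t].get(event)
            if lat is None:
                continue  # passive trials lack letter/button events
            start = epochs.time_zero + int(round((lat + w0) * rate))
            stop = start + n_win
            valid_end = int(epochs.lengths[t])
            if start < 0 or stop > valid_end:
                n_skipped += 1
                continue
            kept.append(t)
            slabs.append(envelope.data[t, :, start:stop])
        if n_skipped:
            logger.info("event %s: %d trial(s) excluded (window exceeds "
                        "epoch)", event, n_skipped)
        if not kept:
            continue
        out[event] = AlignedSegment(event=event, times=rel_times,
                                    data=np.stack(slabs),
                                    trial_index=np.asarray(kept))
    return out


def concatenate_segments(segments: dict[str, AlignedSegment],
                         order: tuple[str, ...] = ("sound", "letter", "button"),
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate aligned segments on a display/analysis axis.

    Only trials present in *every* requested segment are kept, so the
    concatenated array is rectangular.  Returns ``(data, times, trial_index)``
    where ``times`` is a synthetic running axis (segment offsets accumulate).
    """
    present = [segments[e] for e in order if e in segments]
    if not present:
        raise FeatureError("no aligned segments to concatenate")
    common = present[0].trial_index
    for seg in present[1:]:
        common = np.intersect1d(common, seg.trial_index)
    if common.size == 0:
        raise FeatureError("no trial appears in every aligned segment")
    blocks, taxes, offset = [], [], 0.0
    for seg in present:
        sel = np.searchsorted(seg.trial_index, common)
        blocks.append(seg.data[sel])
        taxes.append(seg.times - seg.times[0] + offset)
        offset = taxes[-1][-1] + (1.0 / len(seg.times))
    return np.concatenate(blocks, axis=-1), np.concatenate(taxes), common


# ---------------------------------------------------------------------------
# feature matrices
# ---------------------------------------------------------------------------

FEATURE_MODES = ("whole_trial", "per_event", "sliding", "window_0_900ms")


def build_feature_matrix(envelopes: dict[str, BandEnvelope], epochs: EpochSet,
                         mode: str = "whole_trial",
                         condition: str = "active",
                         config: PipelineConfig | None = None) -> pd.DataFrame:
    """Reduce per-trial band envelopes to one feature row per electrode.

    Averages are taken per trial first, then across trials.  Modes:

    * ``whole_trial`` — mean over the concatenated event-aligned segments
      (sound + letter + button for active trials, sound only for passive);
    * ``per_event`` — one column per band and event window;
    * ``sliding`` — 100 ms windows, 50 ms steps over the concatenated axis;
    * ``window_0_900ms`` — mean over [0, 0.9) s after sound onset (the only
      period shared by active and passive trials).
    """
    if config is None:
        config = PipelineConfig()
    if mode not in FEATURE_MODES:
        raise FeatureError(f"unknown mode {mode!r}")
    trials = epochs.trial_indices(condition)
    if trials.size == 0:
        raise FeatureError(f"no {condition} trials")
    if condition == "passive" and mode == "per_event":
        raise FeatureError("per_event features are undefined for passive "
                           "trials (no letter/button events)")
    events = (("sound",) if condition == "passive"
              else ("sound", "letter", "button"))
    cols: dict[str, np.ndarray] = {}
    for band, env in envelopes.items():
        if mode == "window_0_900ms":
            sel = (env.times >= 0.0) & (env.times < 0.9)
            per_trial = env.data[trials][:, :, sel].mean(axis=-1)
            cols[band] = per_trial.mean(axis=0)
            continue
        segs = event_align(env, epochs, trials=trials, config=config,
                           windows={e: config.event_windows[e] for e in events})
        if mode == "per_event":
            for e, seg in segs.items():
                cols[f"{band}_{e}"] = seg.data.mean(axis=-1).mean(axis=0)
            continue
        data, _, _ = concatenate_segments(segs, order=events)
        if mode == "whole_trial":
            cols[band] = data.mean(axis=-1).mean(axis=0)
        else:  # sliding
            rate = env.rate
            w = int(round(config.sliding_window * rate))
            s = int(round(config.sliding_step * rate))
            n_win = (data.shape[-1] - w) // s + 1
            if n_win < 1:
                raise FeatureError("sliding window longer than the segment")
            for i in range(n_win):
                cols[f"{band}_w{i:03d}"] = (
                    data[..., i * s:i * s + w].mean(axis=-1).mean(axis=0))
    out = pd.DataFrame(cols)
    out.insert(0, "condition", condition)
    return out


def cohort_feature_matrix(epochsets: list[EpochSet], electrodes: pd.DataFrame,
                          config: PipelineConfig | None = None,
                          mode: str = "whole_trial",
                          condition: str = "active") -> pd.DataFrame:
    """Band-feature matrix for a whole cohort: one row per electrode (and
    condition), with electrode metadata columns merged in.  Electrodes
    flagged as excluded (high noise) are dropped."""
    key = f"{mode}|{condition}"
    return cohort_feature_matrices(epochsets, electrodes,
                                   {key: (mode, condition)}, config)[key]


def cohort_feature_matrices(epochsets: list[EpochSet],
                            electrodes: pd.DataFrame,
                            requests: dict[str, tuple[str, str]],
                            config: PipelineConfig | None = None,
                            ) -> dict[str, pd.DataFrame]:
    """Several cohort feature matrices in one pass.

    ``requests`` maps an output name to ``(mode, condition)``; the band
    envelopes (the expensive step) are computed once per patient and shared
    across all requested matrices.
    """
    if config is None:
        config = PipelineConfig()
    frames: dict[str, list[pd.DataFrame]] = {k: [] for k in requests}
    for epochs in epochsets:
        tab = electrodes[electrodes.patient_id == epochs.patient_id]
        if len(tab) != epochs.n_electrodes:
            raise FeatureError(
                f"patient {epochs.patient_id}: electrode table has "
                f"{len(tab)} rows but the recording has "
                f"{epochs.n_electrodes} electrodes")
        envs = {name: band_envelope(epochs, band, band_name=name, config=config)
                for name, band in config.bands.items()}
        meta = tab.reset_index(drop=True)
        for key, (mode, condition) in requests.items():
            conditions = (("active", "passive") if condition == "both"
                          else (condition,))
            for cond in conditions:
                feats = build_feature_matrix(envs, epochs, mode=mode,
                                             condition=cond, config=config)
                block = pd.concat([meta, feats], axis=1)
                frames[key].append(block[~epochs.excluded_flags])
    return {k: pd.concat(blocks, ignore_index=True)
            for k, blocks in frames.items()}
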