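"""Pre-processing chain: epoching, line-noise removal, downsampling,
noisy-electrode exclusion, and common-average re-referencing.

The chain order is fixed: epoch -> notch -> downsample -> exclude ->
re-reference.  Epochs run from 1 s before the sound onset to 1 s after the
button-press (capped at 8 s of data); passive trials, which have no letter or
button events, use a fixed post-sound window.  All filters are zero-phase and
applied per epoch, so no information leaks between trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .cohort import CohortRecording
from .config import PipelineConfig

logger = logging.getLogger("ecogmap")


class PreprocessError(ValueError):
    """Invalid pre-processing request (bad parameters or degenerate input)."""


@dataclass
class EpochSet:
    """Per-trial epochs of one patient at a single sample rate.

    ``data`` is ``trials x electrodes x samples``; epochs are padded to a
    common length with genuine recorded data (or edge reflection at the
    recording boundary) and ``lengths`` gives each trial's nominal epoch
    length in samples.  ``time_zero`` is the sample index of the sound onset
    within every epoch.  ``event_latencies`` holds per-trial event times in
    seconds relative to sound onset.
    """

    patient_id: str
    rate: float
    data: np.ndarray
    time_zero: int
    lengths: np.ndarray
    trial_ids: list[int]
    conditions: list[str]
    event_latencies: list[dict[str, float]]
    excluded_flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.excluded_flags is None:
            self.excluded_flags = np.zeros(self.data.shape[1], dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Epoch time axis in seconds relative to sound onset."""
        return (np.arange(self.data.shape[2]) - self.time_zero) / self.rate

    def trial_indices(self, condition: str | None = None) -> np.ndarray:
        if condition is None:
            return np.arange(self.n_trials)
        return np.flatnonzero(np.asarray(self.conditions, dtype=object) == condition)


def epoch_trials(rec: CohortRecording,
                 config: PipelineConfig | None = None) -> EpochSet:
    """Cut a continuous recording into per-trial epochs at the raw rate.

    Active trials span ``[sound - pre, min(button + 1 s, sound - pre + 8 s))``;
    passive trials span ``[sound - pre, sound + passive_epoch_end)``.  Trials
    whose pre-sound window would start before the recording are dropped and
    counted in ``n_dropped``.
    """
    if config is None:
        config = PipelineConfig()
    rate = rec.sample_rate
    pre = int(round(config.pre_sound_seconds * rate))
    max_len = int(round(config.max_epoch_seconds * rate))
    passive_post = int(round(config.passive_epoch_end * rate))

    rows = []
    n_dropped = 0
    for trial_id in rec.trial_ids():
        cond = rec.conditions[trial_id]
        sound = rec.event_sample(trial_id, "sound")
        start = sound - pre
        if start < 0:
            n_dropped += 1
            continue
        if cond == "active":
            button = rec.event_sample(trial_id, "button")
            end = min(button + rate, start + max_len)
        else:
            end = sound + passive_post
        if end <= start:
            n_dropped += 1
            continue
        latencies = {"sound": 0.0}
        if cond == "active":
            for kind in ("letter", "button"):
                latencies[kind] = (rec.event_sample(trial_id, kind) - sound) / rate
        rows.append((trial_id, cond, start, end, latencies))
    if n_dropped:
        logger.info("patient %s: dropped %d trial(s) truncated by recording "
                    "edges", rec.patient_id, n_dropped)
    if not rows:
        raise PreprocessError(
            f"patient {rec.patient_id}: no usable trials after epoching")

    longest = max(end - start for _, _, start, end, _ in rows)
    n_el = rec.n_electrodes
    data = np.empty((len(rows), n_el, longest), dtype=np.float32)
    lengths = np.empty(len(rows), dtype=int)
    trial_ids, conditions, latencies_list = [], [], []
    for i, (trial_id, cond, start, end, latencies) in enumerate(rows):
        stop = min(start + longest, rec.n_samples)
        seg = rec.traces[:, start:stop]
        if seg.shape[1] < longest:  # recording boundary: reflect-pad the tail
            pad = longest - seg.shape[1]
            seg = np.concatenate([seg, seg[:, -2:-2 - pad:-1]], axis=1)
        data[i] = seg
        lengths[i] = end - start
        trial_ids.append(trial_id)
        conditions.append(cond)
        latencies_list.append(latencies)
    return EpochSet(patient_id=rec.patient_id, rate=float(rate), data=data,
                    time_zero=pre, lengths=lengths, trial_ids=trial_ids,
                    conditions=conditions, event_latencies=latencies_list,
                    excluded_flags=rec.excluded_flags.copy(),
                    n_dropped=n_dropped)


def remove_line_noise(epochs: EpochSet,
                      freqs: tuple[float, ...] = (50.0, 100.0, 150.0),
                      bandwidth: float = 1.0) -> EpochSet:
    """Zero-phase IIR notch at each line frequency (default 50/100/150 Hz,
    1 Hz bandwidth)."""
    nyq = epochs.rate / 2.0
    sections = []
    for f0 in freqs:
        if f0 >= nyq:
            raise PreprocessError(
                f"notch frequency {f0} Hz >= Nyquist {nyq} Hz")
        b, a = signal.iirnotch(f0, f0 / bandwidth, fs=epochs.rate)
        sections.append(np.concatenate([b, a]))
    sos = np.asarray(sections)  # one zero-phase pass through the cascade
    # a high-Q notch rings for ~1/bandwidth seconds; reflect-pad that long
    padlen = min(epochs.data.shape[-1] - 1,
                 int(round(epochs.rate / bandwidth)))
    data = signal.sosfiltfilt(sos, epochs.data, axis=-1, padlen=padlen)
    return replace(epochs, data=data.astype(epochs.data.dtype, copy=False))


def downsample(epochs: EpochSet, to_rate: int = 500) -> EpochSet:
    """Polyphase anti-aliased rate conversion (2048 -> 500 is exactly
    125/512, so 8 s maps to exactly 4000 samples)."""
    if to_rate >= epochs.rate:
        raise PreprocessError(
            f"to_rate {to_rate} must be below the current rate {epochs.rate}")
    frac = Fraction(int(to_rate), int(round(epochs.rate))).limit_denominator()
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(epochs.data, up, down, axis=-1)
    ratio = to_rate / epochs.rate
    lengths = np.minimum(np.round(epochs.lengths * ratio).astype(int),
                         data.shape[-1])
    return replace(epochs, rate=float(to_rate), data=data, lengths=lengths,
                   time_zero=int(round(epochs.time_zero * ratio)))


def detect_noisy_electrodes(epochs: EpochSet, k: float = 5.0) -> np.ndarray:
    """Flag electrodes whose log broadband RMS deviates from the median by
    more than ``k`` robust (scaled-MAD) deviations.  Deterministic."""
    if epochs.n_electrodes < 4:
        raise PreprocessError("need at least 4 electrodes to detect outliers")
    rms = np.sqrt(np.mean(epochs.data.astype(np.float64) ** 2, axis=(0, 2)))
    log_rms = np.log10(np.maximum(rms, 1e-30))
    med = np.median(log_rms)
    mad = 1.4826 * np.median(np.abs(log_rms - med))
    if not np.isfinite(k):
        return np.zeros(epochs.n_electrodes, dtype=bool)
    if mad == 0.0:
        return log_rms != med
    return np.abs(log_rms - med) > k * mad


def common_average_reference(epochs: EpochSet,
                             excluded: np.ndarray | None = None) -> EpochSet:
    """Subtract the mean over non-excluded electrodes from every electrode.

    Excluded electrodes are re-referenced too but never contribute to the
    mean; the post-condition is that the mean over non-excluded output
    channels is zero at every sample.
    """
    if excluded is None:
        excluded = epochs.excluded_flags
    excluded = np.asarray(excluded, dtype=bool)
    keep = ~excluded
    if keep.sum() < 2:
        raise PreprocessError(
            "common average reference needs at least 2 non-excluded electrodes")
    ref = epochs.data[:, keep, :].mean(axis=1, keepdims=True)
    return replace(epochs, data=epochs.data - ref,
                   excluded_flags=excluded.copy())


def preprocess_recording(rec: CohortRecording,
                         config: PipelineConfig | None = None) -> EpochSet:
    """Run the full chain on one patient:
    epoch -> notch -> downsample -> exclude -> common average reference."""
    if config is None:
        config = PipelineConfig()
    epochs = epoch_trials(rec, config)
    epochs = remove_line_noise(epochs, freqs=config.line_freqs,
                               bandwidth=config.notch_bandwidth)
    epochs = downsample(epochs, to_rate=config.analysis_rate)
    noisy = detect_noisy_electrodes(epochs, k=config.noisy_electrode_mads)
    excluded = noisy | epochs.excluded_flags
    if noisy.any():
        logger.info("patient %s: excluding %d high-noise electrode(s)",
                    rec.patient_id, int(noisy.sum()))
    return common_average_reference(epochs, excluded)
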