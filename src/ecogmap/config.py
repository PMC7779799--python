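"""Pipeline configuration shared by all stages.

The configuration collects the fixed analysis constants of the mapping
procedure: the frequency bands being combined (alpha 8-12 Hz, beta 15-25 Hz,
broadband gamma 55-200 Hz), the pre-stimulus baseline window, the event-aligned
display/analysis windows, time-frequency parameters, and the cross-validation /
resampling counts.  All randomized stages draw their seeds from ``rng_seed``
through :func:`child_seed`, so a single integer reproduces an entire run.

Window conventions: all windows are half-open ``[start, end)`` in seconds
relative to the named event; sample indices are 0-based.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger("ecogmap")

#: Canonical band edges in Hz.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "alpha": (8.0, 12.0),
    "beta": (15.0, 25.0),
    "gamma": (55.0, 200.0),
}

#: Event-aligned windows in seconds relative to each event onset.
DEFAULT_EVENT_WINDOWS: dict[str, tuple[float, float]] = {
    "sound": (-0.5, 1.0),
    "letter": (-0.2, 0.7),
    "button": (-0.3, 0.7),
}

#: The six band sets evaluated against each other, keyed by display name.
MODEL_BATTERY: dict[str, tuple[str, ...]] = {
    "gamma": ("gamma",),
    "alpha": ("alpha",),
    "beta": ("beta",),
    "alpha+gamma": ("alpha", "gamma"),
    "beta+gamma": ("beta", "gamma"),
    "alpha+beta+gamma": ("alpha", "beta", "gamma"),
}


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Analysis constants for one end-to-end run."""

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS))
    baseline_window: tuple[float, float] = (-0.7, -0.1)
    event_windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_WINDOWS))
    # time-frequency parameters
    tfr_freq_range: tuple[float, float] = (6.0, 250.0)
    tfr_freq_step: float = 2.0
    tfr_cycles: float = 7.0
    tfr_time_step: float = 0.010
    # pre-processing
    analysis_rate: int = 500
    line_freqs: tuple[float, ...] = (50.0, 100.0, 150.0)
    notch_bandwidth: float = 1.0
    noisy_electrode_mads: float = 5.0
    passive_epoch_end: float = 1.9
    max_epoch_seconds: float = 8.0
    pre_sound_seconds: float = 1.0
    # statistics
    n_folds: int = 10
    n_cv_repeats: int = 20
    n_bootstrap: int = 1000
    n_permutations: int = 1000
    bootstrap_cv_repeats: int = 1
    sliding_window: float = 0.100
    sliding_step: float = 0.050
    significance_consistency: float = 0.95
    # normalization: "relative" = (P - B)/B, "symmetric" = (P - B)/(P + B)
    normalization: str = "relative"
    # repeat averaging: "probabilities" (default) or "auroc"
    repeat_averaging: str = "probabilities"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        nyq = self.analysis_rate / 2.0
        for name, (lo, hi) in self.bands.items():
            if not (0.0 < lo < hi):
                raise ConfigError(f"band {name!r}: interval ({lo}, {hi}) not positive")
            if hi >= nyq:
                raise ConfigError(
                    f"band {name!r}: upper edge {hi} Hz >= Nyquist {nyq} Hz "
                    f"of analysis rate")
        if self.n_folds < 2:
            raise ConfigError(f"n_folds must be >= 2, got {self.n_folds}")
        for attr in ("n_cv_repeats", "n_bootstrap", "n_permutations",
                     "bootstrap_cv_repeats"):
            if getattr(self, attr) < 1:
                raise ConfigError(f"{attr} must be >= 1")
        if self.baseline_window[0] >= self.baseline_window[1]:
            raise ConfigError("baseline_window must be an increasing interval")
        if self.normalization not in ("relative", "symmetric"):
            raise ConfigError(f"unknown normalization {self.normalization!r}")
        if self.repeat_averaging not in ("probabilities", "auroc"):
            raise ConfigError(f"unknown repeat_averaging {self.repeat_averaging!r}")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = {k: list(v) for k, v in self.bands.items()}
        d["event_windows"] = {k: list(v) for k, v in self.event_windows.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "bands" in kwargs:
            kwargs["bands"] = {k: tuple(v) for k, v in kwargs["bands"].items()}
        if "event_windows" in kwargs:
            kwargs["event_windows"] = {
                k: tuple(v) for k, v in kwargs["event_windows"].items()}
        for key in ("baseline_window", "line_freqs", "tfr_freq_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def child_seed(seed: int, *tags: str | int) -> int:
    """Deterministic per-stage seed derived from a master seed.

    Stages are tagged by name (and optional indices) so that reordering or
    adding stages never shifts the seeds of the others.  Returned values fit
    in 31 bits.
    """
    ss = np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF] + [_tag_to_int(t) for t in tags])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def _tag_to_int(tag: str | int) -> int:
    if isinstance(tag, (int, np.integer)):
        return int(tag) & 0x7FFFFFFF
    h = 0
    for ch in str(tag):
        h = (h * 131 + ord(ch)) & 0x7FFFFFFF
    return h
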