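"""Synthetic multi-patient ECoG cohort generator with known ground truth.

The generator emulates the response structure of a delayed match-to-sample
recording session: each patient contributes a continuous multichannel trace at
2048 Hz containing trial events (sound onset, letter onset, button-press for
active trials; sound only for passive trials).  Each electrode's signal is

* spectrally shaped Gaussian background noise with power ~ 1/f^exponent,
* an additive 50 Hz line-noise sinusoid (so the notch stage has work to do),
* one band-limited carrier per frequency band (white noise brick-wall
  band-passed to the carrier range) whose amplitude envelope follows
  ``sqrt(1 + s * E(t))`` where ``E`` sums smooth event kernels over trials and
  ``s`` is the electrode's signed peak fractional *power* change (positive for
  gamma increases, negative for alpha/beta suppression; the envelope is
  floored at 0.1x baseline amplitude so power stays positive).

Effect sizes are ordered by electrode group — strongest in eloquent
electrodes, with beta suppression deepest in "output" (motor/Broca-type)
electrodes near the button-press — and attenuated by ``passive_scale`` in
passive trials.  Heterogeneity enters at two levels: a lognormal per-patient
responsiveness multiplier, and lognormal per-electrode multipliers whose
band-to-band correlation is controlled by latent-factor loadings (by default
alpha and gamma load on a common responsiveness factor while beta carries a
largely independent component, so beta contributes genuinely new information
to a band-combining classifier while alpha is mostly redundant).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import fft

from .cohort import CohortRecording, make_electrode_table
from .config import PipelineConfig, child_seed

logger = logging.getLogger("ecogmap")


class ParameterError(ValueError):
    """Invalid generator specification."""


class CalibrationError(RuntimeError):
    """Requested target AUROC is unattainable within the search bounds."""


@dataclass
class EventKernel:
    """Smooth response kernel for one trial event.

    ``k(x) = (1 - exp(-x/rise)) * exp(-x/decay)`` for ``x = t - latency >= 0``,
    normalized to unit peak; ``amplitude`` scales the band's group effect size
    for this event.
    """

    latency: float = 0.05
    rise: float = 0.10
    decay: float = 0.40
    amplitude: float = 1.0

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        t = np.asarray(x, dtype=float) - self.latency
        out = np.zeros_like(t)
        pos = t > 0
        tp = t[pos]
        raw = (1.0 - np.exp(-tp / self.rise)) * np.exp(-tp / self.decay)
        # unit-peak normalization (peak location solved in closed form)
        xpk = self.rise * math.log(1.0 + self.decay / self.rise)
        peak = (1.0 - math.exp(-xpk / self.rise)) * math.exp(-xpk / self.decay)
        out[pos] = raw / peak
        return out

    @property
    def support(self) -> float:
        """Time after the event beyond which the kernel is negligible."""
        return self.latency + 5.0 * self.rise + 8.0 * self.decay


def _default_kernels_fast() -> dict[str, EventKernel]:
    # prompt, transient responses (gamma-like)
    return {
        "sound": EventKernel(0.05, 0.08, 0.35, 1.0),
        "letter": EventKernel(0.05, 0.08, 0.35, 0.9),
        "button": EventKernel(-0.10, 0.10, 0.35, 0.8),
    }


def _default_kernels_slow(button_amp: float,
                          sound_amp: float = 0.6) -> dict[str, EventKernel]:
    # slower build-up/decay (alpha/beta desynchronization-like)
    return {
        "sound": EventKernel(0.15, 0.25, 0.80, sound_amp),
        "letter": EventKernel(0.10, 0.25, 0.80, 0.7),
        "button": EventKernel(-0.30, 0.25, 0.90, button_amp),
    }


@dataclass
class BandEffectSpec:
    """Generative parameters for one frequency band's carrier."""

    band: str
    carrier_range: tuple[float, float]
    direction: str                                  # "increase" | "suppress"
    effect_size_by_group: dict[str, float]          # peak fractional power change
    event_kernel: dict[str, EventKernel]
    passive_scale: float = 0.5
    carrier_rms: float = 6.0                        # microvolts
    latent_loading: float = 0.5                     # weight on shared factor
    latent_sigma_scale: float = 1.0                 # band's share of electrode spread

    def validate(self) -> None:
        if self.direction not in ("increase", "suppress"):
            raise ParameterError(f"band {self.band}: bad direction {self.direction!r}")
        if not 0.0 <= self.passive_scale <= 1.0:
            raise ParameterError(f"band {self.band}: passive_scale must be in [0, 1]")
        sizes = self.effect_size_by_group
        for grp in ("input", "output", "non_eloquent"):
            if grp not in sizes:
                raise ParameterError(f"band {self.band}: missing group {grp!r}")
            if sizes[grp] < 0:
                raise ParameterError(
                    f"band {self.band}: effect sizes are magnitudes, got "
                    f"{sizes[grp]} for {grp}")
        if min(sizes["input"], sizes["output"]) < sizes["non_eloquent"]:
            raise ParameterError(
                f"band {self.band}: eloquent-group effect sizes must be >= the "
                f"non-eloquent size in magnitude")
        if self.direction == "suppress" and max(sizes.values()) > 1.0:
            raise ParameterError(
                f"band {self.band}: a suppression of more than 100% of baseline "
                f"power would drive the carrier amplitude below the floor")
        if not 0.0 <= self.latent_loading <= 1.0:
            raise ParameterError(f"band {self.band}: latent_loading must be in [0, 1]")
        if self.latent_sigma_scale < 0.0:
            raise ParameterError(
                f"band {self.band}: latent_sigma_scale must be >= 0")


def default_band_effects() -> list[BandEffectSpec]:
    """Band effects mirroring the qualitative cohort response structure:
    gamma power increases and alpha/beta decreases after task events, larger
    at eloquent sites, beta suppression deepest in output electrodes around
    the button-press, all attenuated under passive listening."""
    return [
        BandEffectSpec(
            band="gamma", carrier_range=(55.0, 200.0), direction="increase",
            effect_size_by_group={"input": 0.9, "output": 0.45, "non_eloquent": 0.12},
            event_kernel=_default_kernels_fast(),
            passive_scale=0.5, carrier_rms=6.0, latent_loading=0.95,
            latent_sigma_scale=0.35),
        BandEffectSpec(
            band="alpha", carrier_range=(8.0, 12.0), direction="suppress",
            effect_size_by_group={"input": 0.55, "output": 0.30, "non_eloquent": 0.12},
            event_kernel=_default_kernels_slow(button_amp=0.75),
            passive_scale=0.5, carrier_rms=10.0, latent_loading=0.95),
        BandEffectSpec(
            band="beta", carrier_range=(15.0, 25.0), direction="suppress",
            effect_size_by_group={"input": 0.15, "output": 0.65, "non_eloquent": 0.10},
            event_kernel=_default_kernels_slow(button_amp=1.0, sound_amp=0.85),
            passive_scale=0.5, carrier_rms=8.0, latent_loading=0.0),
    ]


# category mixes within each io group, proportional to the cohort's clinical
# label frequencies (motor 46, mixed-sensorimotor 8, language-Broca 16;
# sensory 22, language-Wernicke 14, language-temporobasal 2, auditory 12,
# visual 7)
_OUTPUT_CATEGORIES = (("motor", 46), ("mixed-sensorimotor", 8),
                      ("language-Broca", 16))
_INPUT_CATEGORIES = (("sensory", 22), ("language-Wernicke", 14),
                     ("language-temporobasal", 2), ("auditory", 12),
                     ("visual", 7))


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort."""

    n_patients: int = 10
    electrodes_per_patient: int = 57
    prevalence_eloquent: float = 129.0 / 572.0
    prevalence_output: float = 0.55          # output share within eloquent
    emotion_rate: float = 0.015              # emotion share within eloquent
    seizure_onset_rate: float = 41.0 / 572.0
    trials_active: int = 240
    trials_passive: int = 80
    sample_rate: int = 2048
    # event schedule (seconds)
    letter_latency: float = 1.5
    letter_jitter: float = 0.10
    button_latency: float = 2.5
    button_jitter: float = 0.15
    inter_trial_interval: float = 3.5
    iti_jitter: float = 0.3
    # noise model
    one_over_f_exponent: float = 2.0
    background_rms: float = 40.0             # microvolts
    line_noise_amplitude: float = 5.0        # microvolts at line_freq
    line_freq: float = 50.0
    gain_spread_sigma: float = 0.05          # lognormal per-electrode gain
    # heterogeneity
    patient_sigma: float = 0.20              # lognormal patient multiplier
    electrode_sigma: float = 0.45            # lognormal electrode multiplier
    band_effects: list[BandEffectSpec] = field(default_factory=default_band_effects)
    seed: int = 0

    def validate(self) -> None:
        for name in ("prevalence_eloquent", "prevalence_output"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ParameterError(f"{name} must be in (0, 1), got {v}")
        if not 0.0 <= self.emotion_rate < 1.0:
            raise ParameterError("emotion_rate must be in [0, 1)")
        if not (0.0 < self.letter_latency < self.button_latency):
            raise ParameterError(
                "event latencies must be ordered sound (0) < letter < button")
        if self.sample_rate <= 2 * max(
                hi for b in self.band_effects for hi in [b.carrier_range[1]]):
            raise ParameterError("sample_rate too low for the carrier ranges")
        for b in self.band_effects:
            b.validate()

    def scaled_effects(self, band: str, factor: float) -> "CohortSpec":
        """Copy of the spec with the named band's eloquent (input and output)
        effect sizes scaled by ``factor``."""
        effects = []
        for b in self.band_effects:
            if b.band == band:
                sizes = dict(b.effect_size_by_group)
                sizes["input"] = sizes["input"] * factor
                sizes["output"] = sizes["output"] * factor
                # keep the eloquent >= non-eloquent invariant meaningful
                sizes["non_eloquent"] = min(
                    sizes["non_eloquent"], min(sizes["input"], sizes["output"]))
                b = replace(b, effect_size_by_group=sizes)
            effects.append(b)
        return replace(self, band_effects=effects)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _complex_gauss(rng, shape) -> np.ndarray:
    re = rng.standard_normal(shape, dtype=np.float32)
    im = rng.standard_normal(shape, dtype=np.float32)
    return re + 1j * im


def _one_over_f_noise(rng, n_el: int, n_samp: int, rate: float,
                      exponent: float) -> np.ndarray:
    """Gaussian noise with PSD ~ 1/f^exponent, unit RMS per electrode.

    Synthesized directly in the frequency domain (iid complex-Gaussian bins
    scaled by f^(-exponent/2)); single precision throughout.
    """
    n_fft = fft.next_fast_len(n_samp, real=True)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    shape = np.ones_like(freqs, dtype=np.float32)
    f_floor = 0.5  # flatten below 0.5 Hz to keep variance finite
    nz = freqs > 0
    shape[nz] = np.maximum(freqs[nz], f_floor) ** (-exponent / 2.0)
    shape[0] = 0.0
    spec = _complex_gauss(rng, (n_el, len(freqs))) * shape
    x = fft.irfft(spec, n=n_fft, axis=1)[:, :n_samp]
    rms = np.sqrt(np.mean(np.square(x, dtype=np.float64), axis=1,
                          keepdims=True)).astype(np.float32)
    return x / rms


def _bandlimited_noise(rng, n_el: int, n_samp: int, rate: float,
                       band: tuple[float, float]) -> np.ndarray:
    """Gaussian noise brick-wall limited to ``band``, unit RMS per electrode
    (frequency-domain synthesis, single precision)."""
    n_fft = fft.next_fast_len(n_samp, real=True)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    sel = np.flatnonzero((freqs >= band[0]) & (freqs <= band[1]))
    spec = np.zeros((n_el, len(freqs)), dtype=np.complex64)
    spec[:, sel] = _complex_gauss(rng, (n_el, len(sel)))
    x = fft.irfft(spec, n=n_fft, axis=1)[:, :n_samp]
    rms = np.sqrt(np.mean(np.square(x, dtype=np.float64), axis=1,
                          keepdims=True)).astype(np.float32)
    return x / rms


def _assign_electrodes(rng, spec: CohortSpec, patient_id: str):
    """Sample group membership and ESM categories for one patient."""
    n = spec.electrodes_per_patient
    eloquent = rng.random(n) < spec.prevalence_eloquent
    cats = np.full(n, "non-eloquent", dtype=object)
    out_names, out_w = zip(*_OUTPUT_CATEGORIES)
    in_names, in_w = zip(*_INPUT_CATEGORIES)
    out_p = np.array(out_w, float) / sum(out_w)
    in_p = np.array(in_w, float) / sum(in_w)
    for i in np.flatnonzero(eloquent):
        if rng.random() < spec.emotion_rate:
            cats[i] = "emotion"
        elif rng.random() < spec.prevalence_output:
            cats[i] = rng.choice(out_names, p=out_p)
        else:
            cats[i] = rng.choice(in_names, p=in_p)
    seizure = rng.random(n) < spec.seizure_onset_rate
    cols = int(math.ceil(math.sqrt(n)))
    xy = [(i % cols, i // cols) for i in range(n)]
    ids = [f"{patient_id}-E{i + 1:03d}" for i in range(n)]
    return ids, cats, seizure, xy


def _schedule_trials(rng, spec: CohortSpec):
    """Build the per-trial event schedule (seconds), interleaving active and
    passive trials in random order."""
    kinds = ["active"] * spec.trials_active + ["passive"] * spec.trials_passive
    rng.shuffle(kinds)
    trials = []
    t = 2.0  # lead-in margin
    for k, cond in enumerate(kinds):
        sound = t
        ev = {"sound": sound}
        if cond == "active":
            # +/- 3 sigma truncation, with a hard floor keeping letter- and
            # button-locked responses clear of the 0-0.9 s sound window
            letter = sound + _truncnorm(
                rng, spec.letter_latency, spec.letter_jitter,
                max(1.1, spec.letter_latency - 3 * spec.letter_jitter),
                spec.letter_latency + 3 * spec.letter_jitter)
            button = sound + _truncnorm(
                rng, spec.button_latency, spec.button_jitter,
                max((letter - sound) + 0.4,
                    spec.button_latency - 3 * spec.button_jitter),
                spec.button_latency + 3 * spec.button_jitter)
            ev["letter"] = letter
            ev["button"] = button
            t = button + max(0.5, spec.inter_trial_interval
                             + rng.uniform(-spec.iti_jitter, spec.iti_jitter))
        else:
            t = sound + 2.2 + max(0.3, spec.inter_trial_interval - 1.0
                                  + rng.uniform(-spec.iti_jitter, spec.iti_jitter))
        trials.append((k, cond, ev))
    total = t + 2.0  # tail margin
    return trials, total


def _truncnorm(rng, mean, sd, lo, hi):
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo < v < hi:
            return v
    return float(np.clip(mean, lo + 1e-6, hi - 1e-6))


def generate_cohort(spec: CohortSpec, seed: int | None = None):
    """Generate a cohort: recordings, electrode table, and ground truth.

    Deterministic given ``spec`` (and ``seed``, which overrides
    ``spec.seed`` when given).  Returns
    ``(recordings, electrode_table, ground_truth)`` where ``ground_truth``
    records the per-patient multipliers and per-electrode signed power-change
    effects actually used.
    """
    spec.validate()
    master = spec.seed if seed is None else seed
    recordings: list[CohortRecording] = []
    tabs = []
    truth: dict = {"patient_multiplier": {}, "bands": {
        b.band: {"direction": b.direction,
                 "effect_size_by_group": dict(b.effect_size_by_group),
                 "passive_scale": b.passive_scale}
        for b in spec.band_effects}}
    for p in range(spec.n_patients):
        pid = f"P{p + 1:02d}"
        rng = np.random.default_rng(child_seed(master, "patient", p))
        # dedicated stream: the patient's responsiveness multiplier is
        # invariant to electrode/trial counts (calibration replicas see the
        # same cohort-level heterogeneity)
        mult_rng = np.random.default_rng(child_seed(master, "patient-mult", p))
        patient_mult = float(np.exp(mult_rng.normal(0.0, spec.patient_sigma)))
        rec, tab, pt_truth = _generate_patient(rng, spec, pid, patient_mult)
        recordings.append(rec)
        tabs.append(tab)
        truth["patient_multiplier"][pid] = pt_truth["patient_multiplier"]
    electrodes = pd.concat(tabs, ignore_index=True)
    return recordings, electrodes, truth


def _generate_patient(rng, spec: CohortSpec, pid: str, patient_mult: float):
    rate = spec.sample_rate
    ids, cats, seizure, xy = _assign_electrodes(rng, spec, pid)
    tab = make_electrode_table(ids, [pid] * len(ids), cats,
                               seizure_onset=seizure, xy=xy)
    trials, total_s = _schedule_trials(rng, spec)
    n_samp = int(round(total_s * rate))
    n_el = len(ids)
    tvec = np.arange(n_samp) / rate

    gains = np.exp(rng.normal(0.0, spec.gain_spread_sigma, size=n_el))

    # per-electrode latent responsiveness factors shared across bands
    z_shared = rng.standard_normal(n_el)
    z_own = {b.band: rng.standard_normal(n_el) for b in spec.band_effects}

    # base event-kernel time course per band (shared across electrodes)
    group_of = tab.io_group.to_numpy()
    base_env = {}
    signed_effect = {}
    for b in spec.band_effects:
        env = np.zeros(n_samp)
        for _, cond, ev in trials:
            scale = b.passive_scale if cond == "passive" else 1.0
            if scale == 0.0:
                continue
            for kind, t_ev in ev.items():
                kern = b.event_kernel.get(kind)
                if kern is None or kern.amplitude == 0.0:
                    continue
                lo = max(0.0, t_ev + min(0.0, kern.latency) - 0.2)
                hi = min(total_s, t_ev + kern.support)
                i0, i1 = int(lo * rate), int(hi * rate)
                env[i0:i1] += (scale * kern.amplitude
                               * kern.evaluate(tvec[i0:i1] - t_ev))
        base_env[b.band] = env
        rho = b.latent_loading
        z = rho * z_shared + math.sqrt(max(0.0, 1.0 - rho ** 2)) * z_own[b.band]
        sigma_b = spec.electrode_sigma * b.latent_sigma_scale
        el_mult = np.exp(sigma_b * z - 0.5 * sigma_b ** 2)
        sizes = b.effect_size_by_group
        group_size = np.where(
            group_of == "non-eloquent", sizes["non_eloquent"],
            np.where(group_of == "output", sizes["output"], sizes["input"]))
        # emotion electrodes ("excluded" group) respond like input sites
        sign = 1.0 if b.direction == "increase" else -1.0
        signed_effect[b.band] = sign * group_size * patient_mult * el_mult

    # assemble traces in electrode chunks to bound memory
    traces = np.empty((n_el, n_samp), dtype=np.float32)
    chunk = max(1, int(8e6 // n_samp))
    line_wave = None
    if spec.line_noise_amplitude > 0:
        line_wave = np.sin(2 * np.pi * spec.line_freq * tvec).astype(np.float32)
        line_quad = np.cos(2 * np.pi * spec.line_freq * tvec).astype(np.float32)
    env32 = {b.band: base_env[b.band].astype(np.float32)
             for b in spec.band_effects}
    for lo in range(0, n_el, chunk):
        hi = min(n_el, lo + chunk)
        block = np.float32(spec.background_rms) * _one_over_f_noise(
            rng, hi - lo, n_samp, rate, spec.one_over_f_exponent)
        if line_wave is not None:
            phases = rng.uniform(0, 2 * np.pi, size=(hi - lo, 1))
            amp = np.float32(spec.line_noise_amplitude)
            block += amp * (np.cos(phases).astype(np.float32) * line_wave
                            + np.sin(phases).astype(np.float32) * line_quad)
        for b in spec.band_effects:
            carrier = _bandlimited_noise(rng, hi - lo, n_samp, rate,
                                         b.carrier_range)
            power_env = (1.0 + signed_effect[b.band][lo:hi, None].astype(
                np.float32) * env32[b.band][None, :])
            np.clip(power_env, 0.01, None, out=power_env)  # 0.1x amp floor
            carrier *= np.sqrt(power_env, out=power_env)
            block += np.float32(b.carrier_rms) * carrier
        block *= gains[lo:hi, None].astype(np.float32)
        traces[lo:hi] = block

    event_rows = []
    conditions = {}
    for trial_id, cond, ev in trials:
        conditions[trial_id] = cond
        for kind, t_ev in ev.items():
            event_rows.append((trial_id, kind, int(round(t_ev * rate))))
    events = pd.DataFrame(event_rows,
                          columns=["trial_id", "event_kind", "sample_index"])
    rec = CohortRecording(patient_id=pid, sample_rate=rate, traces=traces,
                          events=events, conditions=conditions)
    pt_truth = {"patient_multiplier": patient_mult}
    return rec, tab, pt_truth


# ---------------------------------------------------------------------------
# calibration of effect sizes to a target discriminability
# ---------------------------------------------------------------------------

def realized_single_band_aurocs(spec: CohortSpec, config: PipelineConfig,
                                seed: int) -> dict[str, float]:
    """Generate a cohort from ``spec`` and run it through the full
    preprocessing + feature chain, returning each band's realized
    ideal-observer discriminability (AUROC folded above 0.5)."""
    from .features import cohort_feature_matrix
    from .preprocess import preprocess_recording
    from .roc import auroc_value

    recordings, electrodes, _ = generate_cohort(spec, seed=seed)
    epochsets = [preprocess_recording(rec, config) for rec in recordings]
    feats = cohort_feature_matrix(epochsets, electrodes, config,
                                  mode="whole_trial", condition="active")
    labels = feats["eloquent"].to_numpy(dtype=bool)
    out = {}
    for band in config.bands:
        a = auroc_value(feats[band].to_numpy(dtype=float), labels)
        out[band] = max(a, 1.0 - a)
    return out


def calibrate_to_target_auroc(spec: CohortSpec, band: str, target: float,
                              tolerance: float = 0.02,
                              config: PipelineConfig | None = None,
                              eval_seed: int = 12345, max_iter: int = 10,
                              upper_factor: float = 4.0):
    """Binary-search the band's eloquent effect size so that the realized
    single-band AUROC (under a fixed evaluation seed) hits ``target``.

    Returns ``(adjusted_spec, achieved_auroc)``.  Raises
    :class:`CalibrationError` when the target is outside the attainable
    bracket.
    """
    specs, achieved = calibrate_bands(
        spec, {band: target}, tolerance=tolerance, config=config,
        eval_seed=eval_seed, max_iter=max_iter, upper_factor=upper_factor)
    return specs, achieved[band]


def calibrate_bands(spec: CohortSpec, targets: dict[str, float],
                    tolerance: float = 0.02,
                    config: PipelineConfig | None = None,
                    eval_seed: int = 12345, max_iter: int = 10,
                    upper_factor: float = 4.0):
    """Jointly calibrate several bands' eloquent effect sizes to target
    discriminabilities; one cohort generation per iteration updates every
    band's bisection bracket (the bands use separate carriers, so their
    single-band AUROCs respond nearly independently).
    """
    if config is None:
        config = PipelineConfig()
    for band, target in targets.items():
        if not 0.5 <= target < 1.0:
            raise ParameterError(f"target AUROC for {band} must be in [0.5, 1)")
        if band not in {b.band for b in spec.band_effects}:
            raise ParameterError(f"no band effect named {band!r} in the spec")

    # cap the search so a suppression band never exceeds 100% of baseline
    hi0 = {}
    for band in targets:
        b = next(x for x in spec.band_effects if x.band == band)
        peak = max(b.effect_size_by_group["input"], b.effect_size_by_group["output"])
        hi0[band] = (min(upper_factor, 0.98 / peak)
                     if b.direction == "suppress" else upper_factor)
    lo = {band: 0.0 for band in targets}       # AUROC 0.5 by construction
    hi = dict(hi0)
    factor = {band: min(1.0, hi[band]) for band in targets}

    def apply(fs: dict[str, float]) -> CohortSpec:
        s = spec
        for band, f in fs.items():
            s = s.scaled_effects(band, f)
        return s

    achieved = {}
    for it in range(max_iter):
        realized = realized_single_band_aurocs(apply(factor), config, eval_seed)
        done = True
        for band, target in targets.items():
            achieved[band] = realized[band]
            if abs(realized[band] - target) <= tolerance:
                continue
            done = False
            if realized[band] < target:
                lo[band] = factor[band]
            else:
                hi[band] = factor[band]
            if hi[band] - lo[band] < 1e-6 * max(hi0[band], 1.0):
                raise CalibrationError(
                    f"band {band}: target AUROC {target} unattainable; "
                    f"bracket factor [0, {hi0[band]:.3g}] tops out at "
                    f"{realized[band]:.3f}")
            factor[band] = 0.5 * (lo[band] + hi[band])
        logger.info("calibration iter %d: %s", it,
                    {k: round(v, 3) for k, v in achieved.items()})
        if done:
            break
    else:
        off = {b: achieved[b] for b in targets
               if abs(achieved[b] - targets[b]) > tolerance}
        if off:
            raise CalibrationError(
                f"calibration did not converge within {max_iter} iterations: "
                f"achieved {off}, brackets "
                f"{ {b: (lo[b], hi[b]) for b in off} }")
    return apply(factor), achieved
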