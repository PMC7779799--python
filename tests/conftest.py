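"""Shared fixtures: a small synthetic cohort exercised by most unit tests.

The cohort is deliberately tiny (2 patients, 16 electrodes, a dozen trials)
so the full raw-trace pipeline stays fast; statistical assertions that need
power build their own feature-level data instead.
"""

import numpy as np
import pandas as pd
import pytest

from ecogmap import (CohortRecording, CohortSpec, PipelineConfig,
                     cohort_feature_matrix, generate_cohort,
                     preprocess_recording)


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def tiny_cohort():
    spec = CohortSpec(n_patients=2, electrodes_per_patient=16,
                      trials_active=8, trials_passive=4,
                      prevalence_eloquent=0.35, seed=101)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_epochsets(tiny_cohort, config):
    recordings, _, _ = tiny_cohort
    return [preprocess_recording(rec, config) for rec in recordings]


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort, tiny_epochsets, config):
    _, electrodes, _ = tiny_cohort
    return cohort_feature_matrix(tiny_epochsets, electrodes, config,
                                 mode="whole_trial", condition="active")


def make_recording(patient_id="T01", rate=2048, n_electrodes=3, duration=20.0,
                   events=None, conditions=None, seed=0) -> CohortRecording:
    """Hand-built recording with sinusoid+noise traces for epoching tests."""
    rng = np.random.default_rng(seed)
    n = int(duration * rate)
    t = np.arange(n) / rate
    traces = (np.sin(2 * np.pi * 11.0 * t)[None, :]
              + 0.1 * rng.standard_normal((n_electrodes, n))).astype(np.float32)
    if events is None:
        events = [(0, "sound", int(2.0 * rate)),
                  (0, "letter", int(3.5 * rate)),
                  (0, "button", int(5.0 * rate))]
        conditions = {0: "active"}
    ev = pd.DataFrame(events, columns=["trial_id", "event_kind", "sample_index"])
    return CohortRecording(patient_id=patient_id, sample_rate=rate,
                           traces=traces, events=ev, conditions=conditions)
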