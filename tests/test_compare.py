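"""Bootstrap model comparison, subgroup analysis, attention contrast."""

import numpy as np
import pandas as pd
import pytest

from ecogmap import (ComparisonError, PairingError, attention_contrast,
                     bootstrap_auroc, paired_compare, subgroup_analysis,
                     PipelineConfig)


def _feature_frame(n=200, seed=0, prevalence=0.3, strong=1.4, weak=0.0):
    """Feature-level cohort: gamma informative, beta optionally informative,
    alpha pure noise."""
    rng = np.random.default_rng(seed)
    y = rng.random(n) < prevalence
    df = pd.DataFrame({
        "gamma": rng.normal(0, 1, n) + strong * y,
        "beta": rng.normal(0, 1, n) - weak * y,
        "alpha": rng.normal(0, 1, n),
        "eloquent": y,
        "patient_id": np.repeat([f"P{i}" for i in range(4)], n // 4),
    })
    return df


def test_duplicate_models_are_symmetric_and_not_significant():
    df = _feature_frame(seed=1)
    ev = bootstrap_auroc(df, df.eloquent, {"a": ("gamma",), "b": ("gamma",)},
                         B=200, seed=0, k=5, original_cv_repeats=2)
    comp = paired_compare(ev, reference="a")[0]
    assert comp.mean_pct_change == pytest.approx(0.0, abs=1e-9)
    assert 0.4 <= comp.frac_improved <= 0.6
    assert not comp.significant


def test_dominating_model_is_significant():
    df = _feature_frame(seed=2, strong=1.2, weak=1.2)
    ev = bootstrap_auroc(
        df, df.eloquent,
        {"gamma": ("gamma",), "both": ("gamma", "beta")},
        B=200, seed=0, k=5, original_cv_repeats=2)
    comp = paired_compare(ev, reference="gamma")[0]
    assert comp.frac_improved >= 0.95 and comp.significant
    assert comp.mean_pct_change > 0


def test_b_too_small_rejected():
    df = _feature_frame()
    with pytest.raises(ComparisonError, match="coarse"):
        bootstrap_auroc(df, df.eloquent, {"g": ("gamma",)}, B=10, seed=0)


def test_percent_change_matches_brute_force():
    df = _feature_frame(seed=3)
    ev = bootstrap_auroc(df, df.eloquent,
                         {"g": ("gamma",), "gb": ("gamma", "beta")},
                         B=200, seed=5, k=5, original_cv_repeats=1)
    comps = paired_compare(ev, reference="g")
    g = ev.distributions["g"]
    gb = ev.distributions["gb"]
    manual = 100.0 * (gb - g) / g
    np.testing.assert_allclose(comps[0].pct_change, manual, rtol=1e-12)
    assert comps[0].mean_pct_change == pytest.approx(manual.mean(), rel=1e-12)
    assert comps[0].frac_improved == pytest.approx(
        np.mean(gb > g) + 0.5 * np.mean(gb == g), abs=1e-12)


def test_shuffled_resample_order_raises_pairing_error():
    df = _feature_frame(seed=4)
    ev = bootstrap_auroc(df, df.eloquent, {"a": ("gamma",), "b": ("beta",)},
                         B=150, seed=0, k=5, original_cv_repeats=1)
    rng = np.random.default_rng(0)
    perm = rng.permutation(150)
    ev.distributions["b"] = ev.distributions["b"][perm]
    ev.resample_order["b"] = ev.resample_order["b"][perm]
    with pytest.raises(PairingError):
        paired_compare(ev, reference="a")


def test_reproducible_given_seed():
    df = _feature_frame(seed=6)
    kw = dict(B=120, seed=9, k=5, original_cv_repeats=1)
    ev1 = bootstrap_auroc(df, df.eloquent, {"g": ("gamma",)}, **kw)
    ev2 = bootstrap_auroc(df, df.eloquent, {"g": ("gamma",)}, **kw)
    np.testing.assert_array_equal(ev1.distributions["g"],
                                  ev2.distributions["g"])


def test_equal_models_rarely_declared_significant():
    """Null calibration: structurally identical models cross the 95%
    consistency threshold in well under 10% of independent runs."""
    n_sig = 0
    runs = 15
    for s in range(runs):
        df = _feature_frame(seed=100 + s, n=160)
        ev = bootstrap_auroc(df, df.eloquent,
                             {"a": ("gamma",), "b": ("gamma",)},
                             B=150, seed=s, k=5, original_cv_repeats=1)
        n_sig += paired_compare(ev, reference="a")[0].significant
    assert n_sig <= max(1, int(0.1 * runs))


# ---------------------------------------------------------------------------
# subgroups
# ---------------------------------------------------------------------------

def _grouped_frame(n_in=40, n_out=40, n_non=160, n_emotion=0, seed=0,
                   beta_out=1.5):
    rng = np.random.default_rng(seed)
    rows = []
    for grp, count in (("input", n_in), ("output", n_out),
                       ("non-eloquent", n_non), ("excluded", n_emotion)):
        for _ in range(count):
            eloquent = grp != "non-eloquent"
            beta_shift = -beta_out if grp == "output" else 0.0
            gamma_shift = 1.0 if eloquent else 0.0
            rows.append({
                "io_group": grp, "eloquent": eloquent,
                "gamma": rng.normal(gamma_shift, 1),
                "beta": rng.normal(beta_shift, 1),
                "alpha": rng.normal(0, 1),
                "patient_id": "P1",
            })
    return pd.DataFrame(rows)


def test_subgroup_analysis_structure_and_ordering(config):
    df = _grouped_frame(seed=1, n_emotion=2)
    cfg = PipelineConfig(n_folds=5, n_cv_repeats=2)
    out = subgroup_analysis(df, config=cfg, seed=0, B=120)
    assert set(out) == {"input", "output"}
    # emotion electrodes enter neither evaluation
    assert out["input"].n_electrodes == 40 + 160
    assert out["output"].n_electrodes == 40 + 160
    # beta suppression concentrated in the output group: beta beats alpha
    assert (out["output"].auroc_original["beta"]
            > out["output"].auroc_original["alpha"])


def test_subgroup_with_empty_group_is_skipped(config):
    df = _grouped_frame(n_out=0, seed=2)
    cfg = PipelineConfig(n_folds=5, n_cv_repeats=1)
    out = subgroup_analysis(df, config=cfg, seed=0, B=120)
    assert set(out) == {"input"}


# ---------------------------------------------------------------------------
# attention contrast
# ---------------------------------------------------------------------------

def test_attention_contrast_detects_attenuation():
    act = _feature_frame(seed=7, n=240, strong=1.5)
    pas = act.copy()
    rng = np.random.default_rng(8)
    pas["gamma"] = rng.normal(0, 1, len(pas)) + 0.2 * pas.eloquent
    cfg = PipelineConfig(n_folds=5, n_cv_repeats=2)
    out = attention_contrast(act, pas, model_sets={"gamma": ("gamma",)},
                             config=cfg, seed=0, B=200)
    c = out["gamma"]
    assert c.auroc_passive < c.auroc_active
    assert c.mean_pct_change < 0
    assert c.frac_worse_in_passive >= 0.95 and c.significant
    assert c.p5 <= c.mean_pct_change <= c.p95


def test_attention_contrast_requires_matching_electrodes():
    act = _feature_frame(seed=9)
    with pytest.raises(PairingError, match="size"):
        attention_contrast(act, act.iloc[:-2],
                           model_sets={"g": ("gamma",)})
    pas = act.copy()
    pas["electrode_id"] = np.arange(len(pas))
    act2 = act.copy()
    act2["electrode_id"] = np.arange(len(act))[::-1]
    with pytest.raises(PairingError, match="electrodes"):
        attention_contrast(act2, pas, model_sets={"g": ("gamma",)})
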