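"""Paired bootstrap model comparison, function-specific (input/output)
subgroup analysis, and the active-vs-passive attention contrast.

Model comparison resamples electrodes with replacement (B datasets of the
original size), computes every model's cross-validated AUROC on the *same*
resample, and summarizes each model against a reference (gamma-only by
default) as the per-resample percent change.  A difference is called
significant when at least 95% of resamples agree in direction — the
threshold implied by treating 98% consistency as significant and 94% as not.
Resamples that lose a class are redrawn (and counted), since AUROC is
undefined on a single class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MODEL_BATTERY, PipelineConfig, child_seed
from .glm import FitError, crossval_auroc
from .roc import auroc_value

logger = logging.getLogger("ecogmap")


class ComparisonError(ValueError):
    """Ill-posed comparison request."""


class PairingError(ComparisonError):
    """Distributions do not share resample indices."""


@dataclass
class BootstrapComparison:
    """Paired summary of one model against a reference."""

    model: str
    reference: str
    pct_change: np.ndarray          # per-resample 100 * (A - A_ref) / A_ref
    mean_pct_change: float
    frac_improved: float
    significant: bool


@dataclass
class ModelEvaluation:
    """Per-model AUROC on the original data plus bootstrap distributions
    sharing one set of resamples."""

    model_names: list[str]
    auroc_original: dict[str, float]
    distributions: dict[str, np.ndarray]
    resample_order: dict[str, np.ndarray]
    n_electrodes: int
    n_redrawn: int = 0
    comparisons: list[BootstrapComparison] = field(default_factory=list)


def _resample_indices(rng, labels: np.ndarray, B: int, min_class: int = 1):
    """B with-replacement electrode resamples.

    Resamples whose minority class drops below ``min_class`` (at least 1;
    callers pass the fold count so stratified CV stays feasible) are redrawn
    and counted.
    """
    n = len(labels)
    out = np.empty((B, n), dtype=int)
    n_redrawn = 0
    for b in range(B):
        for _ in range(1000):
            idx = rng.integers(0, n, size=n)
            pos = int(labels[idx].sum())
            if min(pos, n - pos) >= max(1, min_class):
                break
            n_redrawn += 1
        else:
            raise ComparisonError(
                "could not draw a resample with both classes represented")
        out[b] = idx
    if n_redrawn:
        logger.info("redrew %d class-degenerate bootstrap resample(s)",
                    n_redrawn)
    return out, n_redrawn


def bootstrap_auroc(features, labels, model_sets: dict[str, tuple[str, ...]],
                    B: int = 1000, seed: int = 0, k: int = 10,
                    cv_repeats: int = 1, original_cv_repeats: int = 20,
                    ) -> ModelEvaluation:
    """Bootstrap AUROC distributions for several band sets on one dataset.

    Every model is evaluated on the same B electrode resamples with 10-fold
    cross-validation (``cv_repeats`` inner repeats; the original, unresampled
    dataset uses ``original_cv_repeats``).  Deterministic given ``seed``.
    """
    if B < 100:
        raise ComparisonError(
            f"B = {B} is too coarse for 2.5/97.5 percentile use (need >= 100)")
    if isinstance(features, pd.DataFrame):
        X = features
    else:
        X = pd.DataFrame(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=bool).ravel()
    if not (y.any() and not y.all()):
        raise ComparisonError("original data must contain both classes")
    rng = np.random.default_rng(child_seed(seed, "resample"))
    idx, n_redrawn = _resample_indices(rng, y, B, min_class=k)
    auroc_original = {}
    dists = {name: np.empty(B) for name in model_sets}
    for name, bands in model_sets.items():
        Xb = X[list(bands)].to_numpy(dtype=float)
        auroc_original[name] = crossval_auroc(
            Xb, y, k=k, repeats=original_cv_repeats,
            seed=child_seed(seed, "orig", name))
        for b in range(B):
            dists[name][b] = crossval_auroc(
                Xb[idx[b]], y[idx[b]], k=k, repeats=cv_repeats,
                seed=child_seed(seed, "boot", b))
    order = np.arange(B)
    return ModelEvaluation(
        model_names=list(model_sets),
        auroc_original=auroc_original,
        distributions=dists,
        resample_order={name: order.copy() for name in model_sets},
        n_electrodes=len(y), n_redrawn=n_redrawn)


def paired_compare(evaluation: ModelEvaluation, reference: str = "gamma",
                   consistency: float = 0.95,
                   pct_method: str = "per_resample",
                   ) -> list[BootstrapComparison]:
    """Percent-change summaries of every model against ``reference``.

    ``pct_method="per_resample"`` averages the per-resample percent changes
    (the paired convention); ``"of_means"`` reports the percent change of the
    distribution means.  Significance = directional consistency of at least
    ``consistency`` of resamples.  Raises :class:`PairingError` when a
    model's resample order differs from the reference's.
    """
    if reference not in evaluation.distributions:
        raise ComparisonError(f"no reference model {reference!r}")
    ref = evaluation.distributions[reference]
    ref_order = evaluation.resample_order[reference]
    out = []
    for name in evaluation.model_names:
        if name == reference:
            continue
        dist = evaluation.distributions[name]
        if (len(dist) != len(ref)
                or not np.array_equal(evaluation.resample_order[name],
                                      ref_order)):
            raise PairingError(
                f"model {name!r} does not share resample indices with "
                f"{reference!r}")
        pct = 100.0 * (dist - ref) / ref
        frac = float(np.mean(dist > ref) + 0.5 * np.mean(dist == ref))
        mean_pct = (float(pct.mean()) if pct_method == "per_resample"
                    else float(100.0 * (dist.mean() - ref.mean()) / ref.mean()))
        out.append(BootstrapComparison(
            model=name, reference=reference, pct_change=pct,
            mean_pct_change=mean_pct, frac_improved=frac,
            significant=bool(frac >= consistency or frac <= 1.0 - consistency)))
    evaluation.comparisons = out
    return out


def evaluate_models(features, labels, model_sets=None, reference="gamma",
                    config: PipelineConfig | None = None, seed=None,
                    B=None) -> ModelEvaluation:
    """Bootstrap the full model battery and attach pairwise comparisons."""
    if config is None:
        config = PipelineConfig()
    if model_sets is None:
        model_sets = MODEL_BATTERY
    ev = bootstrap_auroc(
        features, labels, model_sets,
        B=config.n_bootstrap if B is None else B,
        seed=config.rng_seed if seed is None else seed,
        k=config.n_folds, cv_repeats=config.bootstrap_cv_repeats,
        original_cv_repeats=config.n_cv_repeats)
    if reference in model_sets:
        paired_compare(ev, reference=reference,
                       consistency=config.significance_consistency)
    return ev


# ---------------------------------------------------------------------------
# subgroup (input/output) analysis
# ---------------------------------------------------------------------------

def subgroup_analysis(features: pd.DataFrame, model_sets=None,
                      config: PipelineConfig | None = None,
                      seed: int | None = None, B: int | None = None,
                      ) -> dict[str, ModelEvaluation]:
    """Input-eloquent vs non-eloquent and output-eloquent vs non-eloquent
    evaluations of the full model battery.

    ``features`` must carry ``io_group`` and ``eloquent`` columns; emotion
    electrodes (io_group ``"excluded"``) enter neither group.  Empty groups
    are skipped with a warning.
    """
    if config is None:
        config = PipelineConfig()
    if "io_group" not in features.columns:
        raise ComparisonError("features lack an io_group column")
    out = {}
    non_eloquent = features[features.io_group == "non-eloquent"]
    for group in ("input", "output"):
        members = features[features.io_group == group]
        if not len(members):
            logger.warning("subgroup %s: no electrodes; skipped", group)
            continue
        sub = pd.concat([members, non_eloquent], ignore_index=True)
        labels = sub["eloquent"].to_numpy(dtype=bool)
        out[group] = evaluate_models(
            sub, labels, model_sets=model_sets, config=config,
            seed=child_seed(config.rng_seed if seed is None else seed,
                            "subgroup", group),
            B=B)
    return out


# ---------------------------------------------------------------------------
# attention (active vs passive) contrast
# ---------------------------------------------------------------------------

@dataclass
class AttentionContrast:
    model: str
    auroc_active: float
    auroc_passive: float
    pct_change: np.ndarray          # per-resample 100 * (A_pass - A_act)/A_act
    mean_pct_change: float
    p5: float
    p95: float
    frac_worse_in_passive: float
    significant: bool


def attention_contrast(features_active: pd.DataFrame,
                       features_passive: pd.DataFrame,
                       model_sets=None, config: PipelineConfig | None = None,
                       seed: int | None = None, B: int | None = None,
                       k: int | None = None,
                       ) -> dict[str, AttentionContrast]:
    """Paired active-vs-passive comparison per model.

    Both feature tables must describe the same electrodes in the same order
    (0-900 ms post-sound features, the only window shared by the two
    conditions).  Negative percent change means worse performance in the
    passive condition.  Significance = 95% directional consistency across
    paired bootstrap resamples; 5/95 percentile intervals are attached.
    """
    if config is None:
        config = PipelineConfig()
    if model_sets is None:
        model_sets = MODEL_BATTERY
    if len(features_active) != len(features_passive):
        raise PairingError("active and passive feature sets differ in size")
    if ("electrode_id" in features_active.columns
            and "electrode_id" in features_passive.columns):
        if not (features_active.electrode_id.to_numpy()
                == features_passive.electrode_id.to_numpy()).all():
            raise PairingError(
                "active and passive feature sets cover different electrodes")
    labels = features_active["eloquent"].to_numpy(dtype=bool)
    if "eloquent" in features_passive.columns:
        if not (features_passive["eloquent"].to_numpy(dtype=bool)
                == labels).all():
            raise PairingError("eloquence labels disagree between conditions")
    seed = config.rng_seed if seed is None else seed
    B = config.n_bootstrap if B is None else B
    k = config.n_folds if k is None else k
    if B < 100:
        raise ComparisonError(f"B = {B} too coarse (need >= 100)")
    rng = np.random.default_rng(child_seed(seed, "attention"))
    idx, _ = _resample_indices(rng, labels, B, min_class=k)
    out = {}
    for name, bands in model_sets.items():
        Xa = features_active[list(bands)].to_numpy(dtype=float)
        Xp = features_passive[list(bands)].to_numpy(dtype=float)
        a_act = crossval_auroc(Xa, labels, k=k, repeats=config.n_cv_repeats,
                               seed=child_seed(seed, "att-orig", name, 0))
        a_pas = crossval_auroc(Xp, labels, k=k, repeats=config.n_cv_repeats,
                               seed=child_seed(seed, "att-orig", name, 1))
        d_act = np.empty(B)
        d_pas = np.empty(B)
        for b in range(B):
            sub_labels = labels[idx[b]]
            cv_seed = child_seed(seed, "att-boot", b)
            d_act[b] = crossval_auroc(Xa[idx[b]], sub_labels, k=k,
                                      repeats=config.bootstrap_cv_repeats,
                                      seed=cv_seed)
            d_pas[b] = crossval_auroc(Xp[idx[b]], sub_labels, k=k,
                                      repeats=config.bootstrap_cv_repeats,
                                      seed=cv_seed)
        pct = 100.0 * (d_pas - d_act) / d_act
        frac_worse = float(np.mean(d_pas < d_act)
                           + 0.5 * np.mean(d_pas == d_act))
        cons = config.significance_consistency
        out[name] = AttentionContrast(
            model=name, auroc_active=a_act, auroc_passive=a_pas,
            pct_change=pct, mean_pct_change=float(pct.mean()),
            p5=float(np.percentile(pct, 5)), p95=float(np.percentile(pct, 95)),
            frac_worse_in_passive=frac_worse,
            significant=bool(frac_worse >= cons or frac_worse <= 1.0 - cons))
    return out
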