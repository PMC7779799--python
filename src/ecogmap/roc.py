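"""Tie-corrected AUROC, the signed display convention, permutation nulls,
and sliding-window AUROC time courses.

AUROC is computed with the rank (Mann-Whitney) formulation — the probability
that a randomly chosen eloquent electrode's score exceeds a randomly chosen
non-eloquent one, counting ties as 1/2 — which equals the trapezoidal area
under the ROC curve.  For display, bands whose discriminative power comes
from *suppression* (eloquent power below non-eloquent, as for alpha/beta
desynchronization) are shown below 0.5, so the plotted value carries the sign
of the underlying power change; model fitting always consumes raw features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import child_seed


class RocError(ValueError):
    """Undefined or ill-parameterized ROC computation."""


@dataclass
class AurocResult:
    auroc: float
    signed_auroc: float
    n_pos: int
    n_neg: int
    permutation_bounds: tuple[float, float] | None = None
    significant: bool | None = None


def auroc_value(scores, labels) -> float:
    """Rank-based AUROC of ``scores`` against boolean ``labels``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise RocError("scores and labels must be matching 1-D arrays")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise RocError(
            f"AUROC undefined with a single class ({n_pos} positive, "
            f"{n_neg} negative)")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def signed_display(auroc: float, mean_effect_sign: float) -> float:
    """Map an AUROC to the display convention: suppression-driven
    discriminability (eloquent mean below non-eloquent) is shown below 0.5,
    increases are left untouched."""
    if mean_effect_sign < 0:
        return 1.0 - auroc if auroc > 0.5 else auroc
    return auroc


def auroc(scores, labels, n_perm: int | None = None,
          seed: int | None = None) -> AurocResult:
    """Full AUROC diagnostic for one feature.

    The signed display value is below 0.5 when the eloquent-class mean is
    below the non-eloquent mean (power suppression).  With ``n_perm`` the
    two-sided permutation test at the 2.5/97.5 percentiles is attached.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    a = auroc_value(scores, labels)
    sign = float(scores[labels].mean() - scores[~labels].mean())
    res = AurocResult(auroc=a, signed_auroc=signed_display(a, sign),
                      n_pos=int(labels.sum()), n_neg=int((~labels).sum()))
    if n_perm is not None:
        lo, hi, sig = permutation_null(scores, labels, n_perm, seed=seed)
        res.permutation_bounds = (lo, hi)
        res.significant = sig
    return res


def permutation_null(scores, labels, n_perm: int = 1000,
                     seed: int | None = None,
                     observed: float | None = None):
    """Label-shuffling null distribution of the AUROC.

    Returns ``(p2.5, p97.5, significant)`` where significance means the
    observed AUROC falls outside the central 95% of the permutation
    distribution (two-sided, uncorrected).
    """
    if n_perm < 200:
        raise RocError(f"n_perm must be >= 200 for 2.5/97.5 percentile use, "
                       f"got {n_perm}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if observed is None:
        observed = auroc_value(scores, labels)
    n = len(scores)
    n_pos = int(labels.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise RocError("permutation null undefined with a single class")
    ranks = stats.rankdata(scores)
    rng = np.random.default_rng(seed)
    # a label shuffle only re-selects which ranks count as positive
    perm = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_pos]
    u = ranks[perm].sum(axis=1) - n_pos * (n_pos + 1) / 2.0
    null = u / (n_pos * n_neg)
    lo, hi = np.percentile(null, [2.5, 97.5])
    significant = bool(observed < lo or observed > hi)
    return float(lo), float(hi), significant


def frequency_wise_auroc(feature_by_freq: np.ndarray, freqs, labels,
                         n_perm: int = 1000, seed: int = 0):
    """Per-frequency signed AUROC with uncorrected two-sided permutation
    tests; ``feature_by_freq`` is ``electrodes x frequencies``."""
    labels = np.asarray(labels, dtype=bool)
    rows = []
    for i, f in enumerate(np.asarray(freqs)):
        res = auroc(feature_by_freq[:, i], labels, n_perm=n_perm,
                    seed=child_seed(seed, "freq", i))
        rows.append((float(f), res))
    return rows


def sliding_auroc(time_courses: np.ndarray, times: np.ndarray, labels,
                  window: float = 0.100, step: float = 0.050):
    """AUROC time series over sliding windows.

    ``time_courses`` is ``electrodes x time`` (per-electrode feature time
    courses on a common axis); each window's feature is the within-window
    mean.  Returns ``(window_centers, auroc_series)``.
    """
    time_courses = np.asarray(time_courses, dtype=float)
    times = np.asarray(times, dtype=float)
    if time_courses.shape[-1] != times.shape[0]:
        raise RocError("time axis mismatch between courses and times")
    dt = float(np.median(np.diff(times)))
    w = max(1, int(round(window / dt)))
    s = max(1, int(round(step / dt)))
    n = time_courses.shape[-1]
    if w > n:
        raise RocError(f"window ({w} samples) longer than the segment ({n})")
    n_win = (n - w) // s + 1
    centers = np.empty(n_win)
    series = np.empty(n_win)
    for i in range(n_win):
        sl = slice(i * s, i * s + w)
        centers[i] = times[sl].mean()
        series[i] = auroc_value(time_courses[:, sl].mean(axis=-1), labels)
    return centers, series
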