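"""Leave-one-patient-out probabilistic eloquence maps and calibration bins.

For every patient, a beta&gamma combiner is fitted on all *other* patients'
electrodes and applied to the held-out patient, so each electrode's predicted
probability of a positive ESM outcome uses no information from its own
patient — the situation of a new patient mapped before stimulation.  The map
carries per-patient summaries (mean +/- SD predicted probability among
ESM-positive and ESM-negative electrodes; a per-patient AUROC only where
both classes have at least two electrodes) and one cohort AUROC pooled over
all out-of-patient predictions.

The calibration curve bins electrodes by predicted probability into 10
equally spaced, 50%-overlapping bins over the observed prediction range and
reports each bin's electrode count and empirical eloquence proportion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .glm import FitError, fit_glm
from .roc import RocError, auroc_value

logger = logging.getLogger("ecogmap")


class MapError(ValueError):
    """Ill-posed eloquence-map request."""


@dataclass
class EloquenceMap:
    """Out-of-patient predictions with per-patient and cohort summaries.

    ``electrodes`` columns: patient_id, electrode_id, probability, eloquent,
    seizure_onset, x, y.  ``per_patient`` maps patient id to mean/SD per
    class and an optional AUROC.
    """

    electrodes: pd.DataFrame
    per_patient: dict[str, dict]
    cohort_auroc: float | None
    band_set: tuple[str, ...]


@dataclass
class CalibrationCurve:
    centers: np.ndarray
    counts: np.ndarray
    proportions: np.ndarray   # NaN where masked (fewer than min_count)
    prevalence: float
    bin_width: float


def leave_one_patient_out(features: pd.DataFrame,
                          band_set: tuple[str, ...] = ("beta", "gamma"),
                          ) -> EloquenceMap:
    """Build the probabilistic eloquence map by patient-wise hold-out.

    ``features`` needs ``patient_id``, ``eloquent`` and the band columns
    (plus optional ``electrode_id``, ``seizure_onset``, ``x``, ``y`` carried
    through).  Raises :class:`MapError` with the offending patient when a
    training fold is single-class.
    """
    for col in ("patient_id", "eloquent", *band_set):
        if col not in features.columns:
            raise MapError(f"features lack a {col!r} column")
    patients = list(dict.fromkeys(features.patient_id))
    if len(patients) < 2:
        raise MapError("leave-one-patient-out needs at least 2 patients")
    prob = np.full(len(features), np.nan)
    y_all = features["eloquent"].to_numpy(dtype=bool)
    X_all = features[list(band_set)].to_numpy(dtype=float)
    pid_col = features.patient_id.to_numpy()
    n_folds_fit = 0
    for pid in patients:
        test = pid_col == pid
        train = ~test
        y_train = y_all[train]
        if y_train.all() or not y_train.any():
            logger.warning(
                "training set single-class when holding out patient %s; "
                "no predictions for this patient", pid)
            continue
        try:
            model = fit_glm(X_all[train], y_train, bands=band_set)
        except FitError as exc:
            raise MapError(f"fold for patient {pid}: {exc}") from exc
        prob[test] = model.predict(X_all[test])
        n_folds_fit += 1
    if n_folds_fit == 0:
        raise MapError("training set single-class for every patient fold")

    cols = {"patient_id": pid_col, "probability": prob, "eloquent": y_all}
    for opt in ("electrode_id", "seizure_onset", "x", "y"):
        if opt in features.columns:
            cols[opt] = features[opt].to_numpy()
    table = pd.DataFrame(cols)
    order = ["patient_id", "electrode_id", "probability", "eloquent",
             "seizure_onset", "x", "y"]
    table = table[[c for c in order if c in table.columns]]

    per_patient: dict[str, dict] = {}
    for pid in patients:
        sub = table[table.patient_id == pid]
        sub = sub[np.isfinite(sub.probability)]
        p_elo = sub.probability[sub.eloquent].to_numpy()
        p_non = sub.probability[~sub.eloquent].to_numpy()
        entry = {
            "n": int(len(sub)),
            "eloquent_mean": float(p_elo.mean()) if p_elo.size else None,
            "eloquent_sd": float(p_elo.std(ddof=0)) if p_elo.size else None,
            "non_eloquent_mean": float(p_non.mean()) if p_non.size else None,
            "non_eloquent_sd": float(p_non.std(ddof=0)) if p_non.size else None,
            "auroc": None,
        }
        if p_elo.size >= 2 and p_non.size >= 2:
            entry["auroc"] = auroc_value(
                sub.probability.to_numpy(), sub.eloquent.to_numpy(dtype=bool))
        per_patient[str(pid)] = entry
    ok = np.isfinite(prob)
    try:
        cohort_auroc = auroc_value(prob[ok], y_all[ok])
    except RocError:
        cohort_auroc = None
    return EloquenceMap(electrodes=table, per_patient=per_patient,
                        cohort_auroc=cohort_auroc, band_set=tuple(band_set))


def calibration_bins(emap: EloquenceMap | pd.DataFrame, n_bins: int = 10,
                     min_count: int = 3) -> CalibrationCurve:
    """Relate predicted probability to the empirical eloquence proportion.

    Bins span the observed prediction range with 50% overlap (bin width w,
    stride w/2, so ``n_bins`` bins tile the range); bins with fewer than
    ``min_count`` electrodes are masked.
    """
    table = emap.electrodes if isinstance(emap, EloquenceMap) else emap
    prob = table["probability"].to_numpy(dtype=float)
    labels = table["eloquent"].to_numpy(dtype=bool)
    if len(prob) < 20:
        raise MapError(f"need at least 20 electrodes, got {len(prob)}")
    lo, hi = float(prob.min()), float(prob.max())
    if hi <= lo:
        raise MapError("degenerate prediction range (all predictions equal)")
    span = hi - lo
    width = span / (0.5 * (n_bins - 1) + 1.0)
    stride = width / 2.0
    centers = np.empty(n_bins)
    counts = np.empty(n_bins, dtype=int)
    props = np.full(n_bins, np.nan)
    for i in range(n_bins):
        start = lo + i * stride
        stop = start + width
        centers[i] = start + width / 2.0
        if i == n_bins - 1:
            sel = (prob >= start) & (prob <= stop + 1e-12)
        else:
            sel = (prob >= start) & (prob < stop)
        counts[i] = int(sel.sum())
        if counts[i] >= min_count:
            props[i] = float(labels[sel].mean())
    return CalibrationCurve(centers=centers, counts=counts, proportions=props,
                            prevalence=float(labels.mean()), bin_width=width)


def render_map(emap: EloquenceMap, out_dir) -> list[Path]:
    """Write per-patient planar map files.

    Always writes the electrode TSV; when layout coordinates are present, a
    schematic grid figure per patient is written too (dot color = predicted
    probability, center marker = ESM label, red ring = seizure onset), with
    the per-patient mean +/- SD per class and AUROC in the title.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    tsv = out_dir / "eloquence_map.tsv"
    emap.electrodes.to_csv(tsv, sep="\t", index=False)
    written.append(tsv)
    has_layout = ("x" in emap.electrodes.columns
                  and np.isfinite(emap.electrodes["x"].to_numpy(float)).all()
                  and "y" in emap.electrodes.columns
                  and np.isfinite(emap.electrodes["y"].to_numpy(float)).all())
    if not has_layout:
        logger.warning("no layout coordinates; TSV-only map output")
        return written
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for pid, sub in emap.electrodes.groupby("patient_id", sort=False):
        fig, ax = plt.subplots(figsize=(5, 4))
        sc = ax.scatter(sub.x, sub.y, c=sub.probability, cmap="Reds",
                        vmin=0.0, vmax=max(0.5, float(sub.probability.max())),
                        s=220, edgecolors="gray")
        elo = sub[sub.eloquent.astype(bool)]
        non = sub[~sub.eloquent.astype(bool)]
        ax.scatter(elo.x, elo.y, c="black", s=25, zorder=3)
        ax.scatter(non.x, non.y, c="white", s=25, edgecolors="black",
                   linewidths=0.5, zorder=3)
        if "seizure_onset" in sub.columns:
            soz = sub[sub.seizure_onset.astype(bool)]
            ax.scatter(soz.x, soz.y, facecolors="none", edgecolors="red",
                       s=340, linewidths=1.6, zorder=4)
        info = emap.per_patient.get(str(pid), {})
        bits = []
        if info.get("eloquent_mean") is not None:
            bits.append(f"eloq {info['eloquent_mean']:.2f}"
                        f"±{info['eloquent_sd']:.2f}")
        if info.get("non_eloquent_mean") is not None:
            bits.append(f"non-eloq {info['non_eloquent_mean']:.2f}"
                        f"±{info['non_eloquent_sd']:.2f}")
        if info.get("auroc") is not None:
            bits.append(f"AUROC {info['auroc']:.2f}")
        ax.set_title(f"{pid}  " + "  ".join(bits), fontsize=9)
        ax.set_aspect("equal")
        ax.invert_yaxis()
        fig.colorbar(sc, ax=ax, label="P(eloquent)")
        path = out_dir / f"map_{pid}.png"
        fig.savefig(path, dpi=110, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
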