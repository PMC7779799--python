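"""Cohort container, electrode table, and results serialization.

A *cohort* is a directory with one HDF5 file per patient holding the raw
voltage traces (``/traces``, float32, electrodes x samples, with a
``sample_rate`` attribute), one JSON sidecar per patient with the event and
condition tables, and a single ``electrodes.tsv`` describing every electrode
(identity, ESM category, eloquence label, input/output group, seizure-onset
flag, optional planar layout coordinates).

ESM categories follow the clinical labels; the input/output grouping is the
fixed partition used for the function-specific analysis:

* input  — auditory, visual, sensory, language-Wernicke, language-temporobasal
* output — motor, mixed-sensorimotor, language-Broca
* excluded — emotion (does not fit either role)
* non-eloquent — ESM negative
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger("ecogmap")

EVENT_KINDS = ("sound", "letter", "button")

ESM_CATEGORIES = (
    "sensory", "motor", "mixed-sensorimotor", "language-Wernicke",
    "language-Broca", "language-temporobasal", "auditory", "visual",
    "emotion", "non-eloquent",
)

#: Fixed ESM-category -> input/output partition.
IO_GROUP_OF_CATEGORY = {
    "auditory": "input",
    "visual": "input",
    "sensory": "input",
    "language-Wernicke": "input",
    "language-temporobasal": "input",
    "motor": "output",
    "mixed-sensorimotor": "output",
    "language-Broca": "output",
    "emotion": "excluded",
    "non-eloquent": "non-eloquent",
}

ELECTRODE_COLUMNS = [
    "electrode_id", "patient_id", "esm_category", "eloquent", "io_group",
    "seizure_onset", "x", "y",
]


class CohortFormatError(ValueError):
    """Malformed cohort container (missing files, wrong schema)."""


class CohortIntegrityError(ValueError):
    """Container parses but violates a structural invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CohortRecording:
    """Raw multichannel recording of one patient with trial event markers.

    ``events`` has columns ``trial_id, event_kind, sample_index`` (0-based
    sample indices into ``traces``); ``conditions`` maps each trial to
    ``"active"`` or ``"passive"``.
    """

    patient_id: str
    sample_rate: int
    traces: np.ndarray              # electrodes x samples, microvolts
    events: pd.DataFrame
    conditions: dict[int, str]
    excluded_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces)
        if self.excluded_flags is None:
            self.excluded_flags = np.zeros(self.traces.shape[0], dtype=bool)
        self.excluded_flags = np.asarray(self.excluded_flags, dtype=bool)
        self.validate()

    @property
    def n_electrodes(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    def validate(self) -> None:
        if self.sample_rate <= 0 or int(self.sample_rate) != self.sample_rate:
            raise CohortIntegrityError(
                f"patient {self.patient_id}: sample_rate must be a positive "
                f"integer, got {self.sample_rate}")
        if self.traces.ndim != 2:
            raise CohortIntegrityError(
                f"patient {self.patient_id}: traces must be 2-D "
                f"(electrodes x samples)")
        if len(self.excluded_flags) != self.n_electrodes:
            raise CohortIntegrityError(
                f"patient {self.patient_id}: excluded_flags length "
                f"{len(self.excluded_flags)} != {self.n_electrodes} electrodes")
        ev = self.events
        required = {"trial_id", "event_kind", "sample_index"}
        if not required.issubset(ev.columns):
            raise CohortFormatError(
                f"patient {self.patient_id}: event table missing columns "
                f"{sorted(required - set(ev.columns))}")
        bad_kind = set(ev["event_kind"]) - set(EVENT_KINDS)
        if bad_kind:
            raise CohortIntegrityError(
                f"patient {self.patient_id}: unknown event kinds {bad_kind}")
        out = ev[(ev.sample_index < 0) | (ev.sample_index >= self.n_samples)]
        if len(out):
            t = int(out.iloc[0].trial_id)
            raise CohortIntegrityError(
                f"patient {self.patient_id}: trial {t} has event sample index "
                f"outside the trace (length {self.n_samples})")
        for trial_id, grp in ev.groupby("trial_id"):
            cond = self.conditions.get(int(trial_id))
            if cond not in ("active", "passive"):
                raise CohortIntegrityError(
                    f"patient {self.patient_id}: trial {trial_id} has no "
                    f"valid condition flag (got {cond!r})")
            kinds = dict(zip(grp.event_kind, grp.sample_index))
            if cond == "active":
                if set(kinds) != set(EVENT_KINDS):
                    raise CohortIntegrityError(
                        f"patient {self.patient_id}: active trial {trial_id} "
                        f"must have sound, letter and button events, has "
                        f"{sorted(kinds)}")
                if not (kinds["sound"] < kinds["letter"] < kinds["button"]):
                    raise CohortIntegrityError(
                        f"patient {self.patient_id}: active trial {trial_id} "
                        f"events out of order (sound < letter < button "
                        f"required)")
            else:
                if set(kinds) != {"sound"}:
                    raise CohortIntegrityError(
                        f"patient {self.patient_id}: passive trial {trial_id} "
                        f"must have only a sound event, has {sorted(kinds)}")

    def trial_ids(self, condition: str | None = None) -> list[int]:
        ids = sorted(int(t) for t in self.events.trial_id.unique())
        if condition is None:
            return ids
        return [t for t in ids if self.conditions[t] == condition]

    def event_sample(self, trial_id: int, kind: str) -> int:
        sel = self.events[(self.events.trial_id == trial_id)
                          & (self.events.event_kind == kind)]
        if not len(sel):
            raise KeyError(f"trial {trial_id} has no {kind} event")
        return int(sel.iloc[0].sample_index)


def make_electrode_table(electrode_ids, patient_ids, esm_categories,
                         seizure_onset=None, xy=None) -> pd.DataFrame:
    """Assemble a validated electrode table, deriving ``eloquent`` and
    ``io_group`` from the ESM categories."""
    cats = list(esm_categories)
    unknown = set(cats) - set(ESM_CATEGORIES)
    if unknown:
        raise CohortIntegrityError(f"unknown ESM categories {sorted(unknown)}")
    n = len(cats)
    tab = pd.DataFrame({
        "electrode_id": list(electrode_ids),
        "patient_id": list(patient_ids),
        "esm_category": cats,
        "eloquent": [c != "non-eloquent" for c in cats],
        "io_group": [IO_GROUP_OF_CATEGORY[c] for c in cats],
        "seizure_onset": (list(seizure_onset) if seizure_onset is not None
                          else [False] * n),
        "x": ([p[0] for p in xy] if xy is not None else [np.nan] * n),
        "y": ([p[1] for p in xy] if xy is not None else [np.nan] * n),
    })
    validate_electrode_table(tab)
    return tab


def validate_electrode_table(tab: pd.DataFrame) -> None:
    missing = set(ELECTRODE_COLUMNS) - set(tab.columns)
    if missing:
        raise CohortFormatError(f"electrode table missing columns {sorted(missing)}")
    bad = set(tab.esm_category) - set(ESM_CATEGORIES)
    if bad:
        raise CohortIntegrityError(f"unknown ESM categories {sorted(bad)}")
    mismatch = tab[tab.eloquent != (tab.esm_category != "non-eloquent")]
    if len(mismatch):
        eid = mismatch.iloc[0].electrode_id
        raise CohortIntegrityError(
            f"electrode {eid}: eloquent flag inconsistent with ESM category")
    expected = tab.esm_category.map(IO_GROUP_OF_CATEGORY)
    wrong = tab[tab.io_group != expected]
    if len(wrong):
        eid = wrong.iloc[0].electrode_id
        raise CohortIntegrityError(
            f"electrode {eid}: io_group {wrong.iloc[0].io_group!r} does not "
            f"match the fixed partition for {wrong.iloc[0].esm_category!r}")
    if tab.electrode_id.duplicated().any():
        dup = tab.electrode_id[tab.electrode_id.duplicated()].iloc[0]
        raise CohortIntegrityError(f"duplicate electrode_id {dup!r}")


# ---------------------------------------------------------------------------
# cohort container I/O
# ---------------------------------------------------------------------------

def write_cohort(recordings: list[CohortRecording], electrodes: pd.DataFrame,
                 path, ground_truth: dict | None = None) -> None:
    """Write a cohort directory: per-patient HDF5 + JSON sidecar and a
    cohort-level electrode TSV."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    validate_electrode_table(electrodes)
    for rec in recordings:
        with h5py.File(path / f"{rec.patient_id}.h5", "w") as h5:
            ds = h5.create_dataset("traces", data=rec.traces.astype(np.float32))
            ds.attrs["sample_rate"] = int(rec.sample_rate)
        sidecar = {
            "patient_id": rec.patient_id,
            "sample_rate": int(rec.sample_rate),
            "event_table": [
                [int(r.trial_id), str(r.event_kind), int(r.sample_index)]
                for r in rec.events.itertuples()],
            "condition_table": {str(k): v for k, v in rec.conditions.items()},
            "excluded_flags": [bool(b) for b in rec.excluded_flags],
        }
        (path / f"{rec.patient_id}.json").write_text(json.dumps(sidecar))
    electrodes.to_csv(path / "electrodes.tsv", sep="\t", index=False)
    if ground_truth is not None:
        (path / "ground_truth.json").write_text(
            json.dumps(ground_truth, default=_jsonable))


def read_cohort(path) -> tuple[list[CohortRecording], pd.DataFrame]:
    """Read a cohort directory written by :func:`write_cohort`.

    Returns fully validated recordings (sorted by patient id) and the
    electrode table.
    """
    path = Path(path)
    etab_path = path / "electrodes.tsv"
    if not etab_path.exists():
        raise CohortFormatError(f"{path}: no electrodes.tsv in cohort directory")
    electrodes = pd.read_csv(etab_path, sep="\t")
    validate_electrode_table(electrodes)
    recordings = []
    for h5path in sorted(path.glob("*.h5")):
        sidecar_path = h5path.with_suffix(".json")
        if not sidecar_path.exists():
            raise CohortFormatError(f"{h5path.name}: missing JSON sidecar")
        meta = json.loads(sidecar_path.read_text())
        with h5py.File(h5path, "r") as h5:
            if "traces" not in h5:
                raise CohortFormatError(f"{h5path.name}: no /traces dataset")
            traces = h5["traces"][()]
            rate = int(h5["traces"].attrs["sample_rate"])
        events = pd.DataFrame(
            meta["event_table"],
            columns=["trial_id", "event_kind", "sample_index"])
        recordings.append(CohortRecording(
            patient_id=meta["patient_id"],
            sample_rate=rate,
            traces=traces,
            events=events,
            conditions={int(k): v for k, v in meta["condition_table"].items()},
            excluded_flags=np.asarray(meta["excluded_flags"], dtype=bool),
        ))
    if not recordings:
        raise CohortFormatError(f"{path}: no patient HDF5 files found")
    return recordings, electrodes


def read_ground_truth(path) -> dict | None:
    p = Path(path) / "ground_truth.json"
    return json.loads(p.read_text()) if p.exists() else None


# ---------------------------------------------------------------------------
# results serialization
# ---------------------------------------------------------------------------

def write_results(evaluation, eloquence_map, path) -> None:
    """Serialize a model evaluation and an eloquence map to ``path``.

    Writes ``models.tsv`` (per-model AUROC summary), ``pairwise.json``
    (paired bootstrap comparisons keyed ``"model|reference"``),
    ``bootstrap.json`` (raw per-model distributions) and, when a map is
    given, ``electrode_probabilities.tsv`` + ``map_summary.json``.
    Every table re-parses to the in-memory values (floats round-trip at
    full precision).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if evaluation is not None:
        rows = []
        for name in evaluation.model_names:
            dist = np.asarray(evaluation.distributions[name], dtype=float)
            rows.append({
                "model": name,
                "auroc_original": evaluation.auroc_original[name],
                "boot_mean": float(dist.mean()) if dist.size else np.nan,
                "boot_p2_5": float(np.percentile(dist, 2.5)) if dist.size else np.nan,
                "boot_p97_5": float(np.percentile(dist, 97.5)) if dist.size else np.nan,
            })
        pd.DataFrame(rows, columns=["model", "auroc_original", "boot_mean",
                                    "boot_p2_5", "boot_p97_5"]).to_csv(
            path / "models.tsv", sep="\t", index=False)
        (path / "bootstrap.json").write_text(json.dumps(
            {name: [float(v) for v in evaluation.distributions[name]]
             for name in evaluation.model_names}))
        pairwise = {}
        for comp in evaluation.comparisons:
            key = f"{comp.model}|{comp.reference}"
            pairwise[key] = {
                "model": comp.model,
                "reference": comp.reference,
                "mean_pct_change": comp.mean_pct_change,
                "frac_improved": comp.frac_improved,
                "significant": bool(comp.significant),
                "pct_change": [float(v) for v in comp.pct_change],
            }
        (path / "pairwise.json").write_text(json.dumps(pairwise))
    if eloquence_map is not None:
        eloquence_map.electrodes.to_csv(
            path / "electrode_probabilities.tsv", sep="\t", index=False)
        summary = {
            "cohort_auroc": eloquence_map.cohort_auroc,
            "per_patient": eloquence_map.per_patient,
        }
        (path / "map_summary.json").write_text(
            json.dumps(summary, default=_jsonable))


def read_results(path) -> dict:
    """Re-parse a results directory written by :func:`write_results`."""
    path = Path(path)
    out: dict = {}
    p = path / "models.tsv"
    if p.exists():
        out["models"] = pd.read_csv(p, sep="\t")
    p = path / "bootstrap.json"
    if p.exists():
        out["bootstrap"] = json.loads(p.read_text())
    p = path / "pairwise.json"
    if p.exists():
        out["pairwise"] = json.loads(p.read_text())
    p = path / "electrode_probabilities.tsv"
    if p.exists():
        out["electrodes"] = pd.read_csv(p, sep="\t")
    p = path / "map_summary.json"
    if p.exists():
        out["map_summary"] = json.loads(p.read_text())
    return out


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
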