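"""Readers and writers: HDF5 trial container, EDF import, report files.

The container layout is ``/subjects/<sid>/runs/<rid>/trials/<k>`` with the
sample-by-channel matrix as the dataset and fs, labels, target, and the
flash schedule (JSON) as attributes — schedules always travel with the data,
since decoding is meaningless without the per-trial sequences.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cca import FilterModel
from .evaluate import EvaluationReport, SCHEMA_VERSION
from .preprocess import TrialData
from .schedule import StimulusSchedule

__all__ = [
    "save_dataset",
    "load_dataset",
    "read_trials",
    "save_model",
    "load_model",
    "write_report",
    "read_report",
    "write_results_csv",
]


def _h5py():
    import h5py

    return h5py


# ---------------------------------------------------------------------------
# trial container


def save_dataset(path, trials: list[TrialData]) -> None:
    """Write trials to the HDF5 container, grouped by subject and run."""
    h5py = _h5py()
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        counters: dict = {}
        for tr in trials:
            sid = "none" if tr.subject_id is None else str(tr.subject_id)
            rid = "none" if tr.run_id is None else str(tr.run_id)
            key = (sid, rid)
            k = counters.get(key, 0)
            counters[key] = k + 1
            grp = f.require_group(f"subjects/{sid}/runs/{rid}/trials")
            ds = grp.create_dataset(str(k), data=tr.X)
            ds.attrs["fs"] = tr.fs
            ds.attrs["schedule"] = tr.schedule.to_json()
            ds.attrs["channel_labels"] = json.dumps(tr.channel_labels)
            ds.attrs["modalities"] = json.dumps(tr.modalities)
            ds.attrs["target"] = -1 if tr.target is None else int(tr.target)
            ds.attrs["buffer"] = tr.buffer


def load_dataset(path) -> list[TrialData]:
    """Read every trial back from the container, sorted by subject/run/index."""
    h5py = _h5py()
    trials: list[TrialData] = []
    with h5py.File(path, "r") as f:
        if "subjects" not in f:
            raise ValueError(f"{path}: not a trial container (missing /subjects)")
        for sid in sorted(f["subjects"], key=_natural):
            for rid in sorted(f[f"subjects/{sid}/runs"], key=_natural):
                grp = f[f"subjects/{sid}/runs/{rid}/trials"]
                for k in sorted(grp, key=_natural):
                    ds = grp[k]
                    target = int(ds.attrs["target"])
                    trials.append(
                        TrialData(
                            X=ds[()],
                            fs=float(ds.attrs["fs"]),
                            schedule=StimulusSchedule.from_json(ds.attrs["schedule"]),
                            channel_labels=json.loads(ds.attrs["channel_labels"]),
                            modalities=json.loads(ds.attrs["modalities"]),
                            target=None if target < 0 else target,
                            run_id=_maybe_int(rid),
                            subject_id=_maybe_int(sid),
                            buffer=float(ds.attrs["buffer"]),
                        )
                    )
    return trials


def _natural(s: str):
    return (0, int(s)) if s.isdigit() else (1, s)


def _maybe_int(s: str):
    if s == "none":
        return None
    return int(s) if s.isdigit() else s


# ---------------------------------------------------------------------------
# EDF import


def read_trials(path, format: str | None = None) -> list[TrialData]:
    """Read trials from a container (``.h5``) or a continuous EDF recording.

    For EDF, flash onsets are taken from EDF+ annotations with descriptions
    ``flash:<object>`` (plus optional ``target:<object>``); if the file has
    no such annotations, a JSON sidecar ``<path>.schedule.json`` holding the
    serialized schedule (plus optional ``target`` and ``trial_start``) is
    accepted.  The whole recording is treated as one trial segment starting
    at the first flash onset.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "container"
    if format == "container":
        return load_dataset(path)
    if format != "edf":
        raise ValueError(f"unknown format {format!r} (expected 'edf' or 'container')")
    return _read_edf(path)


def _read_edf(path: Path) -> list[TrialData]:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - corrupt-file path
        raise ValueError(f"{path}: failed to parse as EDF ({exc})") from exc
    fs = float(raw.info["sfreq"])
    data = raw.get_data().T  # samples x channels
    labels = list(raw.ch_names)

    flashes: list[tuple[float, int]] = []
    target: int | None = None
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if desc.startswith("flash:"):
            flashes.append((float(onset), int(desc.split(":", 1)[1])))
        elif desc.startswith("target:"):
            target = int(desc.split(":", 1)[1])

    if flashes:
        flashes.sort()
        t0 = flashes[0][0]
        order = tuple(e for _, e in flashes)
        soas = np.diff([t for t, _ in flashes])
        soa = float(np.median(soas)) if len(soas) else 1.0
        n_objects = max(order) + 1
        schedule = StimulusSchedule(
            n_objects=n_objects,
            n_reps=max(1, len(order) // n_objects),
            soa=soa,
            min_same_object_gap=0.0,
            global_order=order,
        )
    else:
        sidecar = path.with_suffix(path.suffix + ".schedule.json")
        if not sidecar.exists():
            raise ValueError(
                f"{path}: no flash annotations and no sidecar {sidecar.name}; "
                "cannot recover the stimulus schedule"
            )
        meta = json.loads(sidecar.read_text())
        schedule = StimulusSchedule.from_json(json.dumps(meta["schedule"]))
        target = meta.get("target")
        t0 = float(meta.get("trial_start", 0.0))

    i0 = int(round(t0 * fs))
    return [
        TrialData(
            X=data[i0:],
            fs=fs,
            schedule=schedule,
            channel_labels=labels,
            modalities=["eeg"] * len(labels),
            target=target,
        )
    ]


# ---------------------------------------------------------------------------
# models


def save_model(path, model: FilterModel) -> None:
    h5py = _h5py()
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_dataset("W", data=model.W)
        f.create_dataset("S", data=model.S)
        f.create_dataset("rho", data=model.rho)
        if model.rho_full is not None:
            f.create_dataset("rho_full", data=model.rho_full)
        f.attrs["K"] = model.K
        f.attrs["d"] = model.d
        f.attrs["n_train_samples"] = model.n_train_samples
        f.attrs["channel_labels"] = json.dumps(model.channel_labels)
        f.attrs["provenance"] = json.dumps(model.provenance, default=str)


def load_model(path) -> FilterModel:
    h5py = _h5py()
    with h5py.File(path, "r") as f:
        return FilterModel(
            W=f["W"][()],
            S=f["S"][()],
            rho=f["rho"][()],
            rho_full=f["rho_full"][()] if "rho_full" in f else None,
            K=int(f.attrs["K"]),
            d=int(f.attrs["d"]),
            n_train_samples=int(f.attrs["n_train_samples"]),
            channel_labels=json.loads(f.attrs["channel_labels"]),
            provenance=json.loads(f.attrs["provenance"]),
        )


# ---------------------------------------------------------------------------
# reports


def write_report(report: EvaluationReport, path_prefix) -> list[Path]:
    """Write a report as ``<prefix>.json`` plus one CSV per curve."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "schema_version": report.schema_version,
        "scheme": report.scheme,
        "da": report.da,
        "per_subject": {str(k): v for k, v in report.per_subject.items()},
        "itr_bit_per_min": report.itr_bit_per_min,
        "permutation": _clean(report.permutation),
        "config": _clean(report.config),
        "seed": report.seed,
    }
    json_path = prefix.with_suffix(".json")
    json_path.write_text(json.dumps(payload, indent=2))
    written = [json_path]
    for name, values in report.curves.items():
        arr = np.asarray(values, dtype=float)
        if np.isnan(arr).any():
            raise ValueError(f"curve {name!r} contains NaN")
        csv_path = prefix.parent / f"{prefix.name}_{name}.csv"
        pd.DataFrame({"index": np.arange(len(arr)), name: arr}).to_csv(
            csv_path, index=False
        )
        written.append(csv_path)
    return written


def read_report(path) -> dict:
    payload = json.loads(Path(path).read_text())
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"report schema version {version!r} not supported (expected {SCHEMA_VERSION})"
        )
    return payload


def write_results_csv(results, trials: list[TrialData], path) -> Path:
    """Per-trial decoding results table (one row per trial, scores included)."""
    rows = []
    for tr, res in zip(trials, results):
        row = {
            "subject": tr.subject_id,
            "run": tr.run_id,
            "true": tr.target,
            "predicted": res.predicted,
            "rank_of_true": res.rank_of_true,
        }
        for e, s in enumerate(res.scores):
            row[f"score_{e}"] = s
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def _clean(obj):
    if obj is None or isinstance(obj, (str, int, float, bool)):
        return obj
    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return str(obj)
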