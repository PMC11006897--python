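"""Session bundle I/O.

A session bundle is one HDF5 file (datasets F, Fneu, events, frame_rate,
roi_ids), a stimulus-log CSV, and a ground-truth JSON for synthetic
sessions. Trial tensors are stored as HDF5 with window metadata in
attributes.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import RoiTraces, TrialTensor, GroundTruth, validate_stim_log

__all__ = [
    "save_session",
    "load_session",
    "save_stim_log",
    "load_stim_log",
    "save_ground_truth",
    "load_ground_truth",
    "save_tensor",
    "load_tensor",
]


def save_session(path: str | Path, traces: RoiTraces) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("F", data=traces.F)
        if traces.Fneu is not None:
            f.create_dataset("Fneu", data=traces.Fneu)
        if traces.events is not None:
            f.create_dataset("events", data=traces.events)
        f.attrs["frame_rate"] = traces.frame_rate
        f.create_dataset(
            "roi_ids", data=np.array(traces.roi_ids, dtype=h5py.string_dtype())
        )


def load_session(path: str | Path) -> RoiTraces:
    with h5py.File(path, "r") as f:
        return RoiTraces(
            F=f["F"][()],
            Fneu=f["Fneu"][()] if "Fneu" in f else None,
            events=f["events"][()] if "events" in f else None,
            frame_rate=float(f.attrs["frame_rate"]),
            roi_ids=[r.decode() for r in f["roi_ids"][()]],
        )


def save_stim_log(path: str | Path, log: pd.DataFrame) -> None:
    validate_stim_log(log)
    log.to_csv(path, index=False)


def load_stim_log(path: str | Path) -> pd.DataFrame:
    log = pd.read_csv(path)
    validate_stim_log(log)
    return log


def save_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    payload = {
        "rois": truth.rois.to_dict(orient="list"),
        "axons": truth.axons.to_dict(orient="list"),
        "extra": truth.extra,
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=float))


def load_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        rois=pd.DataFrame(d["rois"]),
        axons=pd.DataFrame(d["axons"]),
        extra=d.get("extra", {}),
    )


def save_tensor(path: str | Path, tensor: TrialTensor) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("dff", data=tensor.dff)
        f.create_dataset("frame_offsets", data=tensor.frame_offsets)
        f.attrs["frame_rate"] = tensor.frame_rate
        f.attrs["baseline_window"] = tensor.baseline_window
        f.attrs["response_window"] = tensor.response_window
        f.create_dataset(
            "roi_ids", data=np.array(tensor.roi_ids, dtype=h5py.string_dtype())
        )
        f.create_dataset(
            "trials_json",
            data=tensor.trials.to_json(orient="split"),
        )


def load_tensor(path: str | Path) -> TrialTensor:
    from io import StringIO

    with h5py.File(path, "r") as f:
        raw = f["trials_json"][()]
        payload = raw.decode() if isinstance(raw, bytes) else str(raw)
        trials = pd.read_json(StringIO(payload), orient="split")
        return TrialTensor(
            dff=f["dff"][()],
            frame_offsets=f["frame_offsets"][()],
            frame_rate=float(f.attrs["frame_rate"]),
            roi_ids=[r.decode() for r in f["roi_ids"][()]],
            trials=trials,
            baseline_window=tuple(f.attrs["baseline_window"]),
            response_window=tuple(f.attrs["response_window"]),
        )
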