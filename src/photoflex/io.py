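"""On-disk formats for sessions and analysis outputs.

A session directory holds ``events.tsv`` (documented column order),
``licks.csv`` (single column of lick times in seconds), ``traces.h5``
(datasets green_raw/red_raw with a sample_rate attribute) and, for
synthetic sessions, ``ground_truth.h5``.  Analysis outputs are TSV/JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import DffSession, DffTrial
from .synthetic import EVENT_COLUMNS, SessionBundle

__all__ = [
    "write_session",
    "read_session",
    "write_dff_session",
    "read_dff_session",
    "write_table",
    "read_table",
    "file_digest",
]


def write_session(bundle: SessionBundle, directory) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    bundle.events.to_csv(d / "events.tsv", sep="\t", index=False)
    pd.DataFrame({"lick_time_s": bundle.lick_times}).to_csv(d / "licks.csv", index=False)
    with h5py.File(d / "traces.h5", "w") as fh:
        fh.create_dataset("green_raw", data=bundle.green_raw, track_times=False)
        fh.create_dataset("red_raw", data=bundle.red_raw, track_times=False)
        fh.attrs["sample_rate"] = bundle.sample_rate
        fh.attrs["session_index"] = bundle.session_index
    if bundle.ground_truth is not None:
        with h5py.File(d / "ground_truth.h5", "w") as fh:
            for key, val in bundle.ground_truth.items():
                arr = np.asarray(val)
                if arr.ndim == 0:
                    fh.attrs[key] = arr.item()
                else:
                    fh.create_dataset(key, data=arr, track_times=False)
    return d


def read_session(directory) -> SessionBundle:
    d = Path(directory)
    events = pd.read_csv(d / "events.tsv", sep="\t")
    events["cs_id"] = events["cs_id"].astype("Int64")
    events = events[EVENT_COLUMNS]
    licks = pd.read_csv(d / "licks.csv")["lick_time_s"].to_numpy()
    with h5py.File(d / "traces.h5", "r") as fh:
        green = fh["green_raw"][:]
        red = fh["red_raw"][:]
        fs = float(fh.attrs["sample_rate"])
        session_index = int(fh.attrs.get("session_index", 0))
    truth = None
    gt_path = d / "ground_truth.h5"
    if gt_path.exists():
        truth = {}
        with h5py.File(gt_path, "r") as fh:
            for key in fh:
                truth[key] = fh[key][:]
            for key, val in fh.attrs.items():
                truth[key] = val
    return SessionBundle(
        green_raw=green,
        red_raw=red,
        lick_times=licks,
        events=events,
        sample_rate=fs,
        session_index=session_index,
        ground_truth=truth,
    )


def write_dff_session(session: DffSession, path) -> Path:
    """Corrected per-trial dF/F as one HDF5 file (group per trial)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as fh:
        fh.attrs["sample_rate"] = session.sample_rate
        for tr in session.trials:
            g = fh.create_group(f"trial_{tr.trial_index:04d}")
            for name in ("t", "green", "red", "valid_mask"):
                g.create_dataset(name, data=getattr(tr, name), track_times=False)
            if tr.corrected is not None:
                g.create_dataset("corrected", data=tr.corrected, track_times=False)
            g.attrs.update(
                trial_index=tr.trial_index,
                align_time=tr.align_time,
                us_time_rel=tr.us_time_rel,
                cued=tr.cued,
                session_day=tr.session_day,
                f0_green=tr.f0_green,
                f0_red=tr.f0_red,
                valid=tr.valid,
                correction_applied=tr.correction_applied,
            )
    return path


def read_dff_session(path, events: pd.DataFrame) -> DffSession:
    trials = []
    with h5py.File(path, "r") as fh:
        fs = float(fh.attrs["sample_rate"])
        for name in sorted(fh):
            g = fh[name]
            trials.append(
                DffTrial(
                    trial_index=int(g.attrs["trial_index"]),
                    t=g["t"][:],
                    green=g["green"][:],
                    red=g["red"][:],
                    valid_mask=g["valid_mask"][:].astype(bool),
                    align_time=float(g.attrs["align_time"]),
                    us_time_rel=float(g.attrs["us_time_rel"]),
                    cued=bool(g.attrs["cued"]),
                    session_day=int(g.attrs["session_day"]),
                    f0_green=float(g.attrs["f0_green"]),
                    f0_red=float(g.attrs["f0_red"]),
                    corrected=g["corrected"][:] if "corrected" in g else None,
                    valid=bool(g.attrs["valid"]),
                    correction_applied=bool(g.attrs["correction_applied"]),
                )
            )
    return DffSession(trials=trials, sample_rate=fs, events=events)


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def file_digest(path) -> str:
    """Content hash of an output file.

    HDF5 files are hashed by logical content (sorted dataset paths, raw
    array bytes and attributes) so the digest is independent of HDF5
    header bookkeeping; everything else is hashed by bytes.
    """
    path = Path(path)
    h = hashlib.sha256()
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            names: list = []
            fh.visit(names.append)
            for name in sorted(names):
                obj = fh[name]
                h.update(name.encode())
                if isinstance(obj, h5py.Dataset):
                    h.update(np.ascontiguousarray(obj[...]).tobytes())
                for key in sorted(obj.attrs):
                    h.update(key.encode())
                    h.update(np.asarray(obj.attrs[key]).tobytes())
            for key in sorted(fh.attrs):
                h.update(key.encode())
                h.update(np.asarray(fh.attrs[key]).tobytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating, np.bool_)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
    return path
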