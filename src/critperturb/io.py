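"""HDF5 persistence for Recordings and writers for tabular results."""

from __future__ import annotations

import json
import os

import h5py
import numpy as np
import pandas as pd

from .recording import Recording

FORMAT_VERSION = "1.0"


class RecordingFormatError(IOError):
    """The file is not a valid Recording container."""


def write_recording(rec: Recording, path) -> None:
    """Write a Recording to HDF5 (groups /spikes, /positions, /tc_indices,
    /trials, attributes under /meta)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("spikes", data=rec.counts.astype(np.uint16),
                         compression="gzip")
        f.create_dataset("positions", data=rec.positions)
        f.create_dataset("tc_indices", data=rec.tc_indices)
        if rec.trials is not None and len(rec.trials):
            g = f.create_group("trials")
            for col in rec.trials.columns:
                g.create_dataset(col, data=rec.trials[col].to_numpy())
        m = f.create_group("meta")
        m.attrs["format_version"] = FORMAT_VERSION
        m.attrs["frame_ms"] = rec.frame_ms
        m.attrs["n_cells"] = rec.n_cells
        m.attrs["n_frames"] = rec.n_frames
        for k, v in rec.meta.items():
            try:
                m.attrs[k] = v
            except TypeError:
                m.attrs[k] = json.dumps(v)


def read_recording(path) -> Recording:
    """Read a Recording; shapes are validated against the stored manifest.

    A missing /trials group yields a spontaneous-only Recording.
    """
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise RecordingFormatError(f"cannot open {path}: {e}") from e
    with f:
        for key in ("spikes", "positions", "tc_indices", "meta"):
            if key not in f:
                raise RecordingFormatError(f"missing group/dataset '{key}'")
        meta = dict(f["meta"].attrs)
        version = str(meta.pop("format_version", ""))
        if version.split(".")[0] != FORMAT_VERSION.split(".")[0]:
            raise RecordingFormatError(f"unsupported format version {version!r}")
        counts = f["spikes"][()]
        if counts.shape != (int(meta["n_cells"]), int(meta["n_frames"])):
            raise RecordingFormatError("spike matrix shape disagrees with manifest")
        trials = None
        if "trials" in f:
            trials = pd.DataFrame({k: f["trials"][k][()] for k in f["trials"]})
        frame_ms = float(meta.pop("frame_ms"))
        meta.pop("n_cells"), meta.pop("n_frames")
        return Recording(counts=counts, positions=f["positions"][()],
                         tc_indices=f["tc_indices"][()], trials=trials,
                         frame_ms=frame_ms, meta=meta)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serialisable: {type(o)}")


def write_results(tables: dict, out_dir) -> list:
    """Write result objects: DataFrames as CSV (deterministic column order,
    fixed float precision), everything else as JSON.  Returns written paths."""
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for name, obj in tables.items():
        if isinstance(obj, pd.DataFrame):
            path = os.path.join(out_dir, f"{name}.csv")
            obj.to_csv(path, index=False, float_format="%.6g")
        else:
            path = os.path.join(out_dir, f"{name}.json")
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=1, sort_keys=True,
                          default=_json_default)
        written.append(path)
    return written
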