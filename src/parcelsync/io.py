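"""Reading and writing recordings, connectivity matrices, and results.

On-disk recording format ("matrix" format): a directory holding one
tab-delimited text file per trial (``trial_0000.tsv`` ..., samples x
parcels) plus a ``recording.json`` sidecar with labels, sampling rate,
``t0``, trial count, and optional group / provenance fields.  EDF files
are supported read-only through :mod:`mne` (one trial per file).

Connectivity matrices are written both as square CSV (with ``#``-prefixed
header lines carrying method / band / trial-count metadata) and as
long-format tables (row label, column label, value).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .errors import SidecarError
from .recording import ParcelRecording

SIDECAR_NAME = "recording.json"
_TRIAL_FMT = "trial_{:04d}.tsv"


def write_recording(
    rec: ParcelRecording,
    directory: str | Path,
    group: str | None = None,
    extra_meta: dict | None = None,
) -> Path:
    """Write one trial file per trial plus the JSON sidecar; returns the dir."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i in range(rec.n_trials):
        np.savetxt(
            directory / _TRIAL_FMT.format(i),
            rec.data[i].T,  # samples x parcels
            delimiter="\t",
            fmt="%.12g",
        )
    meta = {
        "labels": list(rec.labels),
        "rate": rec.rate,
        "t0": rec.t0,
        "n_trials": rec.n_trials,
    }
    if group is not None:
        meta["group"] = group
    if extra_meta:
        meta.update(extra_meta)
    (directory / SIDECAR_NAME).write_text(json.dumps(meta, indent=1))
    return directory


def _read_matrix_recording(directory: Path) -> ParcelRecording:
    sidecar = directory / SIDECAR_NAME
    if not sidecar.exists():
        raise SidecarError(f"missing sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
        labels = tuple(meta["labels"])
        rate = float(meta["rate"])
        t0 = float(meta.get("t0", 0.0))
        n_trials = int(meta["n_trials"])
    except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
        raise SidecarError(f"unparseable sidecar {sidecar}: {exc}") from exc
    trials = []
    for i in range(n_trials):
        path = directory / _TRIAL_FMT.format(i)
        if not path.exists():
            raise SidecarError(f"sidecar promises {n_trials} trials but {path} is missing")
        arr = np.loadtxt(path, delimiter="\t", ndmin=2)
        if arr.shape[1] != len(labels):
            raise SidecarError(
                f"{path} has {arr.shape[1]} columns for {len(labels)} labels"
            )
        trials.append(arr.T)
    return ParcelRecording(
        data=np.stack(trials), rate=rate, labels=labels, t0=t0
    )


def _read_edf_recording(path: Path) -> ParcelRecording:
    import mne  # heavy import, deferred

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()  # channels x samples
    return ParcelRecording(
        data=data[np.newaxis, :, :],
        rate=float(raw.info["sfreq"]),
        labels=tuple(raw.ch_names),
        t0=float(raw.first_time),
    )


def read_recording(path: str | Path, format: str = "matrix") -> ParcelRecording:
    """Read a parcel recording.

    ``format="matrix"``: ``path`` is a directory written by
    :func:`write_recording`.  ``format="edf"``: a single EDF file; channel
    labels become parcel labels and the file is treated as one trial.
    """
    path = Path(path)
    if format == "matrix":
        return _read_matrix_recording(path)
    if format == "edf":
        return _read_edf_recording(path)
    raise SidecarError(f"unknown recording format {format!r}")


def read_group(path: str | Path) -> str | None:
    """Group label from a matrix-format recording's sidecar, if present."""
    sidecar = Path(path) / SIDECAR_NAME
    if not sidecar.exists():
        return None
    return json.loads(sidecar.read_text()).get("group")


def write_connectivity_csv(m: ConnectivityMatrix, path: str | Path) -> Path:
    """Square CSV with metadata header comments."""
    path = Path(path)
    header = (
        f"# method={m.method}\n"
        f"# band={m.band[0]},{m.band[1]}\n"
        f"# n_trials={m.n_trials}\n"
    )
    frame = pd.DataFrame(m.values, index=m.labels, columns=m.labels)
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh)
    return path


def read_connectivity_csv(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh, index_col=0)
    band = tuple(float(x) for x in meta.get("band", "0,0").split(","))
    return ConnectivityMatrix(
        values=frame.to_numpy(),
        method=meta.get("method", "ciplv"),
        band=band,  # type: ignore[arg-type]
        labels=tuple(frame.index),
        n_trials=int(meta.get("n_trials", 1)),
    )


def matrix_to_long(m: ConnectivityMatrix) -> pd.DataFrame:
    """Long-format (row, col, value) table of a connectivity matrix."""
    rows, cols = np.meshgrid(
        np.arange(m.n_parcels), np.arange(m.n_parcels), indexing="ij"
    )
    return pd.DataFrame(
        {
            "row": [m.labels[i] for i in rows.ravel()],
            "col": [m.labels[j] for j in cols.ravel()],
            "value": m.values.ravel(),
        }
    )
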