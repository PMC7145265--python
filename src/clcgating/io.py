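"""Artifact readers/writers: discrete trajectories, MSM containers, tables.

All text artifacts carry a schema-versioned first line; a mismatch raises
with the offending schema string.  Feature-matrix CSV I/O lives in
:mod:`clcgating.featurize`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .msm import MSModel

__all__ = ["write_dtraj", "load_dtraj", "save_msm", "load_msm"]

DTRAJ_HEADER = "# clcgating-dtraj v1"


def write_dtraj(dtraj, path) -> None:
    """Write one discrete trajectory as integer CSV (one state per line)."""
    d = np.asarray(dtraj, dtype=np.int64)
    with open(path, "w", newline="\n") as fh:
        fh.write(DTRAJ_HEADER + "\n")
        fh.write("state\n")
        np.savetxt(fh, d, fmt="%d")


def load_dtraj(path) -> np.ndarray:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# clcgating-dtraj"):
            raise ValueError(f"{path}: missing dtraj header")
        if first != DTRAJ_HEADER:
            raise ValueError(f"{path}: unsupported dtraj schema: {first}")
        header = fh.readline().strip()
        if header != "state":
            raise ValueError(f"{path}: malformed column header {header!r}")
        try:
            d = np.loadtxt(fh, dtype=np.int64, ndmin=1)
        except ValueError as e:
            raise ValueError(f"{path}: parse error: {e}") from e
    return d


def save_msm(model: MSModel, prefix) -> None:
    """Serialize an MSM to ``<prefix>.json`` + ``<prefix>.npz``."""
    prefix = Path(prefix)
    meta = {"schema": "clcgating-msm v1", "lag": int(model.lag),
            "frame_time": float(model.frame_time),
            "n_states_full": int(model.n_states_full)}
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    np.savez(prefix.with_suffix(".npz"),
             transition_matrix=model.transition_matrix,
             stationary=model.stationary, active_set=model.active_set,
             counts=model.counts)


def load_msm(prefix) -> MSModel:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    if meta.get("schema") != "clcgating-msm v1":
        raise ValueError(f"unsupported MSM container schema: {meta.get('schema')}")
    arr = np.load(prefix.with_suffix(".npz"))
    return MSModel(lag=meta["lag"], transition_matrix=arr["transition_matrix"],
                   stationary=arr["stationary"], active_set=arr["active_set"],
                   n_states_full=meta["n_states_full"], counts=arr["counts"],
                   frame_time=meta["frame_time"])
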