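"""HDF5/CSV persistence for traces, ground truth and feature sets.

Traces are stored one HDF5 dataset per channel per segment
(``segXXX/S405`` etc., float32) with ``sample_rate_hz`` and
``segment_index`` attributes; feature sets as an ``X`` float32 matrix,
``y`` int8 labels and a ``day`` string array.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import CHANNELS

__all__ = [
    "write_traces",
    "read_traces",
    "write_traces_csv",
    "write_features",
    "read_features",
]


def write_traces(
    path: str | Path,
    segments: list[dict[str, np.ndarray]],
    sample_rate_hz: float,
) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["sample_rate_hz"] = sample_rate_hz
        for i, seg in enumerate(segments):
            grp = f.create_group(f"seg{i:03d}")
            grp.attrs["segment_index"] = i
            for ch in CHANNELS:
                grp.create_dataset(ch, data=np.asarray(seg[ch], dtype=np.float32))


def read_traces(path: str | Path) -> tuple[list[dict[str, np.ndarray]], float]:
    segments = []
    with h5py.File(path, "r") as f:
        fs = float(f.attrs["sample_rate_hz"])
        for name in sorted(f.keys()):
            grp = f[name]
            segments.append({ch: grp[ch][:].astype(float) for ch in CHANNELS})
    return segments, fs


def write_traces_csv(
    path: str | Path, segment: dict[str, np.ndarray], compress: bool = True
) -> None:
    """One segment as (gzipped) CSV: sample_index plus the five channels."""
    df = pd.DataFrame(
        {"sample_index": np.arange(len(segment[CHANNELS[0]]))}
        | {ch: segment[ch] for ch in CHANNELS}
    )
    if compress:
        with gzip.open(path, "wt") as fh:
            df.to_csv(fh, index=False)
    else:
        df.to_csv(path, index=False)


def write_features(
    path: str | Path, X: np.ndarray, y: np.ndarray, days: np.ndarray
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=np.asarray(X, dtype=np.float32))
        f.create_dataset("y", data=np.asarray(y, dtype=np.int8))
        f.create_dataset(
            "day", data=np.asarray([str(d) for d in days], dtype="S32")
        )


def read_features(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    with h5py.File(path, "r") as f:
        X = f["X"][:].astype(float)
        y = f["y"][:].astype(int)
        days = np.array([d.decode() for d in f["day"][:]], dtype=object)
    return X, y, days
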