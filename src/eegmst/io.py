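"""Plain-text file formats: recordings, connectivity matrices, tables.

The recording dialect is deliberately diff-able: line 1 holds tab-separated
channel labels, line 2 ``fs=<Hz>``, and each subsequent line one time point
of tab-separated samples (channels as columns, µV, 6 decimals). Connectivity
matrices and statistics tables travel as CSV via pandas, each matrix with a
key=value metadata sidecar recording the estimator conventions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .montage import BandSpec
from .preprocess import Recording


class RecordingParseError(ValueError):
    """Malformed ascii recording file; message carries the line number."""


def write_recording(recording: Recording, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(recording.channel_labels) + "\n")
        fs = recording.fs
        fh.write(f"fs={fs:g}\n")
        np.savetxt(fh, recording.data.T, fmt="%.6f", delimiter="\t")


def read_recording(path, subject_id: str | None = None) -> Recording:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise RecordingParseError(f"{path}:1: empty header line")
        labels = header.split("\t")
        fs_line = fh.readline().rstrip("\n")
        if not fs_line.startswith("fs="):
            raise RecordingParseError(
                f"{path}:2: expected 'fs=<Hz>', got {fs_line!r}"
            )
        try:
            fs = float(fs_line[3:])
        except ValueError as exc:
            raise RecordingParseError(f"{path}:2: bad sampling rate: {exc}") from exc
        rows = []
        for lineno, line in enumerate(fh, start=3):
            line = line.strip()
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(labels):
                raise RecordingParseError(
                    f"{path}:{lineno}: expected {len(labels)} samples, got {len(cells)}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise RecordingParseError(f"{path}:{lineno}: non-numeric cell: {exc}") from exc
    if not rows:
        raise RecordingParseError(f"{path}: no sample rows")
    return Recording(
        subject_id=subject_id or path.stem,
        channel_labels=tuple(labels),
        fs=fs,
        data=np.asarray(rows, dtype=float).T,
    )


def write_connectivity(m: ConnectivityMatrix, path, metadata: dict | None = None) -> None:
    """Matrix CSV (labels as index/header) plus a ``.meta.txt`` sidecar."""
    path = Path(path)
    df = pd.DataFrame(m.values, index=m.channel_labels, columns=m.channel_labels)
    df.to_csv(path, float_format="%.10g")
    meta = {
        "method": m.method,
        "band": m.band.name if m.band else "",
        "band_low_hz": m.band.low if m.band else "",
        "band_high_hz": m.band.high if m.band else "",
        "aec_sign_convention": "signed (no rectification)",
        "wpli_zero_lag_convention": "0",
    }
    meta.update(metadata or {})
    side = path.with_suffix(path.suffix + ".meta.txt")
    with open(side, "w") as fh:
        for key, val in meta.items():
            fh.write(f"{key}={val}\n")


def read_connectivity(path, method: str = "", band: BandSpec | None = None) -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConnectivityMatrix(
        method=method or "wPLI",
        band=band,
        values=df.to_numpy(dtype=float),
        channel_labels=tuple(df.index),
    )


def write_tree_edges(edges, path) -> None:
    pd.DataFrame(list(edges), columns=["node_a", "node_b"]).to_csv(path, index=False)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
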