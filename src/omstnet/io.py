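"""Readers and writers: delimited connectivity matrices, multichannel
signals with a JSON sidecar, HDF5 tensors and JSON reports.

Matrices are square numeric TSV/CSV blocks with an optional first header row
of node labels; writers emit 17 significant digits so read-back is exact.
Node labels in files are 1-based strings; indices are 0-based in memory.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .dynamics import BandSpec, TVGraphTensor
from .graph import ConnectivityMatrix, GraphValidationError

__all__ = [
    "load_connectivity_matrix",
    "save_connectivity_matrix",
    "load_signals",
    "save_signals",
    "save_tensor",
    "load_tensor",
    "save_report",
]


def _parse_block(path: Path, delim: str) -> tuple[np.ndarray, list[str]]:
    rows: list[list[str]] = []
    with open(path) as fh:
        for raw in fh:
            raw = raw.strip()
            if raw:
                rows.append(raw.split(delim))
    if not rows:
        raise GraphValidationError(f"{path}: empty file")
    labels: list[str] = []
    first = rows[0]
    try:
        [float(v) for v in first]
    except ValueError:
        labels = list(first)
        rows = rows[1:]
    width = len(rows[0])
    data = np.empty((len(rows), width))
    for i, row in enumerate(rows):
        if len(row) != width:
            raise GraphValidationError(
                f"{path}: ragged row at line {i + (2 if labels else 1)} "
                f"({len(row)} fields, expected {width})"
            )
        try:
            data[i] = [float(v) for v in row]
        except ValueError as exc:
            raise GraphValidationError(f"{path}: non-numeric value in row {i}: {exc}")
    return data, labels


def load_connectivity_matrix(
    path, *, absolute: bool = False, delim: str = "\t"
) -> ConnectivityMatrix:
    """Load a square connectivity matrix from delimited text.

    Asymmetric input is symmetrized as (M + Mᵀ)/2 with a warning; NaNs are
    rejected; negative entries are rejected unless ``absolute`` is set, in
    which case absolute values are taken and the matrix max-normalized (the
    convention for correlation-based matrices).
    """
    import warnings

    path = Path(path)
    M, labels = _parse_block(path, delim)
    if M.shape[0] != M.shape[1]:
        raise GraphValidationError(f"{path}: non-square block {M.shape}")
    if np.isnan(M).any():
        i, j = np.argwhere(np.isnan(M))[0]
        raise GraphValidationError(f"{path}: NaN entry at row {i}, col {j}")
    if (M < 0).any():
        if not absolute:
            i, j = np.argwhere(M < 0)[0]
            raise GraphValidationError(
                f"{path}: negative entry at row {i}, col {j} (pass absolute=True "
                "to take magnitudes of correlation-type matrices)"
            )
        M = np.abs(M)
        mx = M.max()
        if mx > 0:
            M = M / mx
    if not np.allclose(M, M.T):
        warnings.warn(f"{path}: asymmetric matrix symmetrized as (M + M.T)/2")
        M = (M + M.T) / 2.0
    np.fill_diagonal(M, 0.0)
    return ConnectivityMatrix(M, labels)


def save_connectivity_matrix(cm: ConnectivityMatrix | np.ndarray, path, *, delim: str = "\t") -> None:
    """Write a matrix as delimited text with a node-label header row."""
    if isinstance(cm, ConnectivityMatrix):
        W, labels = cm.weights, cm.node_labels
    else:
        W = np.asarray(cm, float)
        labels = [f"n{i + 1}" for i in range(W.shape[0])]
    with open(path, "w") as fh:
        fh.write(delim.join(labels) + "\n")
        for row in W:
            fh.write(delim.join(f"{v:.17g}" for v in row) + "\n")


def save_signals(signals: np.ndarray, fs: float, path, channel_names=None) -> None:
    """Write (samples × channels) signals as CSV plus a JSON sidecar."""
    path = Path(path)
    X = np.asarray(signals, float)
    np.savetxt(path, X, delimiter=",", fmt="%.17g")
    names = channel_names or [f"ch{c + 1}" for c in range(X.shape[1])]
    sidecar = {"fs": fs, "channel_names": list(names)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_signals(path) -> tuple[np.ndarray, float, list[str]]:
    """Read signals CSV + JSON sidecar; returns (signals, fs, channel names)."""
    path = Path(path)
    X = np.loadtxt(path, delimiter=",", ndmin=2)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return X, float(sidecar["fs"]), list(sidecar["channel_names"])


def save_tensor(tensor: TVGraphTensor, path) -> None:
    """Write a masked iPLV tensor to an HDF5 container."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("values", data=tensor.values)
        h5.create_dataset("window_times", data=tensor.window_times)
        h5.create_dataset("n_windows", data=tensor.n_windows)
        h5.attrs["fs"] = tensor.fs
        h5.attrs["band_names"] = [b.name for b in tensor.bands]
        h5.attrs["band_lows"] = [b.low for b in tensor.bands]
        h5.attrs["band_highs"] = [b.high for b in tensor.bands]


def load_tensor(path) -> TVGraphTensor:
    with h5py.File(path, "r") as h5:
        bands = tuple(
            BandSpec(str(n), float(lo), float(hi))
            for n, lo, hi in zip(
                h5.attrs["band_names"], h5.attrs["band_lows"], h5.attrs["band_highs"]
            )
        )
        return TVGraphTensor(
            h5["values"][()],
            h5["window_times"][()],
            h5["n_windows"][()],
            bands,
            float(h5.attrs["fs"]),
        )


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_report(report: dict, path) -> None:
    """Write a JSON report with numpy values coerced to plain types."""
    Path(path).write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
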