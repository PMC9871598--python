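"""Reading and writing time series, networks and cohort manifests.

Formats are plain text: comma- or tab-delimited time-series matrices
(T rows x N columns, optional single header row of ROI names), RFC-4180
comma CSV for square matrices, TSV for manifests and edge lists.  ROI
indices in files are 0-based.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_time_series",
    "write_time_series",
    "read_manifest",
    "write_manifest",
    "write_network_csv",
    "read_network_csv",
    "write_edge_list",
]


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def _has_header(path: Path, delim: str) -> bool:
    with open(path, newline="") as fh:
        first = fh.readline()
    for tok in first.strip().split(delim):
        try:
            float(tok)
        except ValueError:
            return True
    return False


def read_time_series(path) -> tuple[np.ndarray, list[str] | None]:
    """Load a T x N delimited time-series matrix.

    Delimiter (comma/tab) and an optional ROI-name header row are
    auto-detected.  Returns ``(data, roi_names)`` with ``roi_names``
    None when the file has no header.  All values must parse as finite
    reals.
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    header = 0 if _has_header(path, delim) else None
    df = pd.read_csv(path, sep=delim, header=header)
    data = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: non-finite values in time series")
    names = [str(c) for c in df.columns] if header is not None else None
    return data, names


def write_time_series(path, data, roi_names=None) -> None:
    df = pd.DataFrame(np.asarray(data, dtype=float), columns=roi_names)
    df.to_csv(path, index=False, header=roi_names is not None)


def read_manifest(path) -> pd.DataFrame:
    """Cohort manifest TSV with columns subject_id, path, label (0/1).

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = {"subject_id", "path", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    if not set(df["label"].unique()) <= {0, 1}:
        raise ValueError(f"{path}: labels must be 0 or 1")
    df["path"] = [
        str(p) if Path(p).is_absolute() else str(path.parent / p)
        for p in df["path"]
    ]
    return df


def write_manifest(path, subject_ids, paths, labels) -> None:
    pd.DataFrame(
        {"subject_id": subject_ids, "path": paths, "label": labels}
    ).to_csv(path, sep="\t", index=False)


def write_network_csv(path, weights, roi_names=None) -> None:
    """N x N weight matrix as comma CSV with an ROI-name header row."""
    W = np.asarray(weights, dtype=float)
    n = W.shape[0]
    names = roi_names if roi_names is not None else [f"roi{i}" for i in range(n)]
    pd.DataFrame(W, columns=names).to_csv(path, index=False)


def read_network_csv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_edge_list(path, weights, *, symmetric: bool | None = None) -> None:
    """Edge-list TSV: roi_i, roi_j, weight (0-based indices).

    For symmetric matrices only pairs with i < j are written; pass
    ``symmetric=False`` to force writing both directions of an
    asymmetric regression network.  Auto-detected by default.
    """
    W = np.asarray(weights, dtype=float)
    n = W.shape[0]
    if symmetric is None:
        symmetric = bool(np.allclose(W, W.T, atol=1e-12))
    rows = []
    for i in range(n):
        for j in range(i + 1 if symmetric else 0, n):
            if i == j:
                continue
            rows.append((i, j, W[i, j]))
    pd.DataFrame(rows, columns=["roi_i", "roi_j", "weight"]).to_csv(
        path, sep="\t", index=False
    )
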