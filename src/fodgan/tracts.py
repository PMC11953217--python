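"""Streamline sets and weighted connectomes, with plain-text I/O.

Streamlines are ordered 3D point sequences in millimetres (as produced by
tractography); connectomes are symmetric non-negative region-by-region
weight matrices with zero diagonal (here 116 AAL-style nodes at paper
scale).  Both are consumed by the validation metrics and produced
synthetically by :mod:`fodgan.phantoms`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StreamlineSet", "Connectome", "read_streamlines", "write_streamlines",
           "read_connectome", "write_connectome"]


@dataclass
class StreamlineSet:
    """Polylines in mm with optional non-negative per-streamline weights."""

    streamlines: list
    weights: np.ndarray | None = None

    def __post_init__(self):
        lines = []
        for i, line in enumerate(self.streamlines):
            pts = np.asarray(line, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
                raise ValueError(f"streamline {i} must be an (n>=2, 3) point array")
            if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
                raise ValueError(f"streamline {i} has repeated consecutive points")
            lines.append(pts)
        self.streamlines = lines
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (len(lines),) or np.any(w < 0):
                raise ValueError("weights must be one non-negative value per streamline")
            self.weights = w

    def __len__(self):
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


@dataclass
class Connectome:
    """Symmetric non-negative node-by-node weight matrix, zero diagonal."""

    weights: np.ndarray
    labels: list = field(default=None)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("connectome must be a square matrix")
        if not np.array_equal(w, w.T):
            raise ValueError("connectome must be exactly symmetric")
        if np.any(w < 0):
            raise ValueError("connectome weights must be non-negative")
        np.fill_diagonal(w, 0.0)
        self.weights = w
        if self.labels is None:
            self.labels = [f"node{i:03d}" for i in range(w.shape[0])]
        elif len(self.labels) != w.shape[0]:
            raise ValueError("one label per node required")

    @property
    def n_nodes(self):
        return self.weights.shape[0]

    def total_weight(self) -> float:
        return float(self.weights.sum())


def write_streamlines(tract: StreamlineSet, path) -> None:
    """JSON polyline format: {"streamlines": [[[x,y,z],...],...], "weights": ...}."""
    obj = {"streamlines": [line.tolist() for line in tract]}
    if tract.weights is not None:
        obj["weights"] = tract.weights.tolist()
    with open(path, "w") as fh:
        json.dump(obj, fh)


def read_streamlines(path) -> StreamlineSet:
    with open(path) as fh:
        obj = json.load(fh)
    return StreamlineSet(obj["streamlines"], weights=obj.get("weights"))


def write_connectome(conn: Connectome, path) -> None:
    """Square CSV, header row/index = node labels."""
    pd.DataFrame(conn.weights, index=conn.labels, columns=conn.labels).to_csv(path)


def read_connectome(path) -> Connectome:
    df = pd.read_csv(path, index_col=0)
    return Connectome(df.to_numpy(dtype=float), labels=list(df.columns))
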