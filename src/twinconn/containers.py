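"""Shared in-memory containers and their plain-text serialization.

Everything in the package moves through three simple containers: BIDS-style
event tables (pandas DataFrames), per-subject ROI time series, and stacks of
per-subject symmetric connectivity matrices on the Fisher-z scale. All disk
formats are tab-separated text with header rows.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EVENT_COLUMNS = ["onset", "duration", "trial_type"]
MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]

CS_PLUS_US = "CSplus_US"
CS_PLUS_NOUS = "CSplus_noUS"
US = "US"


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table lacks columns: {missing}")
    ev = events[EVENT_COLUMNS].reset_index(drop=True)
    if not ev["onset"].is_monotonic_increasing:
        raise ValueError("event onsets must be non-decreasing")
    if (ev["duration"] <= 0).any():
        raise ValueError("event durations must be positive")
    return ev


def save_events(events: pd.DataFrame, path) -> None:
    validate_events(events).to_csv(path, sep="\t", index=False)


def load_events(path) -> pd.DataFrame:
    return validate_events(pd.read_csv(path, sep="\t"))


@dataclass
class RoiTimeSeries:
    """BOLD time series extracted on a node parcellation.

    ``data`` is a volumes x nodes float array sampled every ``tr`` seconds.
    """

    data: np.ndarray
    tr: float
    subject_id: str = ""
    node_ids: list = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2-D (volumes x nodes)")
        if not np.isfinite(self.data).all():
            raise ValueError("time series contains non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.node_ids is None:
            self.node_ids = [f"n{i:03d}" for i in range(self.data.shape[1])]
        if len(self.node_ids) != self.data.shape[1]:
            raise ValueError("node_ids length mismatch")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.data, columns=self.node_ids).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, tr: float, subject_id: str = "") -> "RoiTimeSeries":
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(float), tr=tr, subject_id=subject_id, node_ids=list(df.columns))


@dataclass
class FCMatrixStack:
    """Per-subject symmetric node x node matrices (Fisher-z scale).

    ``data`` has shape (n_subjects, n_nodes, n_nodes); every slice must be
    symmetric with a zero diagonal and finite entries. ``node_meta``, when
    present, maps node ids to a large-scale network label and coordinates
    (columns ``node_id``, ``network``, ``x``, ``y``, ``z``).
    """

    data: np.ndarray
    subject_ids: list
    node_meta: pd.DataFrame = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1] != self.data.shape[2]:
            raise ValueError("stack must have shape (n_subjects, n_nodes, n_nodes)")
        if len(self.subject_ids) != self.data.shape[0]:
            raise ValueError("subject_ids length mismatch")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite connectivity values")
        if not np.allclose(self.data, np.swapaxes(self.data, 1, 2), atol=1e-8):
            raise ValueError("connectivity matrices must be symmetric")
        if np.abs(np.diagonal(self.data, axis1=1, axis2=2)).max(initial=0.0) > 1e-12:
            raise ValueError("connectivity matrices must have zero diagonal")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    def edge_index(self) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangle (i, j) node indices defining the edge order."""
        return np.triu_indices(self.n_nodes, k=1)

    def edge_matrix(self) -> np.ndarray:
        """Vectorize the upper triangle: (n_subjects, n_edges) array."""
        iu, ju = self.edge_index()
        return self.data[:, iu, ju]

    def save_dir(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        node_ids = (
            list(self.node_meta["node_id"])
            if self.node_meta is not None
            else [f"n{i:03d}" for i in range(self.n_nodes)]
        )
        for sid, mat in zip(self.subject_ids, self.data):
            pd.DataFrame(mat, columns=node_ids).to_csv(
                os.path.join(outdir, f"{sid}_fc.tsv"), sep="\t", index=False
            )
        if self.node_meta is not None:
            self.node_meta.to_csv(os.path.join(outdir, "nodes.tsv"), sep="\t", index=False)

    @classmethod
    def load_dir(cls, indir, subject_ids) -> "FCMatrixStack":
        mats = [
            pd.read_csv(os.path.join(indir, f"{sid}_fc.tsv"), sep="\t").to_numpy(float)
            for sid in subject_ids
        ]
        meta_path = os.path.join(indir, "nodes.tsv")
        meta = pd.read_csv(meta_path, sep="\t") if os.path.exists(meta_path) else None
        return cls(np.stack(mats), list(subject_ids), node_meta=meta)


def stack_from_edges(
    edge_values: np.ndarray, n_nodes: int, subject_ids, node_meta: pd.DataFrame = None
) -> FCMatrixStack:
    """Inverse of :meth:`FCMatrixStack.edge_matrix`: rebuild symmetric matrices."""
    edge_values = np.asarray(edge_values, dtype=float)
    iu, ju = np.triu_indices(n_nodes, k=1)
    if edge_values.shape[1] != len(iu):
        raise ValueError("edge count does not match n_nodes")
    data = np.zeros((edge_values.shape[0], n_nodes, n_nodes))
    data[:, iu, ju] = edge_values
    data[:, ju, iu] = edge_values
    return FCMatrixStack(data, list(subject_ids), node_meta=node_meta)
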