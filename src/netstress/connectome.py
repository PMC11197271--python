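"""Connectivity matrices and network-restricted strength (NRS).

A scan's connectome is the node x node matrix of pairwise Pearson
correlations between parcel timeseries, variance-stabilized by the Fisher
z-transform z = atanh(r).  The network-restricted strength of a network is
the unweighted mean of z over all unordered node pairs within that network;
"DMN strength" is the NRS of the default mode network.  Nodal strength is
each member node's mean z to the other members, so the nodal values average
back to the NRS exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas_io import NetworkAtlas, ParcelTimeseries

__all__ = [
    "ConnectivityMatrix",
    "StrengthValue",
    "NodalStrengthVector",
    "correlation_matrix",
    "fisher_z",
    "network_strength",
    "nodal_strength",
    "split_halves",
    "scan_strength",
    "write_matrix_tsv",
    "write_matrix_long",
]

#: |r| is clipped here before atanh so degenerate (perfectly correlated)
#: series yield a large finite z instead of infinity.
R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric node x node connectivity matrix.

    The diagonal (self-pairs) is stored as 0 and excluded from every
    downstream computation.
    """

    values: np.ndarray
    node_ids: tuple[str, ...]
    scale: str  # "pearson_r" | "fisher_z"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(vals, vals.T, atol=1e-12, rtol=0.0):
            raise ValueError("connectivity matrix must be symmetric to 1e-12")
        if self.scale not in ("pearson_r", "fisher_z"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "pearson_r":
            off = vals[~np.eye(vals.shape[0], dtype=bool)]
            if off.size and (np.abs(off) > 1.0 + 1e-12).any():
                raise ValueError("pearson_r entries must lie in [-1, 1]")
        ids = tuple(str(i) for i in self.node_ids)
        if len(ids) != vals.shape[0] or len(set(ids)) != len(ids):
            raise ValueError("node_ids must be unique and match the matrix size")
        vals = vals.copy()
        np.fill_diagonal(vals, 0.0)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "node_ids", ids)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class StrengthValue:
    """Mean within-network Fisher-z connectivity (the NRS)."""

    value: float
    network: str
    scan_label: str
    n_nodes: int
    n_pairs: int

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("NRS needs >=2 member nodes")
        if self.n_pairs != self.n_nodes * (self.n_nodes - 1) // 2:
            raise ValueError("n_pairs inconsistent with n_nodes")


@dataclass(frozen=True)
class NodalStrengthVector:
    """Per-member-node mean z to the other members of one network."""

    values: np.ndarray
    node_ids: tuple[str, ...]
    network: str
    scan_label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or len(vals) != len(self.node_ids):
            raise ValueError("one value per member node required")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "node_ids", tuple(str(i) for i in self.node_ids))

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def correlation_matrix(ts: ParcelTimeseries) -> ConnectivityMatrix:
    """Pairwise Pearson correlation over frames for every node pair."""
    if ts.n_frames < 3:
        raise ValueError("need >=3 frames for a correlation matrix")
    sd = ts.values.std(axis=1)
    zero = np.where(sd < 1e-14)[0]
    if zero.size:
        raise ValueError(
            f"zero-variance node(s): {[ts.node_ids[i] for i in zero[:5]]}"
        )
    r = np.corrcoef(ts.values)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)  # enforce exact symmetry
    return ConnectivityMatrix(values=r, node_ids=ts.node_ids, scale="pearson_r")


def fisher_z(c: ConnectivityMatrix) -> ConnectivityMatrix:
    """Entrywise z = atanh(r), with |r| clipped to keep z finite."""
    if c.scale != "pearson_r":
        raise ValueError("input already Fisher z-transformed")
    z = np.arctanh(np.clip(c.values, -R_CLIP, R_CLIP))
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(values=z, node_ids=c.node_ids, scale="fisher_z")


def _member_indices(c: ConnectivityMatrix, atlas: NetworkAtlas, network: str) -> np.ndarray:
    members = atlas.members(network)
    if len(members) < 2:
        raise ValueError(f"network {network!r} has {len(members)} member(s); need >=2")
    pos = {n: i for i, n in enumerate(c.node_ids)}
    missing = [m for m in members if m not in pos]
    if missing:
        raise ValueError(
            f"atlas nodes missing from the matrix: {missing[:10]}"
        )
    return np.array([pos[m] for m in members], dtype=int)


def network_strength(
    c: ConnectivityMatrix, atlas: NetworkAtlas, network: str, scan_label: str = ""
) -> StrengthValue:
    """Unweighted mean z over the n(n-1)/2 within-network pairs."""
    if c.scale != "fisher_z":
        raise ValueError("network_strength expects a fisher_z matrix")
    idx = _member_indices(c, atlas, network)
    sub = c.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return StrengthValue(
        value=float(sub[iu].mean()),
        network=network,
        scan_label=scan_label or "unlabelled",
        n_nodes=len(idx),
        n_pairs=len(iu[0]),
    )


def nodal_strength(
    c: ConnectivityMatrix, atlas: NetworkAtlas, network: str, scan_label: str = ""
) -> NodalStrengthVector:
    """Per-node mean z to the other members; averages back to the NRS."""
    if c.scale != "fisher_z":
        raise ValueError("nodal_strength expects a fisher_z matrix")
    idx = _member_indices(c, atlas, network)
    sub = c.values[np.ix_(idx, idx)]
    m = len(idx)
    vals = sub.sum(axis=1) / (m - 1)  # diagonal is zero by construction
    return NodalStrengthVector(
        values=vals,
        node_ids=tuple(c.node_ids[i] for i in idx),
        network=network,
        scan_label=scan_label,
    )


def split_halves(ts: ParcelTimeseries) -> tuple[ParcelTimeseries, ParcelTimeseries]:
    """Split a scan into two contiguous equal-length halves.

    With an odd frame count the single middle frame is dropped so both halves
    cover the same duration.
    """
    n = ts.n_frames
    if n < 6:
        raise ValueError(f"need >=6 frames to split, got {n}")
    half = n // 2
    first = ts.values[:, :half]
    second = ts.values[:, n - half:]
    label = ts.scan_label
    return (
        replace(ts, values=first, scan_label=f"{label}_h1"),
        replace(ts, values=second, scan_label=f"{label}_h2"),
    )


def scan_strength(
    ts: ParcelTimeseries, atlas: NetworkAtlas, network: str = "DMN"
) -> StrengthValue:
    """Timeseries -> Pearson -> Fisher z -> NRS, in one call."""
    z = fisher_z(correlation_matrix(ts))
    return network_strength(z, atlas, network, scan_label=ts.scan_label)


def write_matrix_tsv(c: ConnectivityMatrix, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(c.values, index=list(c.node_ids), columns=list(c.node_ids))
    df.index.name = "node"
    df.to_csv(path, sep="\t", float_format="%.17g")
    return path


def write_matrix_long(
    r: ConnectivityMatrix, z: ConnectivityMatrix, path: str | Path
) -> Path:
    """Flat long-format CSV of the upper triangle: node_i, node_j, r, z."""
    if r.node_ids != z.node_ids:
        raise ValueError("r and z matrices must share node ids")
    iu = np.triu_indices(r.n_nodes, k=1)
    df = pd.DataFrame(
        {
            "node_i": [r.node_ids[i] for i in iu[0]],
            "node_j": [r.node_ids[j] for j in iu[1]],
            "r": r.values[iu],
            "z": z.values[iu],
        }
    )
    path = Path(path)
    df.to_csv(path, index=False)
    return path
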