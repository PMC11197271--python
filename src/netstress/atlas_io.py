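"""I/O and post-preprocessing cleanup for parcellated fMRI timeseries.

The analysis entry point is a node x frame matrix of parcel-averaged BOLD
series (one per scan) plus a node -> network affiliation table.  This module
reads and writes those as plain TSV, optionally reads CIFTI-2 parcellated
timeseries, and applies the cleanup steps that follow minimal preprocessing:
dropping initial (non-steady-state) frames, nuisance regression of motion
parameters and their Volterra-style expansion (derivatives and squares), and
mean-timeseries regression (MGTR) of the global parcel-average signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NETWORK_LABELS",
    "ParcelTimeseries",
    "NetworkAtlas",
    "ConfoundSet",
    "read_timeseries",
    "write_timeseries",
    "read_atlas",
    "write_atlas",
    "drop_initial_frames",
    "expand_motion_confounds",
    "regress_confounds",
    "mgtr",
]

#: The six intrinsic connectivity networks of the consensus hierarchical atlas:
#: default mode, central executive, dorsal salience, ventral salience,
#: somatomotor, visual.
NETWORK_LABELS = ("DMN", "CE", "DS", "VS", "SM", "VI")


class ValidationError(ValueError):
    """Raised when an input object or file violates a structural invariant."""


@dataclass(frozen=True)
class ParcelTimeseries:
    """One scan's parcel-averaged timeseries.

    Parameters
    ----------
    values
        node x frame matrix of BOLD signal, finite floats.
    node_ids
        Unique node labels aligned with the matrix rows.
    tr_seconds
        Sampling interval (repetition time) in seconds.
    scan_label
        Free-text scan identifier, e.g. ``"pre"`` or ``"post"``.
    """

    values: np.ndarray
    node_ids: tuple[str, ...]
    tr_seconds: float = 0.7
    scan_label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValidationError("values must be a 2-D node x frame matrix")
        if vals.shape[0] < 2 or vals.shape[1] < 2:
            raise ValidationError(
                f"need >=2 nodes and >=2 frames, got shape {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite value at node index {bad[0]}, frame {bad[1]}"
            )
        ids = tuple(str(i) for i in self.node_ids)
        if len(ids) != vals.shape[0]:
            raise ValidationError(
                f"{len(ids)} node_ids for {vals.shape[0]} matrix rows"
            )
        if len(set(ids)) != len(ids):
            raise ValidationError("node_ids must be unique")
        if not self.tr_seconds > 0:
            raise ValidationError("tr_seconds must be positive")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "node_ids", ids)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class NetworkAtlas:
    """Node -> intrinsic-connectivity-network affiliation map."""

    node_ids: tuple[str, ...]
    affiliation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.node_ids)
        if len(set(ids)) != len(ids):
            raise ValidationError("atlas node_ids must be unique")
        aff = {str(k): str(v) for k, v in self.affiliation.items()}
        missing = [i for i in ids if i not in aff]
        if missing:
            raise ValidationError(f"nodes without affiliation: {missing[:5]}")
        extra = set(aff) - set(ids)
        if extra:
            raise ValidationError(f"affiliations for unknown nodes: {sorted(extra)[:5]}")
        bad = sorted({v for v in aff.values()} - set(NETWORK_LABELS))
        if bad:
            raise ValidationError(
                f"unknown network labels {bad}; allowed: {list(NETWORK_LABELS)}"
            )
        sizes = pd.Series(list(aff.values())).value_counts()
        if not (sizes >= 2).any():
            raise ValidationError("at least one network needs >=2 member nodes")
        object.__setattr__(self, "node_ids", ids)
        object.__setattr__(self, "affiliation", aff)

    def members(self, network: str) -> list[str]:
        """Node ids affiliated with ``network``, in atlas order."""
        return [i for i in self.node_ids if self.affiliation[i] == network]

    @property
    def networks(self) -> list[str]:
        return [n for n in NETWORK_LABELS if any(v == n for v in self.affiliation.values())]


@dataclass(frozen=True)
class ConfoundSet:
    """frame x k nuisance regressor matrix with column labels."""

    regressors: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        reg = np.asarray(self.regressors, dtype=float)
        if reg.ndim != 2:
            raise ValidationError("regressors must be a 2-D frame x k matrix")
        if reg.shape[1] == 0:
            raise ValidationError("confound set has zero columns")
        if not np.all(np.isfinite(reg)):
            raise ValidationError("non-finite confound value")
        labels = tuple(str(x) for x in self.labels)
        if len(labels) != reg.shape[1]:
            raise ValidationError("label count must match column count")
        object.__setattr__(self, "regressors", reg)
        object.__setattr__(self, "labels", labels)

    @property
    def n_frames(self) -> int:
        return self.regressors.shape[0]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_timeseries(
    path: str | Path,
    format: str = "tsv",
    tr_seconds: float = 0.7,
    scan_label: str | None = None,
) -> ParcelTimeseries:
    """Read a parcellated timeseries from TSV or a CIFTI-2 ptseries file.

    The TSV dialect is one row per node, first column the node id, header row
    ``node<TAB>f0<TAB>f1...``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if scan_label is None:
        scan_label = path.stem
    if format == "tsv":
        return _read_timeseries_tsv(path, tr_seconds, scan_label)
    if format == "cifti-ptseries":
        return _read_timeseries_cifti(path, scan_label)
    raise ValueError(f"unknown format {format!r}; use 'tsv' or 'cifti-ptseries'")


def _read_timeseries_tsv(path: Path, tr_seconds: float, scan_label: str) -> ParcelTimeseries:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | ~np.isfinite(numeric.fillna(0.0))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        # +2: one for the header line, one for 1-based line numbering
        raise ValidationError(
            f"{path}: non-numeric or non-finite cell {df.iat[r, c]!r} for node "
            f"{df.index[r]!r} (line {r + 2}, column {df.columns[c]!r})"
        )
    # parse the final matrix from the raw strings with the correctly-rounded
    # converter so writer/reader round trips are bit-exact
    values = df.to_numpy(dtype="U32").astype(np.float64)
    return ParcelTimeseries(
        values=values,
        node_ids=tuple(str(i) for i in df.index),
        tr_seconds=tr_seconds,
        scan_label=scan_label,
    )


def _read_timeseries_cifti(path: Path, scan_label: str) -> ParcelTimeseries:
    import nibabel as nib
    from nibabel.cifti2 import cifti2_axes

    img = nib.load(str(path))
    series_ax = img.header.get_axis(0)
    parcel_ax = img.header.get_axis(1)
    if not isinstance(series_ax, cifti2_axes.SeriesAxis):
        raise ValidationError(f"{path}: first CIFTI axis is not a series axis")
    if not isinstance(parcel_ax, cifti2_axes.ParcelsAxis):
        raise ValidationError(f"{path}: second CIFTI axis is not a parcels axis")
    data = np.asarray(img.get_fdata(), dtype=float).T  # -> node x frame
    step = float(series_ax.step)
    if series_ax.unit == "SECOND":
        tr = step
    elif series_ax.unit == "HERTZ":
        tr = 1.0 / step
    else:  # pragma: no cover - exotic units
        raise ValidationError(f"{path}: unsupported series unit {series_ax.unit}")
    return ParcelTimeseries(
        values=data,
        node_ids=tuple(str(n) for n in parcel_ax.name),
        tr_seconds=tr,
        scan_label=scan_label,
    )


def write_timeseries(ts: ParcelTimeseries, path: str | Path) -> Path:
    """Write a timeseries as canonical TSV (header ``node\\tf0\\tf1...``)."""
    path = Path(path)
    cols = [f"f{i}" for i in range(ts.n_frames)]
    df = pd.DataFrame(ts.values, index=list(ts.node_ids), columns=cols)
    df.index.name = "node"
    df.to_csv(path, sep="\t", float_format="%.17g")
    return path


def read_atlas(path: str | Path) -> NetworkAtlas:
    """Read a two-column ``node<TAB>network`` affiliation table."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["node", "network"]:
        raise ValidationError(
            f"{path}: expected columns ['node', 'network'], got {list(df.columns)}"
        )
    nodes = [str(n) for n in df["node"]]
    dup = pd.Series(nodes)[pd.Series(nodes).duplicated()].tolist()
    if dup:
        raise ValidationError(f"{path}: duplicate node ids {sorted(set(dup))[:5]}")
    return NetworkAtlas(
        node_ids=tuple(nodes),
        affiliation=dict(zip(nodes, (str(v) for v in df["network"]))),
    )


def write_atlas(atlas: NetworkAtlas, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"node": list(atlas.node_ids),
         "network": [atlas.affiliation[n] for n in atlas.node_ids]}
    ).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# cleanup operations
# ---------------------------------------------------------------------------

def drop_initial_frames(ts: ParcelTimeseries, k: int) -> ParcelTimeseries:
    """Remove the first ``k`` frames (non-steady-state volumes)."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    if k >= ts.n_frames:
        raise ValueError(f"cannot drop {k} of {ts.n_frames} frames")
    if k == 0:
        return ts
    return replace(ts, values=ts.values[:, k:])


def expand_motion_confounds(base: ConfoundSet) -> ConfoundSet:
    """Expand k motion regressors to 4k: originals, backward first differences
    (first element 0), squares, and squared differences.

    Six rigid-body motion parameters thus become the standard 24-regressor set.
    """
    x = base.regressors
    dx = np.diff(x, axis=0, prepend=x[:1, :])  # backward difference, first row 0
    cols = np.hstack([x, dx, x**2, dx**2])
    labels = (
        list(base.labels)
        + [f"{l}_d1" for l in base.labels]
        + [f"{l}_sq" for l in base.labels]
        + [f"{l}_d1sq" for l in base.labels]
    )
    return ConfoundSet(regressors=cols, labels=tuple(labels))


def _design_matrix(conf: np.ndarray, labels: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + confounds, dropping exactly-collinear columns (warned)."""
    n = conf.shape[0]
    design = np.ones((n, 1))
    kept: list[str] = ["intercept"]
    tol = 1e-10
    for j in range(conf.shape[1]):
        cand = np.column_stack([design, conf[:, j]])
        # column is usable iff it adds rank
        s = np.linalg.svd(cand, compute_uv=False)
        if s[-1] > tol * max(cand.shape) * s[0]:
            design = cand
            kept.append(str(labels[j]))
        else:
            warnings.warn(
                f"dropping exactly-collinear confound {labels[j]!r}", stacklevel=2
            )
    return design, kept


def regress_confounds(ts: ParcelTimeseries, conf: ConfoundSet) -> ParcelTimeseries:
    """Residualize every node series against the confounds plus an intercept.

    Exactly-collinear confound columns are dropped with a warning; the
    residuals are orthogonal to every retained regressor.
    """
    if conf.n_frames != ts.n_frames:
        raise ValueError(
            f"confound frames ({conf.n_frames}) != timeseries frames ({ts.n_frames})"
        )
    design, kept = _design_matrix(conf.regressors, conf.labels)
    if design.shape[1] == 0:  # pragma: no cover - intercept always usable
        raise ValueError("no usable regressors")
    beta, *_ = np.linalg.lstsq(design, ts.values.T, rcond=None)
    resid = ts.values.T - design @ beta
    return replace(ts, values=resid.T)


def mgtr(ts: ParcelTimeseries) -> ParcelTimeseries:
    """Mean-timeseries regression: residualize each node on the across-node
    mean series (plus intercept).

    The global parcel-average signal is removed from every node, the parcel
    analogue of global-signal regression at grayordinate level.
    """
    mean_series = ts.values.mean(axis=0)
    if np.std(mean_series) < 1e-12:
        raise ValueError("across-node mean series has (near-)zero variance")
    design = np.column_stack([np.ones(ts.n_frames), mean_series])
    beta, *_ = np.linalg.lstsq(design, ts.values.T, rcond=None)
    resid = ts.values.T - design @ beta
    return replace(ts, values=resid.T)
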