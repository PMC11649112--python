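"""Atlas and functional-volume I/O: label volumes, ROI centroids, ROI time series.

Atlases are integer-labelled 3D volumes (0 = background).  ROI centroids are
computed in world (mm) coordinates through the NIfTI affine so that networks
derived from different atlases can be compared in a shared physical frame.
Grids of a functional volume and its atlas must already be aligned;
resampling is the caller's responsibility and mismatches fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Atlas",
    "FunctionalVolume",
    "RunTimeSeries",
    "load_atlas",
    "extract_roi_timeseries",
    "save_timeseries",
    "load_timeseries",
]


@dataclass
class Atlas:
    """Integer-labelled parcellation with per-ROI world-space centroids.

    Attributes
    ----------
    labels : (x, y, z) integer array, 0 marks background.
    roi_ids : ordered positive label values present in ``labels``.
    affine : 4x4 voxel-to-world transform (mm).
    centroids : (p, 3) mean world coordinate of each ROI's voxels.
    roi_names : optional name per ROI, aligned with ``roi_ids``.
    """

    labels: np.ndarray
    roi_ids: np.ndarray
    affine: np.ndarray
    centroids: np.ndarray
    roi_names: list[str] | None = None

    @property
    def p(self) -> int:
        return len(self.roi_ids)


@dataclass
class FunctionalVolume:
    """4D (x, y, z, t) functional data with its affine and sampling interval."""

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError(f"functional data must be 4D, got {self.data.ndim}D")
        if self.data.shape[3] < 1:
            raise ValueError("functional volume has no time points")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")


@dataclass
class RunTimeSeries:
    """One run's ROI-by-time matrix with acquisition metadata."""

    X: np.ndarray
    subject: str
    condition: str
    tr_seconds: float
    run_id: str
    roi_ids: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2D ROI-by-time matrix")
        if self.X.shape[0] < 2 or self.X.shape[1] < 2:
            raise ValueError("need at least 2 ROIs and 2 time points")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("time series contains non-finite values")

    @property
    def p(self) -> int:
        return self.X.shape[0]

    @property
    def t(self) -> int:
        return self.X.shape[1]


def _voxel_centroids(labels: np.ndarray, roi_ids: np.ndarray, affine: np.ndarray) -> np.ndarray:
    centroids = np.empty((len(roi_ids), 3), dtype=float)
    for j, rid in enumerate(roi_ids):
        idx = np.argwhere(labels == rid)
        if idx.size == 0:
            raise ValueError(f"ROI id {rid} has no voxels")
        voxel_mean = idx.mean(axis=0)
        centroids[j] = affine[:3, :3] @ voxel_mean + affine[:3, 3]
    return centroids


def load_atlas(label_volume: str | Path, lookup: str | Path | None = None) -> Atlas:
    """Load an integer label volume (NIfTI-1) into an :class:`Atlas`.

    ``lookup`` is an optional TSV with columns ``id`` and ``name``; every id
    it lists must occur in the volume.  Label values are preserved as given
    (no re-indexing) and ordered ascending.
    """
    img = nib.load(str(label_volume))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"label volume must be 3D, got {data.ndim}D")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.round(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError("label volume is not integer-valued")
        data = rounded.astype(np.int64)
    roi_ids = np.unique(data)
    roi_ids = roi_ids[roi_ids > 0]
    if roi_ids.size == 0:
        raise ValueError("label volume contains no non-zero labels")
    affine = np.asarray(img.affine, dtype=float)
    centroids = _voxel_centroids(data, roi_ids, affine)

    roi_names = None
    if lookup is not None:
        table = pd.read_csv(lookup, sep="\t")
        if not {"id", "name"}.issubset(table.columns):
            raise ValueError("lookup table must have 'id' and 'name' columns")
        missing = set(table["id"].astype(int)) - set(roi_ids.tolist())
        if missing:
            raise ValueError(f"lookup ids missing from the volume: {sorted(missing)}")
        name_of = dict(zip(table["id"].astype(int), table["name"].astype(str)))
        roi_names = [name_of.get(int(rid), str(rid)) for rid in roi_ids]

    return Atlas(labels=data, roi_ids=roi_ids, affine=affine, centroids=centroids, roi_names=roi_names)


def atlas_from_array(labels: np.ndarray, affine: np.ndarray | None = None,
                     roi_names: list[str] | None = None) -> Atlas:
    """Build an :class:`Atlas` from an in-memory integer label grid."""
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("labels must be integer-valued")
    if affine is None:
        affine = np.eye(4)
    roi_ids = np.unique(labels)
    roi_ids = roi_ids[roi_ids > 0]
    if roi_ids.size == 0:
        raise ValueError("label grid contains no non-zero labels")
    centroids = _voxel_centroids(labels, roi_ids, np.asarray(affine, dtype=float))
    return Atlas(labels=labels, roi_ids=roi_ids, affine=np.asarray(affine, dtype=float),
                 centroids=centroids, roi_names=roi_names)


def extract_roi_timeseries(vol: FunctionalVolume, atlas: Atlas, *, subject: str = "",
                           condition: str = "", run_id: str = "") -> RunTimeSeries:
    """Average the voxel time series within each ROI of ``atlas``.

    Row ``j`` of the returned p-by-t matrix is the mean over voxels labelled
    ``atlas.roi_ids[j]`` at each time point.  An ROI with zero voxels inside
    the functional grid signals an atlas/data topology failure and raises.
    """
    if vol.data.shape[:3] != atlas.labels.shape:
        raise ValueError(
            f"grid mismatch: functional {vol.data.shape[:3]} vs atlas {atlas.labels.shape}"
        )
    t = vol.data.shape[3]
    flat = vol.data.reshape(-1, t)
    lab = atlas.labels.reshape(-1)
    X = np.empty((atlas.p, t), dtype=float)
    for j, rid in enumerate(atlas.roi_ids):
        mask = lab == rid
        if not mask.any():
            raise ValueError(f"ROI {rid} has no voxels in the functional grid")
        X[j] = flat[mask].mean(axis=0)
    return RunTimeSeries(X=X, subject=subject, condition=condition,
                         tr_seconds=vol.tr_seconds, run_id=run_id,
                         roi_ids=atlas.roi_ids.copy())


def save_timeseries(run: RunTimeSeries, path: str | Path) -> None:
    """Write a run as TSV (ROI ids as row index) with a JSON metadata sidecar."""
    import json

    path = Path(path)
    index = run.roi_ids if run.roi_ids is not None else np.arange(run.p)
    pd.DataFrame(run.X, index=index).to_csv(path, sep="\t", header=False)
    meta = {"subject": run.subject, "condition": run.condition,
            "tr_seconds": run.tr_seconds, "run_id": run.run_id}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def load_timeseries(path: str | Path) -> RunTimeSeries:
    import json

    path = Path(path)
    frame = pd.read_csv(path, sep="\t", header=None, index_col=0)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return RunTimeSeries(X=frame.to_numpy(dtype=float), roi_ids=frame.index.to_numpy(), **meta)
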