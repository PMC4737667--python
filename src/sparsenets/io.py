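"""NIfTI volume I/O and the whole-brain signal matrix.

A 4D BOLD image plus a 3D brain mask become an ``m × n`` signal matrix
``S`` whose rows are time points and whose columns are the time series of
the ``n`` in-mask voxels.  The voxel ordering is an explicit, deterministic
raster order (first grid axis varying fastest) stored in ``voxel_index`` so
that every coefficient row can be mapped back onto the 3D grid without
relying on any array-layout convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.signal import detrend as _linear_detrend

from .errors import InsufficientDataError, ShapeError

__all__ = [
    "BrainMask",
    "SignalMatrix",
    "load_mask",
    "load_fmri",
    "normalize_signals",
    "map_row_to_volume",
    "flatten_volume",
    "save_volume",
]

#: variance below this is treated as zero (column dropped by normalization)
ZERO_VARIANCE = 1e-12


@dataclass(frozen=True)
class BrainMask:
    """Boolean voxel grid defining "whole brain" plus its voxel→world affine."""

    grid: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=bool)
        affine = np.asarray(self.affine, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "affine", affine)
        if grid.ndim != 3:
            raise ShapeError(f"mask grid must be 3D, got shape {grid.shape}")
        if affine.shape != (4, 4):
            raise ShapeError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("mask affine is singular")
        if self.n_voxels < 1:
            raise InsufficientDataError("mask contains no voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.grid))

    def voxel_index(self) -> np.ndarray:
        """(n, 3) integer coordinates of true voxels in raster order (x fastest)."""
        return _raster_index(self.grid)


def _raster_index(grid: np.ndarray) -> np.ndarray:
    coords = np.column_stack(np.nonzero(grid))
    flat = np.ravel_multi_index(
        (coords[:, 0], coords[:, 1], coords[:, 2]), grid.shape, order="F"
    )
    return coords[np.argsort(flat, kind="stable")]


@dataclass(frozen=True)
class SignalMatrix:
    """The m×n whole-brain data matrix S with its voxel↔grid index map.

    ``data[t, j]`` is the BOLD value at time point ``t`` for the voxel at
    grid coordinate ``voxel_index[j]``.
    """

    data: np.ndarray
    voxel_index: np.ndarray
    mask: BrainMask
    tr_seconds: float | None = None
    #: coordinates removed by :func:`normalize_signals` (zero-variance voxels)
    dropped_voxel_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        vi = np.asarray(self.voxel_index, dtype=int)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_index", vi)
        if data.ndim != 2:
            raise ShapeError(f"signal matrix must be 2D, got shape {data.shape}")
        if vi.ndim != 2 or vi.shape[1] != 3:
            raise ShapeError("voxel_index must be (n, 3)")
        if vi.shape[0] != data.shape[1]:
            raise ShapeError(
                f"{data.shape[1]} columns but {vi.shape[0]} voxel coordinates"
            )
        if len(np.unique(vi, axis=0)) != vi.shape[0]:
            raise ValueError("voxel_index contains duplicate coordinates")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


def load_mask(path: str | Path) -> BrainMask:
    img = nib.load(str(path))
    grid = np.asarray(img.dataobj) != 0
    if grid.ndim != 3:
        raise ShapeError(f"mask {path} must be 3D, got shape {grid.shape}")
    return BrainMask(grid=grid, affine=img.affine)


def load_fmri(
    path: str | Path, mask_path: str | Path, tr_seconds: float | None = None
) -> SignalMatrix:
    """Aggregate a 4D BOLD image into the m×n signal matrix over a mask.

    Column ``j`` is the full time series of the voxel at ``voxel_index[j]``;
    row ``t`` is the whole-brain image at time point ``t``.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ShapeError(f"expected 4D image, got shape {data.shape}")
    mask = load_mask(mask_path)
    if data.shape[:3] != mask.shape:
        raise ShapeError(
            f"image grid {data.shape[:3]} does not match mask grid {mask.shape}"
        )
    m = data.shape[3]
    if m < 2:
        raise InsufficientDataError(f"need at least 2 time points, got {m}")
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else None
    vi = mask.voxel_index()
    series = data[vi[:, 0], vi[:, 1], vi[:, 2], :]  # (n, m)
    return SignalMatrix(
        data=np.ascontiguousarray(series.T),
        voxel_index=vi,
        mask=mask,
        tr_seconds=tr_seconds,
    )


def normalize_signals(signals: SignalMatrix) -> SignalMatrix:
    """Linearly detrend each voxel time series, then standardize it.

    Columns whose detrended variance is below ``ZERO_VARIANCE`` (constant
    signals, pure linear drift) are removed; their coordinates are recorded
    in ``dropped_voxel_index``.  Unit-variance scaling is undefined for them.
    """
    if signals.n_timepoints < 2:
        raise InsufficientDataError("need at least 2 time points to normalize")
    data = _linear_detrend(signals.data, axis=0, type="linear")
    var = data.var(axis=0)
    keep = var >= ZERO_VARIANCE
    if not np.any(keep):
        raise InsufficientDataError("all voxel time series have zero variance")
    data = data[:, keep]
    data = (data - data.mean(axis=0)) / data.std(axis=0)
    dropped = signals.voxel_index[~keep]
    if signals.dropped_voxel_index is not None and len(signals.dropped_voxel_index):
        dropped = np.vstack([signals.dropped_voxel_index, dropped])
    return replace(
        signals,
        data=data,
        voxel_index=signals.voxel_index[keep],
        dropped_voxel_index=dropped,
    )


def map_row_to_volume(
    values: np.ndarray, mask: BrainMask, voxel_index: np.ndarray
) -> np.ndarray:
    """Place a length-n vector back onto the 3D grid (zeros elsewhere).

    Exact inverse of the flattening used by :func:`load_fmri`.
    """
    values = np.asarray(values, dtype=float)
    voxel_index = np.asarray(voxel_index, dtype=int)
    if values.ndim != 1 or values.shape[0] != voxel_index.shape[0]:
        raise ShapeError(
            f"got {values.shape[0] if values.ndim == 1 else values.shape} values "
            f"for {voxel_index.shape[0]} voxel coordinates"
        )
    vol = np.zeros(mask.shape, dtype=float)
    vol[voxel_index[:, 0], voxel_index[:, 1], voxel_index[:, 2]] = values
    return vol


def flatten_volume(volume: np.ndarray, voxel_index: np.ndarray) -> np.ndarray:
    """Extract the values at ``voxel_index`` coordinates as a flat vector."""
    volume = np.asarray(volume)
    voxel_index = np.asarray(voxel_index, dtype=int)
    return volume[voxel_index[:, 0], voxel_index[:, 1], voxel_index[:, 2]]


def save_volume(
    volume: np.ndarray, mask: BrainMask, path: str | Path, dtype=np.float32
) -> Path:
    """Write a 3D map as NIfTI with the mask's affine geometry."""
    volume = np.asarray(volume)
    if volume.shape != mask.shape:
        raise ShapeError(f"volume {volume.shape} does not match mask {mask.shape}")
    img = nib.Nifti1Image(volume.astype(dtype), mask.affine)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path
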