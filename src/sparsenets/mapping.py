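"""From coefficient rows to candidate functional-network volumes.

Each row of the sparse coefficient matrix α holds the loading of one
dictionary atom over all voxels.  Mapped back onto the grid and z-scored
over the in-mask voxels, it becomes the spatial map of one candidate
network; thresholding |z| (two-sided, because atom sign is indeterminate)
yields the binary network map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ShapeError
from .io import BrainMask, map_row_to_volume

__all__ = ["NetworkComponent", "build_components", "component_summary"]

DEFAULT_Z_THRESH = 2.0


@dataclass(frozen=True)
class NetworkComponent:
    """One dictionary atom with its reconstructed spatial maps."""

    index: int
    timecourse: np.ndarray
    raw_map: np.ndarray
    z_map: np.ndarray
    binary_map: np.ndarray
    n_active: int

    @property
    def is_empty(self) -> bool:
        return self.n_active == 0


def build_components(
    D,
    alpha: np.ndarray,
    mask: BrainMask,
    voxel_index: np.ndarray,
    z_thresh: float = DEFAULT_Z_THRESH,
) -> list[NetworkComponent]:
    """Turn every α row into a (raw, z, binary) spatial map triple.

    z-scores use the mean and population sd over the row's voxels; rows
    with zero sd are returned as empty components rather than errors.
    """
    atoms = getattr(D, "atoms", D)
    atoms = np.asarray(atoms, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim != 2:
        raise ShapeError(f"alpha must be 2D, got shape {alpha.shape}")
    if atoms.shape[1] != alpha.shape[0]:
        raise ShapeError(
            f"dictionary has {atoms.shape[1]} atoms but alpha has "
            f"{alpha.shape[0]} rows"
        )
    if alpha.shape[1] != len(voxel_index):
        raise ShapeError(
            f"alpha rows have length {alpha.shape[1]} but voxel_index has "
            f"{len(voxel_index)} entries"
        )
    components = []
    for i, row in enumerate(alpha):
        sd = row.std()
        if sd <= 0.0:
            z = np.zeros_like(row)
            active = np.zeros_like(row, dtype=bool)
        else:
            z = (row - row.mean()) / sd
            active = np.abs(z) > z_thresh
        components.append(
            NetworkComponent(
                index=i,
                timecourse=atoms[:, i].copy(),
                raw_map=map_row_to_volume(row, mask, voxel_index),
                z_map=map_row_to_volume(z, mask, voxel_index),
                binary_map=map_row_to_volume(active.astype(float), mask, voxel_index)
                > 0.5,
                n_active=int(active.sum()),
            )
        )
    return components


def component_summary(components: list[NetworkComponent]) -> pd.DataFrame:
    """Per-component table: active-voxel count, peak |z| and its coordinate."""
    records = []
    for c in components:
        if c.n_active == 0 and not np.any(c.z_map):
            peak_z = 0.0
            px = py = pz = -1
        else:
            flat = np.argmax(np.abs(c.z_map))
            px, py, pz = np.unravel_index(flat, c.z_map.shape)
            peak_z = float(np.abs(c.z_map[px, py, pz]))
        records.append(
            {
                "component": c.index,
                "n_active": c.n_active,
                "peak_abs_z": peak_z,
                "peak_x": int(px),
                "peak_y": int(py),
                "peak_z_coord": int(pz),
            }
        )
    columns = ["component", "n_active", "peak_abs_z", "peak_x", "peak_y", "peak_z_coord"]
    return pd.DataFrame.from_records(records, columns=columns)
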