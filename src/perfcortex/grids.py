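"""Voxel-grid containers shared by every pipeline stage.

All volumes in one run live on a single 3-D lattice.  The third array axis
is the slice (acquisition) axis: slice numbering for post-labeling-delay
adjustment is 1-based on that axis, i.e. the first slice of the stack is
slice 1.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ShapeError

__all__ = ["VolumeGrid", "TissueProbMaps", "check_same_grid"]


@dataclass
class VolumeGrid:
    """A 3-D scalar field on a fixed voxel lattice.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar values in arbitrary physical units.
    voxel_size : tuple of float
        Voxel edge lengths ``(dx, dy, dz)`` in millimetres.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (3.5, 3.5, 8.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError(
                f"VolumeGrid requires a 3-D array, got ndim={self.data.ndim}"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ShapeError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        """Number of slices along the acquisition (third) axis."""
        return self.data.shape[2]

    def like(self, data: np.ndarray) -> "VolumeGrid":
        """A new grid carrying `data` with this grid's geometry."""
        return VolumeGrid(np.asarray(data), self.voxel_size)


@dataclass
class TissueProbMaps:
    """Per-voxel GM/WM/CSF posterior probabilities on a shared grid.

    Invariants: each probability lies in [0, 1] and the per-voxel sum over
    the three tissues does not exceed 1 (the remainder is non-brain).
    """

    p_gm: VolumeGrid
    p_wm: VolumeGrid
    p_csf: VolumeGrid
    _tol: float = field(default=1e-9, repr=False)

    def __post_init__(self) -> None:
        check_same_grid(self.p_gm, self.p_wm, self.p_csf)
        for name in ("p_gm", "p_wm", "p_csf"):
            p = getattr(self, name).data
            if np.nanmin(p) < -self._tol or np.nanmax(p) > 1 + self._tol:
                raise ShapeError(f"{name} outside [0, 1]")
        if np.nanmax(self.total().data) > 1 + 1e-6:
            raise ShapeError("tissue probabilities sum to > 1 at some voxel")

    @property
    def grid(self) -> VolumeGrid:
        return self.p_gm

    def total(self) -> VolumeGrid:
        """Per-voxel total tissue probability p_gm + p_wm + p_csf."""
        return self.p_gm.like(self.p_gm.data + self.p_wm.data + self.p_csf.data)


def check_same_grid(*grids: VolumeGrid) -> None:
    """Raise ShapeError unless all grids share shape and voxel size."""
    first = grids[0]
    for g in grids[1:]:
        if g.shape != first.shape:
            raise ShapeError(f"grid shape mismatch: {g.shape} vs {first.shape}")
        if not np.allclose(g.voxel_size, first.voxel_size):
            raise ShapeError(
                f"voxel size mismatch: {g.voxel_size} vs {first.voxel_size}"
            )
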