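"""Midsagittal voxel grid shared by all pipeline stages.

The grid is a 2-D lattice (anterior-posterior ``x`` by dorso-ventral ``y``)
carrying a boolean corpus-callosum mask.  Millimetre coordinates are always
expressed relative to the anterior-commissure reference point, which sits at
``origin`` (in fractional grid units) and maps to ``[0, 0]`` mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

#: 8-connectivity structuring element (objects are 8-connected throughout).
EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass(eq=False)
class VoxelGrid:
    """A masked 2-D voxel lattice.

    Parameters
    ----------
    shape
        ``(n_x, n_y)`` grid extent: anterior-posterior by dorso-ventral.
    voxel_size
        Isotropic voxel edge length in millimetres, strictly positive.
    origin
        Grid coordinates (fractional allowed) of the anterior-commissure
        reference point; must lie inside the grid bounds.
    mask
        Boolean array of shape ``(n_x, n_y)``; must form a single
        8-connected component.
    """

    shape: tuple[int, int]
    voxel_size: float
    origin: tuple[float, float]
    mask: np.ndarray
    _voxels: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.shape = (int(self.shape[0]), int(self.shape[1]))
        if self.shape[0] <= 0 or self.shape[1] <= 0:
            raise ValueError(f"grid dimensions must be positive, got {self.shape}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        self.voxel_size = float(self.voxel_size)
        self.origin = (float(self.origin[0]), float(self.origin[1]))
        if not (0 <= self.origin[0] <= self.shape[0] - 1
                and 0 <= self.origin[1] <= self.shape[1] - 1):
            raise ValueError(f"origin {self.origin} outside grid bounds {self.shape}")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match grid shape {self.shape}")
        if not self.mask.any():
            raise ValueError("mask is empty")
        _, n_comp = ndimage.label(self.mask, structure=EIGHT_CONN)
        if n_comp != 1:
            raise ValueError(
                f"mask must be a single 8-connected component, found {n_comp}")
        # fixed row-major voxel enumeration used by every masked-vector layout
        self._voxels = np.argwhere(self.mask)

    # ------------------------------------------------------------------ #

    @property
    def voxels(self) -> np.ndarray:
        """``(V, 2)`` integer indices of masked voxels in row-major order."""
        return self._voxels

    @property
    def n_voxels(self) -> int:
        return self._voxels.shape[0]

    @property
    def x_mm(self) -> np.ndarray:
        """Anterior-posterior mm coordinate of every masked voxel."""
        return (self._voxels[:, 0] - self.origin[0]) * self.voxel_size

    @property
    def y_mm(self) -> np.ndarray:
        """Dorso-ventral mm coordinate of every masked voxel."""
        return (self._voxels[:, 1] - self.origin[1]) * self.voxel_size

    def to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Convert grid indices (…, 2) to mm relative to the AC origin."""
        return (np.asarray(idx, dtype=float) - np.asarray(self.origin)) * self.voxel_size

    def embed(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a masked vector (or ``(V, k)`` stack) onto the full grid."""
        values = np.asarray(values)
        out_shape = self.shape + values.shape[1:]
        out = np.full(out_shape, fill, dtype=values.dtype if values.dtype.kind == "f" else float)
        out[self._voxels[:, 0], self._voxels[:, 1]] = values
        return out

    def extract(self, arr2d: np.ndarray) -> np.ndarray:
        """Gather the masked-vector view of a full-grid array."""
        return np.asarray(arr2d)[self._voxels[:, 0], self._voxels[:, 1]]

    def same_geometry(self, other: "VoxelGrid") -> bool:
        return (self.shape == other.shape
                and self.voxel_size == other.voxel_size
                and self.origin == other.origin
                and bool(np.array_equal(self.mask, other.mask)))
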