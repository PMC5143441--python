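"""Voxel grid geometry.

Conventions used project-wide:

* arrays are indexed ``[i, j, k]`` = (x, y, z); the acoustic beam marches
  along +z, slice by slice;
* voxel (i, j, k) is *centered* at ``origin + (i*dx, j*dy, k*dz)`` with
  0-based indices, so ``origin`` is the center of the first voxel;
* all lengths are SI meters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel lattice with spacing and origin metadata.

    Parameters
    ----------
    dims : (nx, ny, nz) voxel counts, each >= 1.
    spacing : (dx, dy, dz) voxel edge lengths in meters, each > 0.
    origin : physical position (m) of the center of voxel (0, 0, 0).
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise InvalidParameterError(f"dims must be three integers >= 1, got {self.dims}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InvalidParameterError(f"spacing must be three positive lengths, got {self.spacing}")

    # -- derived geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    @property
    def dx(self) -> float:
        return self.spacing[0]

    @property
    def dy(self) -> float:
        return self.spacing[1]

    @property
    def dz(self) -> float:
        return self.spacing[2]

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical center coordinates of the voxels along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    @property
    def x(self) -> np.ndarray:
        return self.axis_coords(0)

    @property
    def y(self) -> np.ndarray:
        return self.axis_coords(1)

    @property
    def z(self) -> np.ndarray:
        return self.axis_coords(2)

    @property
    def z_extent(self) -> float:
        """Span from the entry face of the first slab to the exit face of the last."""
        return self.dims[2] * self.dz

    def index_to_world(self, index) -> np.ndarray:
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, point) -> np.ndarray:
        """Fractional voxel index of a physical point (no rounding)."""
        p = np.asarray(point, dtype=float)
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)

    def contains_index(self, index) -> bool:
        idx = np.asarray(index, dtype=float)
        return bool(np.all(idx >= 0) and np.all(idx <= np.asarray(self.dims) - 1))


def centered_grid(dims, spacing, z0: float = 0.0) -> VoxelGrid:
    """Grid whose lateral (x, y) extent is centered on the beam axis x=y=0.

    ``z0`` is the z position of the first slice (the solver entry plane).
    """
    dims = tuple(int(d) for d in dims)
    spacing = tuple(float(s) for s in spacing)
    origin = (
        -0.5 * (dims[0] - 1) * spacing[0],
        -0.5 * (dims[1] - 1) * spacing[1],
        float(z0),
    )
    return VoxelGrid(dims=dims, spacing=spacing, origin=origin)
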