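"""Simulation-based phase-aberration correction.

Every array element is simulated once at unit amplitude and zero phase
through the acoustic model; the resulting per-element complex fields (the
*bank*) hold the phase each element's wave accrues to any voxel.  Driving
element i with the conjugate phase ``phi_i = -arg(p_i(target))`` makes all
contributions arrive in phase at the target (in-silico time reversal), and
because the full 3D fields are stored, phase solutions for additional
treatment locations are pure lookups with no further propagation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .arrays import TransducerArray, element_source_plane
from .errors import ContractError, NumericalError, RangeError
from .grid import VoxelGrid
from .models import AcousticModel
from .solver import PressureVolume, SolverConfig, propagate
from .units import wrap_phase

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Region:
    """Axis-aligned voxel-index box [x0:x1, y0:y1, z0:z1) within a grid."""

    x0: int
    x1: int
    y0: int
    y1: int
    z0: int
    z1: int

    @classmethod
    def full(cls, grid: VoxelGrid) -> "Region":
        nx, ny, nz = grid.dims
        return cls(0, nx, 0, ny, 0, nz)

    @classmethod
    def around(cls, grid: VoxelGrid, center, half_extent) -> "Region":
        """Box of physical half-extent (m) around a physical center point."""
        c = np.asarray(grid.world_to_index(center))
        h = np.asarray(half_extent, dtype=float) / np.asarray(grid.spacing)
        lo = np.maximum(0, np.floor(c - h).astype(int))
        hi = np.minimum(np.asarray(grid.dims), np.ceil(c + h).astype(int) + 1)
        return cls(lo[0], hi[0], lo[1], hi[1], lo[2], hi[2])

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return (slice(self.x0, self.x1), slice(self.y0, self.y1), slice(self.z0, self.z1))

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.x1 - self.x0, self.y1 - self.y0, self.z1 - self.z0)


@dataclass
class ElementFieldBank:
    """Per-element zero-phase unit-drive complex fields over a region.

    ``fields`` has shape (n_elements, *region.shape); all records share the
    grid, the frequency and the stored region.
    """

    fields: np.ndarray
    grid: VoxelGrid
    frequency: float
    region: Region
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.fields = np.asarray(self.fields)
        if self.fields.ndim != 4 or self.fields.shape[1:] != self.region.shape:
            raise ContractError(
                f"bank fields shape {self.fields.shape} does not match region {self.region.shape}"
            )

    @property
    def n_elements(self) -> int:
        return self.fields.shape[0]

    def _local_index(self, target) -> np.ndarray:
        idx = self.grid.world_to_index(np.asarray(target, dtype=float))
        local = idx - np.array([self.region.x0, self.region.y0, self.region.z0])
        shape = np.asarray(self.region.shape)
        if np.any(local < -1e-9) or np.any(local > shape - 1 + 1e-9):
            raise RangeError(f"target {target} outside the bank's stored region")
        return np.clip(local, 0, shape - 1)

    def complex_at(self, target) -> np.ndarray:
        """Trilinear complex interpolation of every element field at a point."""
        from scipy.ndimage import map_coordinates

        local = self._local_index(target)
        coords = local.reshape(3, 1)
        out = np.empty(self.n_elements, dtype=complex)
        for i in range(self.n_elements):
            re = map_coordinates(self.fields[i].real, coords, order=1, mode="nearest")
            im = map_coordinates(self.fields[i].imag, coords, order=1, mode="nearest")
            out[i] = complex(re[0], im[0])
        return out


@dataclass
class PhaseSolution:
    """Per-element conjugate drive phases for one treatment location."""

    phases: np.ndarray
    target: np.ndarray
    target_index: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.phases = wrap_phase(np.asarray(self.phases, dtype=float))
        self.target = np.asarray(self.target, dtype=float)

    @property
    def n_elements(self) -> int:
        return self.phases.shape[0]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def simulate_element_bank(
    array: TransducerArray,
    model: AcousticModel,
    cfg: SolverConfig | None = None,
    region: Region | None = None,
    c_coupling: float | None = None,
    a_coupling: float | None = None,
    checkpoint=None,
    progress: bool = False,
) -> ElementFieldBank:
    """Propagate every element at unit amplitude / zero phase; store fields.

    Elements are simulated independently (no shared mutable state).  When a
    ``checkpoint`` HDF5 path is given, each element's field is written as it
    completes and a rerun resumes from the elements already present.
    """
    cfg = cfg or SolverConfig()
    g = model.grid
    region = region or Region.full(g)
    c0 = float(np.mean(model.speed[:, :, 0])) if c_coupling is None else c_coupling
    a0 = float(np.mean(model.attenuation[:, :, 0])) if a_coupling is None else a_coupling

    fields = np.empty((array.n_elements, *region.shape), dtype=complex)
    done = set()
    h5 = None
    if checkpoint is not None:
        import h5py

        h5 = h5py.File(checkpoint, "a")
        h5.attrs["n_elements"] = array.n_elements
        h5.attrs["region"] = [region.x0, region.x1, region.y0, region.y1, region.z0, region.z1]
        h5.attrs["frequency"] = array.frequency
        for name in h5:
            if name.startswith("element_"):
                i = int(name.split("_")[1])
                fields[i] = h5[name][...]
                done.add(i)

    try:
        for i in range(array.n_elements):
            if i in done:
                continue
            try:
                sp = element_source_plane(array, i, g, c0, a0, apply_drive=False)
                vol = propagate(sp, model, cfg)
            except Exception as exc:
                raise NumericalError(f"propagation failed for element {i}: {exc}") from exc
            fields[i] = vol.pressure[region.slices]
            if h5 is not None:
                h5.create_dataset(f"element_{i:03d}", data=fields[i].astype(np.complex64))
                h5.flush()
            if progress:
                log.info("bank element %d/%d done", i + 1, array.n_elements)
    finally:
        if h5 is not None:
            h5.close()

    return ElementFieldBank(
        fields=fields, grid=g, frequency=array.frequency, region=region,
        metadata={"coupling_speed": c0, "coupling_attenuation": a0},
    )


def correction_phases(bank: ElementFieldBank, target) -> PhaseSolution:
    """Conjugate-phase solution at a treatment location.

    ``phi_i = -arg(p_i(target))`` wrapped to (-pi, pi]; element amplitudes
    are never altered.  A vanishing element amplitude leaves the phase
    undefined; it is set to 0 with a logged warning.
    """
    p = bank.complex_at(target)
    phases = np.zeros(bank.n_elements)
    nz = np.abs(p) > 0
    phases[nz] = -np.angle(p[nz])
    n_null = int(np.count_nonzero(~nz))
    if n_null:
        log.warning("correction_phases: %d element(s) with zero amplitude at target; phase set to 0", n_null)
    idx = bank.grid.world_to_index(target)
    return PhaseSolution(
        phases=phases,
        target=np.asarray(target, dtype=float),
        target_index=idx,
        provenance={"n_elements": bank.n_elements, "frequency": bank.frequency},
    )


def multi_target_solutions(bank: ElementFieldBank, targets) -> list[PhaseSolution]:
    """Phase solutions for many treatment locations by lookup only.

    No propagation is performed: cost is O(targets x elements) on the
    already-computed bank.
    """
    return [correction_phases(bank, t) for t in targets]


def corrected_field(
    array: TransducerArray,
    model: AcousticModel,
    cfg: SolverConfig | None,
    solution: PhaseSolution,
    element_planes: np.ndarray | None = None,
) -> PressureVolume:
    """Full-array propagation with the solution's drive phases applied.

    The returned volume's metadata reports the peak location and magnitude
    and the peak-to-target distance (m).
    """
    if solution.n_elements != array.n_elements:
        raise ContractError("solution element count does not match the array")
    driven = array.with_phases(solution.phases)
    from .solver import simulate_full_array

    vol = simulate_full_array(driven, model, cfg, element_planes=element_planes)
    peak = vol.peak_position()
    vol.metadata.update(
        peak_position=peak,
        peak_magnitude=vol.peak_value(),
        target=solution.target,
        peak_to_target_m=float(np.linalg.norm(peak - solution.target)),
    )
    return vol
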