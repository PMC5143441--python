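"""Simulation-based treatment metrics.

Three procedures built on the solver + correction stack:

* **steering-improvement maps** -- ratio of corrected to uncorrected
  focal-plane peak pressure over a lattice of electronically steered
  targets;
* **misregistration maps** -- focal-plane peak pressure (normalized to the
  unshifted case) when the model is translated laterally while the phase
  solution is kept fixed, mimicking a registration error;
* **phase-length autocorrelation** -- lateral map of straight-ray
  accumulated phase through the model, converted to phasors and
  cross-correlated with a beam-sized circular patch of itself; the contour
  areas of the normalized correlation predict how tolerant a given medium
  is to misregistration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .arrays import TransducerArray, geometric_phases, unit_element_planes
from .correction import (
    ElementFieldBank,
    PhaseSolution,
    Region,
    correction_phases,
    simulate_element_bank,
)
from .errors import GeometryError, InvalidParameterError
from .models import AcousticModel, translate_model
from .solver import SolverConfig, simulate_full_array
from .units import WATER_ATTENUATION, WATER_DENSITY, WATER_SPEED, propagation_constant

log = logging.getLogger(__name__)


@dataclass
class RatioMap:
    """2D lattice of non-negative scalar ratios over (x, y) shifts/targets."""

    values: np.ndarray
    x: np.ndarray
    y: np.ndarray
    reference: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.values.shape != (self.x.size, self.y.size):
            raise InvalidParameterError("ratio map shape must match its lattice")
        if np.any(self.values < 0):
            raise InvalidParameterError("ratios must be >= 0")


@dataclass
class PhaseLengthMap:
    """Accumulated straight-ray phase phi(x, y) through a model (rad)."""

    phase: np.ndarray
    spacing: tuple[float, float]
    sigma_px: float = 0.0

    def __post_init__(self):
        self.phase = np.asarray(self.phase, dtype=float)
        if not np.all(np.isfinite(self.phase)):
            raise InvalidParameterError("phase-length map must be finite")

    @property
    def phasor(self) -> np.ndarray:
        """Unit-modulus phasor form e^{j phi}, the interference-relevant view."""
        return np.exp(1j * self.phase)


@dataclass
class CorrelationResult:
    """Normalized phasor cross-correlation map with contour areas (mm^2)."""

    correlation: np.ndarray
    spacing: tuple[float, float]
    contour_areas_mm2: dict = field(default_factory=dict)

    def __post_init__(self):
        self.correlation = np.asarray(self.correlation, dtype=float)


# ---------------------------------------------------------------------------
# focal-plane helpers
# ---------------------------------------------------------------------------

def _focal_slice_index(model: AcousticModel, focal_z: float) -> int:
    k = int(round((focal_z - model.grid.origin[2]) / model.grid.dz))
    if not (0 <= k < model.grid.dims[2]):
        raise GeometryError(f"focal plane z={focal_z} outside the model grid")
    return k


def focal_plane_peak(volume, focal_z: float) -> float:
    """Maximum |p| over the transverse plane nearest to focal_z."""
    k = _focal_slice_index_from_grid(volume.grid, focal_z)
    return float(np.abs(volume.pressure[:, :, k]).max())


def _focal_slice_index_from_grid(grid, focal_z: float) -> int:
    k = int(round((focal_z - grid.origin[2]) / grid.dz))
    if not (0 <= k < grid.dims[2]):
        raise GeometryError(f"focal plane z={focal_z} outside the grid")
    return k


# ---------------------------------------------------------------------------
# steering-improvement map
# ---------------------------------------------------------------------------

def steering_improvement_map(
    array: TransducerArray,
    model: AcousticModel,
    cfg: SolverConfig | None,
    targets_x: np.ndarray,
    targets_y: np.ndarray,
    focal_z: float | None = None,
    bank: ElementFieldBank | None = None,
    c_ref: float = WATER_SPEED,
) -> RatioMap:
    """Corrected/uncorrected focal-plane peak ratio per steered target.

    For each lattice target the uncorrected drive uses water-path geometric
    steering phases and the corrected drive uses conjugate phases from the
    element bank; the ratio compares the focal-plane peak pressures of the
    two full-array simulations.
    """
    cfg = cfg or SolverConfig()
    g = model.grid
    focal_z = array.focal_length if focal_z is None else focal_z
    targets_x = np.atleast_1d(np.asarray(targets_x, dtype=float))
    targets_y = np.atleast_1d(np.asarray(targets_y, dtype=float))

    if bank is None:
        half = (
            max(abs(targets_x).max(), g.dx) + 2 * g.dx,
            max(abs(targets_y).max(), g.dy) + 2 * g.dy,
            2 * g.dz,
        )
        region = Region.around(g, (0.0, 0.0, focal_z), half)
        bank = simulate_element_bank(array, model, cfg, region=region)

    planes = unit_element_planes(
        array, g,
        c_medium=float(np.mean(model.speed[:, :, 0])),
        a_medium=float(np.mean(model.attenuation[:, :, 0])),
    )

    values = np.empty((targets_x.size, targets_y.size))
    for i, tx in enumerate(targets_x):
        for j, ty in enumerate(targets_y):
            target = np.array([tx, ty, focal_z])
            uncorr = array.with_phases(geometric_phases(array, target, c_ref))
            v_u = simulate_full_array(uncorr, model, cfg, element_planes=planes)
            sol = correction_phases(bank, target)
            corr = array.with_phases(sol.phases)
            v_c = simulate_full_array(corr, model, cfg, element_planes=planes)
            values[i, j] = focal_plane_peak(v_c, focal_z) / focal_plane_peak(v_u, focal_z)
    return RatioMap(values=values, x=targets_x, y=targets_y,
                    reference="corrected/uncorrected focal-plane peak pressure")


# ---------------------------------------------------------------------------
# misregistration map
# ---------------------------------------------------------------------------

def misregistration_map(
    array: TransducerArray,
    model: AcousticModel,
    cfg: SolverConfig | None,
    solution: PhaseSolution,
    shifts_x: np.ndarray,
    shifts_y: np.ndarray,
    focal_z: float | None = None,
    background=(WATER_SPEED, WATER_ATTENUATION, WATER_DENSITY),
) -> RatioMap:
    """Focal-plane peak vs lateral model shift at a *fixed* phase solution.

    Each lattice cell translates the model perpendicular to the beam,
    re-simulates the full array with the unshifted-model phases, and
    records the focal-plane peak normalized by the zero-shift value (so the
    origin cell is exactly 1).
    """
    cfg = cfg or SolverConfig()
    g = model.grid
    focal_z = array.focal_length if focal_z is None else focal_z
    shifts_x = np.atleast_1d(np.asarray(shifts_x, dtype=float))
    shifts_y = np.atleast_1d(np.asarray(shifts_y, dtype=float))
    driven = array.with_phases(solution.phases)
    planes = unit_element_planes(
        array, g,
        c_medium=float(np.mean(model.speed[:, :, 0])),
        a_medium=float(np.mean(model.attenuation[:, :, 0])),
    )

    def peak_for(shift):
        shifted = translate_model(model, shift, background=background)
        vol = simulate_full_array(driven, shifted, cfg, element_planes=planes)
        return focal_plane_peak(vol, focal_z)

    ref = peak_for((0.0, 0.0))
    values = np.empty((shifts_x.size, shifts_y.size))
    for i, sx in enumerate(shifts_x):
        for j, sy in enumerate(shifts_y):
            if sx == 0.0 and sy == 0.0:
                values[i, j] = 1.0
            else:
                values[i, j] = peak_for((sx, sy)) / ref
    return RatioMap(values=values, x=shifts_x, y=shifts_y,
                    reference="focal-plane peak normalized to zero shift")


# ---------------------------------------------------------------------------
# phase-length map and phasor autocorrelation
# ---------------------------------------------------------------------------

def phase_length_map(model: AcousticModel, frequency: float, sigma_px: float = 0.0) -> PhaseLengthMap:
    """Straight-ray accumulated phase along +z: phi(x,y) = sum_z b dz.

    No refraction is modeled -- this is a path accumulation, not a wave
    solve.  Gaussian smoothing (``sigma_px`` in pixels, e.g. 2 to mimic CT
    measurement noise suppression) is applied to the phase map before the
    phasor conversion.
    """
    if sigma_px < 0:
        raise InvalidParameterError("smoothing sigma must be >= 0")
    b = propagation_constant(model.speed, frequency)
    phi = b.sum(axis=2) * model.grid.dz
    if sigma_px > 0:
        phi = ndimage.gaussian_filter(phi, sigma=sigma_px)
    return PhaseLengthMap(phase=phi, spacing=(model.grid.dx, model.grid.dy), sigma_px=sigma_px)


def beam_radius_at_plane(array: TransducerArray, z_plane: float) -> float:
    """Cone-geometry beam radius where the converging beam crosses z_plane."""
    F = array.focal_length
    return 0.5 * array.aperture_diameter * abs(F - z_plane) / F


def phasor_autocorrelation(
    plm: PhaseLengthMap,
    aperture_radius: float,
    fractions=(0.25, 0.50, 0.75),
    center: tuple[float, float] | None = None,
) -> CorrelationResult:
    """Normalized complex cross-correlation of a beam-sized phasor patch.

    A circular patch of the phasor map (radius ``aperture_radius``,
    centered on the beam axis, default the map center) is correlated
    against the full phasor map; the magnitude is normalized so its global
    maximum is 1.  Contour areas (mm^2) count lattice cells at or above
    each fraction of the maximum; they are non-increasing in the fraction.
    """
    nx, ny = plm.phase.shape
    dx, dy = plm.spacing
    if aperture_radius >= 0.5 * min(nx * dx, ny * dy):
        raise GeometryError("aperture radius must be smaller than half the lateral extent")
    if aperture_radius <= 0:
        raise InvalidParameterError("aperture radius must be > 0")

    cx = 0.5 * (nx - 1) * dx if center is None else center[0]
    cy = 0.5 * (ny - 1) * dy if center is None else center[1]
    xs = np.arange(nx) * dx
    ys = np.arange(ny) * dy
    mask = ((xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2) <= aperture_radius**2

    phasor = plm.phasor
    patch = np.where(mask, phasor, 0.0)
    corr = signal.fftconvolve(phasor, np.conj(patch[::-1, ::-1]), mode="same")
    mag = np.abs(corr)
    mag /= mag.max()

    cell_mm2 = dx * dy * 1e6
    areas = {}
    for f in sorted(fractions):
        areas[float(f)] = float(np.count_nonzero(mag >= f * 1.0) * cell_mm2)
    return CorrelationResult(correlation=mag, spacing=plm.spacing, contour_areas_mm2=areas)
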