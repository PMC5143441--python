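"""Voxelized acoustic models and model builders.

An :class:`AcousticModel` is a voxel grid of medium properties: sound speed
(m/s), attenuation (stored frequency-normalized, dB/(cm MHz)) and density
(kg/m^3).  Builders construct homogeneous water, the random-relief plastic
aberrator plate used for bench-top validation of aberration correction,
synthetic skull-like Hounsfield-unit (HU) volumes, and CT-derived models via
a configurable HU -> property mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import GeometryError, InvalidParameterError
from .grid import VoxelGrid
from .units import WATER_ATTENUATION, WATER_DENSITY, WATER_SPEED, propagation_constant

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class AcousticModel:
    """Per-voxel acoustic properties on a :class:`VoxelGrid`.

    ``speed`` (m/s) and ``density`` (kg/m^3) must be positive everywhere;
    ``attenuation`` (dB/(cm MHz)) non-negative.  Arrays are indexed
    ``[x, y, z]`` with propagation along +z.
    """

    grid: VoxelGrid
    speed: np.ndarray
    attenuation: np.ndarray
    density: np.ndarray

    def __post_init__(self):
        for name in ("speed", "attenuation", "density"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.grid.shape:
                raise InvalidParameterError(
                    f"{name} shape {arr.shape} does not match grid {self.grid.shape}"
                )
            setattr(self, name, arr)
        if np.any(self.speed <= 0):
            raise InvalidParameterError("speed must be > 0 everywhere")
        if np.any(self.density <= 0):
            raise InvalidParameterError("density must be > 0 everywhere")
        if np.any(self.attenuation < 0):
            raise InvalidParameterError("attenuation must be >= 0 everywhere")

    def b(self, frequency_hz: float) -> np.ndarray:
        """Per-voxel propagation constant 2 pi f / c (rad/m)."""
        return propagation_constant(self.speed, frequency_hz)

    def impedance(self) -> np.ndarray:
        """Characteristic acoustic impedance rho * c (rayl)."""
        return self.density * self.speed


@dataclass
class HeightMap:
    """2D relief map of a flat-based plate (the 3D-printable aberrator).

    ``relief`` holds the height (m) of the random surface on top of
    ``base_thickness``; total thickness is ``base + relief``.
    """

    relief: np.ndarray
    base_thickness: float
    spacing: tuple[float, float]

    def __post_init__(self):
        self.relief = np.asarray(self.relief, dtype=float)
        if self.relief.ndim != 2:
            raise InvalidParameterError("relief must be a 2D array")
        if self.base_thickness <= 0:
            raise InvalidParameterError("base thickness must be > 0")
        if np.any(self.relief < 0):
            raise InvalidParameterError("relief heights must be >= 0")

    @property
    def total_thickness(self) -> np.ndarray:
        return self.base_thickness + self.relief

    @property
    def lateral_extent(self) -> tuple[float, float]:
        return (
            self.relief.shape[0] * self.spacing[0],
            self.relief.shape[1] * self.spacing[1],
        )


@dataclass
class HUVolume:
    """A CT-like volume of Hounsfield units (water ~ 0 HU by convention)."""

    grid: VoxelGrid
    hu: np.ndarray

    def __post_init__(self):
        self.hu = np.asarray(self.hu, dtype=float)
        if self.hu.shape != self.grid.shape:
            raise InvalidParameterError(
                f"hu shape {self.hu.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.hu)):
            raise InvalidParameterError("hu values must be finite")


# ---------------------------------------------------------------------------
# HU -> acoustic property mapping
# ---------------------------------------------------------------------------

@dataclass
class HUMappingConfig:
    """Parametric HU -> (density, speed, attenuation) mapping.

    Density is affine in HU over the bone range; speed and attenuation are
    monotone piecewise-linear curves over HU (knots as (hu, value) pairs,
    clamped beyond the end knots).  Voxels below ``bone_threshold_hu`` get
    the homogeneous ``background`` (water / soft tissue) properties.

    The default curves are a documented stand-in with water at the bottom
    knot and cortical-bone-like values (2740 m/s) at the top; real
    calibrated curves can be supplied through the same knot lists.
    """

    density_intercept: float = 1000.0   # kg/m^3 at 0 HU
    density_slope: float = 1.0          # kg/m^3 per HU
    speed_knots: tuple = ((0.0, 1500.0), (2000.0, 2740.0))
    attenuation_knots: tuple = ((0.0, 0.0), (2000.0, 8.0))
    bone_threshold_hu: float = 300.0
    background_speed: float = WATER_SPEED
    background_attenuation: float = WATER_ATTENUATION
    background_density: float = WATER_DENSITY

    def __post_init__(self):
        if self.density_slope <= 0:
            raise InvalidParameterError("density slope must be > 0")
        for name in ("speed_knots", "attenuation_knots"):
            knots = tuple((float(h), float(v)) for h, v in getattr(self, name))
            if len(knots) < 2:
                raise InvalidParameterError(f"{name} needs at least two knots")
            hus = [h for h, _ in knots]
            vals = [v for _, v in knots]
            if sorted(hus) != hus or len(set(hus)) != len(hus):
                raise InvalidParameterError(f"{name} knots must be strictly sorted in HU")
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise InvalidParameterError(f"{name} values must be non-decreasing")
            setattr(self, name, knots)

    def _interp(self, knots, hu):
        xs = np.array([h for h, _ in knots])
        ys = np.array([v for _, v in knots])
        return np.interp(hu, xs, ys)  # np.interp clamps at the end knots

    def speed_of(self, hu):
        return self._interp(self.speed_knots, hu)

    def attenuation_of(self, hu):
        return self._interp(self.attenuation_knots, hu)

    def density_of(self, hu):
        return self.density_intercept + self.density_slope * np.asarray(hu, dtype=float)


def map_hu_to_properties(volume: HUVolume, cfg: HUMappingConfig | None = None) -> AcousticModel:
    """Build an :class:`AcousticModel` from a HU volume.

    Sub-threshold voxels receive the background properties bit-exactly;
    bone voxels get affine density and piecewise-linear speed/attenuation.
    HU beyond the outer knots are clamped with a logged warning rather than
    raising.
    """
    cfg = cfg or HUMappingConfig()
    hu = volume.hu
    lo = min(cfg.speed_knots[0][0], cfg.attenuation_knots[0][0])
    hi = max(cfg.speed_knots[-1][0], cfg.attenuation_knots[-1][0])
    bone = hu >= cfg.bone_threshold_hu
    n_out = int(np.count_nonzero(bone & ((hu < lo) | (hu > hi))))
    if n_out:
        log.warning(
            "map_hu_to_properties: %d bone voxels outside curve range [%g, %g] HU; clamped",
            n_out, lo, hi,
        )

    speed = np.full(hu.shape, cfg.background_speed)
    att = np.full(hu.shape, cfg.background_attenuation)
    rho = np.full(hu.shape, cfg.background_density)
    speed[bone] = cfg.speed_of(hu[bone])
    att[bone] = cfg.attenuation_of(hu[bone])
    rho[bone] = cfg.density_of(hu[bone])
    return AcousticModel(grid=volume.grid, speed=speed, attenuation=att, density=rho)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def make_water_model(
    dims,
    spacing,
    c_water: float = WATER_SPEED,
    a_water: float = WATER_ATTENUATION,
    rho_water: float = WATER_DENSITY,
    origin=(0.0, 0.0, 0.0),
    grid: VoxelGrid | None = None,
) -> AcousticModel:
    """Homogeneous reference medium (water or generic soft tissue)."""
    if c_water <= 0 or rho_water <= 0:
        raise InvalidParameterError("speed and density must be > 0")
    if a_water < 0:
        raise InvalidParameterError("attenuation must be >= 0")
    g = grid or VoxelGrid(dims=tuple(dims), spacing=tuple(spacing), origin=tuple(origin))
    shape = g.shape
    return AcousticModel(
        grid=g,
        speed=np.full(shape, float(c_water)),
        attenuation=np.full(shape, float(a_water)),
        density=np.full(shape, float(rho_water)),
    )


def _smooth_noise_2d(rng: np.random.Generator, shape, sigma_px) -> np.ndarray:
    """Seeded uniform white noise, Gaussian-smoothed; returns raw (unscaled) field."""
    noise = rng.uniform(-1.0, 1.0, size=shape)
    if np.any(np.asarray(sigma_px) > 0):
        noise = ndimage.gaussian_filter(noise, sigma=sigma_px, mode="wrap")
    return noise


def generate_aberrator(
    seed: int,
    grid: VoxelGrid,
    base_thickness: float = 7.5e-3,
    max_relief: float = 4.0e-3,
    feature_scale: float = 5.0e-3,
    plate_speed: float = 2492.0,
    plate_attenuation: float = 4.72,
    plate_density: float = 1175.0,
    plate_entry_z: float | None = None,
    water_speed: float = WATER_SPEED,
    water_attenuation: float = WATER_ATTENUATION,
    water_density: float = WATER_DENSITY,
) -> tuple[AcousticModel, HeightMap]:
    """Water-immersed random-relief plastic plate (skull-mimicking aberrator).

    The plate is flat on the entry (upstream) side and carries a random
    relief on the exit side: seeded uniform noise smoothed to
    ``feature_scale`` laterally, then min-max rescaled to span exactly
    [0, max_relief].  Defaults reproduce the printed design: 7.5 mm base,
    0-4 mm relief (7.5-11.5 mm total) and the measured plastic properties
    2492 m/s, 4.72 dB/(cm MHz), enough to span >= 2 pi of phase at 1 MHz.

    Voxelization assigns plate properties to voxels whose *center* lies
    inside the plate.  Deterministic for a fixed seed.
    """
    if base_thickness <= 0:
        raise InvalidParameterError("base thickness must be > 0")
    if max_relief < 0:
        raise InvalidParameterError("max relief must be >= 0")
    nx, ny, nz = grid.dims
    dz = grid.dz
    # default: leave a small water gap before the plate entry face
    z0 = grid.origin[2] + 2 * dz if plate_entry_z is None else float(plate_entry_z)
    z_top_max = z0 + base_thickness + max_relief
    z_last = grid.z[-1]
    if z_top_max > z_last - dz:
        raise GeometryError(
            f"grid z-extent too small for plate: needs {z_top_max - grid.origin[2]:.4g} m "
            f"plus surrounding water, has {grid.z_extent:.4g} m"
        )

    rng = np.random.default_rng(seed)
    if max_relief > 0:
        sigma_px = (feature_scale / grid.dx, feature_scale / grid.dy)
        raw = _smooth_noise_2d(rng, (nx, ny), sigma_px)
        lo, hi = raw.min(), raw.max()
        relief = (raw - lo) / (hi - lo) * max_relief
    else:
        relief = np.zeros((nx, ny))
    hmap = HeightMap(relief=relief, base_thickness=base_thickness, spacing=(grid.dx, grid.dy))

    zc = grid.z[None, None, :]                       # voxel center z
    top = (z0 + hmap.total_thickness)[:, :, None]    # plate exit surface
    inside = (zc >= z0) & (zc < top)

    model = make_water_model(
        grid.dims, grid.spacing, water_speed, water_attenuation, water_density,
        origin=grid.origin,
    )
    model.speed[inside] = plate_speed
    model.attenuation[inside] = plate_attenuation
    model.density[inside] = plate_density
    return model, hmap


def generate_synthetic_skull(
    seed: int,
    grid: VoxelGrid,
    mean_thickness: float = 6.0e-3,
    thickness_variation: float = 2.0e-3,
    feature_scale: float = 25.0e-3,
    curvature_radius: float = 0.2,
    hu_bone: float = 1200.0,
    hu_texture_amplitude: float = 200.0,
    hu_texture_scale: float = 2.0e-3,
    entry_z: float | None = None,
) -> HUVolume:
    """Synthetic skull-like HU slab: smooth thickness, internal HU texture.

    Emulates a CT of a curved bone flap: a gently bowed slab whose thickness
    varies smoothly with a *long* lateral correlation length
    (``feature_scale``, default 25 mm -- much longer than the aberrator's
    relief), with seeded internal HU texture standing in for trabecular
    inhomogeneity and CT noise.  Deterministic per seed.  Background is
    0 HU (water).
    """
    if thickness_variation < 0 or mean_thickness <= 0:
        raise InvalidParameterError("thickness parameters must be positive")
    nx, ny, nz = grid.dims
    z0 = grid.origin[2] + 2 * grid.dz if entry_z is None else float(entry_z)
    rng = np.random.default_rng(seed)

    # smooth, long-wavelength thickness map
    if thickness_variation > 0:
        sigma_px = (feature_scale / grid.dx, feature_scale / grid.dy)
        raw = _smooth_noise_2d(rng, (nx, ny), sigma_px)
        lo, hi = raw.min(), raw.max()
        thick = mean_thickness + (2 * (raw - lo) / (hi - lo) - 1.0) * thickness_variation
    else:
        thick = np.full((nx, ny), mean_thickness)

    # gently curved entry surface (spherical bow toward the transducer)
    xx = grid.x[:, None]
    yy = grid.y[None, :]
    bow = (xx**2 + yy**2) / (2.0 * curvature_radius)
    entry = z0 + bow
    exit_ = entry + thick
    if np.max(exit_) > grid.z[-1] - grid.dz:
        raise GeometryError("grid z-extent too small for the synthetic skull slab")

    zc = grid.z[None, None, :]
    inside = (zc >= entry[:, :, None]) & (zc < exit_[:, :, None])

    hu = np.zeros(grid.shape)
    if hu_texture_amplitude > 0:
        sig = tuple(hu_texture_scale / s for s in grid.spacing)
        tex = _smooth_noise_3d(rng, grid.shape, sig)
        tex = tex / max(np.abs(tex).max(), np.finfo(float).tiny) * hu_texture_amplitude
    else:
        tex = np.zeros(grid.shape)
    hu[inside] = hu_bone + tex[inside]
    return HUVolume(grid=grid, hu=hu)


def _smooth_noise_3d(rng: np.random.Generator, shape, sigma_px) -> np.ndarray:
    noise = rng.uniform(-1.0, 1.0, size=shape)
    if np.any(np.asarray(sigma_px) > 0):
        noise = ndimage.gaussian_filter(noise, sigma=sigma_px, mode="wrap")
    return noise


def translate_model(
    model: AcousticModel,
    shift: tuple[float, float],
    background: tuple[float, float, float] = (WATER_SPEED, WATER_ATTENUATION, WATER_DENSITY),
) -> AcousticModel:
    """Shift property maps laterally by the nearest whole-voxel amount.

    Shifts are quantized to the grid (no interpolation, so binary material
    boundaries are preserved); vacated voxels are filled with the
    ``background`` (speed, attenuation, density) properties.  Used to mimic
    transducer/model misregistration perpendicular to the beam.
    """
    g = model.grid
    n_shift = (int(round(shift[0] / g.dx)), int(round(shift[1] / g.dy)))
    if abs(n_shift[0]) >= g.dims[0] or abs(n_shift[1]) >= g.dims[1]:
        raise GeometryError(f"shift {shift} exceeds lateral model extent")

    def _shift2(arr, fill):
        out = np.full_like(arr, fill)
        sx, sy = n_shift
        src_x = slice(max(0, -sx), arr.shape[0] - max(0, sx))
        dst_x = slice(max(0, sx), arr.shape[0] - max(0, -sx))
        src_y = slice(max(0, -sy), arr.shape[1] - max(0, sy))
        dst_y = slice(max(0, sy), arr.shape[1] - max(0, -sy))
        out[dst_x, dst_y, :] = arr[src_x, src_y, :]
        return out

    return AcousticModel(
        grid=g,
        speed=_shift2(model.speed, background[0]),
        attenuation=_shift2(model.attenuation, background[1]),
        density=_shift2(model.density, background[2]),
    )
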