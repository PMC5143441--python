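"""Spherical-cap phased-array transducer and entry-plane source fields.

The array sits in the model frame with its apex at the origin and its
geometric focus (center of curvature of the cap) at ``(0, 0, focal_length)``
on the +z beam axis.  Each element's pressure on the solver entry plane is a
Rayleigh-Sommerfeld summation over point sub-sources discretizing the
element surface at <= lambda/2 spacing, propagated through homogeneous
coupling water.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, GeometryError, InvalidParameterError
from .grid import VoxelGrid
from .units import (
    WATER_ATTENUATION,
    WATER_SPEED,
    attenuation_to_neper,
    wrap_phase,
)

log = logging.getLogger(__name__)

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class TransducerArray:
    """Phased-array on a spherical cap.

    ``centers`` (n, 3) element center positions (m), ``normals`` (n, 3)
    unit outward normals pointing toward the focus, ``areas`` (n,) element
    areas (m^2), ``drive`` (n,) complex per-element drive (amplitude and
    phase).  The geometric focus is at (0, 0, focal_length).
    """

    frequency: float
    focal_length: float
    aperture_diameter: float
    centers: np.ndarray
    normals: np.ndarray
    areas: np.ndarray
    drive: np.ndarray | None = None

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.normals = np.atleast_2d(np.asarray(self.normals, dtype=float))
        self.areas = np.atleast_1d(np.asarray(self.areas, dtype=float))
        n = self.centers.shape[0]
        if self.normals.shape != (n, 3) or self.areas.shape != (n,):
            raise ContractError("centers, normals and areas must agree in element count")
        if np.any(self.areas <= 0):
            raise InvalidParameterError("element areas must be > 0")
        if self.drive is None:
            self.drive = np.ones(n, dtype=complex)
        else:
            self.drive = np.asarray(self.drive, dtype=complex)
            if self.drive.shape != (n,):
                raise ContractError("drive must have one complex value per element")

    @property
    def n_elements(self) -> int:
        return self.centers.shape[0]

    @property
    def focus(self) -> np.ndarray:
        """Geometric focus = center of curvature of the cap."""
        return np.array([0.0, 0.0, self.focal_length])

    @property
    def cap_half_angle(self) -> float:
        return float(np.arcsin(0.5 * self.aperture_diameter / self.focal_length))

    @property
    def cap_area(self) -> float:
        return float(2.0 * np.pi * self.focal_length**2 * (1.0 - np.cos(self.cap_half_angle)))

    def with_phases(self, phases: np.ndarray) -> "TransducerArray":
        """Copy of the array with drive phases set (amplitudes preserved)."""
        phases = np.asarray(phases, dtype=float)
        if phases.shape != (self.n_elements,):
            raise ContractError("one phase per element required")
        return TransducerArray(
            frequency=self.frequency,
            focal_length=self.focal_length,
            aperture_diameter=self.aperture_diameter,
            centers=self.centers,
            normals=self.normals,
            areas=self.areas,
            drive=np.abs(self.drive) * np.exp(1j * phases),
        )


@dataclass
class SourcePlane:
    """Complex pressure p0(x, y) on the solver entry plane z = z0."""

    values: np.ndarray
    z: float
    frequency: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2:
            raise InvalidParameterError("source plane must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("source plane values must be finite")


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def build_spherical_array(
    n_elements: int = 256,
    aperture_diameter: float = 0.145,
    focal_length: float = 0.13,
    frequency: float = 1.0e6,
    layout_kind: str = "fermat",
    seed: int | None = None,
    layout_file=None,
) -> TransducerArray:
    """Deterministic equal-area element layout on the spherical cap.

    Default layout: Fermat/sunflower spiral -- equal cap-area rings with
    golden-angle azimuths -- so every element has area ``cap_area / n``.
    ``seed`` only rotates the spiral's starting azimuth (layouts are
    deterministic per seed).  Alternatively a CSV layout file with header
    ``x,y,z,nx,ny,nz,area`` (SI units) is loaded verbatim.
    """
    if layout_file is not None:
        return _array_from_csv(layout_file, frequency, focal_length, aperture_diameter)
    if aperture_diameter >= 2.0 * focal_length:
        raise GeometryError("aperture diameter must be smaller than twice the focal length")
    if layout_kind != "fermat":
        raise InvalidParameterError(f"unknown layout kind '{layout_kind}'")
    if n_elements < 1:
        raise InvalidParameterError("need at least one element")

    F = focal_length
    theta_max = np.arcsin(0.5 * aperture_diameter / F)
    cap_area = 2.0 * np.pi * F**2 * (1.0 - np.cos(theta_max))
    n = int(n_elements)

    phi0 = 0.0
    if seed is not None:
        phi0 = float(np.random.default_rng(seed).uniform(0, 2 * np.pi))

    if n == 1:
        theta = np.array([0.0])
        phi = np.array([phi0])
    else:
        t = (np.arange(n) + 0.5) / n
        cos_theta = 1.0 - t * (1.0 - np.cos(theta_max))   # equal cap-area rings
        theta = np.arccos(np.clip(cos_theta, -1.0, 1.0))
        phi = phi0 + np.arange(n) * GOLDEN_ANGLE

    # apex at origin, focus (center of curvature) at (0, 0, F)
    centers = np.stack(
        [
            F * np.sin(theta) * np.cos(phi),
            F * np.sin(theta) * np.sin(phi),
            F * (1.0 - np.cos(theta)),
        ],
        axis=1,
    )
    focus = np.array([0.0, 0.0, F])
    normals = (focus - centers) / F
    areas = np.full(n, cap_area / n)
    return TransducerArray(
        frequency=frequency,
        focal_length=focal_length,
        aperture_diameter=aperture_diameter,
        centers=centers,
        normals=normals,
        areas=areas,
    )


def _array_from_csv(path, frequency, focal_length, aperture_diameter) -> TransducerArray:
    required = ["x", "y", "z", "nx", "ny", "nz", "area"]
    centers, normals, areas = [], [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != required:
            raise InvalidParameterError(
                f"layout CSV must have header {','.join(required)}, got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                vals = [float(row[k]) for k in required]
            except (TypeError, ValueError, KeyError) as exc:
                raise InvalidParameterError(f"layout CSV parse error at line {lineno}: {exc}") from exc
            centers.append(vals[0:3])
            normals.append(vals[3:6])
            areas.append(vals[6])
    if not centers:
        raise InvalidParameterError("layout CSV contains no elements")
    arr = TransducerArray(
        frequency=frequency,
        focal_length=focal_length,
        aperture_diameter=aperture_diameter,
        centers=np.array(centers),
        normals=np.array(normals),
        areas=np.array(areas),
    )
    # sanity: element centers should lie on the cap radius
    r = np.linalg.norm(arr.centers - arr.focus, axis=1)
    if np.any(np.abs(r - focal_length) > 1e-3 * focal_length):
        raise GeometryError("layout CSV element centers do not lie on the stated focal sphere")
    return arr


# ---------------------------------------------------------------------------
# sub-source discretization and Rayleigh-Sommerfeld summation
# ---------------------------------------------------------------------------

def element_subsources(
    array: TransducerArray, element_index: int, spacing: float | None = None,
    c_medium: float = WATER_SPEED,
) -> tuple[np.ndarray, float]:
    """Equal-area point sub-sources covering one element's cap patch.

    The element is treated as a geodesic disk on the focal sphere centered
    on the element center, with angular radius chosen so the patch area
    equals the element area (for a single full-cap element this recovers
    the entire bowl).  Sub-sources are laid out on a sunflower spiral at
    <= ``spacing`` (default lambda/2) and share equal areas.

    Returns (positions (m, 3), area per sub-source).
    """
    lam = c_medium / array.frequency
    spacing = 0.5 * lam if spacing is None else float(spacing)
    area = float(array.areas[element_index])
    n_sub = max(1, int(np.ceil(area / spacing**2)))

    F = array.focal_length
    focus = array.focus
    # angular radius of the equal-area geodesic disk
    cos_psi = 1.0 - area / (2.0 * np.pi * F**2)
    psi_max = np.arccos(np.clip(cos_psi, -1.0, 1.0))

    if n_sub == 1:
        local = np.array([[0.0, 0.0, 1.0]])
    else:
        t = (np.arange(n_sub) + 0.5) / n_sub
        cos_psi_k = 1.0 - t * (1.0 - np.cos(psi_max))
        psi = np.arccos(np.clip(cos_psi_k, -1.0, 1.0))
        phi = np.arange(n_sub) * GOLDEN_ANGLE
        local = np.stack(
            [np.sin(psi) * np.cos(phi), np.sin(psi) * np.sin(phi), np.cos(psi)], axis=1
        )

    # rotate the local pole (0,0,1) onto the element's direction from the focus
    u = (array.centers[element_index] - focus) / F
    rot = _rotation_from_z(u)
    pts = focus + F * local @ rot.T
    return pts, area / n_sub


def _rotation_from_z(u: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z onto the unit vector u."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, u))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(z, u)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def point_source_field(points_xyz: np.ndarray, source_xyz, k: float, alpha: float = 0.0):
    """Spherical wavelet e^{(jk - alpha) r} / r from a unit point source."""
    d = np.linalg.norm(points_xyz - np.asarray(source_xyz, dtype=float), axis=-1)
    return np.exp((1j * k - alpha) * d) / d


def element_source_plane(
    array: TransducerArray,
    element_index: int,
    grid: VoxelGrid,
    c_medium: float = WATER_SPEED,
    a_medium: float = WATER_ATTENUATION,
    subsource_spacing: float | None = None,
    apply_drive: bool = True,
) -> SourcePlane:
    """Rayleigh-Sommerfeld field of one element on the grid's entry plane.

    The coupling path from the curved element to the flat entry plane
    (z = grid origin z) is homogeneous water with speed ``c_medium`` and
    attenuation ``a_medium``.  Linear in the element drive.
    """
    z0 = grid.origin[2]
    pts, sub_area = element_subsources(array, element_index, subsource_spacing, c_medium)
    if np.any(pts[:, 2] >= z0):
        raise GeometryError(
            f"entry plane z={z0:.4g} m lies behind the transducer surface "
            f"(max element z = {pts[:, 2].max():.4g} m)"
        )
    k = 2.0 * np.pi * array.frequency / c_medium
    alpha = attenuation_to_neper(a_medium, array.frequency)

    xs = grid.x
    ys = grid.y
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    plane_pts = np.stack([gx.ravel(), gy.ravel(), np.full(gx.size, z0)], axis=1)

    out = np.zeros(plane_pts.shape[0], dtype=complex)
    chunk = max(1, int(4e6 // max(1, pts.shape[0])))
    for s in range(0, plane_pts.shape[0], chunk):
        block = plane_pts[s : s + chunk]                     # (m, 3)
        d = np.linalg.norm(block[:, None, :] - pts[None, :, :], axis=2)
        out[s : s + chunk] = (np.exp((1j * k - alpha) * d) / d).sum(axis=1)
    out *= sub_area
    if apply_drive:
        out *= array.drive[element_index]
    return SourcePlane(values=out.reshape(len(xs), len(ys)), z=z0, frequency=array.frequency)


def array_source_plane(
    array: TransducerArray,
    grid: VoxelGrid,
    c_medium: float = WATER_SPEED,
    a_medium: float = WATER_ATTENUATION,
    subsource_spacing: float | None = None,
    element_planes: np.ndarray | None = None,
) -> SourcePlane:
    """Full-array entry-plane field: drive-weighted sum of element planes.

    ``element_planes`` (n_elem, nx, ny), if given, are pre-computed
    *unit-drive* element planes (from :func:`element_source_plane` with
    ``apply_drive=False``); otherwise they are computed on the fly.  The
    superposition is exact: the result equals the sum of single-element
    planes at the same drives.
    """
    if element_planes is not None:
        planes = np.asarray(element_planes)
        if planes.shape[0] != array.n_elements:
            raise ContractError("element_planes count does not match the array")
        total = np.tensordot(array.drive, planes, axes=(0, 0))
        return SourcePlane(values=total, z=grid.origin[2], frequency=array.frequency)
    total = np.zeros((grid.dims[0], grid.dims[1]), dtype=complex)
    for i in range(array.n_elements):
        sp = element_source_plane(
            array, i, grid, c_medium, a_medium, subsource_spacing, apply_drive=True
        )
        total += sp.values
    return SourcePlane(values=total, z=grid.origin[2], frequency=array.frequency)


def unit_element_planes(
    array: TransducerArray,
    grid: VoxelGrid,
    c_medium: float = WATER_SPEED,
    a_medium: float = WATER_ATTENUATION,
    subsource_spacing: float | None = None,
) -> np.ndarray:
    """Stack of unit-drive entry-plane fields, one per element."""
    planes = np.empty((array.n_elements, grid.dims[0], grid.dims[1]), dtype=complex)
    for i in range(array.n_elements):
        planes[i] = element_source_plane(
            array, i, grid, c_medium, a_medium, subsource_spacing, apply_drive=False
        ).values
    return planes


# ---------------------------------------------------------------------------
# geometric (water-path) steering phases
# ---------------------------------------------------------------------------

def geometric_phases(array: TransducerArray, target, c_ref: float = WATER_SPEED) -> np.ndarray:
    """Water-path steering phases referenced to the geometric focus.

    ``phi_i = -k_ref (|center_i - target| - focal_length)``, wrapped to
    (-pi, pi], so that with drives ``e^{+j phi_i}`` (and the project-wide
    e^{+jkz} forward convention) all element contributions arrive in phase
    at the target through homogeneous water.  At the geometric focus every
    path equals the focal length and all phases are zero.
    """
    target = np.asarray(target, dtype=float)
    if target[2] <= 0:
        raise GeometryError("target must lie in front of the array")
    k = 2.0 * np.pi * array.frequency / c_ref
    d = np.linalg.norm(array.centers - target[None, :], axis=1)
    return wrap_phase(-k * (d - array.focal_length))
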