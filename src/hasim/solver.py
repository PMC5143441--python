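"""Hybrid angular spectrum (HAS) steady-state marching solver.

The solver alternates, slice by slice along +z, between

* a **space-domain step** applying each voxel's deviation from the slice-
  average propagation constant and its absorption:
  ``p' = p * exp(j*db(x,y)*dz) * exp(-a(x,y)*dz)``, and
* a **spectral step** applying the homogeneous angular-spectrum diffraction
  transfer function at the slice-average constant b':
  ``A -> A * exp(j*b'*sqrt(1 - alpha^2 - beta^2)*dz)`` with directional
  cosines ``alpha = lambda*f_x``, ``beta = lambda*f_y``.

Radiating lateral boundaries are emulated by zero-padding the lateral FFT
lattice and applying a raised-cosine amplitude taper near the padded edges
each slice.  Evanescent components (alpha^2 + beta^2 > 1) are zeroed by
default, or exponentially damped under the ``decay`` policy.  Under the
paraxial policy both the oblique and perpendicular step distances are dz.

Sign convention: e^{-j omega t} time dependence, forward propagation
multiplies by e^{+jkz} (see :mod:`hasim.units`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import fft2, ifft2, fftfreq, next_fast_len

from .arrays import SourcePlane
from .errors import ContractError, InvalidParameterError, NumericalError
from .grid import VoxelGrid
from .models import AcousticModel
from .units import attenuation_to_neper, propagation_constant

log = logging.getLogger(__name__)


@dataclass
class SolverConfig:
    """Numerical options of the HAS march.

    dz: step distance (m); defaults to the grid dz.
    evanescent: 'zero' hard-cuts non-propagating components; 'decay' damps
        them as exp(-b' sqrt(alpha^2+beta^2-1) dz).
    pad_factor: lateral zero-padding factor (>= 1) emulating radiating
        boundaries; taper_width: raised-cosine amplitude taper width in
        voxels applied each slice near the padded edges.
    reflections: when on, forward plane-wave pressure-transmission factors
        2*Z2/(Z1+Z2) are applied at impedance steps between slices (no
        backward-traveling field is generated).
    oblique: only the 'paraxial' policy (oblique distance = perpendicular
        step = dz) is implemented.
    """

    dz: float | None = None
    evanescent: str = "zero"
    pad_factor: float = 2.0
    taper_width: int = 10
    reflections: bool = False
    oblique: str = "paraxial"

    def __post_init__(self):
        if self.dz is not None and self.dz <= 0:
            raise InvalidParameterError("dz must be > 0")
        if self.evanescent not in ("zero", "decay"):
            raise InvalidParameterError("evanescent policy must be 'zero' or 'decay'")
        if self.pad_factor < 1.0:
            raise InvalidParameterError("pad_factor must be >= 1")
        if self.taper_width < 0:
            raise InvalidParameterError("taper_width must be >= 0")
        if self.oblique != "paraxial":
            raise InvalidParameterError("only the paraxial oblique-distance policy is implemented")


@dataclass
class SpectralField:
    """2D angular spectrum A(f_x, f_y) with its directional-cosine lattice."""

    spectrum: np.ndarray
    fx: np.ndarray
    fy: np.ndarray
    wavelength: float

    @property
    def alpha(self) -> np.ndarray:
        return self.wavelength * self.fx

    @property
    def beta(self) -> np.ndarray:
        return self.wavelength * self.fy


@dataclass
class PressureVolume:
    """3D complex steady-state pressure on the (unpadded) model grid.

    Values are in arbitrary linear units proportional to Pa; linear in the
    source drive.
    """

    pressure: np.ndarray
    grid: VoxelGrid
    frequency: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pressure = np.asarray(self.pressure)
        if self.pressure.shape != self.grid.shape:
            raise ContractError(
                f"pressure shape {self.pressure.shape} != grid {self.grid.shape}"
            )

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.pressure)

    def peak_index(self) -> tuple[int, int, int]:
        return tuple(int(i) for i in np.unravel_index(np.argmax(self.magnitude), self.pressure.shape))

    def peak_position(self) -> np.ndarray:
        return self.grid.index_to_world(self.peak_index())

    def peak_value(self) -> float:
        return float(self.magnitude.max())

    def interpolate(self, point) -> complex:
        """Trilinear complex interpolation at a physical point.

        Real and imaginary parts are interpolated separately so that phases
        come from the interpolated phasor, avoiding angle-unwrapping
        artifacts.
        """
        from scipy.ndimage import map_coordinates

        idx = self.grid.world_to_index(point)
        if not self.grid.contains_index(idx):
            raise InvalidParameterError(f"point {point} outside the volume")
        coords = np.asarray(idx, dtype=float).reshape(3, 1)
        re = map_coordinates(self.pressure.real, coords, order=1, mode="nearest")
        im = map_coordinates(self.pressure.imag, coords, order=1, mode="nearest")
        return complex(re[0], im[0])


# ---------------------------------------------------------------------------
# individual steps
# ---------------------------------------------------------------------------

def slice_average_b(speed_slice: np.ndarray, frequency: float) -> float:
    """Area-weighted arithmetic mean propagation constant b' of one slice."""
    b = propagation_constant(np.asarray(speed_slice, dtype=float), frequency)
    return float(np.mean(b))


def space_domain_step(
    p_in: np.ndarray,
    speed_slice: np.ndarray,
    attenuation_slice: np.ndarray,
    b_avg: float,
    frequency: float,
    dz: float,
    transmission: np.ndarray | None = None,
) -> np.ndarray:
    """Per-voxel heterogeneity step: phase deviation + absorption over dz.

    ``transmission``, if given, multiplies in the plane-wave pressure
    transmission factors of the reflection option.
    """
    p_in = np.asarray(p_in)
    if p_in.shape != np.shape(speed_slice):
        raise ContractError("pressure plane and slice maps must share a shape")
    db = propagation_constant(speed_slice, frequency) - b_avg
    a_np = attenuation_to_neper(attenuation_slice, frequency)
    out = p_in * np.exp((1j * db - a_np) * dz)
    if transmission is not None:
        out = out * transmission
    return out


def spectral_step(
    spectrum: np.ndarray,
    b_avg: float,
    dz: float,
    cfg: SolverConfig,
    fx: np.ndarray,
    fy: np.ndarray,
) -> np.ndarray:
    """Angular-spectrum diffraction step over dz at average constant b'.

    Propagating components (alpha^2 + beta^2 <= 1) advance by
    ``exp(j b' sqrt(1-alpha^2-beta^2) dz)``; evanescent components follow
    the configured policy.
    """
    lam = 2.0 * np.pi / b_avg
    alpha2 = (lam * fx) ** 2
    beta2 = (lam * fy) ** 2
    s = 1.0 - (alpha2[:, None] + beta2[None, :])
    H = np.empty(s.shape, dtype=complex)
    prop = s >= 0.0
    H[prop] = np.exp(1j * b_avg * np.sqrt(s[prop]) * dz)
    if cfg.evanescent == "zero":
        H[~prop] = 0.0
    else:
        H[~prop] = np.exp(-b_avg * np.sqrt(-s[~prop]) * dz)
    return spectrum * H


def _edge_taper(n: int, width: int) -> np.ndarray:
    """1D raised-cosine amplitude window: 1 in the interior, ->0 at edges."""
    w = np.ones(n)
    width = min(width, n // 2)
    if width > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * (np.arange(width) + 0.5) / width))
        w[:width] = ramp
        w[-width:] = ramp[::-1]
    return w


def propagate(source: SourcePlane, model: AcousticModel, cfg: SolverConfig | None = None) -> PressureVolume:
    """March a steady-state field through the model, slice by slice.

    The source plane is the field on the first model slice (z = origin z).
    The returned volume holds the unpadded complex pressure at every slice;
    slice 0 is the source itself.  The heterogeneity of slice k acts on the
    step from plane k-1 to plane k.  Output is linear in the source.
    """
    cfg = cfg or SolverConfig()
    g = model.grid
    nx, ny, nz = g.dims
    if source.values.shape != (nx, ny):
        raise ContractError(
            f"source plane shape {source.values.shape} != lateral grid ({nx}, {ny})"
        )
    if abs(source.frequency) <= 0:
        raise InvalidParameterError("source frequency must be set and > 0")
    f = source.frequency
    dz = cfg.dz if cfg.dz is not None else g.dz

    # padded FFT lattice
    px = next_fast_len(int(np.ceil(nx * cfg.pad_factor)))
    py = next_fast_len(int(np.ceil(ny * cfg.pad_factor)))
    ox = (px - nx) // 2
    oy = (py - ny) // 2
    fx = fftfreq(px, d=g.dx)
    fy = fftfreq(py, d=g.dy)
    taper = np.outer(_edge_taper(px, cfg.taper_width), _edge_taper(py, cfg.taper_width))

    field_p = np.zeros((px, py), dtype=complex)
    field_p[ox : ox + nx, oy : oy + ny] = source.values

    out = np.empty((nx, ny, nz), dtype=complex)
    out[:, :, 0] = source.values

    prev_impedance = None
    for k in range(1, nz):
        speed = model.speed[:, :, k]
        att = model.attenuation[:, :, k]
        b_avg = slice_average_b(speed, f)

        # embed slice maps into the padded lattice (padding region = slice mean
        # speed, zero attenuation: outside the model the medium is homogeneous)
        speed_pad = np.full((px, py), float(np.mean(speed)))
        att_pad = np.zeros((px, py))
        speed_pad[ox : ox + nx, oy : oy + ny] = speed
        att_pad[ox : ox + nx, oy : oy + ny] = att

        transmission = None
        if cfg.reflections:
            z_now = model.impedance()[:, :, k]
            z_prev = model.impedance()[:, :, k - 1]
            t = 2.0 * z_now / (z_now + z_prev)
            transmission = np.ones((px, py))
            transmission[ox : ox + nx, oy : oy + ny] = t

        field_p = space_domain_step(field_p, speed_pad, att_pad, b_avg, f, dz, transmission)
        if cfg.taper_width > 0:
            field_p = field_p * taper
        spec = fft2(field_p)
        spec = spectral_step(spec, b_avg, dz, cfg, fx, fy)
        field_p = ifft2(spec)

        slab = field_p[ox : ox + nx, oy : oy + ny]
        if not np.all(np.isfinite(slab)):
            raise NumericalError(f"non-finite pressure detected at slice {k}")
        out[:, :, k] = slab

    return PressureVolume(pressure=out, grid=g, frequency=f, metadata={"dz": dz})


def simulate_full_array(array, model: AcousticModel, cfg: SolverConfig | None = None,
                        element_planes: np.ndarray | None = None,
                        c_coupling: float | None = None,
                        a_coupling: float | None = None) -> PressureVolume:
    """Convenience: full-array entry-plane field + HAS propagation.

    Coupling-water properties default to the model's entry-slice means.
    """
    from .arrays import array_source_plane

    g = model.grid
    c0 = float(np.mean(model.speed[:, :, 0])) if c_coupling is None else c_coupling
    a0 = float(np.mean(model.attenuation[:, :, 0])) if a_coupling is None else a_coupling
    sp = array_source_plane(array, g, c_medium=c0, a_medium=a0, element_planes=element_planes)
    return propagate(sp, model, cfg)
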