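"""Shared fixtures: small, fast array/model/solver setups.

The test geometry uses a strongly focusing 16-element cap (aperture 50 mm,
focal length 55 mm, 1 MHz) so the natural focal shift of a finite aperture
stays below one voxel, and desk-scale grids (0.5 mm voxels) that keep a
full element-bank simulation in seconds.
"""

import numpy as np
import pytest

import hasim as h


@pytest.fixture(scope="session")
def arr16():
    return h.build_spherical_array(
        n_elements=16, aperture_diameter=0.05, focal_length=0.055, frequency=1.0e6
    )


@pytest.fixture(scope="session")
def grid65():
    # odd lateral dims so the beam axis x=y=0 is a voxel center
    return h.centered_grid((65, 65, 81), (5e-4, 5e-4, 5e-4), z0=0.035)


@pytest.fixture(scope="session")
def water65(grid65):
    return h.make_water_model(grid65.dims, grid65.spacing, origin=grid65.origin)


@pytest.fixture(scope="session")
def grid64():
    return h.centered_grid((64, 64, 80), (5e-4, 5e-4, 5e-4), z0=0.035)


@pytest.fixture(scope="session")
def aberrator64(grid64):
    """Seeded random-relief plate (3 mm features) in front of the focus."""
    model, hmap = h.generate_aberrator(seed=3, grid=grid64, feature_scale=3e-3)
    return model, hmap


@pytest.fixture(scope="session")
def solver_cfg():
    return h.SolverConfig()


@pytest.fixture(scope="session")
def focus_region(grid64):
    return h.Region.around(grid64, (0.0, 0.0, 0.055), (2e-3, 2e-3, 2e-3))


@pytest.fixture(scope="session")
def bank16(arr16, aberrator64, solver_cfg, focus_region):
    """Element bank of the 16-element array through the seeded aberrator."""
    model, _ = aberrator64
    return h.simulate_element_bank(arr16, model, solver_cfg, region=focus_region)


@pytest.fixture(scope="session")
def planes16(arr16, grid64):
    """Unit-drive entry planes of the 16 elements on the 64-voxel grid."""
    return h.unit_element_planes(arr16, grid64)


def plane_wave_source(grid, frequency=1.0e6):
    nx, ny = grid.dims[0], grid.dims[1]
    return h.SourcePlane(values=np.ones((nx, ny)), z=grid.origin[2], frequency=frequency)


def oneil_onaxis(z, aperture_radius, focal_length, k):
    """O'Neil closed-form on-axis pressure magnitude of a focused bowl.

    Arbitrary source-strength units; the removable singularity at the
    center of curvature takes its limit value k * (cap height).
    """
    a, F = aperture_radius, focal_length
    hcap = F - np.sqrt(F**2 - a**2)
    re = np.sqrt(a**2 + (z - hcap) ** 2)
    denom = 1.0 - z / F
    out = np.empty_like(np.asarray(z, dtype=float))
    sing = np.abs(denom) < 1e-9
    out[~sing] = np.abs(2.0 * np.sin(k * (re[~sing] - z[~sing]) / 2.0) / denom[~sing])
    out[sing] = k * hcap
    return out
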