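"""HAS marching solver: analytic oracles and numerical invariants."""

import numpy as np
import pytest
from scipy.fft import fft2, fftfreq

import hasim as h
from hasim.errors import ContractError, NumericalError
from hasim.solver import slice_average_b, space_domain_step, spectral_step

from conftest import oneil_onaxis, plane_wave_source

F0 = 1.0e6
C_W = 1500.0


@pytest.fixture(scope="module")
def nopad_cfg():
    return h.SolverConfig(pad_factor=1.0, taper_width=0)


class TestSliceAverage:
    def test_homogeneous_water(self):
        b = slice_average_b(np.full((8, 8), C_W), F0)
        assert b == pytest.approx(4188.79, abs=0.01)

    def test_two_phase_mean(self):
        s = np.full((4, 4), C_W)
        s[:2] = 2492.0
        b1, b2 = 2 * np.pi * F0 / C_W, 2 * np.pi * F0 / 2492.0
        assert slice_average_b(s, F0) == pytest.approx((b1 + b2) / 2, rel=1e-12)

    def test_mean_bounds(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(1400, 3000, (16, 16))
        b = 2 * np.pi * F0 / s
        assert b.min() <= slice_average_b(s, F0) <= b.max()


class TestSpaceDomainStep:
    def test_identity_at_average_speed(self):
        p = np.ones((8, 8), dtype=complex)
        s = np.full((8, 8), C_W)
        out = space_domain_step(p, s, np.zeros((8, 8)), slice_average_b(s, F0), F0, 1e-3)
        assert np.allclose(out, p, rtol=1e-14)

    def test_uniform_attenuation_scalar_decay(self):
        # 4.72 dB/(cm MHz) at 1 MHz over 1 mm: |out|/|in| = e^{-0.05434}
        p = np.ones((4, 4), dtype=complex)
        s = np.full((4, 4), C_W)
        att = np.full((4, 4), 4.72)
        out = space_domain_step(p, s, att, slice_average_b(s, F0), F0, 1e-3)
        assert np.abs(out).max() == pytest.approx(0.9471, abs=1e-4)
        assert np.abs(out).min() == pytest.approx(0.9471, abs=1e-4)

    def test_slow_voxel_gains_phase(self):
        """c < average => b > b' => positive extra phase (sign convention)."""
        p = np.ones((2, 2), dtype=complex)
        s = np.full((2, 2), C_W)
        s[0, 0] = 1400.0  # slower than average
        out = space_domain_step(p, s, np.zeros((2, 2)), slice_average_b(s, F0), F0, 1e-3)
        assert np.angle(out[0, 0]) > np.angle(out[1, 1])

    def test_shape_mismatch_raises(self):
        with pytest.raises(ContractError):
            space_domain_step(np.ones((4, 4)), np.full((5, 5), C_W),
                              np.zeros((5, 5)), 1.0, F0, 1e-3)


class TestSpectralStep:
    def setup_method(self):
        self.cfg_zero = h.SolverConfig(evanescent="zero")
        self.cfg_decay = h.SolverConfig(evanescent="decay")

    def _single_component(self, alpha, beta, b_avg, dz, cfg):
        """Transfer multiplier of a single (alpha, beta) spectral component."""
        lam = 2 * np.pi / b_avg
        fx = np.array([alpha / lam])
        fy = np.array([beta / lam])
        out = spectral_step(np.ones((1, 1), dtype=complex), b_avg, dz, cfg, fx, fy)
        return out[0, 0]

    def test_on_axis_phase_advance(self):
        b, dz = 4188.79, 3.75e-4
        m = self._single_component(0.0, 0.0, b, dz, self.cfg_zero)
        assert m == pytest.approx(np.exp(1j * b * dz), rel=1e-12)

    def test_grazing_component_unchanged(self):
        m = self._single_component(1.0, 0.0, 4188.79, 3.75e-4, self.cfg_zero)
        assert m == pytest.approx(1.0, rel=1e-12)

    def test_evanescent_zero_policy(self):
        m = self._single_component(1.0, 0.5, 4188.79, 3.75e-4, self.cfg_zero)
        assert m == 0.0

    def test_evanescent_decay_policy(self):
        # alpha^2 + beta^2 = 1.25 -> |multiplier| = e^{-0.5 b dz}
        b, dz = 4188.79, 3.75e-4
        m = self._single_component(1.0, 0.5, b, dz, self.cfg_decay)
        assert abs(m) == pytest.approx(np.exp(-0.5 * b * dz), rel=1e-9)


class TestPropagate:
    def test_plane_wave_closed_form(self, nopad_cfg):
        g = h.centered_grid((32, 32, 40), (5e-4, 5e-4, 5e-4), z0=0.0)
        m = h.make_water_model(g.dims, g.spacing, origin=g.origin)
        vol = h.propagate(plane_wave_source(g), m, nopad_cfg)
        k = 2 * np.pi * F0 / C_W
        expected = np.exp(1j * k * (g.z - g.z[0]))
        assert np.max(np.abs(vol.pressure[16, 16, :] - expected)) < 1e-6
        assert np.max(np.abs(np.abs(vol.pressure) - 1.0)) < 1e-6

    def test_plane_wave_attenuation_oracle(self, nopad_cfg):
        g = h.centered_grid((16, 16, 30), (5e-4, 5e-4, 5e-4), z0=0.0)
        m = h.make_water_model(g.dims, g.spacing, a_water=4.72, origin=g.origin)
        vol = h.propagate(plane_wave_source(g), m, nopad_cfg)
        a = h.attenuation_to_neper(4.72, F0)
        expected = np.exp(-a * (g.z - g.z[0]))
        assert np.allclose(np.abs(vol.pressure[8, 8, :]), expected, rtol=1e-10)

    def test_parseval_energy_conservation(self, nopad_cfg):
        """Propagating spectral energy is conserved in lossless water."""
        g = h.centered_grid((32, 32, 25), (5e-4, 5e-4, 5e-4), z0=0.0)
        m = h.make_water_model(g.dims, g.spacing, origin=g.origin)
        rng = np.random.default_rng(1)
        src = h.SourcePlane(
            values=rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32)),
            z=0.0, frequency=F0,
        )
        vol = h.propagate(src, m, nopad_cfg)
        fx = fftfreq(32, g.dx)
        lam = C_W / F0
        s = 1 - ((lam * fx) ** 2)[:, None] - ((lam * fx) ** 2)[None, :]
        prop = s >= 0

        def energy(p):
            return np.sum(np.abs(fft2(p)) ** 2 * prop)

        e1 = energy(vol.pressure[:, :, 1])
        for k in (5, 12, 24):
            assert abs(energy(vol.pressure[:, :, k]) - e1) / e1 < 1e-9

    def test_linearity_superposition(self, nopad_cfg):
        g = h.centered_grid((16, 16, 12), (5e-4, 5e-4, 5e-4), z0=0.0)
        m = h.make_water_model(g.dims, g.spacing, origin=g.origin)
        rng = np.random.default_rng(2)
        v1 = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        v2 = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        mk = lambda v: h.SourcePlane(values=v, z=0.0, frequency=F0)
        p12 = h.propagate(mk(v1 + v2), m, nopad_cfg).pressure
        p1 = h.propagate(mk(v1), m, nopad_cfg).pressure
        p2 = h.propagate(mk(v2), m, nopad_cfg).pressure
        assert np.allclose(p12, p1 + p2, rtol=1e-11, atol=1e-11)

    def test_focused_bowl_matches_oneil(self):
        """On-axis profile of a focused bowl vs the closed-form solution."""
        arr = h.build_spherical_array(1, aperture_diameter=0.06, focal_length=0.08)
        lam = C_W / F0
        g = h.centered_grid((96, 96, 107), (3e-4, 3e-4, lam / 4), z0=0.06)
        sp = h.element_source_plane(arr, 0, g)
        m = h.make_water_model(g.dims, g.spacing, origin=g.origin)
        vol = h.propagate(sp, m, h.SolverConfig())
        k = 2 * np.pi / lam
        po = oneil_onaxis(g.z, 0.03, 0.08, k)
        ps = np.abs(vol.pressure[48, 48, :])
        sel = np.abs(g.z - 0.08) <= 10 * lam
        scale = np.sum(ps[sel] * po[sel]) / np.sum(ps[sel] ** 2)
        err = np.max(np.abs(scale * ps[sel] - po[sel])) / po[sel].max()
        assert err < 0.05

    def test_reciprocity_across_uniform_slab(self, nopad_cfg):
        """Swapping a point source and receiver across a laterally uniform slab."""
        g = h.centered_grid((32, 32, 30), (5e-4, 5e-4, 5e-4), z0=0.0)
        m = h.make_water_model(g.dims, g.spacing, origin=g.origin)
        m.speed[:, :, 10:16] = 2492.0  # uniform plastic slab
        rev = h.AcousticModel(grid=g, speed=m.speed[:, :, ::-1].copy(),
                              attenuation=m.attenuation[:, :, ::-1].copy(),
                              density=m.density[:, :, ::-1].copy())
        ia, ib = (10, 16), (20, 14)
        src_a = np.zeros((32, 32), dtype=complex); src_a[ia] = 1.0
        src_b = np.zeros((32, 32), dtype=complex); src_b[ib] = 1.0
        fwd = h.propagate(h.SourcePlane(values=src_a, z=0.0, frequency=F0), m, nopad_cfg)
        bwd = h.propagate(h.SourcePlane(values=src_b, z=0.0, frequency=F0), rev, nopad_cfg)
        pa = fwd.pressure[ib[0], ib[1], -1]
        pb = bwd.pressure[ia[0], ia[1], -1]
        assert abs(pa - pb) / abs(pa) < 0.01

    def test_dz_refinement_consistency(self):
        """Halving dz moves the focal pressure of a water bowl by < 1 %."""
        arr = h.build_spherical_array(1, aperture_diameter=0.04, focal_length=0.05)
        lam = C_W / F0
        vals = []
        for dz in (lam / 2, lam / 4):
            nz = int(round(0.03 / dz)) + 1
            g = h.centered_grid((64, 64, nz), (4e-4, 4e-4, dz), z0=0.035)
            sp = h.element_source_plane(arr, 0, g)
            m = h.make_water_model(g.dims, g.spacing, origin=g.origin)
            vol = h.propagate(sp, m, h.SolverConfig())
            vals.append(vol.interpolate((0.0, 0.0, 0.05)))
        assert abs(vals[1] - vals[0]) / abs(vals[1]) < 0.01

    def test_nan_detection_names_slice(self, nopad_cfg):
        g = h.centered_grid((8, 8, 10), (5e-4, 5e-4, 5e-4), z0=0.0)
        m = h.make_water_model(g.dims, g.spacing, origin=g.origin)
        src = np.ones((8, 8), dtype=complex)
        src[0, 0] = np.nan
        with pytest.raises(Exception):
            # non-finite source is rejected at construction
            h.SourcePlane(values=src, z=0.0, frequency=F0)
        good = h.SourcePlane(values=np.ones((8, 8)), z=0.0, frequency=F0)
        m.speed[:, :, 5] = np.nan  # corrupt one slice after construction
        with pytest.raises(NumericalError, match="slice 5"):
            h.propagate(good, m, nopad_cfg)

    def test_reflection_transmission_factor(self):
        """Plane wave across an impedance step picks up 2 Z2/(Z1+Z2)."""
        g = h.centered_grid((8, 8, 12), (5e-4, 5e-4, 5e-4), z0=0.0)
        m = h.make_water_model(g.dims, g.spacing, origin=g.origin)
        m.speed[:, :, 6:] = 2492.0
        m.density[:, :, 6:] = 1175.0
        cfg_r = h.SolverConfig(pad_factor=1.0, taper_width=0, reflections=True)
        cfg_n = h.SolverConfig(pad_factor=1.0, taper_width=0, reflections=False)
        src = plane_wave_source(g)
        pr = h.propagate(src, m, cfg_r)
        pn = h.propagate(src, m, cfg_n)
        z1 = 1500.0 * 1000.0
        z2 = 2492.0 * 1175.0
        t = 2 * z2 / (z1 + z2)
        ratio = np.abs(pr.pressure[4, 4, -1]) / np.abs(pn.pressure[4, 4, -1])
        assert ratio == pytest.approx(t, rel=1e-9)
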