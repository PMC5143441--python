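"""Conjugate-phase correction: bank consistency, optimality, corrected fields."""

import numpy as np
import pytest

import hasim as h
from hasim.errors import ContractError, RangeError

FOCUS = np.array([0.0, 0.0, 0.055])


class TestBank:
    def test_single_element_bank_matches_direct_propagation(self, grid64, solver_cfg):
        arr1 = h.build_spherical_array(1, aperture_diameter=0.05, focal_length=0.055)
        model = h.make_water_model(grid64.dims, grid64.spacing, origin=grid64.origin)
        bank = h.simulate_element_bank(arr1, model, solver_cfg)
        sp = h.element_source_plane(arr1, 0, grid64)
        direct = h.propagate(sp, model, solver_cfg)
        assert np.allclose(bank.fields[0], direct.pressure, rtol=1e-12)

    def test_superposition_with_full_array(self, arr16, aberrator64, solver_cfg,
                                           bank16, planes16):
        """Drive-weighted sum over the bank equals a full-array simulation."""
        model, _ = aberrator64
        rng = np.random.default_rng(7)
        phases = rng.uniform(-np.pi, np.pi, 16)
        driven = arr16.with_phases(phases)
        full = h.simulate_full_array(driven, model, solver_cfg, element_planes=planes16)
        weighted = np.tensordot(np.exp(1j * phases), bank16.fields, axes=(0, 0))
        region = bank16.region
        assert np.allclose(weighted, full.pressure[region.slices], rtol=1e-9)

    def test_equal_phases_at_focus_by_symmetry(self, water65, solver_cfg):
        """Four cap elements at one ring have equal path length to the focus."""
        arr = h.build_spherical_array(4, aperture_diameter=0.05, focal_length=0.055)
        region = h.Region.around(water65.grid, FOCUS, (1e-3, 1e-3, 1e-3))
        bank = h.simulate_element_bank(arr, water65, solver_cfg, region=region)
        phases = np.angle(bank.complex_at(FOCUS))
        spread = np.ptp(h.wrap_phase(phases - phases[0]))
        assert spread < 0.05

    def test_region_out_of_range(self, bank16):
        with pytest.raises(RangeError):
            bank16.complex_at((0.02, 0.02, 0.01))


class TestCorrectionPhases:
    def test_conjugate_definition(self, bank16):
        sol = h.correction_phases(bank16, FOCUS)
        p = bank16.complex_at(FOCUS)
        assert np.allclose(h.wrap_phase(sol.phases + np.angle(p)), 0.0, atol=1e-12)
        assert np.all(sol.phases > -np.pi) and np.all(sol.phases <= np.pi)

    def test_coherent_sum_exact(self, arr16, aberrator64, solver_cfg, bank16, planes16):
        """Corrected on-target magnitude equals the sum of element magnitudes."""
        model, _ = aberrator64
        sol = h.correction_phases(bank16, FOCUS)
        vol = h.corrected_field(arr16, model, solver_cfg, sol, element_planes=planes16)
        p_target = abs(vol.interpolate(FOCUS))
        incoherent = np.sum(np.abs(bank16.complex_at(FOCUS)))
        assert p_target == pytest.approx(incoherent, rel=1e-6)

    def test_conjugate_matches_exhaustive_search(self):
        """Brute-force phase search over 3 phasors reproduces the conjugate set."""
        rng = np.random.default_rng(5)
        p = rng.normal(size=3) + 1j * rng.normal(size=3)
        n_grid = 128
        cand = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
        best, best_phi = -1.0, None
        e = np.exp(1j * cand)
        # maximize |p0 e^{i a} + p1 e^{i b} + p2 e^{i c}| over the grid
        s01 = p[0] * e[:, None] + p[1] * e[None, :]
        for c in range(n_grid):
            mags = np.abs(s01 + p[2] * e[c])
            idx = np.unravel_index(np.argmax(mags), mags.shape)
            if mags[idx] > best:
                best = mags[idx]
                best_phi = np.array([cand[idx[0]], cand[idx[1]], cand[c]])
        conj = -np.angle(p)
        # equal up to a global phase, within the search-grid resolution
        rel_best = h.wrap_phase(best_phi - best_phi[0])
        rel_conj = h.wrap_phase(conj - conj[0])
        step = 2 * np.pi / n_grid
        assert np.all(np.abs(h.wrap_phase(rel_best - rel_conj)) <= step)
        assert best <= np.sum(np.abs(p)) + 1e-12
        assert best >= np.sum(np.abs(p)) * np.cos(step / 2) ** 2

    def test_null_amplitude_warns_and_zeroes(self, bank16, caplog):
        import copy, logging

        bank = h.ElementFieldBank(
            fields=bank16.fields.copy(), grid=bank16.grid,
            frequency=bank16.frequency, region=bank16.region,
        )
        bank.fields[2] = 0.0
        with caplog.at_level(logging.WARNING):
            sol = h.correction_phases(bank, FOCUS)
        assert sol.phases[2] == 0.0
        assert any("zero amplitude" in r.message for r in caplog.records)


class TestMultiTarget:
    def test_duplicate_targets_identical(self, bank16):
        sols = h.multi_target_solutions(bank16, [FOCUS, FOCUS])
        assert np.array_equal(sols[0].phases, sols[1].phases)

    def test_no_propagation_calls(self, bank16, monkeypatch):
        """Many targets resolve from a cached bank without re-simulation."""
        import hasim.correction as corr

        def boom(*a, **k):
            raise AssertionError("solver must not be called for lookups")

        monkeypatch.setattr(corr, "propagate", boom)
        targets = [FOCUS + [0, 0, dzi * 1e-4] for dzi in range(-5, 6)]
        sols = h.multi_target_solutions(bank16, targets)
        assert len(sols) == 11

    def test_water_focus_solution_is_flat(self, arr16, water65, solver_cfg):
        region = h.Region.around(water65.grid, FOCUS, (1e-3, 1e-3, 1e-3))
        bank = h.simulate_element_bank(arr16, water65, solver_cfg, region=region)
        sol = h.correction_phases(bank, FOCUS)
        assert np.ptp(sol.phases) <= 2e-2


class TestCorrectedField:
    def test_corrected_beats_uncorrected_through_aberrator(
        self, arr16, aberrator64, solver_cfg, bank16, planes16
    ):
        model, _ = aberrator64
        sol = h.correction_phases(bank16, FOCUS)
        v_c = h.corrected_field(arr16, model, solver_cfg, sol, element_planes=planes16)
        v_u = h.simulate_full_array(arr16, model, solver_cfg, element_planes=planes16)
        assert abs(v_c.interpolate(FOCUS)) > abs(v_u.interpolate(FOCUS))

    def test_water_correction_peaks_at_focus(self, arr16, water65, solver_cfg):
        region = h.Region.around(water65.grid, FOCUS, (1e-3, 1e-3, 1e-3))
        bank = h.simulate_element_bank(arr16, water65, solver_cfg, region=region)
        sol = h.correction_phases(bank, FOCUS)
        vol = h.corrected_field(arr16, water65, solver_cfg, sol)
        assert vol.metadata["peak_to_target_m"] <= water65.grid.dx + 1e-12

    def test_element_count_mismatch(self, aberrator64, solver_cfg, bank16):
        model, _ = aberrator64
        arr4 = h.build_spherical_array(4, aperture_diameter=0.05, focal_length=0.055)
        sol = h.correction_phases(bank16, FOCUS)
        with pytest.raises(ContractError):
            h.corrected_field(arr4, model, solver_cfg, sol)


class TestCheckpoint:
    def test_bank_checkpoint_resume(self, arr16, aberrator64, solver_cfg,
                                    focus_region, bank16, tmp_path):
        """An interrupted bank run resumes from its checkpoint without loss."""
        model, _ = aberrator64
        path = tmp_path / "bank_ckpt.h5"

        import hasim.correction as corr

        calls = {"n": 0}
        orig = corr.element_source_plane

        def counting(*a, **k):
            calls["n"] += 1
            if calls["n"] == 6:
                raise KeyboardInterrupt  # simulate a crash mid-bank
            return orig(*a, **k)

        corr.element_source_plane = counting
        try:
            with pytest.raises(KeyboardInterrupt):
                h.simulate_element_bank(arr16, model, solver_cfg,
                                        region=focus_region, checkpoint=str(path))
        finally:
            corr.element_source_plane = orig

        assert path.exists()
        import h5py

        with h5py.File(path, "r") as f:
            n_done = sum(1 for k in f if k.startswith("element_"))
        assert 0 < n_done < 16

        bank = h.simulate_element_bank(arr16, model, solver_cfg,
                                       region=focus_region, checkpoint=str(path))
        assert bank.n_elements == 16
        # resumed bank agrees with the uninterrupted one (checkpoint is complex64)
        assert np.allclose(bank.fields, bank16.fields, rtol=1e-5, atol=1e-8)
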