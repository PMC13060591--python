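"""Membrane coupling, poration thresholds, AP caps and transfection draws."""

import numpy as np
import pytest

from tntsim import (
    BoundaryConditions,
    FieldGrid,
    GridSpec,
    Material,
    MembraneParams,
    PulseProtocol,
    ap_events,
    build_geometry,
    conductivity_map,
    field_magnitude,
    induced_vm,
    poration_map,
    smooth_field,
    solve_potential,
    summarize_simulation,
    transfection_map,
)
from tntsim.errors import ConfigurationError
from tntsim.poration import PorationMask


@pytest.fixture
def mem():
    return MembraneParams()


def _field(values, spacing=1.2):
    return FieldGrid(values=np.asarray(values, dtype=float), spacing=spacing)


class TestInducedVm:
    def test_zero_field_gives_resting_magnitude_in_tissue(self, mem):
        tissue = np.zeros((10, 10), dtype=bool)
        tissue[5:, :] = True
        vm = induced_vm(_field(np.zeros((10, 10))), mem, tissue)
        assert np.all(vm[tissue] == 70.0)
        assert np.all(vm[~tissue] == 0.0)

    def test_field_to_vm_is_linear(self, mem):
        tissue = np.ones((5, 5), dtype=bool)
        e = np.full((5, 5), 1e4)
        v1 = induced_vm(_field(e), mem, tissue) - 70.0
        v2 = induced_vm(_field(2 * e), mem, tissue) - 70.0
        assert np.allclose(v2, 2 * v1)

    def test_poration_field_threshold_closed_form(self, mem):
        # |Vm| hits 200 mV when 1.5 E r = 130 mV, i.e. E = 0.13/(1.5*5e-6)
        expected = 0.13 / (1.5 * 5e-6)
        assert np.isclose(mem.poration_field_threshold(), expected)
        assert np.isclose(expected, 1.7333e4, rtol=1e-4)
        tissue = np.ones((3, 3), dtype=bool)
        below = induced_vm(_field(np.full((3, 3), expected * 0.999)), mem, tissue)
        above = induced_vm(_field(np.full((3, 3), expected * 1.001)), mem, tissue)
        assert poration_map(below, mem, tissue).count == 0
        assert poration_map(above, mem, tissue).count == 9


class TestPorationMap:
    def test_subthreshold_vm_porates_nothing(self, mem):
        tissue = np.ones((6, 6), dtype=bool)
        assert poration_map(np.full((6, 6), 199.9), mem, tissue).count == 0

    def test_threshold_is_inclusive(self, mem):
        tissue = np.ones((6, 6), dtype=bool)
        por = poration_map(np.full((6, 6), 200.0), mem, tissue)
        assert np.array_equal(por.porated, tissue)

    def test_restricted_to_tissue(self, mem):
        tissue = np.zeros((6, 6), dtype=bool)
        tissue[3:, :] = True
        por = poration_map(np.full((6, 6), 500.0), mem, tissue)
        assert np.array_equal(por.porated, tissue)

    def test_count_nondecreasing_in_voltage_sweep(self, chip, grid, mem):
        """Re-run the full solve at each voltage: the porated-cell count
        must be monotone in applied voltage."""
        mg = build_geometry(chip, grid, open_fraction=0.65, seed=1)
        sg = conductivity_map(mg)
        from tntsim import tissue_mask

        tis = (mg.labels == Material.TISSUE) & tissue_mask(grid)
        counts = []
        for v in np.linspace(0.0, 400.0, 9):
            bc = BoundaryConditions.plate_electrodes(grid.n_rows, v)
            phi = solve_potential(sg, bc)
            f = smooth_field(field_magnitude(phi, sg), 1.0, mask=sg.sigma > 1e-6)
            counts.append(poration_map(induced_vm(f, mem, tis), mem, tis).count)
        assert counts[0] == 0
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_monotone_in_coupling_radius(self, default_field, default_materials):
        tis = default_materials.labels == Material.TISSUE
        counts = []
        for r in (0.05, 0.2, 1.0, 5.0):
            m = MembraneParams(coupling_radius=r)
            counts.append(poration_map(induced_vm(default_field, m, tis), m, tis).count)
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestApEvents:
    def test_cap_is_pulses_times_refractory_quotient(self, mem):
        vm = np.full((4, 4), 300.0)
        proto = PulseProtocol(voltage=200.0, pulse_ms=10.0, n_pulses=10)
        counts = ap_events(vm, proto, mem)
        assert np.all(counts == 10 * 10)

    def test_subthreshold_cells_never_fire(self, mem):
        vm = np.full((4, 4), 84.9)  # depolarized by < 15 mV
        counts = ap_events(vm, PulseProtocol(), mem)
        assert np.all(counts == 0)

    def test_refractory_equal_to_pulse_gives_one_per_pulse(self):
        mem = MembraneParams(refractory=10.0)
        vm = np.full((4, 4), 300.0)
        counts = ap_events(vm, PulseProtocol(n_pulses=3), mem)
        assert np.all(counts == 3)

    def test_outside_tissue_never_fires(self, mem):
        vm = np.zeros((4, 4))  # zeroed outside tissue
        assert np.all(ap_events(vm, PulseProtocol(), mem) == 0)


class TestTransfectionMap:
    def _mask(self, n_true=100, shape=(20, 20), seed=0):
        rng = np.random.default_rng(seed)
        flat = np.zeros(shape[0] * shape[1], dtype=bool)
        flat[rng.choice(flat.size, n_true, replace=False)] = True
        return PorationMask(porated=flat.reshape(shape), threshold_field=0.0)

    def test_certain_efficiency_realizes_everything(self):
        por = self._mask()
        t = transfection_map(por, mean_eff=1.0, sd_eff=0.0, seed=3)
        assert np.array_equal(t.realized, por.porated)

    def test_zero_efficiency_realizes_nothing(self):
        t = transfection_map(self._mask(), mean_eff=0.0, sd_eff=0.0, seed=3)
        assert not t.realized.any()

    def test_realized_fraction_matches_binomial_oracle(self):
        por = PorationMask(porated=np.ones((100, 100), dtype=bool), threshold_field=0.0)
        t = transfection_map(por, mean_eff=0.6, sd_eff=0.1, seed=11)
        frac = t.realized.sum() / 10_000
        se = np.sqrt(0.6 * 0.4 / 10_000)
        assert abs(frac - 0.6) < 3 * se

    def test_identical_seed_bit_identical(self):
        por = self._mask(500, (40, 40))
        a = transfection_map(por, 0.6, 0.15, seed=5)
        b = transfection_map(por, 0.6, 0.15, seed=5)
        assert np.array_equal(a.realized, b.realized)
        assert np.array_equal(a.probability, b.probability)

    def test_realized_subset_of_porated_and_probability_support(self):
        for seed in range(5):
            por = self._mask(200, (30, 30), seed=seed)
            t = transfection_map(por, 0.5, 0.3, seed=seed)
            assert not np.any(t.realized & ~por.porated)
            assert not np.any((t.probability > 0) & ~por.porated)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            transfection_map(self._mask(), mean_eff=1.5)
        with pytest.raises(ConfigurationError):
            transfection_map(self._mask(), sd_eff=-0.1)


class TestSummarize:
    def test_empty_poration_all_zero_fractions(self):
        tissue = np.ones((10, 10), dtype=bool)
        por = PorationMask(porated=np.zeros((10, 10), dtype=bool), threshold_field=0.0)
        t = transfection_map(por, 0.6, 0.1, seed=0)
        s = summarize_simulation(por, t, tissue)
        assert s.porated_fraction == 0.0
        assert s.realized_fraction == 0.0

    def test_full_poration_certain_transfection_unity_fractions(self):
        tissue = np.ones((10, 10), dtype=bool)
        por = PorationMask(porated=tissue.copy(), threshold_field=0.0)
        t = transfection_map(por, 1.0, 0.0, seed=0)
        s = summarize_simulation(por, t, tissue)
        assert s.porated_fraction == 1.0
        assert s.realized_fraction == 1.0

    def test_counts_agree_with_direct_mask_summation(self):
        rng = np.random.default_rng(9)
        tissue = rng.random((25, 25)) < 0.7
        porated = tissue & (rng.random((25, 25)) < 0.4)
        por = PorationMask(porated=porated, threshold_field=0.0)
        t = transfection_map(por, 0.5, 0.2, seed=1)
        s = summarize_simulation(por, t, tissue)
        assert s.porated_cells == int(porated.sum())
        assert s.tissue_cells == int(tissue.sum())
        assert s.realized_cells == int(t.realized.sum())
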