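"""Cell-on-substrate coupled solver: geometry building, pulse solves,
localization, conservation and the fine-grid oracle equivalence."""

import numpy as np
import pytest

from localep.design import pore_conductance
from localep.oracle import (
    single_pore_patch_oracle,
    slab_conductance_oracle,
    stacked_slab_divider_oracle,
)
from localep.params import CellGeometry, InvalidInputError, SubstrateSpec
from localep.unitcell import (
    EP_DETECTION_THRESHOLD,
    build_unit_cell,
    electroporated_area_fraction,
    onset_voltage_sweep,
    single_site_transmembrane_profile,
    solve_pulse,
)


@pytest.fixture(scope="module")
def problem_04(cells, substrates):
    return build_unit_cell(cells["large"], substrates["0.4um"])


@pytest.fixture(scope="module")
def map_5V(problem_04):
    return solve_pulse(problem_04, 5.0)


class TestBuild:
    def test_pore_count_matches_porosity(self, problem_04, cells):
        expected = cells["large"].footprint_area * 2.0e10
        assert abs(problem_04.n_sites - expected) <= 1.0

    def test_zero_porosity_degenerates_to_insulating_floor(self, cells):
        prob = build_unit_cell(cells["large"], SubstrateSpec(porosity=0.0))
        assert prob.n_sites == 0
        m = solve_pulse(prob, 10.0)
        assert electroporated_area_fraction(m) == 0.0
        assert np.allclose(m.N_final, m.N[0])

    def test_all_commercial_substrates_build(self, cells, substrates):
        for spec in substrates.values():
            prob = build_unit_cell(cells["large"], spec)
            assert prob.n_sites > 0

    def test_element_areas_sum_to_membrane_area(self, problem_04, cells):
        cell = cells["large"]
        total = problem_04.elem_area.sum()
        assert total == pytest.approx(cell.membrane_area, rel=1e-9)
        bottom = problem_04.elem_area[problem_04.elem_class == "substrate"].sum()
        assert bottom == pytest.approx(cell.footprint_area, rel=1e-9)


class TestPulseSolve:
    def test_no_drive_keeps_resting_density(self, problem_04):
        m = solve_pulse(problem_04, 0.0)
        assert np.allclose(m.N_final, m.N[0])
        assert electroporated_area_fraction(m) == 0.0

    def test_current_conservation(self, map_5V):
        assert map_5V.current_imbalance < 1e-6

    def test_field_localizes_in_substrate_pores(self, map_5V, substrates):
        # |E| inside a pore channel ~ U_subs / d_subs while the membrane
        # is still intact
        e_nominal = 5.0 / substrates["0.4um"].thickness
        assert map_5V.in_pore_field_initial == pytest.approx(e_nominal, rel=0.10)

    def test_electroporation_localized_near_pores(self, problem_04):
        m = solve_pulse(problem_04, 10.0)
        frac = electroporated_area_fraction(m)
        assert 0 < frac < 0.15  # localized regime persists at 10 V
        hot = m.N_final > EP_DETECTION_THRESHOLD
        assert set(m.classes[hot]) == {"substrate"}

    def test_pore_count_rises_fast_then_saturates(self, problem_04):
        m = solve_pulse(problem_04, 10.0, n_samples=40)
        final = m.pore_count[-1]
        at_20us = np.interp(2e-5, m.times, m.pore_count)
        at_3ms = np.interp(3e-3, m.times, m.pore_count)
        assert at_20us > 0.5 * final
        assert at_3ms > 0.9 * final
        assert np.all(np.diff(m.pore_count) >= -1e-9 * final)

    def test_fraction_monotone_in_voltage(self, cells, substrates):
        prob = build_unit_cell(cells["large"], substrates["1.0um"])
        fracs = [
            electroporated_area_fraction(solve_pulse(prob, u))
            for u in (1.0, 2.5, 5.0, 7.5, 10.0)
        ]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))

    def test_invalid_duration_rejected(self, problem_04):
        with pytest.raises(InvalidInputError):
            solve_pulse(problem_04, 5.0, duration=0.0)


class TestOnsetSweep:
    def test_grid_censoring_returns_first_point_above_onset(self, problem_04):
        # the true onset is 5 V; a grid starting above it reports its
        # first point
        assert onset_voltage_sweep(problem_04, [7.5, 10.0]) == 7.5

    def test_bad_grids_rejected(self, problem_04):
        with pytest.raises(InvalidInputError):
            onset_voltage_sweep(problem_04, [])
        with pytest.raises(InvalidInputError):
            onset_voltage_sweep(problem_04, [5.0, 2.5])

    def test_subthreshold_sweep_returns_none(self, problem_04):
        assert onset_voltage_sweep(problem_04, [0.5, 1.0]) is None


class TestOracleEquivalence:
    def test_divider_matches_textbook(self):
        v = stacked_slab_divider_oracle(1.0, 1e-3, 0.5, 1e-3)
        assert v == pytest.approx(2.0 / 3.0, rel=0.02)

    @pytest.mark.parametrize("dia", [0.1e-6, 0.4e-6])
    def test_homogenized_slab_matches_closed_form_kernel(self, dia):
        spec = SubstrateSpec(pore_radius=dia / 2, porosity=2.0e10)
        g = slab_conductance_oracle(spec)
        g_kernel = spec.porosity * pore_conductance(dia / 2, spec.thickness, 1.5)
        assert g == pytest.approx(g_kernel, rel=0.02)

    @pytest.mark.parametrize(
        "dia, h",
        [(0.1e-6, 100e-9), (0.2e-6, 100e-9), (0.4e-6, 100e-9),
         (0.4e-6, 50e-9), (0.4e-6, 150e-9)],
    )
    def test_site_reduction_matches_fine_grid(self, dia, h):
        """Pre-poration transmembrane voltage above a pore mouth from
        the production site network agrees with the brute-force
        axisymmetric solve within 5%."""
        spec = SubstrateSpec(pore_radius=dia / 2, porosity=2.0e10)
        oracle = single_pore_patch_oracle(spec, h_gap=h)
        _, ucm = single_site_transmembrane_profile(spec, h_gap=h)
        assert ucm[0] == pytest.approx(oracle.mouth_U_cm, rel=0.05)
        assert oracle.current_in == pytest.approx(oracle.current_out, rel=1e-6)


class TestGeometryRobustness:
    def test_onset_insensitive_to_cell_size(self, cells, substrates):
        grid = [1.0, 2.5, 5.0, 7.5, 10.0]
        large = onset_voltage_sweep(
            build_unit_cell(cells["large"], substrates["0.4um"]), grid
        )
        small = onset_voltage_sweep(
            build_unit_cell(cells["small"], substrates["0.4um"]), grid
        )
        assert large == small == 5.0

    def test_gap_within_supported_range_enforced(self):
        with pytest.raises(InvalidInputError):
            CellGeometry(gap_to_substrate=30e-9)
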