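"""Closed-form design calculators: substrate conductance, translocation
time, resistance and areal fraction."""

import math

import numpy as np
import pytest

from localep.design import (
    UnfoldedTranslocationWarning,
    design_sweep,
    effective_substrate_conductance,
    pore_areal_fraction,
    substrate_resistance,
    translocation_time,
)
from localep.params import InvalidInputError, SubstrateSpec


class TestEffectiveConductance:
    @pytest.mark.parametrize(
        "name, expected",
        [("0.4um", 366.0), ("1.0um", 1748.0)],
    )
    def test_reference_table_values(self, substrates, name, expected):
        g = effective_substrate_conductance(substrates[name], 1.5)
        assert g == pytest.approx(expected, abs=0.5)

    def test_zero_porosity_insulates(self):
        spec = SubstrateSpec(porosity=0.0)
        assert effective_substrate_conductance(spec, 1.5) == 0.0

    def test_linear_in_porosity(self, substrate_04):
        double = SubstrateSpec(
            thickness=substrate_04.thickness,
            pore_radius=substrate_04.pore_radius,
            porosity=2 * substrate_04.porosity,
        )
        assert effective_substrate_conductance(double, 1.5) == pytest.approx(
            2 * effective_substrate_conductance(substrate_04, 1.5), rel=1e-12
        )


class TestTranslocationTime:
    def test_reference_times(self, dna, substrate_04):
        t25 = translocation_time(dna, substrate_04, 2.5)
        t50 = translocation_time(dna, substrate_04, 5.0)
        assert t25 * 1e3 == pytest.approx(16.0 / 15.0, rel=1e-12)
        assert round(t25 * 1e3, 1) == 1.1
        assert round(t50 * 1e3, 1) == 0.5

    def test_inverse_in_voltage(self, dna, substrate_04):
        assert translocation_time(dna, substrate_04, 10.0) == pytest.approx(
            translocation_time(dna, substrate_04, 5.0) / 2.0, rel=1e-12
        )

    def test_independent_of_pore_radius(self, dna):
        ts = {
            translocation_time(
                dna,
                SubstrateSpec(pore_radius=r, porosity=2e10),
                2.5,
            )
            for r in (0.2e-6, 0.5e-6)
        }
        assert len(ts) == 1

    def test_unfolding_warning_gated_by_gyration_radius(self, dna):
        # R_g = 0.110 um: the coil fits through 0.4 um pores but not 0.1/0.2 um
        for dia in (0.1e-6, 0.2e-6):
            spec = SubstrateSpec(pore_radius=dia / 2, porosity=2e10)
            with pytest.warns(UnfoldedTranslocationWarning):
                translocation_time(dna, spec, 2.5)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error")
            translocation_time(
                dna, SubstrateSpec(pore_radius=0.2e-6, porosity=2e10), 2.5
            )

    def test_invalid_voltage_rejected(self, dna, substrate_04):
        with pytest.raises(InvalidInputError):
            translocation_time(dna, substrate_04, 0.0)


class TestSubstrateResistance:
    def test_reference_value(self, substrate_04):
        r = substrate_resistance(substrate_04, 0.33e-4, 1.5)
        assert r == pytest.approx(82.8, rel=5e-3)

    def test_small_pores_order_of_magnitude_more_resistive(self):
        r01 = substrate_resistance(
            SubstrateSpec(pore_radius=0.05e-6, porosity=2e10), 0.33e-4, 1.5
        )
        r04 = substrate_resistance(
            SubstrateSpec(pore_radius=0.2e-6, porosity=2e10), 0.33e-4, 1.5
        )
        assert r01 / r04 == pytest.approx(15.6, rel=0.01)
        assert r01 > 10 * r04

    def test_zero_porosity_gives_infinite_sentinel(self):
        assert substrate_resistance(
            SubstrateSpec(porosity=0.0), 0.33e-4, 1.5
        ) == math.inf

    def test_monotone_in_radius_and_porosity(self):
        radii = [0.05e-6, 0.1e-6, 0.15e-6, 0.2e-6]
        rs = [
            substrate_resistance(SubstrateSpec(pore_radius=r, porosity=2e10),
                                 0.33e-4, 1.5)
            for r in radii
        ]
        assert np.all(np.diff(rs) < 0)
        rhos = [0.5e10, 1e10, 2e10, 4e10]
        rs = [
            substrate_resistance(SubstrateSpec(pore_radius=0.2e-6, porosity=p),
                                 0.33e-4, 1.5)
            for p in rhos
        ]
        assert np.all(np.diff(rs) < 0)


class TestArealFraction:
    @pytest.mark.parametrize(
        "name, expected",
        [("0.4um", 0.0025), ("1.0um", 0.0126)],
    )
    def test_reference_fractions(self, substrates, name, expected):
        assert pore_areal_fraction(substrates[name]) == pytest.approx(
            expected, rel=0.01
        )

    def test_zero_porosity(self):
        assert pore_areal_fraction(SubstrateSpec(porosity=0.0)) == 0.0

    def test_increases_with_radius_and_porosity(self):
        f = lambda r, p: pore_areal_fraction(SubstrateSpec(pore_radius=r, porosity=p))
        assert f(0.2e-6, 2e10) > f(0.1e-6, 2e10)
        assert f(0.2e-6, 4e10) > f(0.2e-6, 2e10)


class TestDesignSweep:
    def test_rows_match_single_calls(self, dna):
        table = design_sweep(
            [0.2e-6, 0.4e-6], [1e10, 2e10], 0.33e-4, dna, [2.5, 5.0]
        )
        assert len(table) == 4
        # diameter-major ordering
        assert list(table["diameter_um"]) == pytest.approx([0.2, 0.2, 0.4, 0.4])
        for _, row in table.iterrows():
            spec = SubstrateSpec(
                pore_radius=row["diameter_um"] * 1e-6 / 2,
                porosity=row["porosity_per_cm2"] * 1e4,
            )
            assert row["G_eff_S_per_m2"] == pytest.approx(
                effective_substrate_conductance(spec, 1.5), rel=1e-12
            )
            assert row["R_ohm"] == pytest.approx(
                substrate_resistance(spec, 0.33e-4, 1.5), rel=1e-12
            )
            assert row["areal_fraction"] == pytest.approx(
                pore_areal_fraction(spec), rel=1e-12
            )
            assert row["t_trans_ms_at_2.5V"] == pytest.approx(
                translocation_time(dna, spec, 2.5) * 1e3, rel=1e-12
            )

    def test_resistance_monotone_in_diameter(self, dna):
        table = design_sweep(
            [0.1e-6, 0.2e-6, 0.3e-6, 0.4e-6], [2e10], 0.33e-4, dna, [2.5]
        )
        assert np.all(np.diff(table["R_ohm"]) < 0)

    def test_empty_grid_rejected(self, dna):
        with pytest.raises(InvalidInputError):
            design_sweep([], [2e10], 0.33e-4, dna, [2.5])
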