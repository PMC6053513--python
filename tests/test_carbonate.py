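"""Carbonate speciation, equilibrium constants, and calcite saturation state."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import matlith as ml


class TestEquilibriumConstants:
    def test_freshwater_pk_values_at_25C(self):
        # canonical dilute-water values: pK1 6.35, pK2 10.33, calcite pKsp 8.48
        c = ml.equilibrium_constants(25.0)
        assert -np.log10(c.k1) == pytest.approx(6.35, abs=0.01)
        assert -np.log10(c.k2) == pytest.approx(10.33, abs=0.01)
        assert -np.log10(c.ksp_calcite) == pytest.approx(8.48, abs=0.01)

    def test_positivity_and_ordering(self):
        for t in (5.0, 25.0, 60.0, 90.0):
            c = ml.equilibrium_constants(t)
            assert c.k1 > c.k2 > 0
            assert c.ksp_calcite > 0

    def test_calcite_solubility_is_retrograde(self):
        # calcite gets less soluble as water warms
        ksps = [
            ml.equilibrium_constants(t).ksp_calcite for t in (10.0, 30.0, 50.0, 70.0)
        ]
        assert ksps == sorted(ksps, reverse=True)

    def test_k2_increases_over_ambient_range(self):
        k2s = [ml.equilibrium_constants(t).k2 for t in (5.0, 25.0, 45.0)]
        assert k2s == sorted(k2s)

    def test_seawater_set_pk_values_at_25C(self):
        # Mehrbach-refit surface-seawater values: pK1 5.85, pK2 8.97 at S=35
        c = ml.equilibrium_constants(25.0, "seawater", salinity=35.0)
        assert -np.log10(c.k1) == pytest.approx(5.85, abs=0.02)
        assert -np.log10(c.k2) == pytest.approx(8.97, abs=0.03)

    def test_unknown_set_rejected(self):
        with pytest.raises(ValueError):
            ml.equilibrium_constants(25.0, "briny")

    def test_freshwater_set_refuses_salinity(self):
        with pytest.raises(ValueError):
            ml.equilibrium_constants(25.0, "freshwater", salinity=5.0)


class TestSpeciation:
    def test_components_sum_to_tco2(self):
        w = ml.WaterChemistry(52.4, 8.34, 11.91, 0.55)
        s = ml.speciate(w)
        assert s.tco2_mm == pytest.approx(11.91, rel=1e-12)

    @pytest.mark.parametrize("ph, dominant", [(3.0, "co2_aq_mm"), (12.5, "co3_mm")])
    def test_limiting_cases(self, ph, dominant):
        w = ml.WaterChemistry(25.0, ph, 10.0, 0.5)
        s = ml.speciate(w)
        assert getattr(s, dominant) / 10.0 > 0.97

    def test_equivalence_point_at_pk2(self):
        c = ml.equilibrium_constants(25.0)
        w = ml.WaterChemistry(25.0, -np.log10(c.k2), 10.0, 0.5)
        s = ml.speciate(w)
        assert s.hco3_mm == pytest.approx(s.co3_mm, rel=1e-9)

    @given(
        t=st.floats(min_value=5.0, max_value=90.0),
        ph=st.floats(min_value=4.0, max_value=11.0),
        tco2=st.floats(min_value=0.1, max_value=50.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_fractions_are_a_partition(self, t, ph, tco2):
        s = ml.speciate(ml.WaterChemistry(t, ph, tco2, 0.5))
        parts = np.array([s.co2_aq_mm, s.hco3_mm, s.co3_mm])
        assert np.all(parts >= 0)
        assert parts.sum() == pytest.approx(tco2, rel=1e-9)

    def test_davies_correction_raises_carbonate_ion(self):
        w = ml.WaterChemistry(25.0, 8.3, 10.0, 0.5)
        plain = ml.speciate(w)
        corrected = ml.speciate(w, ionic_strength=0.05)
        assert corrected.co3_mm > plain.co3_mm


class TestOmega:
    def test_unit_omega_at_equilibrium_ion_product(self):
        c = ml.equilibrium_constants(25.0)
        w = ml.WaterChemistry(25.0, 8.0, 10.0, 0.5)
        co3 = ml.speciate(w).co3_mm * 1e-3
        ca_eq_mm = c.ksp_calcite / co3 * 1e3
        sat = ml.omega_calcite(ml.WaterChemistry(25.0, 8.0, 10.0, ca_eq_mm))
        assert sat.omega == pytest.approx(1.0, rel=1e-9)

    def test_linear_in_calcium(self):
        w1 = ml.WaterChemistry(40.0, 8.2, 11.0, 0.5)
        w2 = ml.WaterChemistry(40.0, 8.2, 11.0, 1.0)
        assert ml.omega_calcite(w2).omega == pytest.approx(
            2 * ml.omega_calcite(w1).omega, rel=1e-12
        )

    def test_strictly_increasing_in_ph(self):
        omegas = [
            ml.omega_calcite(ml.WaterChemistry(40.0, ph, 11.0, 0.55)).omega
            for ph in np.linspace(6.0, 10.0, 9)
        ]
        assert all(a < b for a, b in zip(omegas, omegas[1:]))

    def test_station_rank_order_matches_field_table(self, table1_stations):
        """The printed saturation-state ranking (upstream > 5-cm porewater >
        downstream > 1-cm porewater) is reproduced by the speciation model."""
        omegas = {
            row["station"]: ml.omega_calcite(
                ml.WaterChemistry(
                    row["temperature_c"], row["ph"], row["tco2_mm"], row["calcium_mm"]
                )
            ).omega
            for _, row in table1_stations.iterrows()
        }
        assert (
            omegas["upstream"]
            > omegas["porewater_5cm"]
            > omegas["downstream"]
            > omegas["porewater_1cm"]
        )

    def test_zero_calcium_rejected(self):
        with pytest.raises(ValueError):
            ml.omega_calcite(ml.WaterChemistry(25.0, 8.0, 10.0, 0.0))

    def test_davies_correction_lowers_omega(self):
        w = ml.WaterChemistry(40.0, 8.3, 11.0, 0.55)
        assert (
            ml.omega_calcite(w, ionic_strength=0.05).omega
            < ml.omega_calcite(w).omega
        )


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(temperature_c=-5.0, ph=8.0, tco2_mm=10.0, calcium_mm=0.5),
            dict(temperature_c=25.0, ph=15.0, tco2_mm=10.0, calcium_mm=0.5),
            dict(temperature_c=25.0, ph=8.0, tco2_mm=0.0, calcium_mm=0.5),
            dict(temperature_c=25.0, ph=8.0, tco2_mm=10.0, calcium_mm=-0.1),
        ],
    )
    def test_invalid_water_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ml.WaterChemistry(**kwargs)
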