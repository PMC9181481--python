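"""Landmark extraction, Boltzmann enhancements, classification, Henry link."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import interfep as ifp
from interfep.landmarks import HYDROPHILIC, HYDROPHOBIC
from interfep.reference_table import TABLE1, get_row


class TestExtractLandmarks:
    def test_analytic_profile_ground_truth(self, analytic_profile):
        # 0.01 nm grid: the discrete minimum/plateau means carry O(dz^2)
        # discretisation error of a few 1e-3 kJ/mol
        lm = ifp.extract_landmarks(analytic_profile)
        assert lm.dg_gs == pytest.approx(-10.0, abs=0.01)
        assert lm.dg_hydr == pytest.approx(-4.0, abs=0.01)
        assert lm.dg_sl == pytest.approx(6.0, abs=0.02)
        assert 0.8 <= lm.z_min <= 2.6

    def test_additive_identity_by_construction(self, analytic_profile):
        lm = ifp.extract_landmarks(analytic_profile)
        assert lm.dg_gs + lm.dg_sl - lm.dg_hydr == pytest.approx(0.0, abs=1e-12)

    def test_unreferenced_profile_rejected(self):
        prof = ifp.FreeEnergyProfile(z=np.linspace(-3.5, 3.5, 71), g=np.zeros(71))
        with pytest.raises(ValueError, match="referenced"):
            ifp.extract_landmarks(prof)

    def test_region_without_occupied_bins_rejected(self, analytic_profile):
        g = analytic_profile.g.copy()
        g[np.abs(analytic_profile.z) <= 0.7] = np.nan
        holed = ifp.FreeEnergyProfile(
            z=analytic_profile.z, g=g, reference="vacuum-plateau"
        )
        with pytest.raises(ValueError, match="bulk"):
            ifp.extract_landmarks(holed)

    def test_tolerates_gaps_inside_regions(self, analytic_profile):
        g = analytic_profile.g.copy()
        g[::7] = np.nan  # scattered unvisited bins
        holed = ifp.FreeEnergyProfile(
            z=analytic_profile.z, g=g, reference="vacuum-plateau"
        )
        lm = ifp.extract_landmarks(holed)
        assert lm.dg_gs == pytest.approx(-10.0, abs=0.01)


class TestEnhancement:
    def test_printed_oh_surface_value(self):
        assert ifp.concentration_enhancement(-22.04, 300.0) == pytest.approx(
            6880.9, rel=0.005
        )

    def test_zero_free_energy_is_unity(self):
        assert ifp.concentration_enhancement(0.0, 250.0) == 1.0

    def test_rt_gives_inverse_e(self):
        rt = ifp.kT(300.0)
        assert ifp.concentration_enhancement(rt, 300.0) == pytest.approx(
            math.exp(-1), rel=1e-12
        )

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            ifp.concentration_enhancement(-5.0, 0.0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(dg=st.floats(-40, 15), delta=st.floats(0.1, 5.0))
    def test_strictly_monotone_in_dg(self, dg, delta):
        """Lowering a free energy strictly increases its enhancement."""
        assert ifp.concentration_enhancement(
            dg - delta, 300.0
        ) > ifp.concentration_enhancement(dg, 300.0)


class TestClassification:
    @pytest.mark.parametrize(
        "dg, expected",
        [(-35.76, HYDROPHILIC), (7.47, HYDROPHOBIC), (-1e-9, HYDROPHILIC)],
    )
    def test_sign_convention(self, dg, expected):
        assert ifp.classify_species(dg) == expected

    def test_boundary_zero_warns_hydrophobic(self):
        with pytest.warns(UserWarning, match="convention"):
            assert ifp.classify_species(0.0) == HYDROPHOBIC

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            ifp.classify_species(float("nan"))


class TestHenry:
    def test_printed_ozone_conversion(self):
        h = ifp.HenryConstant(1.0e-4, "mol/m3/Pa", 298.15)
        assert ifp.henry_to_dghydr(h) == pytest.approx(3.46, abs=0.005)

    def test_unit_partition_ratio_gives_zero(self):
        h = ifp.HenryConstant(1.0, "dimensionless", 298.15)
        assert ifp.henry_to_dghydr(h) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(value=st.floats(1e-6, 1e4), temp=st.floats(270, 330))
    def test_round_trip_inverse(self, value, temp):
        """exp(-dG/RT) recovers the dimensionless ratio to 1e-12 relative."""
        h = ifp.HenryConstant(value, "mol/m3/Pa", temp)
        dg = ifp.henry_to_dghydr(h)
        back = math.exp(-dg / ifp.kT(temp))
        assert back == pytest.approx(h.dimensionless(), rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ifp.HenryConstant(-1.0)
        with pytest.raises(ValueError):
            ifp.HenryConstant(1.0, "mol/L/atm")


class TestSummary:
    def test_composes_all_pieces(self, analytic_profile):
        h = ifp.HenryConstant(1.0e-4, "mol/m3/Pa", 298.15)
        s = ifp.summarize_species("X", analytic_profile, henry=h)
        assert s.hydro_class == HYDROPHILIC
        assert s.enhancement_surface == pytest.approx(
            math.exp(10.0 / ifp.kT(300.0)), rel=1e-3
        )
        assert s.enhancement_bulk == pytest.approx(
            math.exp(4.0 / ifp.kT(300.0)), rel=1e-3
        )
        assert s.dg_hydr_expt == pytest.approx(3.46, abs=0.005)

    def test_missing_henry_is_not_an_error(self, analytic_profile):
        s = ifp.summarize_species("X", analytic_profile)
        assert s.dg_hydr_expt is None

    def test_errors_name_the_species(self):
        prof = ifp.FreeEnergyProfile(z=np.linspace(-3.5, 3.5, 71), g=np.zeros(71))
        with pytest.raises(ValueError, match="'NO2'"):
            ifp.summarize_species("NO2", prof)


class TestReferenceTableConsistency:
    def test_all_rows_satisfy_additive_identity(self):
        for row in TABLE1:
            assert row.dg_gs + row.dg_sl == pytest.approx(row.dg_hydr, abs=0.01)

    def test_all_printed_enhancements_reproduced(self):
        """1% relative (ΔG print rounding) plus the enhancement's own print
        granularity (values like 4.8 are printed to one decimal, so carry an
        extra ±0.05 of rounding)."""
        for row in TABLE1:
            for dg, printed in (
                (row.dg_gs, row.enhancement_surface),
                (row.dg_hydr, row.enhancement_bulk),
            ):
                computed = ifp.concentration_enhancement(dg, 300.0)
                assert abs(computed - printed) <= 0.01 * printed + 0.05, row.name

    def test_hydrophilicity_split_nine_three(self):
        classes = [ifp.classify_species(r.dg_hydr) for r in TABLE1]
        assert classes.count(HYDROPHILIC) == 9
        assert classes.count(HYDROPHOBIC) == 3
        hydrophobic = {r.name for r in TABLE1 if ifp.classify_species(r.dg_hydr) == HYDROPHOBIC}
        assert hydrophobic == {"O3", "NO", "NO2"}

    def test_oh_row_identity(self):
        oh = get_row("OH")
        assert oh.dg_gs + oh.dg_sl == pytest.approx(-16.51, abs=0.01)
        assert oh.dg_sl == pytest.approx(5.53)
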