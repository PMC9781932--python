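"""σ-profile algebra, σ-potential solver and descriptor families."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cosolv as cv
from cosolv.sigma import (BANDS, SIGMA_GRID, CosmoParameterSet,
                          ProfileFormatError, _rebin_conserving)
from cosolv.synth import ProfileSpec, make_profile


def delta_profile(area=100.0):
    return cv.SigmaProfile(np.where(SIGMA_GRID == 0.0, area, 0.0))


class TestProfileIO:
    def test_single_bin_file(self):
        prof = cv.load_sigma_profile(io.StringIO("0.0 100.0\n"))
        assert prof.total_area == pytest.approx(100.0)

    def test_comments_and_negative_p(self):
        prof = cv.load_sigma_profile(
            io.StringIO("# header\n-0.01 5.0\n0.0 10.0\n0.01 5.0\n"))
        assert prof.total_area == pytest.approx(20.0)
        with pytest.raises(ProfileFormatError):
            cv.load_sigma_profile(io.StringIO("0.0 -1.0\n0.01 1.0\n"))

    def test_round_trip_preserves_total_area(self, amide, tmp_path):
        path = tmp_path / "p.sigma"
        cv.save_sigma_profile(amide, path)
        back = cv.load_sigma_profile(path)
        assert back.total_area == pytest.approx(amide.total_area, rel=1e-6)

    def test_rebin_conserves_band_integrals(self):
        src = np.round(np.arange(-0.03, 0.0301, 0.002), 10)
        p = np.exp(-0.5 * (src / 0.01) ** 2) * 10.0
        fine = np.round(np.arange(-0.035, 0.0351, 0.001), 10)
        out = _rebin_conserving(src, p, fine)
        assert out.sum() == pytest.approx(p.sum(), rel=1e-12)
        band = lambda g, v, lo, hi: v[(g >= lo - 1e-12) & (g <= hi + 1e-12)].sum()
        assert band(fine, out, -0.0105, 0.0105) == pytest.approx(
            band(src, p, -0.0105, 0.0105), rel=0.05)


class TestMixProfiles:
    def test_identity_and_idempotence(self, water):
        assert np.allclose(cv.mix_profiles([(water, 1.0)]).p, water.p)
        assert np.allclose(
            cv.mix_profiles([(water, 0.5), (water, 0.5)]).p, water.p)

    def test_area_linearity(self, water, alkane):
        w = cv.SigmaProfile(water.p * (100.0 / water.total_area))
        a = cv.SigmaProfile(alkane.p * (200.0 / alkane.total_area))
        mix = cv.mix_profiles([(w, 0.25), (a, 0.75)])
        assert mix.total_area == pytest.approx(175.0)

    def test_associativity(self, water, alkane, amide):
        direct = cv.mix_profiles([(water, 0.2), (alkane, 0.3), (amide, 0.5)])
        inner = cv.mix_profiles([(water, 0.4), (alkane, 0.6)])
        nested = cv.mix_profiles([(inner, 0.5), (amide, 0.5)])
        assert np.allclose(direct.p, nested.p, atol=1e-12)

    def test_bad_composition_rejected(self, water, alkane):
        with pytest.raises(ValueError):
            cv.mix_profiles([(water, 0.5), (alkane, 0.6)])


class TestContactEnergy:
    def test_opposite_charges_cancel_misfit(self):
        e_mf, _, _ = cv.contact_energy(0.01, -0.01, CosmoParameterSet())
        assert e_mf == 0.0

    def test_hb_bracket_hand_value(self):
        p = CosmoParameterSet(sigma_hb=0.0085)
        _, e_hb, _ = cv.contact_energy(-0.02, 0.02, p)
        assert e_hb == pytest.approx(p.a_eff * p.c_hb * (-0.0115))
        assert e_hb < 0

    def test_hb_zero_below_threshold(self):
        p = CosmoParameterSet(sigma_hb=0.0085)
        for s, sp in [(0.0, 0.0), (0.005, -0.005), (0.008, 0.008)]:
            assert cv.contact_energy(s, sp, p)[1] == 0.0

    def test_sign_conventions_over_grid(self):
        p = CosmoParameterSet(tau_vdw=-0.05)
        e_mf, e_hb, e_vdw = cv.contact_energy(
            SIGMA_GRID[:, None], SIGMA_GRID[None, :], p)
        assert np.all(e_mf >= 0)
        assert np.all(e_hb <= 0)
        assert np.ptp(e_vdw) == 0  # constant in sigma


class TestSigmaPotential:
    def test_single_bin_closed_form(self):
        p = CosmoParameterSet()
        pot = cv.sigma_potential(delta_profile(), 298.15, p, tol=1e-12)
        closed = p.a_eff * (p.alpha_prime / 2.0) * SIGMA_GRID ** 2
        i = np.argmin(np.abs(SIGMA_GRID - 0.01))
        assert pot.mu[i] == pytest.approx(closed[i], rel=1e-10)
        assert abs(pot.mu[SIGMA_GRID == 0.0][0]) < 1e-10

    def test_symmetric_profile_no_hb_gives_even_potential(self, water):
        p = CosmoParameterSet(c_hb=0.0)
        pot = cv.sigma_potential(water, 298.15, p)
        assert np.allclose(pot.mu, pot.mu[::-1], atol=1e-10)

    def test_tolerance_monotonicity(self, amide):
        p = CosmoParameterSet()
        rt = cv.R_GAS * 298.15 / 1000.0
        loose = cv.sigma_potential(amide, 298.15, p, tol=2e-8)
        tight = cv.sigma_potential(amide, 298.15, p, tol=1e-8)
        assert np.max(np.abs(loose.mu - tight.mu)) < 2e-8 * rt

    def test_temperature_changes_potential(self, amide):
        a = cv.sigma_potential(amide, 288.15)
        b = cv.sigma_potential(amide, 318.15)
        assert not np.allclose(a.mu, b.mu)


class TestBandsAndAffinity:
    def test_constant_potential_band_mean(self):
        pot = cv.SigmaPotential(mu=np.full_like(SIGMA_GRID, 3.5),
                                temperature=298.15)
        for band in BANDS.values():
            assert cv.band_value(pot, band) == pytest.approx(3.5)

    def test_empty_band_errors(self):
        pot = cv.SigmaPotential(mu=np.zeros_like(SIGMA_GRID),
                                temperature=298.15)
        with pytest.raises(ValueError):
            cv.band_value(pot, (0.2, 0.3))

    def test_symmetric_potential_hba_equals_hbd(self, water):
        pot = cv.sigma_potential(water, 298.15, CosmoParameterSet(c_hb=0.0))
        assert cv.band_value(pot, BANDS["HBA"]) == pytest.approx(
            cv.band_value(pot, BANDS["HBD"]), abs=1e-10)

    def test_self_system_symmetric_profile_zero_descriptors(self, water):
        pot = cv.sigma_potential(water, 298.15, CosmoParameterSet(c_hb=0.0))
        d = cv.affinity_descriptors(pot, pot)
        assert d.hba == pytest.approx(0.0, abs=1e-9)
        assert d.hbd == pytest.approx(0.0, abs=1e-9)
        assert d.hyd == pytest.approx(0.0, abs=1e-9)

    def test_constant_shift_of_solvent_shifts_descriptors(self, water, amide):
        sol = cv.sigma_potential(amide, 298.15)
        solv = cv.sigma_potential(water, 298.15)
        shifted = cv.SigmaPotential(mu=solv.mu + 2.0, temperature=298.15)
        d0 = cv.affinity_descriptors(sol, solv)
        d1 = cv.affinity_descriptors(sol, shifted)
        for a, b in [(d0.hba, d1.hba), (d0.hbd, d1.hbd), (d0.hyd, d1.hyd)]:
            assert b - a == pytest.approx(-2.0, abs=1e-9)

    def test_hyd_ordering_flips_between_polar_and_apolar_solvent(
            self, water, alkane, amide):
        sol = cv.sigma_potential(amide, 298.15)
        in_water = cv.affinity_descriptors(
            sol, cv.sigma_potential(water, 298.15))
        in_alkane = cv.affinity_descriptors(
            sol, cv.sigma_potential(alkane, 298.15))
        # a polar environment penalises neutral surface, an apolar one
        # rewards it: the relative hydrophobicity changes sign
        assert in_water.hyd < 0 < in_alkane.hyd

    def test_grid_mismatch_rejected(self, water):
        pot = cv.sigma_potential(water, 298.15)
        other = cv.SigmaPotential(mu=pot.mu, temperature=308.15)
        with pytest.raises(ValueError):
            cv.affinity_descriptors(pot, other)


class TestEnergyDescriptors:
    def test_simple_shares(self):
        d = cv.energy_descriptors([(1.0, 2.0, 1.0)], [1.0])
        assert (d.de_misfit, d.de_hb, d.de_vdw) == (0.25, 0.5, 0.25)
        assert d.de_misfit + d.de_hb + d.de_vdw == pytest.approx(1.0)

    def test_equal_components_composition_independent(self):
        e = [(2.0, -1.0, 0.5), (2.0, -1.0, 0.5)]
        a = cv.energy_descriptors(e, [0.3, 0.7])
        b = cv.energy_descriptors(e, [0.9, 0.1])
        assert (a.de_misfit, a.de_hb, a.de_vdw) == \
            (b.de_misfit, b.de_hb, b.de_vdw)

    def test_zero_denominator_flagged(self):
        d = cv.energy_descriptors([(1.0, -2.0, 1.0)], [1.0])
        assert not d.defined
        assert d.de_misfit == d.de_hb == d.de_vdw == 0.0

    @given(st.lists(st.tuples(st.floats(-5, 5), st.floats(-5, 5),
                              st.floats(-5, 5)),
                    min_size=1, max_size=4))
    @settings(max_examples=60, deadline=None)
    def test_share_closure_property(self, energies):
        n = len(energies)
        comp = [1.0 / n] * n
        d = cv.energy_descriptors(energies, comp)
        if d.defined:
            assert d.de_misfit + d.de_hb + d.de_vdw == pytest.approx(
                1.0, abs=1e-9)


class TestDescriptorVector:
    def test_length_and_determinism(self, amide, water, alkane):
        comps = [(water, 0.4), (alkane, 0.6)]
        v1 = cv.descriptor_vector(amide, comps, 298.15, -1.5)
        v2 = cv.descriptor_vector(amide, comps, 298.15, -1.5)
        assert v1.values.shape == (8,)
        assert np.array_equal(v1.values, v2.values)  # bit-exact

    def test_temperature_sensitivity(self, amide, water):
        a = cv.descriptor_vector(amide, [(water, 1.0)], 288.15, -1.5)
        b = cv.descriptor_vector(amide, [(water, 1.0)], 318.15, -1.5)
        assert not np.array_equal(a.values, b.values)

    def test_minmax_normalization_maps_to_unit_interval(self):
        rng = np.random.default_rng(0)
        table = rng.normal(size=(40, 8)) * [1, 5, 2, 0.1, 9, 3, 1, 2]
        scaled, (lo, hi) = cv.minmax_normalize(table)
        assert scaled.min() >= 0.0 and scaled.max() <= 1.0
        assert np.allclose(scaled.min(axis=0), 0.0)
        assert np.allclose(scaled.max(axis=0), 1.0)
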