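"""Material data, photon coefficients and stopping powers against
independent oracles (closed forms, numerical quadrature, standard
tabulated reference values)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from ntrtdose.materials import (
    CLASSICAL_ELECTRON_RADIUS_CM,
    ELECTRON_REST_MEV,
    ELEMENTS,
    IRON,
    MAGNETITE,
    SOFT_TISSUE,
    WATER,
    CrossSectionSet,
    Material,
    build_cross_section_set,
    electron_stopping_power,
    klein_nishina_total_cm2,
    load_material_library,
    mix_fenp_compound,
    mu_pair,
    photon_coefficients,
    save_material_library,
)

THOMSON_BARN = 0.6652458


def kn_total_by_quadrature(energy_mev: float) -> float:
    """Independent oracle: numerical integration of the Klein-Nishina
    differential cross section over the scattering angle."""
    k = energy_mev / ELECTRON_REST_MEV
    re2 = CLASSICAL_ELECTRON_RADIUS_CM**2

    def dsigma_dtheta(theta):
        ct = math.cos(theta)
        eps = 1.0 / (1.0 + k * (1.0 - ct))
        return (
            0.5
            * re2
            * eps**2
            * (eps + 1.0 / eps - (1.0 - ct**2))
            * 2.0
            * math.pi
            * math.sin(theta)
        )

    val, _ = quad(dsigma_dtheta, 0.0, math.pi, limit=200)
    return val


class TestKleinNishina:
    def test_thomson_limit(self):
        sigma_barn = klein_nishina_total_cm2(0.001) / 1e-24
        assert sigma_barn == pytest.approx(THOMSON_BARN, rel=0.01)

    @pytest.mark.parametrize("energy", [0.1, 1.0, 6.0])
    def test_total_matches_quadrature(self, energy):
        assert klein_nishina_total_cm2(energy) == pytest.approx(
            kn_total_by_quadrature(energy), rel=1e-3
        )


class TestPhotonCoefficients:
    def test_water_total_at_1mev(self):
        # standard tabulated water attenuation
        c = photon_coefficients(WATER, 1.0)
        assert c["total"] == pytest.approx(0.0707, rel=0.02)

    def test_pair_zero_below_threshold(self):
        for mat in (WATER, IRON, SOFT_TISSUE):
            assert photon_coefficients(mat, 1.0)["pair"] == 0.0
            assert np.all(mu_pair(mat, np.linspace(0.01, 2 * ELECTRON_REST_MEV, 40)) == 0.0)

    def test_process_additivity(self):
        grid = np.geomspace(0.001, 7.0, 64)
        c = photon_coefficients(WATER, grid)
        np.testing.assert_allclose(
            c["total"], c["photoelectric"] + c["compton"] + c["pair"], rtol=1e-12
        )

    def test_energy_range_errors(self):
        with pytest.raises(ValueError):
            photon_coefficients(WATER, 0.0005)
        with pytest.raises(ValueError):
            photon_coefficients(WATER, 8.0)

    def test_cross_section_set_invariants(self):
        cs = build_cross_section_set(SOFT_TISSUE)
        assert np.all(np.diff(cs.energy_grid) > 0)
        below = cs.energy_grid < 2 * ELECTRON_REST_MEV
        assert np.all(cs.mu_pair[below] == 0.0)
        with pytest.raises(ValueError):
            CrossSectionSet(
                energy_grid=cs.energy_grid,
                mu_photoelectric=cs.mu_photoelectric,
                mu_compton=cs.mu_compton,
                mu_pair=cs.mu_pair,
                mu_total=cs.mu_total * 1.5,
            )


class TestMixing:
    def test_zero_admixture_identity(self):
        assert mix_fenp_compound(SOFT_TISSUE, 0.0) is SOFT_TISSUE

    def test_inverse_density_rule_magnetite(self):
        # hand arithmetic: 1/(0.9/1.00 + 0.1/5.17) = 1.0877 g/cm^3
        m = mix_fenp_compound(WATER, 0.10, MAGNETITE)
        assert m.density == pytest.approx(1.0877, abs=2e-4)

    def test_linear_density_rule(self):
        m = mix_fenp_compound(WATER, 0.10, IRON, density_rule="linear")
        assert m.density == pytest.approx(0.9 * 1.0 + 0.1 * 7.874, rel=1e-12)

    def test_out_of_range_rejected_and_overridable(self):
        with pytest.raises(ValueError, match="studied"):
            mix_fenp_compound(WATER, 0.2)
        m = mix_fenp_compound(WATER, 0.2, allow_out_of_range=True)
        assert m.mass_fractions["Fe"] == pytest.approx(0.2)

    @pytest.mark.parametrize("w", [0.005, 0.05, 0.10])
    def test_mass_fraction_additivity_of_mu(self, w):
        """mu of the compound equals the mass-weighted component mu at
        every energy (definition of mass-fraction mixing)."""
        grid = np.geomspace(0.002, 6.5, 50)
        mix = mix_fenp_compound(WATER, w, IRON)
        mu_mix = photon_coefficients(mix, grid)["total"]
        mu_w = photon_coefficients(WATER, grid)["total"]
        mu_fe = photon_coefficients(IRON, grid)["total"]
        np.testing.assert_allclose(mu_mix, (1 - w) * mu_w + w * mu_fe, rtol=1e-12)

    def test_fe_fraction_recorded(self):
        assert mix_fenp_compound(SOFT_TISSUE, 0.05).fe_mass_fraction == 0.05

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        w=st.floats(1e-6, 0.10),
        energy=st.floats(0.002, 6.5),
        rule=st.sampled_from(["inverse", "linear"]),
    )
    def test_mixture_properties_hold_for_any_admixture(self, w, energy, rule):
        """For any admissible fraction and energy: fractions sum to one,
        the density lies between the components', and mu is the
        mass-weighted combination."""
        mix = mix_fenp_compound(SOFT_TISSUE, w, IRON, density_rule=rule)
        assert sum(mix.mass_fractions.values()) == pytest.approx(1.0, abs=1e-12)
        assert SOFT_TISSUE.density <= mix.density <= IRON.density
        mu_mix = photon_coefficients(mix, energy)["total"]
        mu_b = photon_coefficients(SOFT_TISSUE, energy)["total"]
        mu_a = photon_coefficients(IRON, energy)["total"]
        assert mu_mix == pytest.approx((1 - w) * mu_b + w * mu_a, rel=1e-9)


class TestStoppingPower:
    def test_water_collision_at_1mev(self):
        # standard tabulated electron stopping power for water
        s, _ = electron_stopping_power(WATER, 1.0)
        assert s == pytest.approx(1.849, rel=0.05)

    def test_csda_monotone(self):
        energies = np.geomspace(0.01, 6.0, 30)
        _, csda = electron_stopping_power(WATER, energies)
        assert np.all(np.diff(csda) > 0)

    def test_mass_stopping_density_independent(self):
        denser = Material("dense_water", dict(WATER.mass_fractions), 2.0, 75.0)
        s1, _ = electron_stopping_power(WATER, 1.0)
        s2, _ = electron_stopping_power(denser, 1.0)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_range_error(self):
        with pytest.raises(ValueError):
            electron_stopping_power(WATER, 1e-5)


class TestMaterialValidation:
    def test_fraction_sum_enforced(self):
        with pytest.raises(ValueError):
            Material("bad", {"H": 0.5, "O": 0.4}, 1.0, 75.0)

    def test_unknown_element(self):
        with pytest.raises(KeyError):
            Material("bad", {"Xx": 1.0}, 1.0, 75.0)

    def test_element_spec_invariants(self):
        with pytest.raises(ValueError):
            type(ELEMENTS["H"])("Q", 0, 1.0, 1.0, 19.2)

    def test_library_round_trip(self, tmp_path):
        path = tmp_path / "mats.yaml"
        save_material_library(path, [WATER, SOFT_TISSUE])
        loaded = load_material_library(path)
        assert loaded[0].mass_fractions == WATER.mass_fractions
        assert loaded[1].density == SOFT_TISSUE.density
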