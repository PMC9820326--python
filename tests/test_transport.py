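"""Monte Carlo transport engine: analytic oracles (helix, attenuation,
Compton kinematics), determinism and energy bookkeeping."""

import math

import numpy as np
import pytest

from ntrtdose.beam import BeamSpec
from ntrtdose.materials import ELECTRON_REST_MEV, WATER, Material, photon_coefficients
from ntrtdose.phantom import make_slab_phantom
from ntrtdose.transport import (
    FieldSpec,
    ParticleState,
    TransportConfig,
    charged_step,
    gyroradius_mm,
    run_simulation,
    _sample_compton,
)

NEAR_VACUUM = Material("near_vacuum", {"H": 1.0}, 1e-9, 19.2)


class TestChargedStep:
    def test_gyroradius_1mev_at_1p5t(self):
        # r = pc/(0.29979 B), pc = sqrt(T^2 + 2 T me) = 1.422 MeV
        assert gyroradius_mm(1.0, 1.5) == pytest.approx(3.16, rel=0.01)

    def test_zero_field_straight_line(self):
        st = ParticleState("electron", [0, 0, 0], [0, 0, 1], 1.0)
        out, _ = charged_step(st, FieldSpec(), NEAR_VACUUM, 5.0)
        np.testing.assert_allclose(out.direction, [0, 0, 1])
        np.testing.assert_allclose(out.position, [0, 0, 5.0])

    def test_parallel_field_no_rotation(self):
        st = ParticleState("electron", [0, 0, 0], [1, 0, 0], 1.0)
        out, _ = charged_step(st, FieldSpec(B=(1.5, 0, 0)), NEAR_VACUUM, 5.0)
        np.testing.assert_allclose(out.direction, [1, 0, 0], atol=1e-12)

    def test_perpendicular_orbit_radius(self):
        st = ParticleState("electron", [0, 0, 0], [0, 0, 1], 1.0)
        fs = FieldSpec(B=(1.5, 0, 0))
        pts = [st.position.copy()]
        for _ in range(300):
            st, _ = charged_step(st, fs, NEAR_VACUUM, 0.1)
            pts.append(st.position.copy())
        pts = np.asarray(pts)
        cy = (pts[:, 1].max() + pts[:, 1].min()) / 2
        cz = (pts[:, 2].max() + pts[:, 2].min()) / 2
        radii = np.hypot(pts[:, 1] - cy, pts[:, 2] - cz)
        assert radii.mean() == pytest.approx(3.1621, rel=0.01)
        assert np.ptp(pts[:, 0]) == 0.0  # no drift along B for alpha = 90 deg

    @pytest.mark.parametrize("alpha_deg", [30, 60, 90])
    def test_helix_radius_and_pitch(self, alpha_deg):
        """Multi-substep trajectory matches the analytic helix: radius
        r sin(alpha) about the field axis, pitch 2 pi r cos(alpha)."""
        alpha = math.radians(alpha_deg)
        t_mev = 1.0
        r_full = gyroradius_mm(t_mev, 1.5)
        u0 = [math.sin(alpha), 0.0, math.cos(alpha)]
        st = ParticleState("electron", [0, 0, 0], u0, t_mev)
        fs = FieldSpec(B=(0, 0, 1.5))  # field along z
        n_sub = 400
        step = 2 * math.pi * r_full / n_sub  # one full turn of path
        pts = [st.position.copy()]
        for _ in range(n_sub):
            st, _ = charged_step(st, fs, NEAR_VACUUM, step)
            pts.append(st.position.copy())
        pts = np.asarray(pts)
        cx = (pts[:, 0].max() + pts[:, 0].min()) / 2
        cy = (pts[:, 1].max() + pts[:, 1].min()) / 2
        radii = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
        assert radii.mean() == pytest.approx(r_full * math.sin(alpha), rel=0.01)
        pitch = pts[-1, 2] - pts[0, 2]
        assert pitch == pytest.approx(2 * math.pi * r_full * math.cos(alpha), rel=0.01, abs=1e-6)

    def test_magnetic_rotation_conserves_energy_in_vacuum(self):
        st = ParticleState("electron", [0, 0, 0], [0, 1, 0], 2.0)
        out, dep = charged_step(st, FieldSpec(B=(0, 0, 1.5)), NEAR_VACUUM, 1.0)
        assert dep == pytest.approx(0.0, abs=1e-9)
        assert out.kinetic_energy == pytest.approx(2.0, abs=1e-9)

    def test_photon_rejected(self):
        st = ParticleState("photon", [0, 0, 0], [0, 0, 1], 1.0)
        with pytest.raises(ValueError):
            charged_step(st, FieldSpec(), WATER, 1.0)

    def test_invalid_direction_rejected(self):
        with pytest.raises(ValueError):
            ParticleState("electron", [0, 0, 0], [0, 0, 2.0], 1.0)


class TestComptonSampling:
    def test_kinematic_consistency(self, rng):
        """Sampled (eps, cos_theta) pairs satisfy the Compton relation
        eps = 1/(1 + k (1 - cos_theta)) exactly, which guarantees the
        kinematic closure E0 = E' + T_e."""
        e0 = np.full(20000, 2.0)
        eps, cos_t = _sample_compton(e0, rng)
        k = e0 / ELECTRON_REST_MEV
        np.testing.assert_allclose(eps, 1.0 / (1.0 + k * (1.0 - cos_t)), rtol=1e-12)
        eps_min = 1.0 / (1.0 + 2.0 * k[0])
        assert eps.min() >= eps_min - 1e-12 and eps.max() <= 1.0 + 1e-12

    @pytest.mark.parametrize("energy", [0.1, 1.0, 6.0])
    def test_mean_energy_fraction_matches_quadrature(self, energy, rng):
        """Sampler mean of eps agrees with numerical integration of the
        Klein-Nishina differential cross section."""
        from scipy.integrate import quad

        k = energy / ELECTRON_REST_MEV

        def kn_weight(ct):
            eps = 1.0 / (1.0 + k * (1.0 - ct))
            return eps**2 * (eps + 1.0 / eps - (1.0 - ct**2))

        norm, _ = quad(kn_weight, -1, 1, limit=200)
        mean_eps_oracle, _ = quad(
            lambda ct: kn_weight(ct) / (1.0 + k * (1.0 - ct)), -1, 1, limit=200
        )
        mean_eps_oracle /= norm
        n = 200_000
        eps, _ = _sample_compton(np.full(n, energy), rng)
        se = eps.std() / math.sqrt(n)
        assert abs(eps.mean() - mean_eps_oracle) < 3.5 * se


class TestEngine:
    def test_determinism_bit_identical(self, beam6):
        ph = make_slab_phantom([(WATER, 30.0)], lateral_size=(20.0, 20.0))
        cfg = TransportConfig(n_primaries=3000, n_cycles=2, seed=5)
        a = run_simulation(ph, beam6, FieldSpec(B=(1.5, 0, 0)), cfg)
        b = run_simulation(ph, beam6, FieldSpec(B=(1.5, 0, 0)), cfg)
        np.testing.assert_array_equal(a.energy_deposit, b.energy_deposit)
        np.testing.assert_array_equal(a.fluence_charged, b.fluence_charged)

    def test_energy_bookkeeping_per_cycle(self, water_1mev_run):
        _, grids = water_1mev_run
        for c in grids.metadata["cycles"]:
            total = c["deposited_mev"] + c["escaped_mev"]
            assert total == pytest.approx(c["energy_in_mev"], rel=1e-6)

    def test_uncollided_attenuation_exp_mu_d(self, water_1mev_run):
        """Primary fluence decays as exp(-mu d) at three depths (3 SE)."""
        ph, grids = water_1mev_run
        mu = photon_coefficients(WATER, 1.0)["total"] * WATER.density  # 1/cm
        nz = ph.shape[2]
        # per-cycle layer-integrated primary fluence; entry face at +z
        layer = grids.fluence_primary.sum(axis=(1, 2))  # (cycles, nz)
        z0 = nz - 2
        for depth_cm in (4.0, 7.0, 10.0):
            zd = nz - 2 - int(depth_cm * 10 / 2.0)
            ratio_c = layer[:, zd] / layer[:, z0]
            expected = math.exp(-mu * depth_cm)
            se = ratio_c.std(ddof=1) / math.sqrt(grids.n_cycles)
            assert abs(ratio_c.mean() - expected) < 3 * se + 0.01 * expected

    def test_depth_dose_monotone_beyond_buildup(self, water_1mev_run):
        ph, grids = water_1mev_run
        dd = grids.energy_deposit.sum(axis=0).sum(axis=(0, 1))[::-1]  # entry first
        peak = int(np.argmax(dd))
        tail = dd[peak : peak + 60]
        # smooth with a short window to suppress voxel noise before asserting
        kernel = np.ones(5) / 5
        sm = np.convolve(tail, kernel, mode="valid")
        assert np.all(np.diff(sm) < 0.02 * sm[:-1])

    def test_no_pair_below_threshold(self, water_1mev_run):
        _, grids = water_1mev_run
        for c in grids.metadata["cycles"]:
            assert c["track_len_positron_mm"] == 0.0

    def test_electron_dominates_positron_fluence_at_6mv(self, beam6):
        ph = make_slab_phantom([(WATER, 60.0)], lateral_size=(30.0, 30.0))
        cfg = TransportConfig(n_primaries=20_000, n_cycles=2, seed=9, score_fluence=False)
        grids = run_simulation(ph, beam6, FieldSpec(), cfg)
        e = sum(c["track_len_electron_mm"] for c in grids.metadata["cycles"])
        p = sum(c["track_len_positron_mm"] for c in grids.metadata["cycles"])
        assert p > 0  # pair production does happen at 6 MV
        assert e >= 10 * p

    def test_primary_fluence_unaffected_by_field(self, beam6):
        """Uncharged primaries see no Lorentz force: with a shared seed the
        primary-fluence grids are identical with and without the field."""
        ph = make_slab_phantom([(WATER, 50.0)], lateral_size=(20.0, 20.0))
        cfg = TransportConfig(n_primaries=5000, n_cycles=2, seed=13, score_fluence=True)
        g0 = run_simulation(ph, beam6, FieldSpec(B=(0, 0, 0)), cfg)
        gb = run_simulation(ph, beam6, FieldSpec(B=(1.5, 0, 0)), cfg)
        np.testing.assert_array_equal(g0.fluence_primary, gb.fluence_primary)

    def test_n_cycles_validation(self):
        with pytest.raises(ValueError):
            TransportConfig(n_cycles=1)
        with pytest.raises(ValueError):
            TransportConfig(photon_cutoff_mev=1e-5)
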