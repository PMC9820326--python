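"""LQ survival, TER evaluation/fitting and iso-effect dose ratios."""

import numpy as np
import pandas as pd
import pytest

from ntrtdose.synthetic import GeneratorSpec, generate_survival_dataset
from ntrtdose.thermal import (
    FitResult,
    LQParameters,
    SurvivalDataset,
    TERModel,
    fit_ter_model,
    iso_effect_dose,
    iso_effect_ter,
    lq_survival,
    survival_dataset_to_ter,
    ter_evaluate,
    ter_with_uncertainty,
)


class TestLQSurvival:
    def test_zero_dose_full_survival(self):
        assert lq_survival(LQParameters(0.2, 0.05), 0.0) == 1.0

    def test_hand_value(self):
        # -ln S = 0.2*2 + 0.05*4 = 0.6
        assert lq_survival(LQParameters(0.2, 0.05), 2.0) == pytest.approx(np.exp(-0.6))

    def test_monotone_nonincreasing(self):
        doses = np.linspace(0, 10, 50)
        s = lq_survival(LQParameters(0.3, 0.03), doses)
        assert np.all(np.diff(s) <= 0)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            lq_survival(LQParameters(0.2, 0.05), -1.0)

    def test_negative_coefficients_rejected(self):
        with pytest.raises(ValueError):
            LQParameters(-0.1, 0.05)


class TestTEREvaluate:
    def test_offset_at_zero_time(self):
        m = TERModel(ter0=1.05, c1=0.02, c2=0.4, t_c=45.0)
        assert ter_evaluate(m, 43.0, 0.0) == pytest.approx(1.05)

    def test_hand_value(self):
        # 1 + 0.01*90*exp(0.5*(42-45)) = 1 + 0.9 e^-1.5
        m = TERModel(ter0=1.0, c1=0.01, c2=0.5, t_c=45.0)
        assert ter_evaluate(m, 42.0, 90.0) == pytest.approx(1.0 + 0.9 * np.exp(-1.5), rel=1e-9)
        assert ter_evaluate(m, 42.0, 90.0) == pytest.approx(1.2008, abs=2e-4)

    def test_strictly_increasing_in_t_and_time(self):
        m = TERModel(ter0=1.0, c1=0.02, c2=0.3, t_c=45.0)
        temps = np.linspace(37, 45, 20)
        assert np.all(np.diff(ter_evaluate(m, temps, 60.0)) > 0)
        times = np.linspace(0, 120, 20)
        assert np.all(np.diff(ter_evaluate(m, 41.0, times)) > 0)

    def test_invariants(self):
        with pytest.raises(ValueError):
            TERModel(ter0=0.8, c1=0.01, c2=0.3)
        with pytest.raises(ValueError):
            TERModel(ter0=1.0, c1=0.01, c2=0.0)


class TestIsoEffect:
    def test_identity(self):
        p = LQParameters(0.2, 0.02)
        assert iso_effect_ter(p, p, 0.1) == pytest.approx(1.0)

    def test_linear_limit_alpha_doubling(self):
        ref = LQParameters(0.2, 0.0)
        heat = LQParameters(0.4, 0.0)
        for s in (0.5, 0.1, 0.01):
            assert iso_effect_ter(ref, heat, s) == pytest.approx(2.0)

    def test_joint_scaling_closed_form(self):
        """alpha, beta jointly scaled by 1.5: explicit quadratic roots give
        the iso-effect ratio (less than 1.5 because the effect is quadratic
        in dose)."""
        ref = LQParameters(0.2, 0.02)
        heat = LQParameters(0.3, 0.03)
        effect = -np.log(0.1)
        d_ref = (-0.2 + np.sqrt(0.2**2 + 4 * 0.02 * effect)) / (2 * 0.02)
        d_heat = (-0.3 + np.sqrt(0.3**2 + 4 * 0.03 * effect)) / (2 * 0.03)
        assert iso_effect_ter(ref, heat, 0.1) == pytest.approx(d_ref / d_heat, rel=1e-9)
        assert d_ref / d_heat == pytest.approx(1.3441, abs=1e-4)

    def test_quadratic_root_against_bruteforce(self):
        params = LQParameters(0.25, 0.04)
        d = iso_effect_dose(params, 0.1)
        assert lq_survival(params, d) == pytest.approx(0.1, rel=1e-9)

    def test_sensitization_direction(self):
        """Heated parameters with larger coefficients give TER >= 1."""
        ref = LQParameters(0.2, 0.02)
        heat = LQParameters(0.35, 0.025)
        assert iso_effect_ter(ref, heat, 0.1) >= 1.0

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            iso_effect_dose(LQParameters(0.0, 0.0), 0.1)
        with pytest.raises(ValueError):
            iso_effect_dose(LQParameters(0.2, 0.02), 1.5)


class TestFit:
    def test_noiseless_recovery(self):
        truth = TERModel(ter0=1.0, c1=0.02, c2=0.3, t_c=45.0)
        spec = GeneratorSpec(true_model=truth, noise_sigma=0.0, seed=1)
        data, _ = generate_survival_dataset(spec, cell_labels=("A",))
        fit = fit_ter_model(data, t_c=45.0)
        assert fit.converged
        assert fit.model.ter0 == pytest.approx(truth.ter0, abs=1e-6)
        assert fit.model.c1 == pytest.approx(truth.c1, abs=1e-6)
        assert fit.model.c2 == pytest.approx(truth.c2, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_noisy_recovery_short_study(self):
        """2% multiplicative noise: coefficients recovered to ~10% in the
        median over replicate fits (reduced replicate count; the full study
        runs in the acceptance suite)."""
        truth = TERModel(ter0=1.0, c1=0.02, c2=0.3, t_c=45.0)
        errs = {"c1": [], "c2": []}
        r2 = []
        for rep in range(20):
            spec = GeneratorSpec(true_model=truth, noise_sigma=0.02, seed=100 + rep)
            data, _ = generate_survival_dataset(spec, cell_labels=("A",))
            fit = fit_ter_model(data, t_c=45.0)
            errs["c1"].append(abs(fit.model.c1 - truth.c1) / truth.c1)
            errs["c2"].append(abs(fit.model.c2 - truth.c2) / truth.c2)
            r2.append(fit.r_squared)
        assert np.median(errs["c1"]) < 0.10
        assert np.median(errs["c2"]) < 0.10
        assert np.median(r2) > 0.99

    def test_needs_three_temperatures(self):
        table = pd.DataFrame(
            {
                "cell_type": ["A"] * 2,
                "T_C": [39.0, 41.0],
                "t_min": [60.0] * 2,
                "value": [1.1, 1.3],
                "sigma": [0.01] * 2,
            }
        )
        with pytest.raises(ValueError):
            fit_ter_model(SurvivalDataset(table=table, value_kind="ter"))

    def test_free_tc_round_trip(self):
        truth = TERModel(ter0=1.0, c1=0.015, c2=0.35, t_c=43.0)
        spec = GeneratorSpec(
            true_model=truth,
            noise_sigma=0.0,
            temperatures=(37, 39, 41, 43, 45),
            times=(30.0, 60.0, 90.0),
            seed=2,
        )
        data, _ = generate_survival_dataset(spec, cell_labels=("A",))
        fit = fit_ter_model(data, t_c=None, init={"t_c": 44.0})
        # c1 and t_c trade off through c1*exp(-c2*t_c); check the prediction
        pred = ter_evaluate(fit.model, 42.0, 75.0)
        assert pred == pytest.approx(ter_evaluate(truth, 42.0, 75.0), rel=1e-4)

    def test_uncertainty_propagation_positive(self):
        truth = TERModel(ter0=1.0, c1=0.02, c2=0.3, t_c=45.0)
        spec = GeneratorSpec(true_model=truth, noise_sigma=0.02, seed=5)
        data, _ = generate_survival_dataset(spec, cell_labels=("A",))
        fit = fit_ter_model(data, t_c=45.0)
        ter, sigma = ter_with_uncertainty(fit, 42.0, 90.0)
        assert ter > 1.0 and sigma > 0.0


class TestSurvivalConversion:
    def test_jointly_scaled_survival_converts_to_iso_effect_ratio(self):
        """Survival generated from LQ parameters scaled by k converts to the
        iso-effect dose ratio computed from explicit quadratic roots."""
        ref = LQParameters(0.2, 0.02)
        d0 = iso_effect_dose(ref, 0.1)
        effect = -np.log(0.1)
        scales = [1.0, 1.2, 1.5]
        rows, expected = [], []
        for k, temp in zip(scales, (37.0, 41.0, 44.0)):
            heated = LQParameters(ref.alpha * k, ref.beta * k)
            rows.append(
                {
                    "cell_type": "A",
                    "T_C": temp,
                    "t_min": 60.0,
                    "value": lq_survival(heated, d0),
                    "sigma": 0.01,
                }
            )
            a, b = ref.alpha * k, ref.beta * k
            d_heat = (-a + np.sqrt(a * a + 4 * b * effect)) / (2 * b)
            expected.append(d0 / d_heat)
        data = SurvivalDataset(table=pd.DataFrame(rows), value_kind="survival")
        converted = survival_dataset_to_ter(data, ref, survival_level=0.1)
        np.testing.assert_allclose(converted.table["value"].to_numpy(), expected, rtol=1e-7)
        assert np.all(converted.table["sigma"].to_numpy() > 0)
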