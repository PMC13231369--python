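"""Quadratic temperature model, expansibility and Hepler classification."""

import numpy as np
import pytest

from solvatherm import datasets
from solvatherm.temperature_model import (
    QuadraticTemperatureModel,
    fit_temperature_model,
    fit_quality,
    expansibility_slope_from_values,
    hepler_classification,
)

T_STUDY = np.array([288.15, 298.15, 308.15, 318.15])


def vandermonde_oracle(T, V, T_ref):
    """Independent polynomial solve (normal equations on the Vandermonde design)."""
    t = np.asarray(T) - T_ref
    A = np.vander(t, 3, increasing=True)
    return np.linalg.solve(A.T @ A, A.T @ np.asarray(V))


class TestQuadraticFit:
    def test_recovers_published_threonine_coefficients(self):
        a, b, c = 77.70e-6, 0.00915e-6, 0.00016e-6
        V = a + b * (T_STUDY - 298.15) + c * (T_STUDY - 298.15) ** 2
        model = fit_temperature_model(zip(T_STUDY, V))
        assert model.a_ == pytest.approx(a, rel=1e-12)
        assert model.b_ == pytest.approx(b, rel=1e-9)
        assert model.c_ == pytest.approx(c, rel=1e-9)

    def test_constant_input(self):
        model = fit_temperature_model([(T, 5.0) for T in T_STUDY])
        assert model.a_ == pytest.approx(5.0)
        assert model.b_ == pytest.approx(0.0, abs=1e-12)
        assert model.c_ == pytest.approx(0.0, abs=1e-14)

    def test_matches_vandermonde_oracle(self, rng):
        for _ in range(100):
            V = rng.normal(100, 5, 4)
            model = QuadraticTemperatureModel().fit(T_STUDY, V)
            a0, b0, c0 = vandermonde_oracle(T_STUDY, V, 298.15)
            assert model.a_ == pytest.approx(a0, rel=1e-10, abs=1e-12)
            assert model.b_ == pytest.approx(b0, rel=1e-8, abs=1e-10)
            assert model.c_ == pytest.approx(c0, rel=1e-8, abs=1e-10)

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_temperature_model([(288.15, 1.0), (298.15, 2.0)])
        with pytest.raises(ValueError, match="duplicate"):
            fit_temperature_model([(288.15, 1.0), (288.15, 2.0), (298.15, 3.0)])


class TestFitQuality:
    def test_exact_fit_is_zero(self):
        V = 100.0 + 0.1 * (T_STUDY - 298.15)
        model = fit_temperature_model(zip(T_STUDY, V))
        pts = list(zip(T_STUDY, V))
        assert fit_quality(pts, model, "residual_sd") == pytest.approx(0.0, abs=1e-10)
        assert fit_quality(pts, model, "ard") == pytest.approx(0.0, abs=1e-12)

    def test_perturbation_vs_refit_oracle(self):
        V = 100 + 0.05 * (T_STUDY - 298.15)
        delta = 0.01
        Vp = V.copy()
        Vp[2] += delta
        model = fit_temperature_model(zip(T_STUDY, Vp))
        got = fit_quality(list(zip(T_STUDY, Vp)), model, "residual_sd")
        # direct numerical oracle: residual of the refit
        t = T_STUDY - 298.15
        A = np.vander(t, 3, increasing=True)
        H = A @ np.linalg.solve(A.T @ A, A.T)
        resid = (np.eye(4) - H) @ (Vp - V)
        assert got == pytest.approx(np.sqrt(resid @ resid / 1), rel=1e-8)

    def test_scale_behaviour(self):
        V = 100 + 0.05 * (T_STUDY - 298.15) + np.array([0.0, 0.01, -0.01, 0.0])
        model = fit_temperature_model(zip(T_STUDY, V))
        k = 3.0
        model_k = fit_temperature_model(zip(T_STUDY, k * V))
        pts, pts_k = list(zip(T_STUDY, V)), list(zip(T_STUDY, k * V))
        assert fit_quality(pts_k, model_k, "ard") == pytest.approx(
            fit_quality(pts, model, "ard"), rel=1e-9)
        assert fit_quality(pts_k, model_k, "residual_sd") == pytest.approx(
            k * fit_quality(pts, model, "residual_sd"), rel=1e-9)

    def test_three_point_residual_sd_flagged(self):
        model = fit_temperature_model([(288.15, 1.0), (298.15, 2.0), (308.15, 2.5)])
        assert np.isnan(fit_quality([(288.15, 1.0), (298.15, 2.0), (308.15, 2.5)],
                                    model, "residual_sd"))


class TestExpansibility:
    def test_equals_b_at_reference_temperature(self):
        # published l-threonine m_B = 0.100 row: E0(298.15) = b = 0.01177e-6
        V = 78.03e-6 + 0.01177e-6 * (T_STUDY - 298.15) + 0.00015e-6 * (T_STUDY - 298.15) ** 2
        model = fit_temperature_model(zip(T_STUDY, V))
        assert model.expansibility(298.15) == pytest.approx(0.01177e-6, rel=1e-9)

    def test_published_dipeptide_cell_within_print_rounding(self):
        # glycyl-l-threonine m_B = 0, signed c = -0.00056e-6
        b, c = 0.05113e-6, -0.00056e-6
        model = QuadraticTemperatureModel()
        model.a_, model.b_, model.c_, model.n_T_ = 108.78e-6, b, c, 4
        got = model.expansibility(318.15)
        assert got == pytest.approx(0.02873e-6, rel=1e-4)       # exact from coefficients
        assert got == pytest.approx(0.02869e-6, abs=2.1e-10)    # printed, 2-sf rounding of c

    def test_constant_when_c_zero(self):
        V = 100.0 + 0.1 * (T_STUDY - 298.15)
        model = fit_temperature_model(zip(T_STUDY, V))
        E = model.expansibility(T_STUDY)
        assert np.allclose(E, 0.1, rtol=1e-9)

    def test_derivative_consistency_with_finite_differences(self):
        V = 77.7e-6 + 0.009e-6 * (T_STUDY - 298.15) + 0.0002e-6 * (T_STUDY - 298.15) ** 2
        model = fit_temperature_model(zip(T_STUDY, V))
        h = 1e-3
        for T in [290.0, 300.0, 315.0]:
            num = (model.predict([T + h])[0] - model.predict([T - h])[0]) / (2 * h)
            assert model.expansibility(T) == pytest.approx(num, rel=1e-8)

    def test_slope_of_model_values_equals_2c(self):
        V = 100.0 + 0.1 * (T_STUDY - 298.15) - 0.002 * (T_STUDY - 298.15) ** 2
        model = fit_temperature_model(zip(T_STUDY, V))
        pts = [(T, float(model.expansibility(T))) for T in (290.0, 305.0, 311.0)]
        assert expansibility_slope_from_values(pts) == pytest.approx(model.dE0_dT_, rel=1e-8)

    def test_classification_invariant_to_reference_temperature(self):
        V = 100.0 + 0.1 * (T_STUDY - 298.15) - 0.002 * (T_STUDY - 298.15) ** 2
        signs = set()
        for T_ref in (273.15, 298.15, 310.0):
            model = QuadraticTemperatureModel(T_ref=T_ref).fit(T_STUDY, V)
            signs.add(hepler_classification(model.dE0_dT_))
        assert signs == {"structure_breaker"}


class TestExpansibilitySlopeFromValues:
    @pytest.mark.parametrize("values,expected", [
        ((0.00602, 0.00915, 0.01227, 0.01539), 0.00031),    # l-threonine, water
        ((0.06235, 0.05113, 0.03991, 0.02869), -0.00112),   # glycyl-l-threonine, water
    ])
    def test_published_rows(self, values, expected):
        slope = expansibility_slope_from_values(zip(T_STUDY, values))
        assert slope == pytest.approx(expected, abs=5e-6)

    def test_constant_values(self):
        slope = expansibility_slope_from_values([(288.15, 1.0), (318.15, 1.0)])
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            expansibility_slope_from_values([(298.15, 1.0)])


class TestHeplerClassification:
    @pytest.mark.parametrize("d,tol,expected", [
        (0.00031e-6, 0.0, "structure_maker"),
        (-0.00112e-6, 0.0, "structure_breaker"),
        (0.0, 0.0, "indeterminate"),
        (1e-12, 1e-9, "indeterminate"),
    ])
    def test_signs(self, d, tol, expected):
        assert hepler_classification(d, tol) == expected

    def test_rejects_negative_tolerance(self):
        with pytest.raises(ValueError):
            hepler_classification(1.0, tol=-1.0)


def test_published_derivative_column_reconstructs_from_expansibilities():
    """Every row's printed |dE0/dT| equals the OLS slope of its four printed
    E0 values to within half a unit in the fifth decimal."""
    table = datasets.load_expansibility()
    for _, row in table.iterrows():
        pts = [(T, row[f"E_{T}"]) for T in T_STUDY]
        slope = expansibility_slope_from_values(pts)
        assert abs(abs(slope) - row["dE_dT_abs"]) <= 5e-6 + 1e-12, (
            row["solute"], row["m_B"])
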