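"""Quadratic temperature dependence of the limiting volume; expansibility and
the Hepler structure-maker criterion.

The limiting volume over the studied temperature window is modelled as

    V0(T) = a + b*(T - T_ref) + c*(T - T_ref)^2

with T_ref = 298.15 K by default.  Its temperature derivative is the limiting
apparent molar expansibility

    E0(T) = dV0/dT = b + 2*c*(T - T_ref),

whose own (constant) temperature derivative 2c carries Hepler's criterion:
solutes with (d2 V0 / dT2)_p > 0 reinforce solvent structure
(structure-makers, kosmotropes); < 0 marks structure-breakers.

Coefficients are kept signed internally even though published tables often
print magnitudes; the sign of c is what classification rests on.
"""

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "QuadraticTemperatureModel",
    "fit_temperature_model",
    "fit_quality",
    "expansibility",
    "expansibility_slope_from_values",
    "hepler_classification",
]


class QuadraticTemperatureModel(BaseEstimator, RegressorMixin):
    """Least-squares quadratic V0(T) = a + b*(T-T_ref) + c*(T-T_ref)^2.

    Parameters
    ----------
    T_ref : float, default 298.15
        Reference temperature, K.  At T = T_ref the expansibility equals b,
        which is how published coefficient/expansibility table pairs pin the
        reference.

    Attributes
    ----------
    a_, b_, c_ : float
        Coefficients (m3 mol-1, m3 mol-1 K-1, m3 mol-1 K-2), signed.
    residual_sd_ : float
        sqrt(RSS / (n - 3)); NaN when n = 3 (no residual degrees of freedom).
    ard_ : float
        Mean absolute relative deviation of the fit (dimensionless).
    n_T_ : int
    """

    def __init__(self, T_ref=298.15):
        self.T_ref = T_ref

    def fit(self, X, y):
        T = np.asarray(X, dtype=float).reshape(-1)
        V = np.asarray(y, dtype=float).reshape(-1)
        if T.shape != V.shape:
            raise ValueError("X and y must have the same length")
        if T.size < 3:
            raise ValueError(f"need at least 3 temperatures, got {T.size}")
        if np.unique(T).size != T.size:
            raise ValueError("duplicate temperatures in input")
        t = T - self.T_ref
        A = np.column_stack([np.ones_like(t), t, t * t])
        beta, _, _, _ = np.linalg.lstsq(A, V, rcond=None)
        self.a_, self.b_, self.c_ = map(float, beta)
        resid = V - A @ beta
        n = T.size
        self.n_T_ = int(n)
        self.residual_sd_ = float(np.sqrt(resid @ resid / (n - 3))) if n > 3 else float("nan")
        self.ard_ = float(np.mean(np.abs(resid) / np.abs(V)))
        return self

    def predict(self, X):
        check_is_fitted(self, "a_")
        t = np.asarray(X, dtype=float).reshape(-1) - self.T_ref
        return self.a_ + self.b_ * t + self.c_ * t * t

    def expansibility(self, T):
        """E0(T) = b + 2c*(T - T_ref), m3 mol-1 K-1."""
        check_is_fitted(self, "a_")
        T = np.asarray(T, dtype=float)
        return self.b_ + 2.0 * self.c_ * (T - self.T_ref)

    @property
    def dE0_dT_(self):
        """Second temperature derivative of V0 (= 2c), m3 mol-1 K-2."""
        check_is_fitted(self, "a_")
        return 2.0 * self.c_


def fit_temperature_model(points, T_ref=298.15) -> QuadraticTemperatureModel:
    """Fit the quadratic model to ``points`` = iterable of (T, V0)."""
    pts = [tuple(p) for p in points]
    return QuadraticTemperatureModel(T_ref=T_ref).fit([p[0] for p in pts], [p[1] for p in pts])


def fit_quality(points, model: QuadraticTemperatureModel, metric="residual_sd"):
    """Fit-quality metric of a fitted temperature model on its points.

    ``metric``: 'residual_sd' -> sqrt(RSS/(n-3)) in the units of V0 (NaN and
    flagged when n = 3); 'ard' -> mean |V_exp - V_calc| / |V_exp|,
    dimensionless and scale-invariant.
    """
    pts = [tuple(p) for p in points]
    T = np.array([p[0] for p in pts], dtype=float)
    V = np.array([p[1] for p in pts], dtype=float)
    resid = V - model.predict(T)
    n = T.size
    if metric == "residual_sd":
        if n <= 3:
            return float("nan")  # no residual degrees of freedom
        return float(np.sqrt(resid @ resid / (n - 3)))
    if metric == "ard":
        return float(np.mean(np.abs(resid) / np.abs(V)))
    raise ValueError(f"unknown metric {metric!r}")


def expansibility(model: QuadraticTemperatureModel, T):
    """Limiting apparent molar expansibility of a fitted model at T, with its
    (constant) temperature derivative.  Returns ``(E0_phi, dE0_dT)``."""
    return model.expansibility(T), model.dE0_dT_


def expansibility_slope_from_values(points):
    """OLS slope of E0_phi against T from ``points`` = iterable of (T, E0_phi).

    This is the consistency route for validating a printed derivative column
    from its own expansibility columns; for model-generated values it equals
    2c exactly.
    """
    pts = [tuple(p) for p in points]
    if len(pts) < 2:
        raise ValueError(f"need at least 2 points, got {len(pts)}")
    T = np.array([p[0] for p in pts], dtype=float)
    E = np.array([p[1] for p in pts], dtype=float)
    A = np.column_stack([np.ones_like(T), T])
    beta, _, _, _ = np.linalg.lstsq(A, E, rcond=None)
    return float(beta[1])


def hepler_classification(dE0_dT, tol=0.0):
    """Hepler's criterion on the sign of (dE0/dT)_p = (d2 V0/dT2)_p.

    > tol -> 'structure_maker'; < -tol -> 'structure_breaker';
    within +/- tol -> 'indeterminate'.  ``tol`` (same units, >= 0) guards
    against classifying from noise; a propagated se of 2c is a sound choice.
    """
    if tol < 0:
        raise ValueError("tol must be non-negative")
    if dE0_dT > tol:
        return "structure_maker"
    if dE0_dT < -tol:
        return "structure_breaker"
    return "indeterminate"
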