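"""Infinite-dilution extrapolation of apparent molar properties.

Both the limiting volume and the limiting compression are obtained from the
same linear model in solute molality,

    Y(m_A) = Y0 + S * m_A,

fitted by ordinary least squares; the intercept is the limiting value
(solute-solvent interactions only) and the slope is the experimental slope
(solute-solute pairwise term).  A linear-in-m form (not the sqrt-m Masson
electrolyte form) is appropriate for zwitterionic non-electrolytes, and a
single slope per condition is what published tables in this field report.

Unweighted OLS is the default because per-point instrument uncertainties are
uniform by design; inverse-variance weighting is available via ``weighted``.
"""

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["LimitingPropertyRegression", "fit_limiting", "fit_all_groups"]


class LimitingPropertyRegression(BaseEstimator, RegressorMixin):
    """OLS extrapolation of an apparent property to infinite dilution.

    Parameters
    ----------
    weighted : bool, default False
        If True, use inverse-variance weights from ``sample_sigma`` passed to
        :meth:`fit`.

    Attributes
    ----------
    intercept_ : float
        Limiting value Y0 at m_A = 0.
    slope_ : float
        Experimental slope S.
    se_intercept_, se_slope_ : float
        Standard errors from the OLS covariance with n - 2 degrees of
        freedom (NaN when n < 3).  This is the classical residual-based
        error, the convention behind printed-table parentheticals; it assumes
        independent, equal-variance points.
    se_intercept_meas_, se_slope_meas_ : float
        Measurement-propagated (delta-method) standard errors, available when
        ``sample_sigma`` is given to :meth:`fit`.  These carry the known
        noise structure of apparent properties through the estimator: the
        per-point independent sigmas plus any error sources *shared* across
        the series (the solvent baseline of a dilution series, passed via
        ``shared_jacobians``).  They stay calibrated where the residual-based
        errors are not -- apparent-property noise grows as 1/m_A toward the
        dilute end and the common baseline error correlates the whole series.
    residual_sd_ : float
        sqrt(RSS / (n - 2)); NaN when n < 3.
    n_points_ : int
    """

    def __init__(self, weighted=False):
        self.weighted = weighted

    def fit(self, X, y, sample_sigma=None, shared_jacobians=None):
        m = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if m.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if m.size < 2:
            raise ValueError(f"need at least 2 points for a limiting fit, got {m.size}")
        if not np.all(np.isfinite(m)) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite values in limiting-fit input")
        if np.any(m <= 0):
            raise ValueError("all solute molalities must be positive")
        if np.unique(m).size < 2:
            raise ValueError("singular design: all m_A values identical")

        A = np.column_stack([np.ones_like(m), m])
        if self.weighted:
            if sample_sigma is None:
                raise ValueError("weighted fit requires sample_sigma")
            w = 1.0 / np.asarray(sample_sigma, dtype=float)
            Aw = A * w[:, None]
            # hat rows of the weighted estimator, applied to unweighted y
            H = np.linalg.solve(Aw.T @ Aw, Aw.T) * w
        else:
            H = np.linalg.solve(A.T @ A, A.T)
        beta = H @ y
        resid = y - A @ beta
        n = m.size
        self.intercept_, self.slope_ = float(beta[0]), float(beta[1])
        self.n_points_ = int(n)
        if n >= 3:
            if self.weighted:
                rw = resid * w
                s2 = float(rw @ rw) / (n - 2)
                cov = s2 * np.linalg.inv(Aw.T @ Aw)
                self.residual_sd_ = float(np.sqrt(resid @ resid / (n - 2)))
            else:
                s2 = float(resid @ resid) / (n - 2)
                cov = s2 * np.linalg.inv(A.T @ A)
                self.residual_sd_ = float(np.sqrt(s2))
            self.se_intercept_ = float(np.sqrt(cov[0, 0]))
            self.se_slope_ = float(np.sqrt(cov[1, 1]))
        else:
            self.residual_sd_ = self.se_intercept_ = self.se_slope_ = float("nan")
        if sample_sigma is not None:
            sig = np.asarray(sample_sigma, dtype=float).reshape(-1)
            var = H**2 @ sig**2
            for g in shared_jacobians or ():
                g = np.asarray(g, dtype=float).reshape(-1)
                var = var + (H @ g) ** 2
            self.se_intercept_meas_ = float(np.sqrt(var[0]))
            self.se_slope_meas_ = float(np.sqrt(var[1]))
        else:
            self.se_intercept_meas_ = self.se_slope_meas_ = float("nan")
        return self

    def predict(self, X):
        check_is_fitted(self, "intercept_")
        m = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ * m


def fit_limiting(points, weighted=False):
    """Fit Y(m_A) = Y0 + S*m_A to ``points`` = iterable of (m_A, value[, sigma]).

    Returns a fitted :class:`LimitingPropertyRegression`.
    """
    pts = [tuple(p) for p in points]
    m = [p[0] for p in pts]
    y = [p[1] for p in pts]
    sigma = [p[2] for p in pts] if pts and len(pts[0]) > 2 else None
    return LimitingPropertyRegression(weighted=weighted).fit(m, y, sample_sigma=sigma)


def fit_all_groups(records: pd.DataFrame, weighted=False):
    """Limiting fits for every (solute, m_B, T, property) group of an
    apparent-property table.

    Returns ``(fits, skipped)``: a long-format DataFrame with one row per
    successful fit (columns solute, m_B, T, property, intercept, slope,
    se_intercept, se_slope, residual_sd, n_points) and a DataFrame of groups
    that failed their preconditions with the reason -- failing groups are
    reported, never silently dropped.
    """
    if records is None or len(records) == 0:
        raise ValueError("empty apparent-property table")
    prop_cols = [("volume", "V_phi", "sigma_V_sol", ["gV_rho0"]),
                 ("compression", "K_phi_s", "sigma_K_sol", ["gK_rho0", "gK_u0"])]
    rows, skipped = [], []
    grouped = records.sort_values(["solute", "m_B", "T"], kind="mergesort").groupby(
        ["solute", "m_B", "T"], sort=True)
    for (solute, m_B, T), g in grouped:
        for prop, col, sigcol, sharedcols in prop_cols:
            if col not in g.columns:
                continue
            sub = g[np.isfinite(g[col])]
            if len(sub) == 0:
                continue
            sigma = shared = None
            if sigcol in sub.columns and np.isfinite(sub[sigcol]).all():
                sigma = sub[sigcol].to_numpy()
                shared = [sub[c].to_numpy() for c in sharedcols if c in sub.columns]
            try:
                est = LimitingPropertyRegression(weighted=weighted).fit(
                    sub["m_A"], sub[col], sample_sigma=sigma, shared_jacobians=shared)
            except ValueError as exc:
                skipped.append({"solute": solute, "m_B": m_B, "T": T,
                                "property": prop, "reason": str(exc)})
                continue
            rows.append({
                "solute": solute, "m_B": m_B, "T": T, "property": prop,
                "intercept": est.intercept_, "slope": est.slope_,
                "se_intercept": est.se_intercept_, "se_slope": est.se_slope_,
                "se_intercept_meas": est.se_intercept_meas_,
                "se_slope_meas": est.se_slope_meas_,
                "residual_sd": est.residual_sd_, "n_points": est.n_points_,
            })
    fits = pd.DataFrame(rows, columns=["solute", "m_B", "T", "property", "intercept",
                                       "slope", "se_intercept", "se_slope",
                                       "se_intercept_meas", "se_slope_meas",
                                       "residual_sd", "n_points"])
    skipped = pd.DataFrame(skipped, columns=["solute", "m_B", "T", "property", "reason"])
    return fits, skipped
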