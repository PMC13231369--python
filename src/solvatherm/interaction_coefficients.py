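"""McMillan-Mayer pair and triplet interaction coefficients.

In the Friedman-Krishnan treatment the transfer of a limiting property from
water to the mixed solvent expands in co-solvent molality with no constant
term (the transfer vanishes at m_B = 0 by construction):

    delta_Y0(m_B) = 2*Y_AB*m_B + 3*Y_ABB*m_B^2

where A is the solute (amino acid / peptide) and B the co-solvent.  Y_AB
captures two-body solute-cosolute interactions, Y_ABB three-body A-B-B
effects.  Both coefficients are fitted jointly by zero-intercept OLS on the
design columns {2*m_B, 3*m_B^2}.
"""

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["PairTripletRegression", "fit_pair_triplet", "fit_interaction_tables"]


class PairTripletRegression(BaseEstimator, RegressorMixin):
    """Zero-intercept OLS of transfer values on {2*m_B, 3*m_B^2}.

    Attributes
    ----------
    pair_ : float
        Two-body coefficient Y_AB (property units * mol-1 kg).
    triplet_ : float
        Three-body coefficient Y_ABB (property units * mol-2 kg2).
    se_pair_, se_triplet_ : float
        Standard errors with n - 2 degrees of freedom (NaN when n < 3).
    n_points_ : int
    """

    def fit(self, X, y):
        m = np.asarray(X, dtype=float).reshape(-1)
        d = np.asarray(y, dtype=float).reshape(-1)
        if m.shape != d.shape:
            raise ValueError("X and y must have the same length")
        if m.size < 2:
            raise ValueError(f"need at least 2 points, got {m.size}")
        if np.any(m <= 0):
            raise ValueError("co-solvent molalities must be positive")
        if np.unique(m).size < 2:
            raise ValueError("singular design: a single distinct m_B cannot separate "
                             "pair from triplet terms")
        A = np.column_stack([2.0 * m, 3.0 * m * m])
        beta, _, _, _ = np.linalg.lstsq(A, d, rcond=None)
        self.pair_, self.triplet_ = float(beta[0]), float(beta[1])
        resid = d - A @ beta
        n = m.size
        self.n_points_ = int(n)
        if n >= 3:
            s2 = float(resid @ resid) / (n - 2)
            cov = s2 * np.linalg.inv(A.T @ A)
            self.se_pair_ = float(np.sqrt(cov[0, 0]))
            self.se_triplet_ = float(np.sqrt(cov[1, 1]))
        else:
            self.se_pair_ = self.se_triplet_ = float("nan")
        return self

    def predict(self, X):
        check_is_fitted(self, "pair_")
        m = np.asarray(X, dtype=float).reshape(-1)
        return 2.0 * self.pair_ * m + 3.0 * self.triplet_ * m * m


def fit_pair_triplet(points) -> PairTripletRegression:
    """Fit pair/triplet coefficients to ``points`` = iterable of (m_B, delta)."""
    pts = [tuple(p) for p in points]
    return PairTripletRegression().fit([p[0] for p in pts], [p[1] for p in pts])


def fit_interaction_tables(transfers: pd.DataFrame):
    """One pair/triplet fit per (solute, T, property) group of a transfer table.

    Returns ``(fits, skipped)``: a DataFrame with columns (solute, T,
    property, pair, triplet, se_pair, se_triplet, n_points) and a report of
    groups that failed their preconditions.
    """
    if transfers is None or len(transfers) == 0:
        raise ValueError("empty transfer table")
    rows, skipped = [], []
    grouped = transfers.sort_values(["solute", "property", "T", "m_B"],
                                    kind="mergesort").groupby(
        ["solute", "T", "property"], sort=True)
    for (solute, T, prop), g in grouped:
        sub = g[np.isfinite(g["delta"])]
        try:
            est = PairTripletRegression().fit(sub["m_B"], sub["delta"])
        except ValueError as exc:
            skipped.append({"solute": solute, "T": T, "property": prop, "reason": str(exc)})
            continue
        rows.append({"solute": solute, "T": T, "property": prop,
                     "pair": est.pair_, "triplet": est.triplet_,
                     "se_pair": est.se_pair_, "se_triplet": est.se_triplet_,
                     "n_points": est.n_points_})
    fits = pd.DataFrame(rows, columns=["solute", "T", "property", "pair", "triplet",
                                       "se_pair", "se_triplet", "n_points"])
    skipped = pd.DataFrame(skipped, columns=["solute", "T", "property", "reason"])
    return fits, skipped
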