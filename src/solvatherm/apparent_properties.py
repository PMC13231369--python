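"""Per-measurement apparent molar properties with first-order uncertainty.

The apparent molar volume of a solute at molality ``m`` (mol per kg of
*solvent*, where the solvent is the whole water + co-solvent mixture) is

    V_phi = M/rho - (rho - rho0) / (m * rho * rho0)

algebraically identical to the total-volume definition
``((1 + m*M)/rho - 1/rho0) / m``: the volume of solution containing 1 kg of
solvent minus the solvent volume, per mole of solute.

The isentropic compressibility comes from the Newton-Laplace relation

    K_s = 1 / (u^2 * rho)

and the apparent molar isentropic compressibility from

    K_phi_s = M*K_s/rho + (K_s*rho0 - K_s0*rho) / (m * rho * rho0)

equivalent to ``((1 + m*M)*K_s/rho - K_s0/rho0) / m``.  Negative values are
physical and common for zwitterionic solutes (hydration shells less
compressible than bulk solvent).

Uncertainties are propagated by the delta method treating rho, rho0, u, u0
as independent (the densimeter reports no covariance between density and
sound speed).
"""

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "apparent_molar_volume",
    "isentropic_compressibility",
    "apparent_molar_compressibility",
    "propagate_uncertainty",
    "uncertainty_components",
    "ApparentPropertiesTransformer",
    "compute_apparent_table",
]


def _require_positive(**kwargs):
    for name, value in kwargs.items():
        if not np.all(np.asarray(value) > 0):
            raise ValueError(f"{name} must be positive, got {value}")


def apparent_molar_volume(m_A, rho, rho0, M):
    """Apparent molar volume (m3 mol-1) from solution and solvent densities.

    Parameters
    ----------
    m_A : float or array
        Solute molality, mol kg-1; must be > 0 (the property is undefined at
        infinite dilution -- extrapolate instead).
    rho, rho0 : float or array
        Solution and solvent density, kg m-3.
    M : float
        Solute molar mass, kg mol-1.
    """
    m_A = np.asarray(m_A, dtype=float)
    if np.any(m_A <= 0):
        raise ValueError(
            "apparent molar volume is undefined at m_A = 0 (infinite dilution); "
            "use the limiting-value extrapolation instead"
        )
    _require_positive(rho=rho, rho0=rho0, M=M)
    rho = np.asarray(rho, dtype=float)
    rho0 = np.asarray(rho0, dtype=float)
    return M / rho - (rho - rho0) / (m_A * rho * rho0)


def isentropic_compressibility(u, rho):
    """Newton-Laplace isentropic compressibility K_s = 1/(u^2 rho), Pa-1."""
    _require_positive(u=u, rho=rho)
    u = np.asarray(u, dtype=float)
    rho = np.asarray(rho, dtype=float)
    return 1.0 / (u * u * rho)


def apparent_molar_compressibility(m_A, rho, rho0, Ks, Ks0, M):
    """Apparent molar isentropic compressibility (m3 mol-1 Pa-1).

    ``Ks``/``Ks0`` are the solution/solvent isentropic compressibilities in
    Pa-1.  Negative return values are expected for these solutes.
    """
    m_A = np.asarray(m_A, dtype=float)
    if np.any(m_A <= 0):
        raise ValueError("apparent molar compressibility is undefined at m_A = 0")
    _require_positive(rho=rho, rho0=rho0, Ks=Ks, Ks0=Ks0, M=M)
    rho = np.asarray(rho, dtype=float)
    rho0 = np.asarray(rho0, dtype=float)
    Ks = np.asarray(Ks, dtype=float)
    Ks0 = np.asarray(Ks0, dtype=float)
    return M * Ks / rho + (Ks * rho0 - Ks0 * rho) / (m_A * rho * rho0)


def propagate_uncertainty(m_A, rho, rho0, u, u0, M, sigma_rho, sigma_rho0=None,
                          sigma_u=None, sigma_u0=None):
    """Delta-method standard deviations of V_phi and K_phi_s.

    Treats (rho, rho0, u, u0) as independent.  ``sigma_rho0``/``sigma_u0``
    default to ``sigma_rho``/``sigma_u`` (same instrument measures baseline
    and solution).  Returns ``(sigma_V_phi, sigma_K_phi_s)``.
    """
    m_A = np.asarray(m_A, dtype=float)
    rho = np.asarray(rho, dtype=float)
    rho0 = np.asarray(rho0, dtype=float)
    u = np.asarray(u, dtype=float)
    u0 = np.asarray(u0, dtype=float)
    sigma_rho = np.asarray(sigma_rho, dtype=float)
    sigma_rho0 = sigma_rho if sigma_rho0 is None else np.asarray(sigma_rho0, dtype=float)
    if sigma_u is None:
        raise ValueError("sigma_u is required")
    sigma_u = np.asarray(sigma_u, dtype=float)
    sigma_u0 = sigma_u if sigma_u0 is None else np.asarray(sigma_u0, dtype=float)
    for name, s in [("sigma_rho", sigma_rho), ("sigma_rho0", sigma_rho0),
                    ("sigma_u", sigma_u), ("sigma_u0", sigma_u0)]:
        if np.any(s < 0):
            raise ValueError(f"{name} must be non-negative")

    one_p = 1.0 + m_A * M
    # V_phi = (one_p/rho - 1/rho0)/m_A
    dV_drho = -one_p / (m_A * rho**2)
    dV_drho0 = 1.0 / (m_A * rho0**2)
    var_V = (dV_drho * sigma_rho) ** 2 + (dV_drho0 * sigma_rho0) ** 2

    # K_phi_s = (one_p/(u^2 rho^2) - 1/(u0^2 rho0^2)) / m_A
    dK_du = -2.0 * one_p / (m_A * u**3 * rho**2)
    dK_drho = -2.0 * one_p / (m_A * u**2 * rho**3)
    dK_du0 = 2.0 / (m_A * u0**3 * rho0**2)
    dK_drho0 = 2.0 / (m_A * u0**2 * rho0**3)
    var_K = ((dK_du * sigma_u) ** 2 + (dK_drho * sigma_rho) ** 2
             + (dK_du0 * sigma_u0) ** 2 + (dK_drho0 * sigma_rho0) ** 2)
    return np.sqrt(var_V), np.sqrt(var_K)


def uncertainty_components(m_A, rho, rho0, u, u0, M, sigma_rho, sigma_rho0=None,
                           sigma_u=None, sigma_u0=None):
    """Split the delta-method uncertainty into independent and shared parts.

    Within a dilution series all points share one measured baseline
    (rho0, u0), so the baseline contributions are *common-mode* errors:
    downstream fits need them separately from the per-point (solution
    rho, u) parts to report calibrated standard errors.

    Returns a dict with per-point independent sigmas (``sigma_V_sol``,
    ``sigma_K_sol``) and signed shared jacobian-times-sigma terms
    (``gV_rho0``, ``gK_rho0``, ``gK_u0``).
    """
    m_A = np.asarray(m_A, dtype=float)
    rho = np.asarray(rho, dtype=float)
    rho0 = np.asarray(rho0, dtype=float)
    u = np.asarray(u, dtype=float)
    u0 = np.asarray(u0, dtype=float)
    sigma_rho0 = sigma_rho if sigma_rho0 is None else sigma_rho0
    sigma_u0 = sigma_u if sigma_u0 is None else sigma_u0
    one_p = 1.0 + m_A * M
    return {
        "sigma_V_sol": np.abs(-one_p / (m_A * rho**2)) * sigma_rho,
        "gV_rho0": (1.0 / (m_A * rho0**2)) * sigma_rho0,
        "sigma_K_sol": np.sqrt(
            (2.0 * one_p / (m_A * u**3 * rho**2) * sigma_u) ** 2
            + (2.0 * one_p / (m_A * u**2 * rho**3) * sigma_rho) ** 2),
        "gK_rho0": (2.0 / (m_A * u0**2 * rho0**3)) * sigma_rho0,
        "gK_u0": (2.0 / (m_A * u0**3 * rho0**2)) * sigma_u0,
    }


class ApparentPropertiesTransformer(BaseEstimator, TransformerMixin):
    """Stateless transformer: measurement table -> apparent-property records.

    ``transform`` consumes a validated measurement table (see
    :func:`solvatherm.io_tables.read_measurements`) and returns one record per
    solute row with ``V_phi``, ``Ks``, ``Ks0``, ``K_phi_s`` and propagated
    uncertainties, keyed by ``(solute, m_B, T, m_A)``.  Rows lacking a sound
    speed yield a volume-only record (``K_phi_s`` = NaN).

    Parameters
    ----------
    solutes : mapping name -> SoluteSpec, optional
        Defaults to the built-in registry.
    """

    def __init__(self, solutes=None):
        self.solutes = solutes

    def fit(self, X, y=None):  # stateless; kept for pipeline compatibility
        self.n_features_in_ = X.shape[1] if hasattr(X, "shape") else None
        return self

    def transform(self, X):
        return compute_apparent_table(X, solutes=self.solutes)


def compute_apparent_table(measurements: pd.DataFrame, solutes=None) -> pd.DataFrame:
    """Compute V_phi and K_phi_s for every solute row of a measurement table.

    The baseline (rho0, u0) for each row is the m_A = 0 row of its
    (m_B, T) group -- the mixed water + co-solvent reference solvent --
    never an interpolation or a water correlation.
    """
    from .solutes import solute_registry

    registry = solutes if solutes is not None else solute_registry()
    df = measurements.copy()
    have_u = "u" in df.columns and df["u"].notna().any()

    base = df[df["m_A"] == 0]
    if base.empty:
        raise ValueError("measurement table contains no baseline (m_A = 0) rows")
    base_idx = base.set_index(["m_B", "T"])

    records = []
    for _, row in df[df["m_A"] > 0].iterrows():
        key = (row["m_B"], row["T"])
        try:
            b = base_idx.loc[key]
        except KeyError:
            raise ValueError(
                f"missing baseline row (m_A = 0) for group m_B={key[0]}, T={key[1]}"
            ) from None
        if isinstance(b, pd.DataFrame):
            b = b.iloc[0]
        name = row["solute"]
        try:
            M = registry[name].molar_mass
        except KeyError:
            raise ValueError(f"unknown solute {name!r}: not in the solute registry") from None
        rho0, u0 = b["rho"], b.get("u", np.nan)
        V_phi = apparent_molar_volume(row["m_A"], row["rho"], rho0, M)
        rec = {
            "solute": name, "m_B": row["m_B"], "T": row["T"], "m_A": row["m_A"],
            "V_phi": V_phi, "Ks": np.nan, "Ks0": np.nan, "K_phi_s": np.nan,
            "sigma_V_phi": np.nan, "sigma_K_phi_s": np.nan,
            "sigma_V_sol": np.nan, "gV_rho0": np.nan,
            "sigma_K_sol": np.nan, "gK_rho0": np.nan, "gK_u0": np.nan,
        }
        row_u = row.get("u", np.nan)
        sigma_rho = row.get("sigma_rho", 0.05)
        sigma_u = row.get("sigma_u", 0.4)
        if have_u and np.isfinite(row_u) and np.isfinite(u0):
            Ks = isentropic_compressibility(row_u, row["rho"])
            Ks0 = isentropic_compressibility(u0, rho0)
            rec["Ks"] = Ks
            rec["Ks0"] = Ks0
            rec["K_phi_s"] = apparent_molar_compressibility(
                row["m_A"], row["rho"], rho0, Ks, Ks0, M)
            sV, sK = propagate_uncertainty(
                row["m_A"], row["rho"], rho0, row_u, u0, M,
                sigma_rho=sigma_rho, sigma_u=sigma_u)
            rec["sigma_V_phi"], rec["sigma_K_phi_s"] = sV, sK
            rec.update(uncertainty_components(
                row["m_A"], row["rho"], rho0, row_u, u0, M,
                sigma_rho=sigma_rho, sigma_u=sigma_u))
        else:
            sV, _ = propagate_uncertainty(
                row["m_A"], row["rho"], rho0, 1500.0, 1500.0, M,
                sigma_rho=sigma_rho, sigma_u=0.0)
            rec["sigma_V_phi"] = sV
            comp = uncertainty_components(
                row["m_A"], row["rho"], rho0, 1500.0, 1500.0, M,
                sigma_rho=sigma_rho, sigma_u=0.0)
            rec["sigma_V_sol"] = comp["sigma_V_sol"]
            rec["gV_rho0"] = comp["gV_rho0"]
        records.append(rec)
    out = pd.DataFrame.from_records(records)
    return out.sort_values(["solute", "m_B", "T", "m_A"], kind="mergesort").reset_index(drop=True)
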