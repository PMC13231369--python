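"""Bundled reference tables for the l-threonine / glycyl-l-threonine /
aqueous [OMIm][Br] system.

These are published derived-property tables (reporting-scale values) for the
ternary systems the package was built around: quadratic temperature-model
coefficients, limiting apparent molar expansibilities, limiting isentropic
compressions with experimental slopes, transfer compressions, and
pair/triplet interaction coefficients.  They serve as inputs for
internal-consistency validation and as realistic defaults for the synthetic
generator; they are not outputs of this package.

All loaders return pandas DataFrames with values on the conventional
reporting scales (columns suffixed ``_e6``: units of 1e-6 m3-based scales;
see :mod:`solvatherm.units`).
"""

from importlib import resources

import pandas as pd

__all__ = [
    "load_temperature_coefficients",
    "load_expansibility",
    "load_limiting_compression",
    "load_transfer_compression",
    "load_interaction_coefficients",
]

_STUDY_TEMPERATURES = (288.15, 298.15, 308.15, 318.15)


def _read(name: str) -> pd.DataFrame:
    with resources.files("solvatherm.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_temperature_coefficients(signed=True) -> pd.DataFrame:
    """Quadratic V0(T) coefficients per (solute, m_B), T_ref = 298.15 K.

    The published table prints |c|; the bundled copy carries a sign column
    inferred from the expansibility trend (E0 decreasing with T requires
    c < 0).  With ``signed=True`` a ``c_e6`` column with the true sign is
    added alongside the printed magnitude ``c_abs_e6``.
    """
    df = _read("omim_br_temperature_coefficients.csv")
    if signed:
        df["c_e6"] = df["c_abs_e6"] * df["c_sign"]
    return df


def load_expansibility(long=False) -> pd.DataFrame:
    """Limiting apparent molar expansibility E0_phi (1e-6 m3 mol-1 K-1) at the
    four study temperatures, plus the printed |dE0/dT| column.

    ``long=True`` melts the temperature columns into (solute, m_B, T, E0_phi_e6).
    """
    df = _read("omim_br_expansibility.csv")
    if not long:
        return df
    value_cols = [f"E_{T}" for T in _STUDY_TEMPERATURES]
    out = df.melt(id_vars=["solute", "m_B"], value_vars=value_cols,
                  var_name="T", value_name="E0_phi_e6")
    out["T"] = out["T"].str.removeprefix("E_").astype(float)
    return out.sort_values(["solute", "m_B", "T"], kind="mergesort").reset_index(drop=True)


def load_limiting_compression() -> pd.DataFrame:
    """Limiting compression K0_phi_s and experimental slope S_k with standard
    errors, per (solute, m_B, T); units 1e-6 m3 mol-1 GPa-1 (per mol kg-1 for
    the slope)."""
    return _read("omim_br_limiting_compression.csv")


def load_transfer_compression() -> pd.DataFrame:
    """Transfer compression dK0_phi_s per (solute, m_B > 0, T), same scale."""
    return _read("omim_br_transfer_compression.csv")


def load_interaction_coefficients() -> pd.DataFrame:
    """Pair/triplet interaction coefficients per (solute, T) as published.

    Note: the compression columns (K_AB, K_ABB) are internally inconsistent
    with the transfer table under the zero-intercept quadratic model --
    refitting the published transfers reproduces them divided by exactly 10
    and 100, i.e. they were evidently fitted with m_B rescaled by 0.1.  Kept
    verbatim for documentation; not used as a reference for validation.
    """
    return _read("omim_br_interaction_coefficients.csv")
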