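"""Reading, validating and writing measurement and result tables.

Raw input is a long-format CSV of (solute, m_B, m_A, T, p, rho, u) rows;
rows with m_A = 0 carry the solvent baseline (rho0, u0) of their (m_B, T)
group.  A TOML config can remap column names and declare input units; values
are converted to strict SI internally (kg m-3, mol kg-1, MPa for the
recorded pressure).  Conversion to reporting scales happens only on output.
"""

import hashlib
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import units

__all__ = ["read_measurements", "write_results", "load_schema", "DEFAULT_SIGMA_RHO",
           "DEFAULT_SIGMA_U"]

# half the instrument's expanded uncertainties (coverage factor 2)
DEFAULT_SIGMA_RHO = 0.05  # kg m-3
DEFAULT_SIGMA_U = 0.4     # m s-1

_CANONICAL = ["solute", "m_B", "m_A", "T", "p", "rho", "u", "sigma_rho", "sigma_u"]
_REQUIRED = ["m_B", "m_A", "T", "rho"]

_UNIT_TABLES = {
    "rho": units.DENSITY_FACTORS,
    "u": units.SPEED_FACTORS,
    "m_A": units.MOLALITY_FACTORS,
    "m_B": units.MOLALITY_FACTORS,
    "p": units.PRESSURE_FACTORS,
}


def load_schema(path):
    """Load a column-map/units schema from a TOML file.

    Expected sections: ``[columns]`` mapping internal names (solute, m_B,
    m_A, T, p, rho, u, sigma_rho, sigma_u) to file column names, and
    ``[units]`` mapping internal names to declared units.
    """
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    return {"columns": cfg.get("columns", {}), "units": cfg.get("units", {})}


def read_measurements(path, schema=None) -> pd.DataFrame:
    """Read and validate a measurement table; return it in internal SI units.

    ``schema`` is an optional dict with ``columns`` (internal -> file column
    name) and ``units`` (internal -> declared unit, e.g. rho = "g/cm^3").

    Raises on: missing file, unresolvable columns, non-numeric cells (with
    the offending row index), duplicate (solute, m_B, m_A, T) keys, and any
    (m_B, T) group with solute rows but no m_A = 0 baseline (named in the
    error).  Validation is order-independent: the returned table is in
    canonical sort order regardless of input row order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = schema or {}
    colmap = schema.get("columns", {})
    unit_decl = schema.get("units", {})

    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    rename = {v: k for k, v in colmap.items()}
    raw = raw.rename(columns=rename)
    missing = [c for c in _REQUIRED if c not in raw.columns]
    if missing:
        raise ValueError(f"cannot resolve required columns {missing} in {path.name}; "
                         f"found {list(raw.columns)}")

    df = pd.DataFrame()
    df["solute"] = (raw["solute"].fillna("none").replace("", "none")
                    if "solute" in raw.columns else "none")
    for col in ["m_B", "m_A", "T", "p", "rho", "u", "sigma_rho", "sigma_u"]:
        if col not in raw.columns:
            continue
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"non-numeric value {raw[col].iloc[idx]!r} in column "
                             f"{col!r} at row {idx}")
        df[col] = parsed
    for col, default in [("p", 0.1), ("u", np.nan),
                         ("sigma_rho", DEFAULT_SIGMA_RHO), ("sigma_u", DEFAULT_SIGMA_U)]:
        if col not in df.columns:
            df[col] = default
        else:
            df[col] = df[col].fillna(default) if col.startswith("sigma") else df[col]

    # declared-unit conversion to SI
    for col, table in _UNIT_TABLES.items():
        unit = unit_decl.get(col)
        if unit is not None:
            try:
                df[col] = df[col] * table[unit]
            except KeyError:
                raise ValueError(f"unknown unit {unit!r} declared for column {col!r}") from None

    if (df["rho"] <= 0).any():
        raise ValueError("densities must be positive")
    finite_u = df["u"].dropna()
    if (finite_u <= 0).any():
        raise ValueError("sound speeds must be positive")
    if (df["m_A"] < 0).any() or (df["m_B"] < 0).any():
        raise ValueError("molalities must be non-negative")
    if (df["T"] <= 0).any():
        raise ValueError("temperatures must be positive (kelvin)")

    df.loc[df["m_A"] == 0, "solute"] = "none"
    dup = df.duplicated(subset=["solute", "m_B", "m_A", "T"], keep=False)
    if dup.any():
        key = df.loc[dup, ["solute", "m_B", "m_A", "T"]].iloc[0].tolist()
        raise ValueError(f"duplicate measurement key (solute, m_B, m_A, T) = {tuple(key)}")

    for (m_B, T), g in df.groupby(["m_B", "T"]):
        if (g["m_A"] > 0).any() and not (g["m_A"] == 0).any():
            raise ValueError(f"missing baseline row (m_A = 0) for group "
                             f"(m_B={m_B}, T={T})")

    df["is_baseline"] = df["m_A"] == 0
    df = df[_CANONICAL + ["is_baseline"]]
    return df.sort_values(["m_B", "T", "solute", "m_A"],
                          kind="mergesort").reset_index(drop=True)


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def write_results(table: pd.DataFrame, path, float_format=None, manifest=None):
    """Write a result table as CSV with stable column order and deterministic
    formatting; optionally write a JSON run manifest alongside.

    ``float_format`` e.g. ``"%.4f"`` for report tables on printed scales;
    default keeps full precision so measurement tables round-trip.
    ``manifest`` is a JSON-serializable dict (inputs, config hash, seed ...);
    it is written to ``<path>.manifest.json`` augmented with the output's
    content hash.
    """
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty table")
    path = Path(path)
    csv = table.to_csv(index=False, float_format=float_format,
                       lineterminator="\n")
    try:
        path.write_text(csv, encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc
    if manifest is not None:
        meta = dict(manifest)
        meta["output"] = path.name
        meta["sha256"] = _sha256(csv.encode())
        Path(str(path) + ".manifest.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def config_hash(config: dict) -> str:
    """Stable hash of a JSON-serializable run configuration."""
    return _sha256(json.dumps(config, sort_keys=True, default=str).encode())
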