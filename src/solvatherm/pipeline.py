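"""Pipeline orchestration and printed-table consistency checks.

``analyze`` runs the full derived-property cascade on a validated
measurement table: apparent properties -> limiting fits -> temperature
models / expansibility / structure-maker classification -> transfer
functions -> pair/triplet interaction coefficients, collecting skipped
groups along the way and optionally writing all result tables, a Markdown
report and a run manifest.

``validate_consistency`` re-derives one printed table from another
(expansibility from temperature-model coefficients; transfers from limiting
compressions) with tolerances propagated from the printed precision:
half a unit in the last printed decimal carried through the arithmetic.
"""

import numpy as np
import pandas as pd

from . import units
from .apparent_properties import compute_apparent_table
from .limiting_fits import fit_all_groups
from .transfer_functions import transfer_all
from .temperature_model import (QuadraticTemperatureModel, hepler_classification,
                                expansibility_slope_from_values)
from .interaction_coefficients import fit_interaction_tables
from .io_tables import write_results, config_hash

__all__ = ["analyze", "validate_consistency", "render_report"]


def _temperature_stage(fits: pd.DataFrame, T_ref: float):
    """Fit V0(T) per (solute, m_B) and evaluate expansibility at each study T."""
    vol = fits[fits["property"] == "volume"]
    models, exp_rows, skipped = [], [], []
    for (solute, m_B), g in vol.groupby(["solute", "m_B"], sort=True):
        pts = g.sort_values("T")
        if len(pts) < 3 or pts["T"].duplicated().any():
            skipped.append({"solute": solute, "m_B": m_B,
                            "reason": f"needs >=3 distinct temperatures, got {len(pts)}"})
            continue
        model = QuadraticTemperatureModel(T_ref=T_ref).fit(pts["T"], pts["intercept"])
        models.append({"solute": solute, "m_B": m_B, "a": model.a_, "b": model.b_,
                       "c": model.c_, "T_ref": T_ref, "residual_sd": model.residual_sd_,
                       "ard": model.ard_, "n_T": model.n_T_})
        dE = model.dE0_dT_
        for T in pts["T"]:
            exp_rows.append({
                "solute": solute, "m_B": m_B, "T": T,
                "E0_phi": float(model.expansibility(T)), "dE0_dT": dE,
                "classification": hepler_classification(dE),
            })
    return (pd.DataFrame(models), pd.DataFrame(exp_rows),
            pd.DataFrame(skipped, columns=["solute", "m_B", "reason"]))


def analyze(measurements: pd.DataFrame, outdir=None, T_ref=298.15, weighted=False,
            solutes=None, seed=None, config=None):
    """Run the full analysis; return a dict of result tables.

    Keys: ``apparent``, ``limiting``, ``transfer``, ``temp_models``,
    ``expansibility``, ``interactions``, ``skipped`` (per-stage skip reports).
    If ``outdir`` is given, the tables, a Markdown report and a manifest are
    written there.  Tables missing a sound-speed column degrade gracefully to
    a volume-only run (logged in the report).
    """
    apparent = compute_apparent_table(measurements, solutes=solutes)
    volume_only = not np.isfinite(apparent["K_phi_s"]).any()
    fits, skipped_fits = fit_all_groups(apparent, weighted=weighted)
    temp_models, expans, skipped_temp = _temperature_stage(fits, T_ref)

    has_water_ref = (fits["m_B"] == 0).any()
    if has_water_ref:
        transfers = transfer_all(fits)
        interactions, skipped_inter = fit_interaction_tables(transfers)
    else:
        transfers = pd.DataFrame(columns=["solute", "m_B", "T", "property",
                                          "delta", "se_delta"])
        interactions = pd.DataFrame(columns=["solute", "T", "property", "pair",
                                             "triplet", "se_pair", "se_triplet",
                                             "n_points"])
        skipped_inter = pd.DataFrame(
            [{"solute": "*", "T": np.nan, "property": "*",
              "reason": "no m_B = 0 water reference in input"}])

    results = {
        "apparent": apparent, "limiting": fits, "transfer": transfers,
        "temp_models": temp_models, "expansibility": expans,
        "interactions": interactions,
        "skipped": {"limiting": skipped_fits, "temperature": skipped_temp,
                    "interactions": skipped_inter},
        "volume_only": volume_only,
    }
    if outdir is not None:
        _write_bundle(results, outdir, seed=seed, config=config)
    return results


def _scaled(df: pd.DataFrame, colscale: dict) -> pd.DataFrame:
    out = df.copy()
    for col, scale in colscale.items():
        if col in out.columns:
            out[col] = out[col] * scale
    return out


def report_scale_tables(results) -> dict:
    """Result tables converted from SI to the conventional reporting scales."""
    V, K, E = units.VOLUME_SCALE, units.COMPRESSION_SCALE, units.EXPANSIBILITY_SCALE
    lim = results["limiting"].copy()
    vol = lim["property"] == "volume"
    for col in ["intercept", "slope", "se_intercept", "se_slope",
                "se_intercept_meas", "se_slope_meas", "residual_sd"]:
        lim[col] = np.where(vol, lim[col] * V, lim[col] * K)
    tr = results["transfer"].copy()
    volt = tr["property"] == "volume"
    for col in ["delta", "se_delta"]:
        tr[col] = np.where(volt, tr[col] * V, tr[col] * K)
    inter = results["interactions"].copy()
    voli = inter["property"] == "volume"
    for col in ["pair", "triplet", "se_pair", "se_triplet"]:
        inter[col] = np.where(voli, inter[col] * V, inter[col] * K)
    return {
        "limiting": lim,
        "transfer": tr,
        "interactions": inter,
        "temp_models": _scaled(results["temp_models"],
                               {"a": V, "b": V, "c": V, "residual_sd": V}),
        "expansibility": _scaled(results["expansibility"],
                                 {"E0_phi": E, "dE0_dT": E}),
        "apparent": _scaled(results["apparent"],
                            {"V_phi": V, "sigma_V_phi": V,
                             "K_phi_s": K, "sigma_K_phi_s": K}),
    }


def _write_bundle(results, outdir, seed=None, config=None):
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scaled = report_scale_tables(results)
    manifest = {"seed": seed, "config_hash": config_hash(config or {}),
                "volume_only": bool(results["volume_only"])}
    for name, fmt in [("apparent", "%.6f"), ("limiting", "%.6f"), ("transfer", "%.6f"),
                      ("temp_models", "%.6f"), ("expansibility", "%.6f"),
                      ("interactions", "%.6f")]:
        table = scaled[name]
        if len(table):
            write_results(table, outdir / f"{name}.csv", float_format=fmt,
                          manifest=manifest)
    for stage, table in results["skipped"].items():
        if len(table):
            write_results(table, outdir / f"skipped_{stage}.csv")
    (outdir / "report.md").write_text(render_report(results), encoding="utf-8")


def render_report(results) -> str:
    """Human-readable Markdown summary of an analysis run."""
    lines = ["# Volumetric / acoustic analysis report", ""]
    if results["volume_only"]:
        lines += ["NOTE: no sound-speed data found; volume-only run "
                  "(compressibility stages skipped).", ""]
    lim = results["limiting"]
    lines += [f"Limiting fits: {len(lim)} "
              f"({(lim['property'] == 'volume').sum()} volume, "
              f"{(lim['property'] == 'compression').sum()} compression)"]
    exact = (len(lim) and np.nanmax(np.abs(lim["residual_sd"].to_numpy()))
             <= 1e-9 * np.nanmax(np.abs(lim["intercept"].to_numpy())))
    if exact:
        lines.append("All limiting fits are exact (zero residuals): "
                     "noiseless input recovered exactly.")
    lines.append(f"Transfer values: {len(results['transfer'])}")
    ex = results["expansibility"]
    if len(ex):
        counts = ex.drop_duplicates(["solute", "m_B"])["classification"].value_counts()
        lines.append("Hepler classification (per solute, m_B): "
                     + ", ".join(f"{k}: {v}" for k, v in counts.items()))
    lines.append(f"Interaction fits: {len(results['interactions'])}")
    for stage, table in results["skipped"].items():
        if len(table):
            lines.append(f"Skipped in {stage} stage: {len(table)} group(s) -- "
                         "see skipped tables.")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# printed-table consistency checks

def _infer_c_sign(E_values):
    """Sign of c from the trend of printed expansibilities (E0 increases with
    T iff c > 0)."""
    return 1.0 if E_values[-1] >= E_values[0] else -1.0


def validate_consistency(temperature_coefficients=None, expansibility=None,
                         limiting_compression=None, transfer_compression=None,
                         T_ref=298.15) -> pd.DataFrame:
    """Cross-validate printed derived tables; returns per-row verdicts.

    Supported pairs (any may be omitted):

    * coefficients -> expansibility: E0(T) = b + 2c(T - T_ref) from the
      printed (b, |c|) with the sign of c inferred from the E-column trend;
      tolerance 0.5 ulp(b) + 2|T - T_ref| * 0.5 ulp(c).  The printed
      derivative column is also rechecked as the OLS slope of the printed
      E columns (tolerance: one unit in its last printed decimal).
    * limiting -> transfer compression: delta = K0(m_B) - K0(0), tolerance
      2e-4 (two 4-decimal roundings).

    Columns: check, solute, m_B, T, computed, printed, tol, passed.
    """
    rows = []
    if temperature_coefficients is not None and expansibility is not None:
        tc = temperature_coefficients.set_index(["solute", "m_B"])
        Ts = [float(c.removeprefix("E_")) for c in expansibility.columns
              if c.startswith("E_")]
        for _, row in expansibility.iterrows():
            key = (row["solute"], row["m_B"])
            coeff = tc.loc[key]
            E_printed = [row[f"E_{T}"] for T in Ts]
            c_abs = coeff.get("c_abs_e6", np.nan)
            if not np.isfinite(c_abs):
                c_abs = abs(coeff["c_e6"])
            c = c_abs * _infer_c_sign(E_printed)
            for T, printed in zip(Ts, E_printed):
                computed = coeff["b_e6"] + 2.0 * c * (T - T_ref)
                tol = 0.5e-5 + 2.0 * abs(T - T_ref) * 0.5e-5
                rows.append({"check": "expansibility_from_coefficients",
                             "solute": key[0], "m_B": key[1], "T": T,
                             "computed": computed, "printed": printed, "tol": tol,
                             "passed": abs(computed - printed) <= tol + 1e-12})
            slope = expansibility_slope_from_values(list(zip(Ts, E_printed)))
            printed_d = row["dE_dT_abs"]
            rows.append({"check": "derivative_from_expansibility",
                         "solute": key[0], "m_B": key[1], "T": np.nan,
                         "computed": abs(slope), "printed": printed_d, "tol": 1e-5,
                         "passed": abs(abs(slope) - printed_d) <= 1e-5 + 1e-12})
    if limiting_compression is not None and transfer_compression is not None:
        lc = limiting_compression.set_index(["solute", "m_B", "T"])
        for _, row in transfer_compression.iterrows():
            key = (row["solute"], row["m_B"], row["T"])
            try:
                mix = lc.loc[key, "K0_e6"]
                water = lc.loc[(row["solute"], 0.0, row["T"]), "K0_e6"]
            except KeyError:
                raise ValueError(f"limiting-compression table lacks entries for {key}") from None
            computed = mix - water
            rows.append({"check": "transfer_from_limiting",
                         "solute": key[0], "m_B": key[1], "T": key[2],
                         "computed": computed, "printed": row["dK0_e6"], "tol": 2e-4,
                         "passed": abs(computed - row["dK0_e6"]) <= 2e-4 + 1e-12})
    if not rows:
        raise ValueError("no supported table pair supplied")
    return pd.DataFrame(rows)
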