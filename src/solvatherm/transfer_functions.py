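"""Transfer of limiting properties from water to the mixed aqueous solvent.

    delta_Y0 = Y0(in water + co-solvent at m_B) - Y0(in water)

defined at infinite dilution only, so transfers are computed between limiting
fits, never between raw apparent values.  A positive transfer volume signals
dominant hydrophilic-hydrophilic (ion-polar group) co-sphere overlap; a
positive transfer compression signals loosening of the hydration shell by
the co-solvent ions.
"""

import math

import numpy as np
import pandas as pd

__all__ = ["transfer_value", "transfer_all"]


def transfer_value(value_mix, value_water, se_mix=float("nan"), se_water=float("nan")):
    """delta = value_mix - value_water, with se = sqrt(se_mix^2 + se_water^2)."""
    delta = value_mix - value_water
    se = math.sqrt(se_mix**2 + se_water**2) if np.isfinite(se_mix) and np.isfinite(se_water) else float("nan")
    return delta, se


def transfer_all(fits: pd.DataFrame) -> pd.DataFrame:
    """Transfer values for every (solute, m_B > 0, T, property) limiting fit.

    ``fits`` is the long-format table from :func:`solvatherm.limiting_fits.fit_all_groups`
    (or a printed-table equivalent with columns solute, m_B, T, property,
    intercept[, se_intercept]).  Raises if a (solute, T, property) group has
    no m_B = 0 water reference, naming the group.
    """
    if fits is None or len(fits) == 0:
        raise ValueError("empty limiting-fit table")
    df = fits.copy()
    if "se_intercept" not in df.columns:
        df["se_intercept"] = np.nan
    water = df[df["m_B"] == 0].set_index(["solute", "T", "property"])
    rows = []
    mix = df[df["m_B"] > 0].sort_values(["solute", "property", "T", "m_B"], kind="mergesort")
    for _, row in mix.iterrows():
        key = (row["solute"], row["T"], row["property"])
        try:
            ref = water.loc[key]
        except KeyError:
            raise ValueError(
                f"missing water reference (m_B = 0) for solute={key[0]}, T={key[1]}, "
                f"property={key[2]}") from None
        if isinstance(ref, pd.DataFrame):
            ref = ref.iloc[0]
        delta, se = transfer_value(row["intercept"], ref["intercept"],
                                   row["se_intercept"], ref["se_intercept"])
        rows.append({"solute": row["solute"], "m_B": row["m_B"], "T": row["T"],
                     "property": row["property"], "delta": delta, "se_delta": se})
    return pd.DataFrame(rows, columns=["solute", "m_B", "T", "property", "delta", "se_delta"])
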