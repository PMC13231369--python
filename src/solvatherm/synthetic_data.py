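"""Synthetic densimetry/ultrasonic data with known ground truth.

The generator emulates a vibrating-tube densimeter with integrated sound
speed cell measuring ternary (solute + co-solvent + water) solutions: for
each co-solvent molality and temperature it lays down a solvent baseline and
a grid of solute molalities, constructs the target apparent properties from
ground-truth limiting values and slopes,

    V_phi(m_A)   = V0(T) + S_v * m_A
    K_phi_s(m_A) = K0(T) + S_k * m_A,

inverts the defining relations exactly to noiseless (rho, u), and adds
independent Gaussian instrument noise.  Default noise standard deviations
are half the instrument's expanded uncertainties (coverage factor 2):
sigma_rho = 0.05 kg m-3, sigma_u = 0.4 m s-1.

Randomness is confined to the seeded generator; each row draws from its own
counter-based substream keyed by position in the canonically sorted grid, so
output is reproducible and independent of iteration order.  The same seed
yields a byte-identical table.
"""

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .solutes import SoluteSpec, SOLUTES
from .units import VOLUME_SCALE, COMPRESSION_SCALE

__all__ = ["GroundTruth", "invert_density", "invert_sound_speed",
           "generate_dataset", "default_ground_truth"]

STUDY_TEMPERATURES = (288.15, 298.15, 308.15, 318.15)
STUDY_MB = (0.0, 0.1, 0.2, 0.3, 0.4)
# 8-point solute-molality grid spanning the dilute working range
DEFAULT_MA_GRID = tuple(np.round(np.linspace(0.05, 0.40, 8), 4))


def invert_density(m_A, V_phi_target, rho0, M):
    """Density that reproduces a target apparent molar volume exactly.

    rho = (1 + m_A*M) / (1/rho0 + m_A*V_phi_target); the exact algebraic
    inverse of the apparent-molar-volume relation.
    """
    m_A = np.asarray(m_A, dtype=float)
    if np.any(m_A <= 0):
        raise ValueError("m_A must be positive")
    denom = 1.0 / rho0 + m_A * V_phi_target
    if np.any(denom <= 0):
        raise ValueError("target volume implies non-positive solution volume")
    return (1.0 + m_A * M) / denom


def invert_sound_speed(m_A, K_phi_s_target, rho, rho0, Ks0, M):
    """Sound speed that reproduces a target apparent molar compressibility.

    Solves the apparent-compressibility relation for the solution K_s, then
    the Newton-Laplace relation for u.
    """
    m_A = np.asarray(m_A, dtype=float)
    if np.any(m_A <= 0):
        raise ValueError("m_A must be positive")
    Ks = (K_phi_s_target * m_A * rho * rho0 + Ks0 * rho) / (rho0 * (1.0 + m_A * M))
    if np.any(Ks <= 0):
        raise ValueError("target compressibility implies non-positive K_s")
    return 1.0 / np.sqrt(Ks * rho)


def _as_T_map(value, temperatures):
    """Normalize a scalar or {T: value} mapping to a dict over temperatures."""
    if isinstance(value, dict):
        return {float(T): float(value[T]) for T in temperatures}
    return {float(T): float(value) for T in temperatures}


@dataclass
class GroundTruth:
    """Generating parameters for a synthetic measurement campaign.

    All property values are SI (m3 mol-1, m3 mol-1 Pa-1).  ``volume_coeffs``
    maps (solute, m_B) -> (a, b, c) of the quadratic V0(T) model around
    ``T_ref``; ``K0`` and the slopes map (solute, m_B) -> scalar or
    {T: value}.  ``baselines`` maps (m_B, T) -> (rho0, u0); user-supplied
    constants, no water equation of state is embedded.
    """
    solutes: dict = field(default_factory=lambda: dict(SOLUTES))
    m_B_values: tuple = STUDY_MB
    temperatures: tuple = STUDY_TEMPERATURES
    m_A_grid: tuple = DEFAULT_MA_GRID
    T_ref: float = 298.15
    volume_coeffs: dict = field(default_factory=dict)   # (solute, m_B) -> (a, b, c)
    S_v: dict = field(default_factory=dict)             # (solute, m_B) -> scalar or {T: v}
    K0: dict = field(default_factory=dict)              # (solute, m_B) -> scalar or {T: v}
    S_k: dict = field(default_factory=dict)
    baselines: dict = field(default_factory=dict)       # (m_B, T) -> (rho0, u0)
    sigma_rho: float = 0.05
    sigma_u: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.sigma_rho < 0 or self.sigma_u < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if any(m <= 0 for m in self.m_A_grid):
            raise ValueError("solute molality grid must be positive")
        for (m_B, T), (rho0, u0) in self.baselines.items():
            if rho0 <= 0 or u0 <= 0:
                raise ValueError(f"non-positive baseline at m_B={m_B}, T={T}")

    def baseline(self, m_B, T):
        key = (round(float(m_B), 6), round(float(T), 4))
        if key in self.baselines:
            return self.baselines[key]
        # water-like defaults with mild composition/temperature trends
        rho0 = 997.047 + 40.0 * m_B - 0.30 * (T - 298.15)
        u0 = 1496.7 + 30.0 * m_B + 2.0 * (T - 298.15)
        return rho0, u0

    def V0(self, solute, m_B, T):
        a, b, c = self.volume_coeffs[(solute, m_B)]
        t = T - self.T_ref
        return a + b * t + c * t * t

    def limiting_compression(self, solute, m_B, T):
        return _as_T_map(self.K0[(solute, m_B)], self.temperatures)[float(T)]

    def volume_slope(self, solute, m_B, T):
        return _as_T_map(self.S_v.get((solute, m_B), 0.5e-6), self.temperatures)[float(T)]

    def compression_slope(self, solute, m_B, T):
        return _as_T_map(self.S_k.get((solute, m_B), -0.3e-15), self.temperatures)[float(T)]


def default_ground_truth(seed=0, m_A_grid=DEFAULT_MA_GRID, sigma_rho=0.05, sigma_u=0.4):
    """Ground truth mirroring the studied l-threonine / glycyl-l-threonine
    campaigns: published temperature-model coefficients (signed) and limiting
    compressions with their experimental slopes, converted to SI."""
    from . import datasets

    tc = datasets.load_temperature_coefficients(signed=True)
    lc = datasets.load_limiting_compression()
    volume_coeffs, K0, S_k, S_v = {}, {}, {}, {}
    for _, row in tc.iterrows():
        key = (row["solute"], float(row["m_B"]))
        volume_coeffs[key] = (row["a_e6"] / VOLUME_SCALE,
                              row["b_e6"] / VOLUME_SCALE,
                              row["c_e6"] / VOLUME_SCALE)
        S_v[key] = 0.5e-6  # typical positive experimental slope for these solutes
    for (solute, m_B), g in lc.groupby(["solute", "m_B"]):
        key = (solute, float(m_B))
        K0[key] = {float(r["T"]): r["K0_e6"] / COMPRESSION_SCALE for _, r in g.iterrows()}
        S_k[key] = {float(r["T"]): r["Sk_e6"] / COMPRESSION_SCALE for _, r in g.iterrows()}
    return GroundTruth(volume_coeffs=volume_coeffs, S_v=S_v, K0=K0, S_k=S_k,
                       m_A_grid=tuple(m_A_grid), sigma_rho=sigma_rho,
                       sigma_u=sigma_u, seed=seed)


def ground_truth_from_toml(path, seed=None) -> GroundTruth:
    """Build a GroundTruth from a TOML file of overrides to the defaults.

    Recognized top-level keys: ``seed``, ``sigma_rho``, ``sigma_u``,
    ``m_A_grid``, ``m_B_values``, ``temperatures``, ``T_ref``; array tables
    ``[[volume]]`` rows {solute, m_B, a_e6, b_e6, c_e6, S_v_e6}, ``[[compression]]``
    rows {solute, m_B, T, K0_e6, S_k_e6}, ``[[baselines]]`` rows
    {m_B, T, rho0, u0} and ``[[solutes]]`` rows {name, molar_mass}.  Values
    use the conventional reporting scales; omitted sections fall back to the
    study defaults.
    """
    import tomllib

    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    truth = default_ground_truth(
        seed=cfg.get("seed", 0) if seed is None else seed,
        m_A_grid=tuple(cfg.get("m_A_grid", DEFAULT_MA_GRID)),
        sigma_rho=cfg.get("sigma_rho", 0.05),
        sigma_u=cfg.get("sigma_u", 0.4),
    )
    truth.T_ref = cfg.get("T_ref", truth.T_ref)
    truth.m_B_values = tuple(cfg.get("m_B_values", truth.m_B_values))
    truth.temperatures = tuple(cfg.get("temperatures", truth.temperatures))
    for row in cfg.get("solutes", []):
        truth.solutes[row["name"]] = SoluteSpec(row["name"], row["molar_mass"])
    for row in cfg.get("volume", []):
        key = (row["solute"], float(row["m_B"]))
        truth.volume_coeffs[key] = (row["a_e6"] / VOLUME_SCALE,
                                    row["b_e6"] / VOLUME_SCALE,
                                    row["c_e6"] / VOLUME_SCALE)
        if "S_v_e6" in row:
            truth.S_v[key] = row["S_v_e6"] / VOLUME_SCALE
    comp = {}
    for row in cfg.get("compression", []):
        key = (row["solute"], float(row["m_B"]))
        comp.setdefault(key, ({}, {}))
        comp[key][0][float(row["T"])] = row["K0_e6"] / COMPRESSION_SCALE
        if "S_k_e6" in row:
            comp[key][1][float(row["T"])] = row["S_k_e6"] / COMPRESSION_SCALE
    for key, (k0, sk) in comp.items():
        truth.K0[key] = k0
        if sk:
            truth.S_k[key] = sk
    for row in cfg.get("baselines", []):
        truth.baselines[(round(float(row["m_B"]), 6), round(float(row["T"]), 4))] = (
            row["rho0"], row["u0"])
    return truth


def generate_dataset(truth: GroundTruth) -> pd.DataFrame:
    """Generate a measurement table (baseline + solute rows) from ground truth.

    Row order and substreams are canonical (sorted by m_B, T, solute, m_A),
    so the output is a pure function of ``truth``.
    """
    from .apparent_properties import isentropic_compressibility

    solute_names = sorted(truth.solutes)
    rows = []
    for m_B in truth.m_B_values:
        for T in truth.temperatures:
            rho0, u0 = truth.baseline(m_B, T)
            rows.append({"solute": "none", "m_B": m_B, "m_A": 0.0, "T": T,
                         "p": 0.1, "rho": rho0, "u": u0})
            Ks0 = float(isentropic_compressibility(u0, rho0))
            for name in solute_names:
                M = truth.solutes[name].molar_mass
                for m_A in truth.m_A_grid:
                    V_t = truth.V0(name, m_B, T) + truth.volume_slope(name, m_B, T) * m_A
                    K_t = (truth.limiting_compression(name, m_B, T)
                           + truth.compression_slope(name, m_B, T) * m_A)
                    rho = float(invert_density(m_A, V_t, rho0, M))
                    u = float(invert_sound_speed(m_A, K_t, rho, rho0, Ks0, M))
                    rows.append({"solute": name, "m_B": m_B, "m_A": m_A, "T": T,
                                 "p": 0.1, "rho": rho, "u": u})
    df = pd.DataFrame(rows)
    # per-row counter-based substreams keyed by canonical position
    for i in range(len(df)):
        rng = np.random.default_rng([int(truth.seed) % (2**31), i])
        eps_rho, eps_u = rng.standard_normal(2)
        df.loc[i, "rho"] += truth.sigma_rho * eps_rho
        df.loc[i, "u"] += truth.sigma_u * eps_u
    if (df["rho"] <= 0).any() or (df["u"] <= 0).any():
        raise ValueError("configuration produced non-positive density or sound speed")
    df["sigma_rho"] = truth.sigma_rho
    df["sigma_u"] = truth.sigma_u
    return df
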