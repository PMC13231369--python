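"""Internal unit convention and reporting scales.

Everything inside the pipeline is strict SI:

===================================  =====================
quantity                             internal unit
===================================  =====================
density                              kg m-3
molality                             mol kg-1
apparent / limiting molar volume     m3 mol-1
isentropic compressibility           Pa-1
apparent molar compressibility       m3 mol-1 Pa-1
expansibility                        m3 mol-1 K-1
===================================  =====================

Published tables in this field mix scale factors (1e6 cm3-style scales for
volumes, GPa-1 scales for compressions); conversion to those reporting scales
happens only at the output boundary via the constants below.
"""

# multiply an SI value by these to obtain the conventional reporting scale
VOLUME_SCALE = 1e6            # m3 mol-1            -> 1e-6 m3 mol-1 (cm3 mol-1)
EXPANSIBILITY_SCALE = 1e6     # m3 mol-1 K-1        -> 1e-6 m3 mol-1 K-1
EXPANSIBILITY_SLOPE_SCALE = 1e6
COMPRESSION_SCALE = 1e15      # m3 mol-1 Pa-1       -> 1e-6 m3 mol-1 GPa-1

# accepted input units and their factors to SI
DENSITY_FACTORS = {"kg/m^3": 1.0, "kg m-3": 1.0, "g/cm^3": 1000.0, "g cm-3": 1000.0}
SPEED_FACTORS = {"m/s": 1.0, "m s-1": 1.0}
MOLALITY_FACTORS = {"mol/kg": 1.0, "mol kg-1": 1.0}
PRESSURE_FACTORS = {"MPa": 1.0, "kPa": 1e-3, "Pa": 1e-6}


def to_si_density(value, unit: str):
    try:
        return value * DENSITY_FACTORS[unit]
    except KeyError:
        raise ValueError(f"unknown density unit {unit!r}") from None
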