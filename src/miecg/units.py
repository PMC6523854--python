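"""Internal unit system and physical constants.

Everything inside the package is expressed in a single, fixed unit system:

====================  =====================
quantity              internal unit
====================  =====================
length                angstrom (Å)
time                  picosecond (ps)
energy                kcal·mol⁻¹
mass                  g·mol⁻¹
temperature           kelvin (K)
charge                elementary charge (e)
pressure              kcal·mol⁻¹·Å⁻³
====================  =====================

With these choices velocity is Å·ps⁻¹ and force kcal·mol⁻¹·Å⁻¹; kinetic
energy ``½ m v²`` needs the conversion factor :data:`KE_CONV` because
1 g·mol⁻¹·Å²·ps⁻² is not 1 kcal·mol⁻¹.
"""

from __future__ import annotations

import math

#: Boltzmann constant, kcal·mol⁻¹·K⁻¹.
KB = 1.987204259e-3

#: Coulomb prefactor e²/(4πϵ₀), kcal·mol⁻¹·Å·e⁻².
COULOMB = 332.06371

#: 1 atm in internal pressure units (kcal·mol⁻¹·Å⁻³).
ATM = 1.458397e-5

#: kinetic-energy conversion: (g·mol⁻¹)(Å·ps⁻¹)² → kcal·mol⁻¹.
#: 1 g·mol⁻¹·Å²·ps⁻² = 1e-4 kg·m²·s⁻²·mol⁻¹ / 4184 (J→kcal)
KE_CONV = 1.0e-4 / 4.184e3 * 1.0e3  # = 1/418.4
KE_CONV = 1.0 / 418.4

#: Avogadro×1e-24: ρ[g·cm⁻³] = M[g·mol⁻¹] / (AVOG_CM3 · V[Å³])
AVOG_CM3 = 0.602214076

DEG = math.pi / 180.0


def density_g_cm3(total_mass: float, volume_A3: float) -> float:
    """Mass density in g·cm⁻³ from a molar mass total (g·mol⁻¹) and a volume (Å³)."""
    if volume_A3 <= 0:
        raise ValueError("volume must be positive")
    return total_mass / (AVOG_CM3 * volume_A3)


# --- unit-string parsing for config files ------------------------------------

#: unit → (dimension, factor-to-internal)
_UNIT_TABLE = {
    "angstrom": ("length", 1.0),
    "Å": ("length", 1.0),
    "A": ("length", 1.0),
    "nm": ("length", 10.0),
    "ps": ("time", 1.0),
    "fs": ("time", 1.0e-3),
    "ns": ("time", 1.0e3),
    "K": ("temperature", 1.0),
    "atm": ("pressure", ATM),
    "bar": ("pressure", ATM / 1.01325),
    "kcal/mol": ("energy", 1.0),
    "g/mol": ("mass", 1.0),
    "e": ("charge", 1.0),
    "1/angstrom": ("inverse_length", 1.0),
    "1/Å": ("inverse_length", 1.0),
    "1/A": ("inverse_length", 1.0),
    "g/cm3": ("density", 1.0),
    "deg": ("angle", DEG),
    "rad": ("angle", 1.0),
}


class UnitError(ValueError):
    """A quantity string could not be parsed or has the wrong dimension."""


def parse_quantity(value, dimension: str, key: str = "?") -> float:
    """Parse a ``"0.004 ps"``-style string into internal units.

    Bare numbers are rejected for dimensioned quantities so that config files
    are always explicit about units.
    """
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if dimension == "dimensionless":
            return float(value)
        raise UnitError(
            f"config key '{key}': bare number {value!r} — write it with a unit, "
            f"e.g. '0.004 ps'"
        )
    if not isinstance(value, str):
        raise UnitError(f"config key '{key}': cannot parse {value!r}")
    parts = value.split()
    if len(parts) != 2:
        raise UnitError(f"config key '{key}': expected '<number> <unit>', got {value!r}")
    try:
        num = float(parts[0])
    except ValueError as exc:
        raise UnitError(f"config key '{key}': bad number in {value!r}") from exc
    unit = parts[1]
    if unit not in _UNIT_TABLE:
        raise UnitError(f"config key '{key}': unknown unit {unit!r}")
    dim, factor = _UNIT_TABLE[unit]
    if dim != dimension:
        raise UnitError(
            f"config key '{key}': unit {unit!r} has dimension {dim}, expected {dimension}"
        )
    return num * factor
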