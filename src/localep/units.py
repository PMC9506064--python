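"""Unit handling for configuration input.

Parameter tables in the bioelectrics literature mix unit systems freely
(µm, nm, cm⁻², S/m, F/m², V, ms).  Configuration files therefore accept
either bare numbers (interpreted as SI) or strings of the form
``"<number> <unit>"`` which are normalised to SI on load.  Silent unit
mix-ups are the dominant failure mode in this kind of model, so the
conversion table is explicit and unknown units raise immediately.
"""

from __future__ import annotations

import re

# multiplicative factors to SI base units
_FACTORS: dict[str, float] = {
    # length
    "m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9, "cm": 1e-2,
    # area
    "m^2": 1.0, "cm^2": 1e-4, "mm^2": 1e-6, "um^2": 1e-12,
    # inverse area (areal number density)
    "1/m^2": 1.0, "m^-2": 1.0, "1/cm^2": 1e4, "cm^-2": 1e4,
    # volume
    "m^3": 1.0, "uL": 1e-9, "µL": 1e-9, "mL": 1e-6, "L": 1e-3,
    # time
    "s": 1.0, "ms": 1e-3, "us": 1e-6, "µs": 1e-6, "ns": 1e-9,
    # voltage
    "V": 1.0, "mV": 1e-3, "kV": 1e3,
    # conductivity / conductance
    "S/m": 1.0, "mS/m": 1e-3, "S/cm": 1e2,
    "S/m^2": 1.0,
    # capacitance per area
    "F/m^2": 1.0, "uF/cm^2": 1e-2, "µF/cm^2": 1e-2,
    # rate prefactor
    "1/(m^2 s)": 1.0, "m^-2 s^-1": 1.0,
    # electrophoretic mobility
    "m^2/(V s)": 1.0, "m^2/(Vs)": 1.0, "cm^2/(V s)": 1e-4, "cm^2/(Vs)": 1e-4,
    # resistance, current, frequency
    "ohm": 1.0, "Ohm": 1.0, "A": 1.0, "Hz": 1.0,
    # dimensionless
    "": 1.0, "1": 1.0,
}

_NUM = re.compile(r"^\s*([+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)\s*(.*)$")


class UnitError(ValueError):
    """Raised for malformed quantities or unknown units."""


def parse_quantity(value: float | int | str) -> float:
    """Return the SI value of ``value``.

    Numbers pass through unchanged; strings must look like ``"1.5 S/m"``
    or ``"0.4 um"`` with a unit from the conversion table.
    """
    if isinstance(value, bool):
        raise UnitError(f"not a physical quantity: {value!r}")
    if isinstance(value, (int, float)):
        return float(value)
    m = _NUM.match(str(value))
    if not m:
        raise UnitError(f"cannot parse quantity {value!r}")
    num, unit = float(m.group(1)), m.group(2).strip()
    if unit not in _FACTORS:
        raise UnitError(f"unknown unit {unit!r} in {value!r}")
    return num * _FACTORS[unit]
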