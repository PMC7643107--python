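"""Unit parsing and conversion to SI.

All internal computation is SI (m, kg, s).  Config files and CLI flags carry
explicit unit tags (``{value: 500, unit: um}`` or ``"1.7ml/min"``) which are
converted exactly once, on load.
"""

from __future__ import annotations

import re

from .errors import UnitError

# multiplicative factor to SI base unit, by dimension
_LENGTH = {"m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "μm": 1e-6, "nm": 1e-9}
_FLOW = {
    "m^3/s": 1.0,
    "m3/s": 1.0,
    "l/min": 1e-3 / 60.0,
    "ml/min": 1e-6 / 60.0,
    "ul/min": 1e-9 / 60.0,
    "µl/min": 1e-9 / 60.0,
    "μl/min": 1e-9 / 60.0,
}
_DENSITY = {
    "kg/m^3": 1.0,
    "kg/m3": 1.0,
    "g/ml": 1000.0,
    "g/cm^3": 1000.0,
    "g/cm3": 1000.0,
}
_VISCOSITY = {
    "Pa.s": 1.0,
    "Pa*s": 1.0,
    "Pa·s": 1.0,
    "pa.s": 1.0,
    "mPa.s": 1e-3,
    "mPa·s": 1e-3,
    "cP": 1e-3,
}
_VELOCITY = {"m/s": 1.0, "mm/s": 1e-3, "um/s": 1e-6}

_ALL = {}
for _table in (_LENGTH, _FLOW, _DENSITY, _VISCOSITY, _VELOCITY):
    _ALL.update(_table)

_QUANTITY_RE = re.compile(r"^\s*([-+]?[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?)\s*(.*?)\s*$")


def to_si(value: float, unit: str) -> float:
    """Convert ``value`` expressed in ``unit`` to the SI base unit."""
    try:
        return float(value) * _ALL[unit]
    except KeyError:
        raise UnitError(f"unknown unit {unit!r}") from None


def parse_quantity(text: str, default_unit: str | None = None) -> float:
    """Parse a string like ``"1.7ml/min"`` or ``"21um"`` into an SI value.

    A bare number is accepted when ``default_unit`` is given.
    """
    m = _QUANTITY_RE.match(str(text))
    if not m:
        raise UnitError(f"cannot parse quantity {text!r}")
    value, unit = float(m.group(1)), m.group(2)
    if not unit:
        if default_unit is None:
            raise UnitError(f"quantity {text!r} has no unit")
        unit = default_unit
    return to_si(value, unit)


def si_length_to_um(x: float) -> float:
    return x * 1e6


def si_density_to_g_per_ml(rho: float) -> float:
    return rho / 1000.0


def si_flow_to_ml_per_min(q: float) -> float:
    return q * 60.0 * 1e6
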