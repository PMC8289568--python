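"""Concentration units for dry-weight sediment data.

The package works internally in mg/kg dry weight; ng/g appears only at I/O
boundaries and in hazard/target report tables, mirroring the mixed usage of
the two units in sediment-quality literature (guidelines and survey tables
in mg/kg, SSD-derived hazardous concentrations in ng/g).
"""

from __future__ import annotations

#: Canonical internal unit for all fitting and risk arithmetic.
CANONICAL_UNIT = "mg/kg"

#: Recognised dry-weight mass-fraction units and their value in mg/kg.
_UNIT_IN_MG_PER_KG = {
    "mg/kg": 1.0,
    "ng/g": 1e-3,
}

SUPPORTED_UNITS = tuple(_UNIT_IN_MG_PER_KG)


class UnitError(ValueError):
    """Raised for unknown or incompatible concentration units."""


def check_unit(unit: str) -> str:
    if unit not in _UNIT_IN_MG_PER_KG:
        raise UnitError(
            f"unknown concentration unit {unit!r}; expected one of {SUPPORTED_UNITS}"
        )
    return unit


def convert_units(value, from_unit: str, to_unit: str):
    """Convert a concentration (scalar or array) between dry-weight units.

    mg/kg -> ng/g multiplies by 1000; the reverse divides; same-unit is the
    identity (returned unchanged, not multiplied by a computed 1.0, so
    round-trips are bit-exact).
    """
    check_unit(from_unit)
    check_unit(to_unit)
    if from_unit == to_unit:
        return value
    factor = _UNIT_IN_MG_PER_KG[from_unit] / _UNIT_IN_MG_PER_KG[to_unit]
    return value * factor
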