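"""Energy unit conversion.

All internal energies are kept in kcal/mol, the unit in which IQA interaction
energies and reaction-profile terms are conventionally discussed. Conversion
constants are pinned so results are bit-stable:

* 1 hartree = 627.5094740631 kcal/mol (CODATA-derived, fixed here)
* 1 kcal = 4.184 kJ (thermochemical calorie, exact by definition)
"""

from __future__ import annotations

from .errors import UsageError

HARTREE_TO_KCAL = 627.5094740631
KCAL_TO_KJ = 4.184

#: Conversion factor from each supported unit to kcal/mol.
_TO_KCAL = {
    "hartree": HARTREE_TO_KCAL,
    "kcal/mol": 1.0,
    "kJ/mol": 1.0 / KCAL_TO_KJ,
}

# accept a few common spellings
_ALIASES = {
    "hartree": "hartree",
    "au": "hartree",
    "a.u.": "hartree",
    "kcal/mol": "kcal/mol",
    "kcal": "kcal/mol",
    "kj/mol": "kJ/mol",
    "kJ/mol": "kJ/mol",
    "kj": "kJ/mol",
}


def canonical_unit(unit: str) -> str:
    """Return the canonical spelling of *unit*, or raise :class:`UsageError`."""
    key = unit.strip()
    if key in _ALIASES:
        return _ALIASES[key]
    if key.lower() in _ALIASES:
        return _ALIASES[key.lower()]
    raise UsageError(
        f"unknown energy unit {unit!r}; expected one of hartree, kcal/mol, kJ/mol"
    )


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert *value* between hartree, kcal/mol and kJ/mol.

    The conversion is a single multiplication by the ratio of the pinned
    constants, so ``convert_units(x, u, u) == x`` exactly and round trips are
    accurate to floating-point rounding.
    """
    src = canonical_unit(from_unit)
    dst = canonical_unit(to_unit)
    if src == dst:
        return value
    return value * (_TO_KCAL[src] / _TO_KCAL[dst])
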