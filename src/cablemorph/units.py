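"""Length-unit handling.

All internal computation is carried out in nanometers; public entry points
accept an explicit unit tag and convert on entry.  Measurement tables for
cable bacteria routinely mix micrometers (perimeters, cell lengths) with
nanometers (ridge and bulb widths) within a single derivation, so an
explicit tag avoids silent factor-of-1000 errors.
"""

from __future__ import annotations

#: nm per unit, by tag
_NM_PER_UNIT = {
    "nm": 1.0,
    "um": 1_000.0,
    "µm": 1_000.0,
    "mm": 1_000_000.0,
}


def to_nm(value: float, unit: str = "nm") -> float:
    """Convert ``value`` in ``unit`` to nanometers.

    Raises
    ------
    ValueError
        If the unit tag is not one of ``nm``, ``um``/``µm``, ``mm``.
    """
    try:
        return float(value) * _NM_PER_UNIT[unit]
    except KeyError:
        raise ValueError(
            f"unknown length unit {unit!r}; expected one of {sorted(_NM_PER_UNIT)}"
        ) from None


def from_nm(value_nm: float, unit: str = "nm") -> float:
    """Convert a nanometer value to ``unit``."""
    try:
        return float(value_nm) / _NM_PER_UNIT[unit]
    except KeyError:
        raise ValueError(
            f"unknown length unit {unit!r}; expected one of {sorted(_NM_PER_UNIT)}"
        ) from None
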