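"""Energy-unit constants and conversion helpers.

All fitting in :mod:`cbslab` is unit-agnostic; records carry an explicit
unit and conversion happens only at module boundaries.
"""

HARTREE_TO_KCAL = 627.5094740631  # kcal/mol per hartree
HARTREE_TO_RY = 2.0
BOHR_TO_ANGSTROM = 0.529177210903

_FACTORS_TO_HARTREE = {
    "hartree": 1.0,
    "kcal/mol": 1.0 / HARTREE_TO_KCAL,
    "ry": 1.0 / HARTREE_TO_RY,
}


def convert_energy(value: float, from_unit: str, to_unit: str) -> float:
    """Convert an energy between hartree, Rydberg and kcal/mol."""
    try:
        f = _FACTORS_TO_HARTREE[from_unit.lower()]
        t = _FACTORS_TO_HARTREE[to_unit.lower()]
    except KeyError as exc:
        raise ValueError(f"unknown energy unit: {exc.args[0]!r}") from None
    return value * f / t
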