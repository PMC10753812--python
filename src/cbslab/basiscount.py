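"""Basis-size bookkeeping for correlation-consistent Gaussian bases.

Contracted spherical-harmonic function counts per element for the
cc-pVXZ / aug-cc-pVXZ families (hydrogen and the first row B-Ne), the
cubic growth of the count with the cardinal number X, and the sphere
estimate of the plane-wave basis size from cell volume and kinetic-energy
cutoff.
"""

from __future__ import annotations

import math
import re
from typing import Mapping

import numpy as np

__all__ = [
    "parse_formula",
    "count_functions",
    "nb_growth",
    "ng_estimate",
    "n_virtual",
]

# Contracted spherical function counts, X = 2(D)..5, from the published
# (aug-)cc-pVXZ compositions.  H at X matches the first-row count at X-1.
_H_CC = {2: 5, 3: 14, 4: 30, 5: 55}
_H_AUG = {2: 9, 3: 23, 4: 46, 5: 80}
_ROW1_CC = {2: 14, 3: 30, 4: 55, 5: 91}
_ROW1_AUG = {2: 23, 3: 46, 4: 80, 5: 127}

_FIRST_ROW = ("B", "C", "N", "O", "F", "Ne")
_SUPPORTED = ("H",) + _FIRST_ROW

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict:
    """Parse a Hill-notation molecular formula into an element-count table."""
    counts: dict = {}
    pos = 0
    for mo in _FORMULA_RE.finditer(formula):
        if mo.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = mo.end()
        el, num = mo.group(1), mo.group(2)
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def _element_count(element: str, family: str, X: int) -> int:
    if X not in (2, 3, 4, 5):
        raise ValueError("X must be in {2..5}")
    if family not in ("cc", "aug-cc"):
        raise ValueError("family must be 'cc' or 'aug-cc'")
    if element == "H":
        return (_H_AUG if family == "aug-cc" else _H_CC)[X]
    if element in _FIRST_ROW:
        return (_ROW1_AUG if family == "aug-cc" else _ROW1_CC)[X]
    raise ValueError(
        f"element not in table: {element!r} (supported: {', '.join(_SUPPORTED)})"
    )


def count_functions(formula: str | Mapping[str, int], family: str, X: int) -> int:
    """Total contracted basis functions of a molecule at one cardinal number.

    Additive over atoms; e.g. the S22 indole-benzene complex C14H13N in
    aug-cc-pV5Z needs 2945 functions.
    """
    table = parse_formula(formula) if isinstance(formula, str) else dict(formula)
    total = 0
    for el, n in table.items():
        if n < 0:
            raise ValueError("element counts must be non-negative")
        total += n * _element_count(el, family, X)
    return total


def nb_growth(X: int, family: str = "cc") -> int:
    """Per-first-row-atom contracted function count as a polynomial in X.

    cc: (X+1)(X+2)(2X+3)/6 spherical functions (14, 30, 55, 91 for
    X = 2..5); aug-cc adds one diffuse function per angular momentum,
    (X+1)^2 more.  Grows as X^3, hence the X^12 basis factor in the
    N^5 * N_b^4 MP2 cost.
    """
    if X < 2:
        raise ValueError("X must be >= 2")
    base = (X + 1) * (X + 2) * (2 * X + 3) // 6
    if family == "cc":
        return base
    if family == "aug-cc":
        return base + (X + 1) ** 2
    raise ValueError("family must be 'cc' or 'aug-cc'")


def ng_estimate(omega: float, e_cut: float) -> float:
    """Sphere-volume estimate of the plane-wave count with |G|^2/2 <= E_cut.

    Omega in bohr^3, E_cut in hartree: Omega * (2*E_cut)^(3/2) / (6*pi^2).
    The exact lattice enumeration approaches this from either side as the
    cutoff grows (at E_cut = 0 the estimate is 0 while the enumeration
    keeps the single G = 0 state).
    """
    if omega <= 0 or e_cut < 0:
        raise ValueError("Omega must be positive and E_cut non-negative")
    return omega * (2.0 * e_cut) ** 1.5 / (6.0 * math.pi**2)


def n_virtual(n_g: int, n_occ: int) -> int:
    """Virtual-orbital count N_vir = N_G - N_occ."""
    if n_occ > n_g:
        raise ValueError("N_occ cannot exceed N_G")
    return int(n_g) - int(n_occ)
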