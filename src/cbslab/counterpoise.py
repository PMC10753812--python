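"""Counterpoise bookkeeping for dimer interaction energies.

Interaction energies of a dimer AB are formed from the dimer energy and
the monomer energies, either in each monomer's own basis (uncorrected) or
recomputed in the full dimer basis with ghost functions at the partner's
positions (counterpoise, CP).  The three flavors are

    uncorr  = E_AB - E_A{A}  - E_B{B}
    cp      = E_AB - E_A{AB} - E_B{AB}
    half_cp = (uncorr + cp) / 2

where E_A{AB} is monomer A evaluated in the ghost-augmented dimer basis.
Monomer geometries are taken frozen at their in-dimer structures, so no
deformation energies enter.  The module also provides the deviation
statistics (MAE, mean signed deviation, signed maximum deviation,
quartiles and 1.5*IQR outliers) used to compare two sets of interaction
energies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .units import convert_energy

__all__ = ["DimerEnergySet", "DeviationStats", "interaction_energies", "deviation_stats"]


@dataclass
class DimerEnergySet:
    """Dimer plus monomer energies needed for counterpoise bookkeeping.

    Ghost-basis monomer energies are optional; without them only the
    uncorrected interaction energy can be formed.  For a variational
    method the ghost-augmented energy cannot rise above the own-basis one;
    since MP2 correlation is not variational this is checked only as a
    warning by the caller, never enforced here.
    """

    E_AB: float
    E_A_own: float
    E_B_own: float
    E_A_ghost: float | None = None
    E_B_ghost: float | None = None
    unit: str = "hartree"

    @property
    def has_ghost(self) -> bool:
        return self.E_A_ghost is not None and self.E_B_ghost is not None


@dataclass
class DeviationStats:
    """Summary statistics of (value - reference) differences in kcal/mol."""

    mae: float
    msd: float
    max_dev: float  # signed value of the largest-magnitude deviation
    median: float
    q1: float
    q3: float
    outliers: list
    n: int

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "mae": self.mae,
            "msd": self.msd,
            "max_dev": self.max_dev,
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "outliers": list(self.outliers),
        }


def interaction_energies(s: DimerEnergySet) -> dict:
    """Uncorrected, CP-corrected and half-CP interaction energies (kcal/mol).

    ``cp`` and ``half_cp`` are present only when both ghost-basis monomer
    energies are available.  ``half_cp`` is by construction the arithmetic
    mean of ``uncorr`` and ``cp``.
    """
    for name in ("E_AB", "E_A_own", "E_B_own"):
        v = getattr(s, name)
        if v is None or not math.isfinite(v):
            raise ValueError(f"{name} must be a finite energy")
    to_kcal = lambda e: convert_energy(e, s.unit, "kcal/mol")
    out = {"uncorr": to_kcal(s.E_AB - s.E_A_own - s.E_B_own)}
    if s.has_ghost:
        out["cp"] = to_kcal(s.E_AB - s.E_A_ghost - s.E_B_ghost)
        out["half_cp"] = 0.5 * (out["uncorr"] + out["cp"])
    return out


def require_cp(s: DimerEnergySet) -> dict:
    """Like :func:`interaction_energies` but demanding ghost energies."""
    if not s.has_ghost:
        raise ValueError("ghost energies required for the counterpoise correction")
    return interaction_energies(s)


def deviation_stats(
    values: Sequence[float],
    reference: Sequence[float],
    labels: Sequence[str] | None = None,
    absolute_max_dev: bool = False,
) -> DeviationStats:
    """Statistics of the differences ``values - reference``.

    ``max_dev`` keeps the original sign of the largest-magnitude
    difference (pass ``absolute_max_dev=True`` for its magnitude).
    Quartiles use linear interpolation between order statistics (type 7),
    and outliers are entries further than 1.5 interquartile ranges from
    the first or third quartile.
    """
    v = np.asarray(values, dtype=float)
    r = np.asarray(reference, dtype=float)
    if v.shape != r.shape or v.ndim != 1:
        raise ValueError("shape error: values and reference must be equal-length 1-D")
    if v.size == 0:
        raise ValueError("shape error: need at least one entry")
    if labels is None:
        labels = [str(i) for i in range(v.size)]
    elif len(labels) != v.size:
        raise ValueError("shape error: labels length mismatch")

    d = v - r
    mae = float(np.mean(np.abs(d)))
    msd = float(np.mean(d))
    imax = int(np.argmax(np.abs(d)))
    max_dev = float(abs(d[imax])) if absolute_max_dev else float(d[imax])
    q1, med, q3 = (float(q) for q in np.quantile(d, [0.25, 0.5, 0.75]))
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = [labels[i] for i in range(d.size) if d[i] < lo or d[i] > hi]
    return DeviationStats(mae, msd, max_dev, med, q1, q3, outliers, int(v.size))
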