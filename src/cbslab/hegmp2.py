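"""Gamma-point plane-wave MP2 for the finite-cell homogeneous electron gas.

The homogeneous electron gas (HEG) in a cubic box is the one system whose
Hartree-Fock orbitals are exactly single plane waves |G>, which makes it a
desk-scale laboratory for the convergence laws of plane-wave MP2: pair
densities have a single momentum-conserving Fourier component, two-electron
integrals reduce to one kernel value per excitation, and the partial
correlation sum over the lowest n virtual orbitals can be followed exactly
out to the full basis.  Its tail approaches the basis-set limit like 1/n
(equivalently like eps_n^(-3/2)), which is the law the virtual-space
extrapolation of :mod:`cbslab.pw_converge` exploits.

Spin-restricted closed shells only: the electron count must complete a
degenerate momentum shell (2, 14, 38, ... in a cubic cell).  Energies are
in hartree throughout; unit conversion is left to the reporting layer.
All operations are deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import coulomb
from .pw_converge import VirtualSeries, virtual_fit, windowed_average

__all__ = [
    "HEGModel",
    "PairDensity",
    "build_model",
    "pair_density",
    "hf_eigenvalues",
    "mp2_correlation",
    "mp2_brute_force",
    "cbs_demo",
]


@dataclass
class HEGModel:
    """Finite-cell HEG state: plane-wave orbitals with shell-complete filling.

    Orbitals are labelled by integer momentum triples m (momentum
    k = 2*pi*m/L); the lowest ``n_occ = n_elec/2`` states are doubly
    occupied.  ``eigenvalues`` hold the kinetic spectrum by default; call
    :func:`hf_eigenvalues` for the exchange-dressed spectrum.
    """

    L: float  # cubic cell edge, bohr
    e_cut: float  # hartree
    n_elec: int
    indices: np.ndarray = field(repr=False, default=None)  # (N_G, 3) ints, ordered
    k: np.ndarray = field(repr=False, default=None)  # (N_G, 3) bohr^-1
    eigenvalues: np.ndarray = field(repr=False, default=None)

    @property
    def omega(self) -> float:
        return self.L**3

    @property
    def n_g(self) -> int:
        return int(self.indices.shape[0])

    @property
    def n_occ(self) -> int:
        return self.n_elec // 2

    @property
    def n_vir(self) -> int:
        return self.n_g - self.n_occ


@dataclass(frozen=True)
class PairDensity:
    """Occupied-virtual overlap density of two plane-wave orbitals.

    The product of two plane waves is a single plane wave, so the Fourier
    expansion of phi_i* phi_a has exactly one nonzero component, at the
    momentum transfer G = k_a - k_i, with unit coefficient: momentum
    conservation made explicit.
    """

    i: int
    a: int
    transfer: tuple  # integer momentum-transfer triple
    amplitude: float = 1.0


def pair_density(model: HEGModel, i: int, a: int) -> PairDensity:
    """The single momentum-conserving Fourier component of phi_i* phi_a."""
    n = model.n_g
    if not (0 <= i < n and 0 <= a < n):
        raise ValueError("orbital index out of range")
    dm = model.indices[a] - model.indices[i]
    return PairDensity(int(i), int(a), tuple(int(v) for v in dm))


def build_model(L: float, e_cut: float, n_elec: int) -> HEGModel:
    """Enumerate the plane-wave basis and fill the lowest closed shells.

    Raises if the Fermi shell would be partially filled: momentum shells
    in a cubic cell close at N_elec = 2, 14, 38, 54, ...
    """
    if L <= 0:
        raise ValueError("cell edge must be positive")
    if n_elec <= 0 or n_elec % 2:
        raise ValueError("N_elec must be a positive even integer (spin-restricted)")
    grid = coulomb.GGrid.build((L, L, L), e_cut)
    m = grid.indices
    k = grid.g
    kin = grid.g2 / 2.0
    # already ordered by (|m|^2, lexicographic)
    n_occ = n_elec // 2
    if n_occ > m.shape[0]:
        raise ValueError(f"basis too small: {m.shape[0]} states for {n_occ} occupied")
    m2 = np.einsum("ij,ij->i", m, m)
    if n_occ < m.shape[0] and m2[n_occ - 1] == m2[n_occ]:
        shells = np.flatnonzero(np.diff(m2)) + 1
        allowed = ", ".join(str(2 * int(s)) for s in shells[:5])
        raise ValueError(
            f"open shell at Fermi level: choose N_elec in {{{allowed}, ...}} for this cell"
        )
    return HEGModel(float(L), float(e_cut), int(n_elec), m, k, kin)


def hf_eigenvalues(model: HEGModel, exchange: bool = True) -> np.ndarray:
    """Plane-wave Fock eigenvalues of the finite-cell gas.

    Kinetic term |k|^2/2, minus (with ``exchange``) the finite-cell
    exchange sum (4*pi/Omega) * sum over occupied k' != k of 1/|k-k'|^2;
    the singular k' = k component is excluded consistently with the bare
    kernel treatment.
    """
    kin = np.einsum("ij,ij->i", model.k, model.k) / 2.0
    if not exchange:
        return kin
    occ = model.k[: model.n_occ]
    diff = model.k[:, None, :] - occ[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    with np.errstate(divide="ignore"):
        inv = np.where(d2 > 0, 1.0 / d2, 0.0)
    return kin - (4.0 * np.pi / model.omega) * inv.sum(axis=1)


def _virtual_order(model: HEGModel, eps: np.ndarray):
    """Virtual indices sorted by (eigenvalue, |m|^2, lexicographic triple).

    Returns (order, shell_sizes) where shells group eigenvalue-degenerate
    contiguous blocks, so truncations snapped to shell boundaries are
    independent of the ordering inside a shell.
    """
    vir = np.arange(model.n_occ, model.n_g)
    m = model.indices[vir]
    m2 = np.einsum("ij,ij->i", m, m)
    order = vir[np.lexsort((m[:, 2], m[:, 1], m[:, 0], m2, np.round(eps[vir], 10)))]
    ev = np.round(eps[order], 10)
    boundaries = np.flatnonzero(np.diff(ev)) + 1
    edges = np.concatenate([[0], boundaries, [order.size]])
    return order, np.diff(edges)


def _kernel_lookup(model: HEGModel, treatment):
    """Map integer momentum-transfer triples to kernel values.

    Momentum transfers live on the reciprocal lattice with norms up to
    twice the orbital G_max, hence the 4*E_cut enumeration.
    """
    if treatment is None or treatment == "bare":
        b2 = (2.0 * np.pi / model.L) ** 2

        def phi(dm: np.ndarray) -> np.ndarray:
            q2 = b2 * np.einsum("ij,ij->i", dm, dm)
            with np.errstate(divide="ignore"):
                return np.where(q2 > 0, 4.0 * np.pi / q2, 0.0)

        return phi
    spec = treatment if isinstance(treatment, coulomb.KernelSpec) else coulomb.KernelSpec(treatment)
    grid = coulomb.GGrid.build((model.L,) * 3, 4.0 * model.e_cut + 1e-9)
    vals = coulomb.kernel_values(grid, spec)
    table = {tuple(idx): v for idx, v in zip(map(tuple, grid.indices), vals)}

    def phi(dm: np.ndarray) -> np.ndarray:
        return np.array([table.get(tuple(row), 0.0) for row in dm])

    return phi


def mp2_correlation(
    model: HEGModel,
    kernel=None,
    n_max: int | None = None,
    exchange_eigenvalues: bool = True,
) -> VirtualSeries:
    """Exact partial-sum MP2 correlation series of the finite-cell gas.

    Each entry E_c,n of the returned series is the exact spin-restricted
    MP2 correlation energy (hartree) of the virtual space truncated to the
    lowest n virtuals; entries are emitted at degenerate-shell boundaries
    so the partial sums do not depend on intra-shell ordering.  ``kernel``
    is None/"bare" for the zeroed bare Coulomb kernel, a treatment name or
    a :class:`cbslab.coulomb.KernelSpec` otherwise.
    """
    eps = hf_eigenvalues(model, exchange=exchange_eigenvalues)
    order, shell_sizes = _virtual_order(model, eps)
    n_vir = order.size
    if n_vir == 0:
        return VirtualSeries(np.array([]), np.array([]), np.array([]), unit="hartree")
    if n_max is None:
        n_max = n_vir
    if n_max > n_vir:
        raise ValueError(f"n_max={n_max} exceeds N_vir={n_vir}")
    edges = np.cumsum(shell_sizes)
    if n_max not in edges:
        snapped = int(edges[np.searchsorted(edges, n_max)]) if n_max < edges[-1] else int(edges[-1])
        warnings.warn(
            f"n_max={n_max} splits a degenerate shell; adjusted to {snapped}", stacklevel=2
        )
        n_max = snapped

    occ = np.arange(model.n_occ)
    kept = order[:n_max]
    vpos = {tuple(model.indices[orb]): p for p, orb in enumerate(kept)}
    phi = _kernel_lookup(model, kernel)
    inv_omega = 1.0 / model.omega

    m = model.indices
    contrib = np.zeros(n_max)
    for i in occ:
        mi = m[i]
        # direct integrals (i a | j b): single momentum-conserving component
        dm_ia = m[kept] - mi  # (n_max, 3)
        v_ia = phi(dm_ia) * inv_omega
        for j in occ:
            mj = m[j]
            msum = mi + mj
            for pa, a in enumerate(kept):
                mb = msum - m[a]
                pb = vpos.get(tuple(mb))
                if pb is None:
                    continue
                b = kept[pb]
                denom = eps[i] + eps[j] - eps[a] - eps[b]
                vd = v_ia[pa]
                vx = phi((m[b] - mi)[None, :])[0] * inv_omega
                bin_ = max(pa, pb)
                contrib[bin_] += vd * (2.0 * vd - vx) / denom
    cum = np.cumsum(contrib)
    ns = edges[edges <= n_max]
    e_series = cum[ns - 1]
    eps_series = eps[kept[ns - 1]]
    return VirtualSeries(ns.astype(float), e_series, eps_series, unit="hartree")


def mp2_brute_force(
    model: HEGModel, kernel=None, exchange_eigenvalues: bool = True
) -> float:
    """Naive quadruple-loop MP2 energy; the oracle for small bases."""
    eps = hf_eigenvalues(model, exchange=exchange_eigenvalues)
    phi = _kernel_lookup(model, kernel)
    m = model.indices
    occ = range(model.n_occ)
    vir = range(model.n_occ, model.n_g)
    inv_omega = 1.0 / model.omega
    total = 0.0
    for i in occ:
        for j in occ:
            for a in vir:
                for b in vir:
                    if not np.array_equal(m[i] + m[j], m[a] + m[b]):
                        continue
                    vd = phi((m[a] - m[i])[None, :])[0] * inv_omega
                    vx = phi((m[b] - m[i])[None, :])[0] * inv_omega
                    total += vd * (2.0 * vd - vx) / (eps[i] + eps[j] - eps[a] - eps[b])
    return total


def cbs_demo(model_small: HEGModel, model_large: HEGModel, kernel=None) -> dict:
    """Demonstrate virtual-space extrapolation against a larger direct sum.

    ``model_small`` and ``model_large`` must differ only in E_cut.  The
    small model's partial-sum tail is extrapolated with both abscissas
    (1/n and eps_n^(-3/2)) and compared with the large model's full
    direct summation.
    """
    if not (
        model_small.L == model_large.L and model_small.n_elec == model_large.n_elec
    ):
        raise ValueError("models must differ only in E_cut")
    series_small = mp2_correlation(model_small, kernel=kernel)
    series_large = mp2_correlation(model_large, kernel=kernel)
    truncated = float(series_small.E_c_n[-1])
    direct = float(series_large.E_c_n[-1])

    # fit on the 1/n-linear tail: windows inside the last three quarters
    lo = int(series_small.n[max(0, series_small.n.size // 4)])
    tail = (lo, series_small.n_max)
    out = {"truncated_small": truncated, "direct_large": direct}
    for mode in ("inv_n", "eps_minus_3_2"):
        fit = virtual_fit(series_small, mode=mode, window=tail)
        sub = VirtualSeries(
            series_small.n[series_small.n >= lo],
            series_small.E_c_n[series_small.n >= lo],
            series_small.eps_n[series_small.n >= lo],
            unit=series_small.unit,
        )
        # HEG partial sums step at shell closures, so the smooth-series
        # validity gate is disabled: every tail window contributes, and
        # sigma is the spread of intercepts across windows.
        mean, sigma, _ = windowed_average(
            sub, mode=mode, min_points=3, r2_min=0.0, max_studentized=np.inf
        )
        out[mode] = {
            "alpha": fit.alpha,
            "alpha_mean": mean,
            "sigma": sigma,
            "r_squared": fit.r_squared,
            "error_vs_direct": fit.alpha - direct,
        }
    out["truncation_error"] = truncated - direct
    return out
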