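"""Plane-wave-side convergence extrapolations.

Two families of plane-wave extrapolations are covered:

* **Virtual space.**  The partial MP2 correlation sum E_c,n over the first
  n virtual orbitals approaches the basis-set limit like 1/n (equivalently
  like eps_n^(-3/2), eps_n being the eigenvalue of the n-th virtual),
  so a straight line

      E_c,n = alpha + beta * x,   x = 1/n  or  eps_n^(-3/2)

  fitted to the tail recovers the converged correlation contribution as
  its intercept alpha.  Because the choice of fitting window matters,
  :func:`windowed_average` fits every window ending at n_max, keeps the
  windows on which the linear law actually holds, and reports the mean
  and standard deviation of the accepted intercepts (the sigma quoted
  alongside extrapolated correlation energies).

* **Supercell volume.**  With a screened Coulomb kernel the remaining
  finite-size error of the correlation energy decays with the supercell
  volume Omega; the default model is linear in 1/Omega, giving the
  isolated-system value as the intercept of a least-squares line (the
  exponent is configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "VirtualSeries",
    "VirtualFitResult",
    "VolumeSeries",
    "virtual_fit",
    "windowed_average",
    "volume_fit",
]

ABSCISSA_MODES = ("inv_n", "eps_minus_3_2")


@dataclass
class VirtualSeries:
    """Ordered (n, eps_n, E_c,n) partial-sum entries.

    ``n`` is the virtual-orbital count (strictly increasing), ``eps_n``
    the eigenvalue of the n-th virtual in hartree (optional, needed only
    for the eigenvalue abscissa) and ``E_c_n`` the partial correlation sum
    in ``unit``.
    """

    n: np.ndarray
    E_c_n: np.ndarray
    eps_n: np.ndarray | None = None
    unit: str = "kcal/mol"

    def __post_init__(self):
        self.n = np.asarray(self.n, dtype=float)
        self.E_c_n = np.asarray(self.E_c_n, dtype=float)
        if self.eps_n is not None:
            self.eps_n = np.asarray(self.eps_n, dtype=float)
            if self.eps_n.shape != self.n.shape:
                raise ValueError("eps_n must align with n")
        if self.n.shape != self.E_c_n.shape or self.n.ndim != 1:
            raise ValueError("n and E_c_n must be equal-length 1-D")
        if self.n.size and np.any(np.diff(self.n) <= 0):
            raise ValueError("n must be strictly increasing")

    @property
    def n_max(self) -> int:
        return int(self.n[-1]) if self.n.size else 0

    @property
    def increment(self) -> float:
        return float(np.min(np.diff(self.n))) if self.n.size > 1 else 0.0


@dataclass
class VirtualFitResult:
    """Outcome of one linear tail fit: intercept alpha is the CBS estimate."""

    alpha: float
    beta: float
    window: tuple
    abscissa_mode: str
    r_squared: float
    n_points: int


@dataclass
class VolumeSeries:
    """(Omega, E_c) supercell-volume series; Omega in cubic angstroms."""

    omega: np.ndarray
    E_c: np.ndarray
    unit: str = "kcal/mol"

    def __post_init__(self):
        self.omega = np.asarray(self.omega, dtype=float)
        self.E_c = np.asarray(self.E_c, dtype=float)
        if self.omega.shape != self.E_c.shape or self.omega.ndim != 1:
            raise ValueError("omega and E_c must be equal-length 1-D")
        if np.any(self.omega <= 0):
            raise ValueError("Omega must be positive")
        if self.omega.size > 1 and np.any(np.diff(self.omega) <= 0):
            raise ValueError("degenerate abscissa: Omega must be strictly increasing")


def _abscissa(series: VirtualSeries, mode: str, mask: np.ndarray) -> np.ndarray:
    if mode == "inv_n":
        return 1.0 / series.n[mask]
    if mode == "eps_minus_3_2":
        if series.eps_n is None:
            raise ValueError("eps values required for the eigenvalue abscissa")
        eps = series.eps_n[mask]
        if np.any(eps <= 0):
            raise ValueError("invalid eigenvalue: eps_n must be positive in eps mode")
        return eps ** (-1.5)
    raise ValueError(f"abscissa_mode must be one of {ABSCISSA_MODES}")


def _line_fit(x: np.ndarray, y: np.ndarray):
    """OLS line y = alpha + beta*x; returns (alpha, beta, r2, residuals)."""
    M = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(M, y, rcond=None)
    resid = y - M @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return float(coef[0]), float(coef[1]), r2, resid


def virtual_fit(
    series: VirtualSeries,
    mode: str = "inv_n",
    window: tuple | None = None,
) -> VirtualFitResult:
    """Linear fit of the partial-sum tail; the intercept is the CBS estimate.

    ``window = (n_start, n_end)`` restricts the fit to entries with
    n_start <= n <= n_end (default: all entries).
    """
    if window is None:
        window = (int(series.n[0]), series.n_max) if series.n.size else (0, 0)
    n_start, n_end = window
    mask = (series.n >= n_start) & (series.n <= n_end)
    if int(mask.sum()) < 2:
        raise ValueError("insufficient window: need at least 2 points")
    x = _abscissa(series, mode, mask)
    y = series.E_c_n[mask]
    alpha, beta, r2, _ = _line_fit(x, y)
    return VirtualFitResult(alpha, beta, (int(n_start), int(n_end)), mode, r2, int(mask.sum()))


def _window_is_valid(x, y, r2_min: float, max_studentized: float) -> bool:
    """Proxy for 'the linear law holds on this window'.

    A window is accepted when its residuals carry no gross outlier
    (largest studentized residual <= ``max_studentized``) and show no
    significant curvature: on windows of four or more points the t
    statistic of an added quadratic term must stay below the same
    threshold, while three-point windows (where curvature is not
    testable) fall back to the r^2 >= ``r2_min`` gate.  Numerically exact
    lines always pass.
    """
    alpha, beta, r2, resid = _line_fit(x, y)
    m = x.size
    if m <= 2:
        return True
    sse = float(resid @ resid)
    scale = max(np.max(np.abs(y)), 1.0)
    if sse <= (1e-12 * scale) ** 2 * m:  # numerically exact line
        return True
    # outlier gate on studentized residuals of the linear fit
    s2 = sse / (m - 2)
    xbar = x.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    h = 1.0 / m + (x - xbar) ** 2 / sxx
    with np.errstate(divide="ignore", invalid="ignore"):
        t = resid / np.sqrt(s2 * (1.0 - h))
    t = t[np.isfinite(t)]
    if t.size and np.max(np.abs(t)) > max_studentized:
        return False
    if m == 3:
        return bool(r2 >= r2_min)
    # curvature gate: significance of a quadratic term
    M = np.column_stack([np.ones_like(x), x, x * x])
    coef, *_ = np.linalg.lstsq(M, y, rcond=None)
    rq = y - M @ coef
    sse_q = float(rq @ rq)
    if sse_q <= (1e-12 * scale) ** 2 * m:
        # the quadratic interpolates: curvature dominates unless it is tiny
        return bool(r2 >= r2_min)
    s2q = sse_q / (m - 3)
    cov = np.linalg.inv(M.T @ M)
    se_c = np.sqrt(s2q * cov[2, 2])
    return bool(abs(coef[2]) <= max_studentized * se_c)


def windowed_average(
    series: VirtualSeries,
    mode: str = "inv_n",
    min_points: int = 3,
    r2_min: float = 0.99,
    max_studentized: float = 3.0,
) -> tuple:
    """Average the intercepts over all valid fitting windows ending at n_max.

    Every window [n_start, n_max] with n_start running over the series
    entries and at least ``min_points`` points is fitted; windows passing
    the validity criterion (no significant curvature and no gross
    residual outlier, see :func:`_window_is_valid`) contribute their
    intercept.  Returns
    ``(alpha_mean, sigma, accepted)`` where sigma is the population
    standard deviation of the accepted intercepts -- the spread quoted
    alongside extrapolated correlation energies -- and ``accepted`` the
    list of accepted :class:`VirtualFitResult`.
    """
    if series.n.size < min_points:
        raise ValueError(f"series has fewer than min_points={min_points} entries")
    n_max = series.n_max
    starts = series.n[: series.n.size - (min_points - 1)]
    accepted, diagnostics = [], []
    for n_start in starts:
        mask = (series.n >= n_start) & (series.n <= n_max)
        x = _abscissa(series, mode, mask)
        y = series.E_c_n[mask]
        ok = _window_is_valid(x, y, r2_min, max_studentized)
        alpha, beta, r2, _ = _line_fit(x, y)
        fit = VirtualFitResult(alpha, beta, (int(n_start), int(n_max)), mode, r2, int(mask.sum()))
        if ok:
            accepted.append(fit)
        else:
            diagnostics.append((int(n_start), r2))
    if not accepted:
        raise ValueError(
            "no valid window: all candidate windows rejected; "
            f"(n_start, r^2) diagnostics: {diagnostics}"
        )
    alphas = np.array([f.alpha for f in accepted])
    return float(alphas.mean()), float(alphas.std()), accepted


def volume_fit(series: VolumeSeries, exponent: float = 1.0) -> tuple:
    """Least-squares fit E_c = E_inf + c / Omega**exponent.

    Returns ``(E_inf, c)``; the intercept E_inf is the infinite-volume
    (isolated-system) estimate.
    """
    if series.omega.size < 2:
        raise ValueError("need at least 2 volumes")
    x = series.omega ** (-float(exponent))
    alpha, beta, _, _ = _line_fit(x, series.E_c)
    return alpha, beta
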