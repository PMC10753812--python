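"""Registry and fitting engine for Gaussian-basis CBS extrapolation laws.

Correlation-consistent (aug-)cc-pVXZ energies converge slowly with the
cardinal number X (D=2, T=3, Q=4, 5), and the complete-basis-set (CBS)
limit is in practice reached by fitting an extrapolation law

    E(X) = E_CBS + correction(X; parameters)

to a short sequence of cardinal numbers.  This module holds the registry of
named laws from the extrapolation literature -- shifted power laws,
exponentials, and double-power forms, including the three-point
``rovibi34``/``rovibi45`` laws that mix a principal-expansion X^-3 term
with angular-momentum-type shifted powers -- together with a single generic
fitting engine.

Fitting is unit-agnostic.  Laws that are linear in their parameters
(every power form with fixed exponents, and the double-exponential
``peterson`` form) are solved exactly when the number of points equals the
number of free parameters and by ordinary least squares otherwise.  Laws
with one genuinely nonlinear parameter (the exponential decay rate of
``feller``/``helgaker_hf``, the free exponent of ``martin_alpha``) are
profiled: for a trial value of the nonlinear parameter the remaining
parameters are solved linearly, and the one-dimensional residual objective
is minimised deterministically (closed-form three-point initialisation,
bracketed root/minimiser, tolerance 1e-12, max 500 iterations).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "EnergyRecord",
    "SchemeSpec",
    "ExtrapolationResult",
    "SCHEMES",
    "get_scheme",
    "extrapolate",
    "enumerate_generic_family",
    "interpolation_error",
]

COMPONENTS = ("HF", "corr", "total")
FAMILIES = ("cc", "aug-cc")
SUBSYSTEMS = ("dimer", "monomer_A", "monomer_B")
CP_FLAVORS = ("own_basis", "ghost_basis")
UNITS = ("hartree", "kcal/mol")
CARDINALS = (2, 3, 4, 5)

#: Map D/T/Q/5 letters to cardinal numbers.
CARDINAL_LETTERS = {"D": 2, "T": 3, "Q": 4, "5": 5, "2": 2, "3": 3, "4": 4}


@dataclass(frozen=True)
class EnergyRecord:
    """One (system, subsystem, family, X, component, CP flavor) energy entry.

    The atom of all Gaussian-basis-side bookkeeping.  ``energy`` is a total
    energy (hartree) or a relative energy (kcal/mol); ``unit`` says which.
    """

    system: str
    subsystem: str
    family: str
    X: int
    component: str
    cp_flavor: str
    energy: float
    unit: str = "hartree"

    def __post_init__(self):
        if self.subsystem not in SUBSYSTEMS:
            raise ValueError(f"subsystem must be one of {SUBSYSTEMS}, got {self.subsystem!r}")
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.X not in CARDINALS:
            raise ValueError(f"X must be in {{2..5}}, got {self.X!r}")
        if self.component not in COMPONENTS:
            raise ValueError(f"component must be one of {COMPONENTS}, got {self.component!r}")
        if self.cp_flavor not in CP_FLAVORS:
            raise ValueError(f"cp_flavor must be one of {CP_FLAVORS}, got {self.cp_flavor!r}")
        if self.unit not in UNITS:
            raise ValueError(f"unit must be one of {UNITS}, got {self.unit!r}")
        if not math.isfinite(self.energy):
            raise ValueError("energy must be finite")


# ---------------------------------------------------------------------------
# Basis terms of the extrapolation laws
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PowerTerm:
    """(X + shift)^(-exponent) correction term."""

    exponent: float
    shift: float = 0.0

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) + self.shift) ** (-self.exponent)

    def label(self) -> str:
        s = f"{self.shift:+g}" if self.shift else ""
        return f"(X{s})^-{self.exponent:g}"


@dataclass(frozen=True)
class FixedExpTerm:
    """exp(-rate * (X + shift)^degree) term with all constants fixed.

    ``degree=1`` gives a plain exponential, ``degree=2`` a Gaussian decay;
    with fixed rate the term is linear in its coefficient.
    """

    rate: float = 1.0
    shift: float = -1.0
    degree: int = 1

    def __call__(self, X: np.ndarray) -> np.ndarray:
        x = np.asarray(X, dtype=float) + self.shift
        return np.exp(-self.rate * x**self.degree)

    def label(self) -> str:
        s = f"{self.shift:+g}" if self.shift else ""
        inner = f"(X{s})" if s else "X"
        if self.degree != 1:
            inner += f"^{self.degree}"
        r = f"{self.rate:g}*" if self.rate != 1.0 else ""
        return f"exp(-{r}{inner})"


@dataclass(frozen=True)
class SchemeSpec:
    """A named extrapolation law.

    ``terms`` are the linear correction terms (each carrying one free
    coefficient on top of the CBS constant).  ``nonlinear`` names an
    optional single nonlinear parameter: ``"exp_rate"`` for
    ``E_CBS + A*exp(-B*X)`` or ``"power_exponent"`` for
    ``E_CBS + A*(X+shift)^-alpha``; ``nl_shift`` is the shift used by the
    latter.  ``coupling`` optionally ties a second fixed-ratio power term
    to the first (``var34_fit``).
    """

    id: str
    terms: tuple = ()
    nonlinear: str | None = None
    nl_shift: float = 0.0
    coupling: float | None = None  # second-term coefficient ratio (var34_fit)
    applies_to: tuple = ("corr", "total")
    description: str = ""

    @property
    def n_free(self) -> int:
        if self.nonlinear is not None:
            return 3  # E_CBS, amplitude, nonlinear parameter
        if self.coupling is not None:
            return 2  # E_CBS plus one tied amplitude
        return 1 + len(self.terms)

    @property
    def min_points(self) -> int:
        return self.n_free

    @property
    def is_linear(self) -> bool:
        return self.nonlinear is None

    def form(self) -> str:
        """Human-readable functional form."""
        if self.nonlinear == "exp_rate":
            return "E_CBS + A*exp(-B*X)"
        if self.nonlinear == "power_exponent":
            s = f"{self.nl_shift:+g}" if self.nl_shift else ""
            return f"E_CBS + A*(X{s})^-alpha"
        parts = ["E_CBS"]
        names = "ABCD"
        for k, t in enumerate(self.terms):
            parts.append(f"{names[k]}*{t.label()}")
        if self.coupling is not None:
            parts[-1] = parts[-1] + f"  [B = {self.coupling:g}*A tied]"
        return " + ".join(parts)


@dataclass
class ExtrapolationResult:
    """Outcome of fitting one scheme to one cardinal-number sequence."""

    scheme_id: str
    e_cbs: float
    params: dict
    residuals: np.ndarray
    points: list
    fit_mode: str  # "exact-solve" | "least-squares"
    converged: bool = True
    unit: str | None = None

    def as_dict(self) -> dict:
        return {
            "scheme": self.scheme_id,
            "points": [[int(x), float(e)] for x, e in self.points],
            "E_CBS": float(self.e_cbs),
            "params": {k: float(v) for k, v in self.params.items()},
            "residuals": [float(r) for r in self.residuals],
            "fit_mode": self.fit_mode,
            "converged": bool(self.converged),
            "interpolation_mae": float(np.mean(np.abs(self.residuals))),
            **({"unit": self.unit} if self.unit else {}),
        }


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

_TRUHLAR_ALPHA = 3.4  # HF power, minimal RMSD against MP2-R12 references
_TRUHLAR_BETA = 2.2  # correlation power, same calibration
_VARANDAS_SHIFT = -3.0 / 8.0
_VAR34_COUPLING = 1.0  # fixed X^-4/X^-3 coefficient ratio of var34_fit


def _registry() -> dict:
    specs = [
        SchemeSpec(
            "feller",
            nonlinear="exp_rate",
            applies_to=("HF", "corr", "total"),
            description="three-parameter exponential of the total energy",
        ),
        SchemeSpec(
            "peterson",
            terms=(FixedExpTerm(shift=-1.0, degree=1), FixedExpTerm(shift=-1.0, degree=2)),
            applies_to=("HF", "corr", "total"),
            description="mixed exponential/Gaussian decay in (X-1)",
        ),
        SchemeSpec(
            "truhlar_hf",
            terms=(PowerTerm(_TRUHLAR_ALPHA),),
            applies_to=("HF",),
            description=f"two-point power law X^-{_TRUHLAR_ALPHA} for the HF energy",
        ),
        SchemeSpec(
            "truhlar_corr",
            terms=(PowerTerm(_TRUHLAR_BETA),),
            description=f"two-point power law X^-{_TRUHLAR_BETA} for the correlation energy",
        ),
        SchemeSpec(
            "martin4",
            terms=(PowerTerm(4.0, 0.5),),
            description="two-point shifted fourth power (X+1/2)^-4",
        ),
        SchemeSpec(
            "martin46",
            terms=(PowerTerm(4.0, 0.5), PowerTerm(6.0, 0.5)),
            description="shifted fourth plus sixth powers",
        ),
        SchemeSpec(
            "martin_alpha",
            nonlinear="power_exponent",
            nl_shift=0.5,
            description="shifted power with free exponent",
        ),
        SchemeSpec(
            "wilson35",
            terms=(PowerTerm(3.0), PowerTerm(5.0)),
            description="third plus fifth powers of X",
        ),
        SchemeSpec(
            "wilson45",
            terms=(PowerTerm(4.0, 1.0), PowerTerm(5.0, 1.0)),
            description="fourth plus fifth powers of (X+1)",
        ),
        SchemeSpec(
            "helgaker_hf",
            nonlinear="exp_rate",
            applies_to=("HF",),
            description="three-parameter exponential for the HF energy",
        ),
        SchemeSpec(
            "helgaker_corr_x3",
            terms=(PowerTerm(3.0),),
            description="two-point X^-3 principal-expansion law",
        ),
        SchemeSpec(
            "varandas34",
            terms=(PowerTerm(3.0), PowerTerm(4.0)),
            description="third plus fourth powers of X",
        ),
        SchemeSpec(
            "varandas3_fit",
            terms=(PowerTerm(3.0, _VARANDAS_SHIFT),),
            description="two-point third power with fixed -3/8 offset",
        ),
        SchemeSpec(
            "var34_fit",
            terms=(PowerTerm(3.0), PowerTerm(4.0)),
            coupling=_VAR34_COUPLING,
            description="two-point third+fourth powers with tied coefficients",
        ),
        SchemeSpec(
            "rovibi34",
            terms=(PowerTerm(3.0), PowerTerm(4.0, 0.5)),
            description="X^-3 principal term plus (X+1/2)^-4 angular-momentum term",
        ),
        SchemeSpec(
            "rovibi45",
            terms=(PowerTerm(4.0, 0.5), PowerTerm(5.0, 0.5)),
            description="(X+1/2)^-4 plus (X+1/2)^-5 shifted powers",
        ),
    ]
    return {s.id: s for s in specs}


SCHEMES: dict = _registry()


def get_scheme(scheme_id: str) -> SchemeSpec:
    try:
        return SCHEMES[scheme_id]
    except KeyError:
        raise ValueError(
            f"unknown scheme {scheme_id!r}; registered: {sorted(SCHEMES)}"
        ) from None


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_PARAM_NAMES = "ABCD"


def _design_matrix(scheme: SchemeSpec, X: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(X, dtype=float)]
    if scheme.coupling is not None:
        t1, t2 = scheme.terms
        cols.append(t1(X) + scheme.coupling * t2(X))
    else:
        for t in scheme.terms:
            cols.append(t(X))
    return np.column_stack(cols)


def _linear_fit(scheme: SchemeSpec, X: np.ndarray, E: np.ndarray):
    M = _design_matrix(scheme, X)
    if M.shape[0] == M.shape[1]:
        coef = np.linalg.solve(M, E)
        mode = "exact-solve"
    else:
        coef, *_ = np.linalg.lstsq(M, E, rcond=None)
        mode = "least-squares"
    resid = E - M @ coef
    return coef, resid, mode


def _profiled_sse(g: Callable[[np.ndarray], np.ndarray], X, E):
    """Solve the linear subproblem E ~ c0 + c1*g(X) and return (sse, c0, c1, resid)."""
    M = np.column_stack([np.ones_like(X), g(X)])
    coef, *_ = np.linalg.lstsq(M, E, rcond=None)
    resid = E - M @ coef
    return float(resid @ resid), coef[0], coef[1], resid

def _ratio_equation(g, X, E):
    """f(theta)=0 condition matching the first three points exactly."""
    num = E[0] - E[1]
    den = E[1] - E[2]

    def f(theta):
        gx = g(theta)
        return num * (gx[1] - gx[2]) - den * (gx[0] - gx[1])

    return f


def _fit_nonlinear(scheme: SchemeSpec, X: np.ndarray, E: np.ndarray):
    """Profiled 1D fit of the exponential rate or free power exponent.

    Deterministic: three-point closed-form/bracketed-root initialisation,
    then (for over-determined input) a bounded scalar minimisation of the
    profiled sum of squares.
    """
    if scheme.nonlinear == "exp_rate":
        def make_g(theta):
            return lambda x: np.exp(-theta * np.asarray(x, dtype=float))
        lo, hi = 1e-8, 80.0
    else:  # power_exponent
        def make_g(theta):
            return lambda x: (np.asarray(x, dtype=float) + scheme.nl_shift) ** (-theta)
        lo, hi = 1e-3, 60.0

    exact = len(X) == 3
    # Bracket a root of the three-point ratio equation for initialisation.
    f = _ratio_equation(lambda th: make_g(th)(X[:3]), X, E)
    theta0 = None
    grid = np.geomspace(lo, hi, 400)
    vals = np.array([f(t) for t in grid])
    sign = np.sign(vals)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if idx.size:
        a, b = grid[idx[0]], grid[idx[0] + 1]
        theta0 = optimize.brentq(f, a, b, xtol=1e-14, rtol=8.9e-16, maxiter=500)

    if exact and theta0 is not None:
        sse, c0, c1, resid = _profiled_sse(make_g(theta0), X, E)
        return theta0, c0, c1, resid, "exact-solve", True

    # Over-determined (or no exact root): minimise the profiled objective,
    # localised around the best available starting value.
    def obj(theta):
        return _profiled_sse(make_g(theta), X, E)[0]

    sses = np.array([obj(t) for t in grid])
    theta_grid = float(grid[int(np.argmin(sses))])
    if theta0 is None or obj(theta_grid) < obj(theta0):
        theta0 = theta_grid
    res = optimize.minimize_scalar(
        obj,
        bounds=(max(lo, theta0 / 4.0), min(hi, theta0 * 4.0)),
        method="bounded",
        options={"xatol": 1e-13, "maxiter": 500},
    )
    theta = float(res.x) if res.x is not None else theta0
    if obj(theta0) < obj(theta):
        theta = theta0
    sse, c0, c1, resid = _profiled_sse(make_g(theta), X, E)
    converged = bool(res.success)
    return theta, c0, c1, resid, "least-squares", converged


def extrapolate(
    points: Sequence[tuple], scheme: SchemeSpec | str, component: str = "corr"
) -> ExtrapolationResult:
    """Fit one extrapolation law to an (X, energy) cardinal sequence.

    Parameters
    ----------
    points
        Sequence of ``(X, energy)`` pairs sorted by strictly increasing X.
    scheme
        A :class:`SchemeSpec` or registered scheme id.
    component
        ``"HF"``, ``"corr"`` or ``"total"``; checked against the scheme's
        applicability.

    Returns
    -------
    ExtrapolationResult
        CBS estimate, per-scheme parameter values and residuals.  With as
        many points as free parameters the law is solved exactly
        (residuals below 1e-10 relative); with more points a least-squares
        fit is returned.
    """
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    if component not in COMPONENTS:
        raise ValueError(f"component must be one of {COMPONENTS}")
    if component not in scheme.applies_to:
        raise ValueError(
            f"scheme {scheme.id!r} applies to {scheme.applies_to}, not {component!r}"
        )
    pts = [(float(x), float(e)) for x, e in points]
    X = np.array([p[0] for p in pts])
    E = np.array([p[1] for p in pts])
    if len(pts) < scheme.min_points:
        raise ValueError(
            f"insufficient points: scheme {scheme.id!r} needs >= {scheme.min_points}, got {len(pts)}"
        )
    if np.any(np.diff(X) == 0):
        raise ValueError("degenerate abscissa: duplicate X values")
    if np.any(np.diff(X) < 0):
        raise ValueError("points must be sorted by strictly increasing X")

    # Degenerate constant series: every scheme returns the common value.
    if np.ptp(E) == 0.0:
        e0 = float(E[0])
        params = {"E_CBS": e0}
        if scheme.is_linear:
            n_amp = 1 if scheme.coupling is not None else len(scheme.terms)
            for k in range(n_amp):
                params[_PARAM_NAMES[k]] = 0.0
            mode = "exact-solve" if len(pts) == scheme.n_free else "least-squares"
        else:
            params["A"] = 0.0
            params["B" if scheme.nonlinear == "exp_rate" else "alpha"] = 1.0
            mode = "exact-solve" if len(pts) == scheme.n_free else "least-squares"
        return ExtrapolationResult(
            scheme.id, e0, params, np.zeros_like(E), pts, mode
        )

    if scheme.is_linear:
        coef, resid, mode = _linear_fit(scheme, X, E)
        params = {"E_CBS": float(coef[0])}
        for k, c in enumerate(coef[1:]):
            params[_PARAM_NAMES[k]] = float(c)
        return ExtrapolationResult(scheme.id, float(coef[0]), params, resid, pts, mode)

    theta, c0, c1, resid, mode, converged = _fit_nonlinear(scheme, X, E)
    if not converged and np.max(np.abs(resid)) > 1e-6 * max(1.0, float(np.max(np.abs(E)))):
        raise RuntimeError(
            f"fit failed: nonlinear fit of scheme {scheme.id!r} did not converge "
            f"(theta={theta:.6g}, max residual={np.max(np.abs(resid)):.3g})"
        )
    theta_name = "B" if scheme.nonlinear == "exp_rate" else "alpha"
    params = {"E_CBS": float(c0), "A": float(c1), theta_name: float(theta)}
    return ExtrapolationResult(
        scheme.id, float(c0), params, resid, pts, mode, converged=converged
    )


# ---------------------------------------------------------------------------
# Generic shifted-power family
# ---------------------------------------------------------------------------

DEFAULT_SHIFTS = (-1.0, -0.5, 0.0, 0.5)


def _shift_tag(s: float) -> str:
    return ("m" if s < 0 else "p") + f"{abs(s):g}".replace(".", "_") if s else "0"


def enumerate_generic_family(
    alphas: Iterable[float],
    betas: Iterable[float] = (),
    shifts: Iterable[float] = DEFAULT_SHIFTS,
) -> list:
    """Enumerate single- and two-power extrapolation laws.

    One single-power spec ``E_CBS + A*(X+s)^-alpha`` per (alpha, s) and one
    two-power spec ``E_CBS + A*(X+s_a)^-alpha + B*(X+s_b)^-beta`` per
    ``alpha < beta`` pair and shift combination, deduplicated by functional
    form.  Every returned spec is fittable with :func:`extrapolate`.
    """
    alphas = sorted(set(float(a) for a in alphas))
    betas = sorted(set(float(b) for b in betas))
    shifts = sorted(set(float(s) for s in shifts))
    if not alphas:
        raise ValueError("empty family: at least one alpha is required")
    if not shifts:
        raise ValueError("empty family: at least one shift is required")

    seen = set()
    out = []
    for a in alphas:
        for s in shifts:
            key = (("p", a, s),)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                SchemeSpec(
                    f"gen_{a:g}{_shift_tag(s)}",
                    terms=(PowerTerm(a, s),),
                    description=f"generic single power {PowerTerm(a, s).label()}",
                )
            )
    exps = sorted(set(alphas) | set(betas))
    for a in exps:
        for b in exps:
            if not (a < b):
                continue
            if a not in alphas or b not in betas:
                continue
            for sa in shifts:
                for sb in shifts:
                    key = (("p", a, sa), ("p", b, sb))
                    if key in seen:
                        continue
                    seen.add(key)
                    out.append(
                        SchemeSpec(
                            f"gen_{a:g}{_shift_tag(sa)}_{b:g}{_shift_tag(sb)}",
                            terms=(PowerTerm(a, sa), PowerTerm(b, sb)),
                            description=(
                                "generic double power "
                                f"{PowerTerm(a, sa).label()} + {PowerTerm(b, sb).label()}"
                            ),
                        )
                    )
    return out


def interpolation_error(result: ExtrapolationResult) -> float:
    """Mean absolute residual of a fit over its own points (input unit)."""
    r = np.asarray(result.residuals, dtype=float)
    if r.size == 0:
        raise ValueError("result carries no residuals")
    return float(np.mean(np.abs(r)))
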