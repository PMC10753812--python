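"""Deterministic, seeded generators for every input the package consumes.

Cardinal-number energy sequences with known CBS limits, dimer/monomer/ghost
energy sets with controllable BSSE and BSIE, virtual-space partial-sum
series obeying the 1/n law, and Gaussian model charges.  The same
configuration always produces bit-identical output (NumPy's PCG64
generator under a fixed integer seed), and seeds are recorded in the
outputs for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .counterpoise import DimerEnergySet
from .pw_converge import VirtualSeries
from .schemes import SCHEMES, SchemeSpec, get_scheme

__all__ = [
    "GeneratorConfig",
    "gen_cardinal_series",
    "gen_dimer_set",
    "gen_virtual_series",
    "gen_gaussian_charges",
]


@dataclass
class GeneratorConfig:
    """Shared knobs of the synthetic generators.

    ``noise_sd`` is the Gaussian noise scale in the generated unit (0 for
    noise-free data); ``heavy_tails`` switches the noise to Student-t with
    3 degrees of freedom for robustness checks.
    """

    seed: int = 0
    noise_sd: float = 0.0
    heavy_tails: bool = False

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def noise(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.noise_sd == 0.0:
            return np.zeros(n)
        if self.heavy_tails:
            return self.noise_sd * rng.standard_t(df=3, size=n)
        return self.noise_sd * rng.standard_normal(n)


def _evaluate_scheme(scheme: SchemeSpec, params: dict, X: np.ndarray) -> np.ndarray:
    e = np.full(X.shape, float(params["E_CBS"]))
    if scheme.nonlinear == "exp_rate":
        e += params["A"] * np.exp(-params["B"] * X)
    elif scheme.nonlinear == "power_exponent":
        e += params["A"] * (X + scheme.nl_shift) ** (-params["alpha"])
    elif scheme.coupling is not None:
        t1, t2 = scheme.terms
        e += params["A"] * (t1(X) + scheme.coupling * t2(X))
    else:
        names = "ABCD"
        for k, t in enumerate(scheme.terms):
            e += params[names[k]] * t(X)
    return e


def gen_cardinal_series(
    config: GeneratorConfig,
    scheme: str | SchemeSpec,
    params: dict,
    X: Sequence[int] = (2, 3, 4, 5),
) -> list:
    """(X, energy) points drawn from a registered scheme's own law.

    With ``noise_sd=0`` the series round-trips: fitting the same scheme
    recovers ``params['E_CBS']`` exactly at exact-solve point counts.
    """
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    Xa = np.asarray(sorted(X), dtype=float)
    e = _evaluate_scheme(scheme, params, Xa)
    e = e + config.noise(config.rng(), Xa.size)
    return [(int(x), float(v)) for x, v in zip(Xa, e)]


def gen_dimer_set(
    config: GeneratorConfig,
    true_interaction: float = -3.0,
    bsse: float = 0.1,
    bsie: float = 0.0,
    unit: str = "kcal/mol",
) -> tuple:
    """A dimer/monomer/ghost energy set with known error structure.

    The ghost-basis monomer energies sit below the own-basis ones by the
    BSSE magnitude (split evenly between the fragments), and the dimer
    energy carries the basis-set incompleteness error ``bsie`` on top of
    the true interaction.  Returns ``(DimerEnergySet, truth)`` where
    ``truth`` maps 'true_interaction'/'bsse'/'bsie' to the planted values.
    With ``bsie = 0`` the CP-corrected interaction energy recovers the
    truth exactly.
    """
    if bsse < 0 or bsie < 0:
        raise ValueError("BSSE and BSIE magnitudes must be non-negative")
    rng = config.rng()
    # arbitrary but reproducible monomer baselines
    e_a = -10.0 + config.noise(rng, 1)[0]
    e_b = -12.0 + config.noise(rng, 1)[0]
    e_a_ghost = e_a - 0.5 * bsse
    e_b_ghost = e_b - 0.5 * bsse
    e_ab = e_a_ghost + e_b_ghost + true_interaction + bsie
    s = DimerEnergySet(e_ab, e_a, e_b, e_a_ghost, e_b_ghost, unit=unit)
    truth = {
        "true_interaction": true_interaction,
        "bsse": bsse,
        "bsie": bsie,
        "seed": config.seed,
    }
    return s, truth


def gen_virtual_series(
    config: GeneratorConfig,
    alpha: float = -10.0,
    beta: float = 5.0,
    n: Sequence[int] | None = None,
    eps_schedule=None,
    unit: str = "kcal/mol",
) -> VirtualSeries:
    """A partial-sum series alpha + beta/n (plus seeded noise).

    ``eps_schedule`` maps n to the eigenvalue abscissa; default
    eps_n = n^(2/3), for which the eigenvalue abscissa eps^(-3/2) equals
    1/n and both fitting modes agree exactly.
    """
    if n is None:
        n = np.arange(100, 1001, 100)
    n = np.asarray(sorted(n), dtype=float)
    eps = (
        np.asarray([eps_schedule(v) for v in n], dtype=float)
        if eps_schedule is not None
        else n ** (2.0 / 3.0)
    )
    e = alpha + beta / n + config.noise(config.rng(), n.size)
    return VirtualSeries(n, e, eps, unit=unit)


def gen_gaussian_charges(
    config: GeneratorConfig,
    sigma: float = 1.0,
    separation: float = 4.0,
    jitter: float = 0.0,
) -> dict:
    """Parameters of a two-Gaussian charge fixture along the x axis.

    Returns widths and centers (bohr) for a pair of unit charges centred
    on the origin at the requested separation, with optional seeded
    positional jitter.
    """
    rng = config.rng()
    half = 0.5 * separation
    centers = np.array([[-half, 0.0, 0.0], [half, 0.0, 0.0]])
    if jitter:
        centers = centers + jitter * rng.standard_normal(centers.shape)
    return {
        "sigma": float(sigma),
        "centers": centers,
        "separation": float(np.linalg.norm(centers[1] - centers[0])),
        "seed": config.seed,
    }
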