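"""Extrapolation-law registry and fitting engine."""

import numpy as np
import pytest

from cbslab import schemes
from cbslab.schemes import (
    SCHEMES,
    EnergyRecord,
    enumerate_generic_family,
    extrapolate,
    get_scheme,
    interpolation_error,
)
from cbslab.synth import GeneratorConfig, gen_cardinal_series

TRUE_PARAMS = {"E_CBS": -76.3, "A": 0.8, "B": 0.9, "alpha": 3.7}


def _exact_points(spec, e_cbs=-76.3):
    params = dict(TRUE_PARAMS, E_CBS=e_cbs)
    if spec.nonlinear == "exp_rate":
        params["B"] = 0.9
    X = list(range(2, 2 + spec.min_points))
    return gen_cardinal_series(GeneratorConfig(), spec, params, X=X), params


@pytest.mark.parametrize("scheme_id", sorted(SCHEMES))
def test_round_trip_recovers_cbs_limit(scheme_id):
    """Noise-free data from a scheme's own law returns its planted limit."""
    spec = get_scheme(scheme_id)
    pts, params = _exact_points(spec)
    res = extrapolate(pts, spec, component=spec.applies_to[0])
    assert abs(res.e_cbs - params["E_CBS"]) <= 1e-9 * max(1.0, abs(params["E_CBS"]))
    assert np.max(np.abs(res.residuals)) <= 1e-10 * max(1.0, abs(params["E_CBS"]))
    assert np.isfinite(res.e_cbs)


@pytest.mark.parametrize("scheme_id", sorted(SCHEMES))
def test_translation_equivariance(scheme_id):
    """Adding a constant to all energies adds exactly that constant to E_CBS."""
    spec = get_scheme(scheme_id)
    pts, _ = _exact_points(spec)
    comp = spec.applies_to[0]
    base = extrapolate(pts, spec, component=comp).e_cbs
    c = 13.625
    shifted = extrapolate([(x, e + c) for x, e in pts], spec, component=comp).e_cbs
    assert shifted - base == pytest.approx(c, abs=1e-9)


@pytest.mark.parametrize("scheme_id", sorted(SCHEMES))
def test_constant_series_degenerate_limit(scheme_id):
    """A flat series returns the common value with zero correction amplitude."""
    spec = get_scheme(scheme_id)
    X = list(range(2, 2 + spec.min_points))
    res = extrapolate([(x, -76.0) for x in X], spec, component=spec.applies_to[0])
    assert res.e_cbs == -76.0
    assert res.params["A"] == 0.0
    assert np.all(res.residuals == 0.0)


def test_helgaker_two_point_closed_form():
    """The X^-3 two-point fit matches its direct algebraic solution."""
    X, Y = 3, 4
    e_x, e_y = -100 + 2 * X**-3.0, -100 + 2 * Y**-3.0
    res = extrapolate([(X, e_x), (Y, e_y)], "helgaker_corr_x3")
    closed = (Y**3 * e_y - X**3 * e_x) / (Y**3 - X**3)
    assert res.e_cbs == pytest.approx(closed, abs=1e-12)
    assert res.e_cbs == pytest.approx(-100.0, abs=1e-10)


def test_truhlar_fixed_exponent_two_point():
    pts = [(3, -50 + 1.5 * 3**-3.4), (4, -50 + 1.5 * 4**-3.4)]
    res = extrapolate(pts, "truhlar_hf", component="HF")
    assert res.e_cbs == pytest.approx(-50.0, abs=1e-10)


@pytest.mark.parametrize(
    "nonlinear_id,params",
    [("feller", {"E_CBS": -40.0, "A": 2.5, "B": 1.3}),
     ("helgaker_hf", {"E_CBS": -112.7, "A": 0.6, "B": 1.63}),
     ("martin_alpha", {"E_CBS": -55.0, "A": 1.2, "alpha": 4.4})],
)
def test_nonlinear_overdetermined_matches_grid_search(nonlinear_id, params):
    """Profiled nonlinear fits agree with an independent brute-force search."""
    spec = get_scheme(nonlinear_id)
    pts = gen_cardinal_series(GeneratorConfig(seed=3, noise_sd=1e-4), spec, params, X=[2, 3, 4, 5])
    res = extrapolate(pts, spec, component=spec.applies_to[0])
    X = np.array([p[0] for p in pts], float)
    E = np.array([p[1] for p in pts], float)

    def sse(theta):
        g = (
            np.exp(-theta * X)
            if spec.nonlinear == "exp_rate"
            else (X + spec.nl_shift) ** (-theta)
        )
        M = np.column_stack([np.ones_like(X), g])
        coef, *_ = np.linalg.lstsq(M, E, rcond=None)
        r = E - M @ coef
        return float(r @ r), coef[0]

    thetas = np.linspace(0.2, 8.0, 4001)
    for _ in range(4):  # refine the grid search around its best point
        vals = [sse(t)[0] for t in thetas]
        t_best = thetas[int(np.argmin(vals))]
        span = thetas[1] - thetas[0]
        thetas = np.linspace(t_best - span, t_best + span, 401)
    best = sse(t_best)[1]
    assert res.e_cbs == pytest.approx(best, abs=1e-6)


def test_linear_overdetermined_matches_lstsq_oracle():
    """Least-squares fits on 4 points agree with an independent normal-equation solve."""
    rng = np.random.default_rng(11)
    for _ in range(10):
        e_cbs = float(rng.normal(-80, 10))
        a = float(rng.normal(0, 2))
        X = np.array([2.0, 3.0, 4.0, 5.0])
        E = e_cbs + a * X**-3.0 + 1e-3 * rng.standard_normal(4)
        res = extrapolate(list(zip(X, E)), "helgaker_corr_x3")
        M = np.column_stack([np.ones_like(X), X**-3.0])
        oracle = np.linalg.inv(M.T @ M) @ (M.T @ E)
        assert res.e_cbs == pytest.approx(float(oracle[0]), abs=1e-6)
        assert res.fit_mode == "least-squares"


@pytest.mark.parametrize("scheme_id", [s for s in sorted(SCHEMES) if SCHEMES[s].is_linear])
def test_difference_additivity_linear_schemes(scheme_id):
    """Extrapolating subsystems then differencing equals extrapolating differences."""
    spec = get_scheme(scheme_id)
    comp = spec.applies_to[0]
    X = list(range(2, 2 + spec.min_points))
    dimer, _ = _exact_points(spec, e_cbs=-150.0)
    mono, _ = _exact_points(spec, e_cbs=-75.2)
    # perturb the monomer series off the exact law; exact-solve still interpolates
    mono = [(x, e + 0.01 * x) for x, e in mono]
    diff = [(x, ed - em) for (x, ed), (_, em) in zip(dimer, mono)]
    e_sep = (
        extrapolate(dimer, spec, component=comp).e_cbs
        - extrapolate(mono, spec, component=comp).e_cbs
    )
    e_joint = extrapolate(diff, spec, component=comp).e_cbs
    assert e_joint == pytest.approx(e_sep, abs=1e-8)


class TestValidation:
    def test_insufficient_points(self):
        with pytest.raises(ValueError, match="insufficient points"):
            extrapolate([(3, -1.0)], "helgaker_corr_x3")

    def test_duplicate_abscissa(self):
        with pytest.raises(ValueError, match="degenerate abscissa"):
            extrapolate([(3, -1.0), (3, -1.1), (4, -1.2)], "wilson35")

    def test_unsorted_points(self):
        with pytest.raises(ValueError, match="increasing X"):
            extrapolate([(4, -1.0), (3, -1.1)], "helgaker_corr_x3")

    def test_component_mismatch(self):
        with pytest.raises(ValueError, match="applies to"):
            extrapolate([(3, -1.0), (4, -1.1)], "truhlar_hf", component="corr")

    def test_unknown_scheme(self):
        with pytest.raises(ValueError, match="unknown scheme"):
            get_scheme("nope")

    def test_energy_record_validation(self):
        with pytest.raises(ValueError, match="X must be"):
            EnergyRecord("s", "dimer", "cc", 6, "corr", "own_basis", -1.0)


class TestGenericFamily:
    def test_single_power_identity_with_x3_law(self):
        fam = enumerate_generic_family({3}, set(), {0})
        assert len(fam) == 1
        pts = [(3, -100 + 2 * 3**-3.0), (4, -100 + 2 * 4**-3.0)]
        assert extrapolate(pts, fam[0]).e_cbs == pytest.approx(
            extrapolate(pts, "helgaker_corr_x3").e_cbs, abs=1e-12
        )

    def test_combinatorial_count(self):
        fam = enumerate_generic_family({3, 4, 5, 6}, {3, 4, 5, 6}, {0})
        assert len(fam) == 10  # 4 single + 6 double

    def test_contains_rovibi34_equivalent(self):
        fam = enumerate_generic_family({3, 4}, {4}, {0, 0.5})
        rv = get_scheme("rovibi34")
        twins = [f for f in fam if f.terms == rv.terms]
        assert len(twins) == 1
        pts = [(2, -10.3), (3, -10.8), (4, -10.95)]
        assert extrapolate(pts, twins[0]).e_cbs == pytest.approx(
            extrapolate(pts, rv).e_cbs, abs=1e-10
        )

    def test_deduplication_and_errors(self):
        fam = enumerate_generic_family({3, 4}, {4}, {0})
        assert len({f.id for f in fam}) == len(fam)
        with pytest.raises(ValueError, match="empty family"):
            enumerate_generic_family(set())


class TestInterpolationError:
    def test_exact_solve_is_zero(self):
        pts, _ = _exact_points(get_scheme("wilson35"))
        res = extrapolate(pts, "wilson35")
        assert interpolation_error(res) == pytest.approx(0.0, abs=1e-10)

    def test_injected_residuals(self):
        res = extrapolate([(2, -1.0), (3, -2.0), (4, -2.5), (5, -2.7)], "helgaker_corr_x3")
        res.residuals = np.array([0.2, -0.2, 0.2, -0.2])
        assert interpolation_error(res) == pytest.approx(0.2)

    def test_model_mismatch_matches_refit_oracle(self):
        """Fitting X^-3 to X^-4 data leaves the oracle's least-squares MAE."""
        X = np.array([2.0, 3.0, 4.0, 5.0])
        E = -10.0 + 3.0 * X**-4.0
        res = extrapolate(list(zip(X, E)), "helgaker_corr_x3")
        M = np.column_stack([np.ones_like(X), X**-3.0])
        coef, *_ = np.linalg.lstsq(M, E, rcond=None)
        oracle_mae = float(np.mean(np.abs(E - M @ coef)))
        assert interpolation_error(res) > 0
        assert interpolation_error(res) == pytest.approx(oracle_mae, abs=1e-12)
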