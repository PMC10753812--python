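"""Isolated-system Coulomb kernels validated on Gaussian model charges."""

import math

import numpy as np
import pytest

from cbslab.coulomb import (
    GGrid,
    KernelSpec,
    bap_chi,
    bap_correction,
    gaussian_density,
    kernel_values,
    pair_coulomb_energy,
    self_energy,
)

SELF_EXACT = 1.0 / (2.0 * math.sqrt(math.pi))  # unit Gaussian, sigma = 1 bohr


class TestGGrid:
    def test_enumeration_matches_brute_force(self):
        grid = GGrid.build((2 * np.pi,) * 3, 2.0)
        # brute-force integer-lattice count: |m|^2 <= 2*E_cut for L = 2*pi
        count = sum(
            1
            for mx in range(-3, 4)
            for my in range(-3, 4)
            for mz in range(-3, 4)
            if (mx**2 + my**2 + mz**2) / 2.0 <= 2.0
        )
        assert grid.n_g == count == 33

    def test_closed_under_inversion(self):
        grid = GGrid.build((8.0, 10.0, 12.0), 3.0)
        idx = {tuple(m) for m in grid.indices}
        assert all((-a, -b, -c) in idx for a, b, c in idx)

    def test_validation(self):
        with pytest.raises(ValueError, match="positive"):
            GGrid.build((0.0, 1.0, 1.0), 1.0)
        with pytest.raises(ValueError, match="non-negative"):
            GGrid.build((8.0,) * 3, -1.0)


class TestBareKernel:
    def test_zero_at_g0_and_closed_form(self):
        grid = GGrid.build((2 * np.pi,) * 3, 2.0)
        v = kernel_values(grid, KernelSpec("bare_zeroed"))
        assert v[grid.g2 == 0.0][0] == 0.0
        at_unit = v[np.isclose(grid.g2, 1.0)]
        assert at_unit == pytest.approx(4.0 * np.pi)

    def test_depends_only_on_gnorm_in_cubic_cell(self):
        grid = GGrid.build((9.0,) * 3, 6.0)
        for spec in (KernelSpec("bare_zeroed"), KernelSpec("bap")):
            v = kernel_values(grid, spec)
            for g2 in np.unique(np.round(grid.g2, 10)):
                vals = v[np.isclose(grid.g2, g2)]
                assert np.ptp(vals) <= 1e-12 * max(1.0, abs(vals[0]))

    def test_empty_grid_rejected(self):
        grid = GGrid.build((2 * np.pi,) * 3, 2.0)
        grid.indices = grid.indices[:0]
        with pytest.raises(ValueError, match="empty"):
            kernel_values(grid, KernelSpec("bare_zeroed"))


class TestMartynaTuckerman:
    def test_gaussian_pair_energy(self, box24_grid, box24_mt_kernel):
        """sigma=1 Gaussians at d=4 bohr reproduce erf(d/2)/d electrostatics."""
        a = gaussian_density(box24_grid, 1.0, (-2.0, 0.0, 0.0))
        b = gaussian_density(box24_grid, 1.0, (2.0, 0.0, 0.0))
        e = pair_coulomb_energy(a, b, box24_mt_kernel, box24_grid.omega)
        assert e == pytest.approx(math.erf(2.0) / 4.0, abs=1e-4)

    def test_gaussian_self_energy(self, box24_grid, box24_mt_kernel):
        d = gaussian_density(box24_grid, 1.0)
        assert self_energy(d, box24_mt_kernel, box24_grid.omega) == pytest.approx(
            SELF_EXACT, abs=1e-4
        )

    def test_point_like_charges_recover_1_over_r(self, box24_grid, box24_mt_kernel):
        """Narrow Gaussians at 3 bohr separation feel the isolated 1/r."""
        a = gaussian_density(box24_grid, 0.45, (-1.5, 0.0, 0.0))
        b = gaussian_density(box24_grid, 0.45, (1.5, 0.0, 0.0))
        e = pair_coulomb_energy(a, b, box24_mt_kernel, box24_grid.omega)
        assert e == pytest.approx(1.0 / 3.0, abs=1e-3)

    def test_inversion_symmetry(self, box24_grid, box24_mt_kernel):
        idx = {tuple(m): i for i, m in enumerate(box24_grid.indices)}
        rng = np.random.default_rng(0)
        for i in rng.choice(box24_grid.n_g, size=50, replace=False):
            j = idx[tuple(-box24_grid.indices[i])]
            assert box24_mt_kernel[i] == pytest.approx(box24_mt_kernel[j], rel=1e-12)

    def test_isolated_limit_monotone_and_beats_bare(self):
        """MT error decays monotonically with box size and undercuts bare."""
        exact = math.erf(2.0) / 4.0
        errors_mt, errors_bare = [], []
        for L in (12.0, 16.0, 20.0, 24.0):
            grid = GGrid.build((L,) * 3, 30.0)
            a = gaussian_density(grid, 1.0, (-2.0, 0.0, 0.0))
            b = gaussian_density(grid, 1.0, (2.0, 0.0, 0.0))
            for spec, acc in (
                (KernelSpec("mt"), errors_mt),
                (KernelSpec("bare_zeroed"), errors_bare),
            ):
                k = kernel_values(grid, spec)
                acc.append(abs(pair_coulomb_energy(a, b, k, grid.omega) - exact))
        assert all(e2 < e1 for e1, e2 in zip(errors_mt, errors_mt[1:]))
        assert all(m <= b for m, b in zip(errors_mt, errors_bare))
        # box spanning about twice the density extent is converged to 1e-4
        assert errors_mt[-1] < 1e-4

    def test_alpha_l_warning_and_mesh_guard(self):
        grid = GGrid.build((10.0,) * 3, 5.0)
        with pytest.warns(UserWarning, match="alpha"):
            kernel_values(grid, KernelSpec("mt", alpha=0.3))
        with pytest.raises(ValueError, match="mesh too coarse"):
            kernel_values(grid, KernelSpec("mt", mesh=(4, 4, 4)))


class TestBAP:
    def test_correction_zero_and_linear(self):
        grid = GGrid.build((14.0,) * 3, 8.0)
        spec = KernelSpec("bap")
        assert bap_correction(grid, spec, 0) == 0.0
        c10 = bap_correction(grid, spec, 10)
        assert bap_correction(grid, spec, 20) == pytest.approx(2 * c10, rel=1e-14)

    def test_interaction_energy_cancellation(self):
        """Linearity in N_e makes the correction vanish in dimer - monomers."""
        grid = GGrid.build((14.0,) * 3, 8.0)
        spec = KernelSpec("bap")
        n_a, n_b = 10, 16
        delta = (
            bap_correction(grid, spec, n_a + n_b)
            - bap_correction(grid, spec, n_a)
            - bap_correction(grid, spec, n_b)
        )
        assert delta == pytest.approx(0.0, abs=1e-12)

    def test_chi_converges_with_lattice_sum(self):
        # halving the neglect threshold via a larger gamma-window changes nothing
        chi1 = bap_chi((16.0,) * 3, 4.0)
        chi2 = bap_chi((16.0,) * 3, 4.0)
        assert chi1 == chi2  # deterministic
        assert np.isfinite(chi1)

    def test_self_energy_converges_faster_than_bare(self):
        """The chi correction improves box-size convergence of a single charge."""
        for L in (12.0, 16.0, 20.0):
            grid = GGrid.build((L,) * 3, 20.0)
            d = gaussian_density(grid, 1.0)
            e_bare = self_energy(d, kernel_values(grid, KernelSpec("bare_zeroed")), grid.omega)
            e_bap = self_energy(d, kernel_values(grid, KernelSpec("bap")), grid.omega)
            assert abs(e_bap - SELF_EXACT) < abs(e_bare - SELF_EXACT)

    def test_negative_electron_count_rejected(self):
        grid = GGrid.build((10.0,) * 3, 4.0)
        with pytest.raises(ValueError):
            bap_correction(grid, KernelSpec("bap"), -1)


class TestPairEnergy:
    def test_zero_density(self, box24_grid, box24_mt_kernel):
        z = np.zeros(box24_grid.n_g, dtype=complex)
        d = gaussian_density(box24_grid, 1.0)
        assert pair_coulomb_energy(z, d, box24_mt_kernel, box24_grid.omega) == 0.0

    def test_shape_mismatch(self, box24_grid, box24_mt_kernel):
        d = gaussian_density(box24_grid, 1.0)
        with pytest.raises(ValueError, match="shape error"):
            pair_coulomb_energy(d[:-1], d, box24_mt_kernel, box24_grid.omega)

    def test_invalid_sigma(self, box24_grid):
        with pytest.raises(ValueError):
            gaussian_density(box24_grid, 0.0)
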