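# Methods

This note records the models implemented in `cbslab`, their assumptions,
the defaults that matter, and the design choices made where the design
was genuinely open.  It states no empirical result that the test suite
and `scripts/acceptance.py` do not themselves compute.

## Extrapolation laws (`cbslab.schemes`)

A CBS extrapolation law models a cardinal-number energy sequence as a
constant plus decaying corrections,

    E(X) = E_CBS + sum_k c_k * g_k(X),

with `g_k` either shifted inverse powers `(X + s)^-alpha` or
exponentials.  The registry holds the sixteen named laws:

| id | form | free parameters |
| --- | --- | --- |
| `feller` | E + A·exp(−B·X) | 3 |
| `peterson` | E + A·exp(−(X−1)) + B·exp(−(X−1)²) | 3 |
| `truhlar_hf` | E + A·X^−3.4 (HF only) | 2 |
| `truhlar_corr` | E + A·X^−2.2 | 2 |
| `martin4` | E + A·(X+1/2)^−4 | 2 |
| `martin46` | E + A·(X+1/2)^−4 + B·(X+1/2)^−6 | 3 |
| `martin_alpha` | E + A·(X+1/2)^−α, α free | 3 |
| `wilson35` | E + A·X^−3 + B·X^−5 | 3 |
| `wilson45` | E + A·(X+1)^−4 + B·(X+1)^−5 | 3 |
| `helgaker_hf` | E + A·exp(−B·X) (HF only) | 3 |
| `helgaker_corr_x3` | E + A·X^−3 | 2 |
| `varandas34` | E + A·X^−3 + B·X^−4 | 3 |
| `varandas3_fit` | E + A·(X−3/8)^−3 | 2 |
| `var34_fit` | E + A·(X^−3 + κ·X^−4), κ fixed | 2 |
| `rovibi34` | E + A·X^−3 + B·(X+1/2)^−4 | 3 |
| `rovibi45` | E + A·(X+1/2)^−4 + B·(X+1/2)^−5 | 3 |

The Truhlar exponents 3.4 (HF) and 2.2 (correlation) are the published
calibration against explicitly correlated references and are kept fixed,
which is what makes those laws usable with two points.  The `wilson35` /
`wilson45` forms are the two constrained cases of the three-term ansatz
`E + A(X+D)^-a + B(X+D)^-(a+1) + C(X+D)^-(a+2)` with (a=3, B=0, D=0) and
(a=4, C=0, D=1) respectively, i.e. power pairs 3/5 and 4/5.  `rovibi34`
combines the principal-expansion X^−3 term (no shift: the principal
quantum number drives the decay) with an angular-momentum-type
(X+1/2)^−4 term whose half-integer shift averages the highest angular
momentum over hydrogen (L = X−1) and first-row (L = X) atoms; `rovibi45`
adds a fifth-order term to the shifted fourth power instead.  Where the
published sources disagree on details of the Varandas family, this
package fixes: `varandas34` as the general third-plus-fourth-order form,
`varandas3_fit` as a third-power law with the −3/8 cardinal offset, and
`var34_fit` with the X^−4 coefficient tied to the X^−3 one by a fixed
ratio κ (default 1.0, configurable at registry level), which is what
reduces it to a two-point scheme.  These are package choices, stated
here so nobody mistakes them for uniquely determined forms.

**Fitting.**  All power-form laws (and `peterson`, whose exponents are
fixed) are linear in their parameters: with as many points as free
parameters the linear system is solved exactly (`numpy.linalg.solve`,
residuals at rounding level), otherwise by least squares.  `feller`,
`helgaker_hf` and `martin_alpha` carry one genuinely nonlinear parameter
(decay rate or exponent); it is profiled out — for a trial value the
remaining two parameters are solved linearly — and determined by a
bracketed root of the three-point ratio equation (exact interpolation)
or, for over-determined input, a bounded scalar minimisation localised
around that root (objective tolerance 1e-12, max 500 iterations, no
random restarts: fits are deterministic).  Degenerate inputs: a constant
series returns the common value with zero amplitudes for every law;
duplicate cardinal numbers are an input error, never averaged.

Fitting is unit-agnostic; records carry an explicit unit and conversion
uses 1 hartree = 627.5094740631 kcal/mol = 2 Ry.  Component routing
follows the applicability tags: exponential laws for HF, power laws for
correlation; "total" accepts the correlation-type laws.

The generic family enumerator produces every single power `(X+s)^-a` and
ordered double power `a < b` over requested exponents (3–6 by default
usage) and shifts; the default shift grid {−1, −1/2, 0, +1/2} is a
package choice covering the shifts used by the named laws.

## Counterpoise bookkeeping (`cbslab.counterpoise`)

Interaction energies of a dimer AB: uncorrected (monomers in their own
bases), CP-corrected (monomers recomputed in the ghost-augmented dimer
basis), and the half-CP mean of the two.  Monomer geometries are assumed
frozen in their in-dimer structures, so deformation energies never
enter.  Ghost-basis energies above own-basis ones are tolerated (MP2
correlation is not variational).  Deviation statistics use type-7
(linearly interpolated) quartiles — stated explicitly because the
1.5×IQR outlier rule depends on the convention — and the maximum
deviation is reported signed (largest magnitude, original sign); an
absolute variant sits behind a flag.

## Virtual-space and volume extrapolation (`cbslab.pw_converge`)

The partial MP2 sum over the lowest n virtuals behaves asymptotically as
`E_c,n = alpha + beta/n`; the intercept of an ordinary least-squares
line against 1/n (or against eps_n^−3/2, using the dimer eigenvalues for
differenced series) is the basis-set-limit estimate.  Because the
result depends on the fitting window, `windowed_average` fits every
window ending at n_max with at least `min_points` (default 3) entries
and averages the intercepts of the windows on which the linear law
holds, reporting their standard deviation as the extrapolation spread.

**Window validity.**  The acceptance rule must pass noise-dominated but
perfectly linear tails while rejecting windows that have not reached the
asymptotic regime.  A plain r² threshold cannot do both (r² measures
signal-to-noise, not linearity), so the default criterion is: no gross
outlier (largest studentized residual ≤ 3) and no significant curvature
(t statistic of an added quadratic term ≤ 3 on windows of ≥ 4 points;
3-point windows, where curvature is not testable, fall back to
r² ≥ 0.99).  Numerically exact lines always pass.  All three thresholds
are configurable.

Supercell-volume series are extrapolated linearly in 1/Omega — the
first-order finite-size correction — with the exponent configurable.

## Coulomb kernels for isolated systems (`cbslab.coulomb`)

Densities are dimensionless Fourier coefficients
`rho(G) = ∫ rho(r) e^{−iG·r} d³r`, and the pair energy is the diagonal
quadrature `(1/Omega) Σ_G conj(rho_A) Phi(G) rho_B`; the single 1/Omega
normalisation lives in that quadrature and nowhere else, and the
analytic Gaussian tests (erf(d/2σ)/d pair energy, 1/(2σ√π) self-energy)
pin the convention.

* `bare_zeroed`: 4π/G² with the G = 0 component dropped.
* `bap`: the auxiliary-function singularity correction.  With the
  Gaussian auxiliary `f(G) = 4π e^{−γG²}/G²`, the G = 0 kernel value is
  `chi = Omega/sqrt(pi*gamma) − Σ_{G≠0} f(G)` (lattice sum taken to
  e^{−40} truncation).  γ defaults to (L_min/2π)², tying the screen to
  the cell.  The induced total-energy shift, `−N_e·chi/(2·Omega)`, is
  strictly linear in the electron count and therefore cancels exactly in
  dimer-minus-monomers interaction energies.
* `mt` (Martyna-Tuckerman): after the Ewald split
  1/r = erfc(αr)/r + erf(αr)/r, the kernel is
  `4π(1 − e^{−G²/4α²})/G² + vhat_long(G)` with `vhat_long` the
  Fourier-series coefficients of erf(αr)/r over the cell
  (first-image/minimum-image convention), evaluated by FFT on a
  real-space mesh; the G = 0 limit is π/α² + vhat_long(0).  The
  splitting parameter defaults to α = 7/L_min (warning below αL = 5).
  The default mesh is the smallest power of two covering the aliasing
  floor 2·m_max+1 per dimension; on the 24-bohr test cell this already
  reproduces isolated Gaussian electrostatics to ~1e-11 hartree, and an
  `oversample` knob densifies it if needed.

Only orthorhombic (including cubic) cells are supported.

## Electron-gas MP2 simulator (`cbslab.hegmp2`)

The finite-cell homogeneous electron gas in a cubic box: Hartree-Fock
orbitals are single plane waves |G⟩, eigenvalues are |k|²/2 minus the
finite-cell exchange sum `(4π/Omega) Σ_{k'≠k occ} 1/|k−k'|²` (the
singular term excluded consistently with the bare kernel; exchange-off
kinetic spectra are kept for debugging).  Occupation is spin-restricted
closed shells only — electron counts must complete a momentum shell
(2, 14, 38, …) or construction fails.  Pair densities have exactly one
Fourier component (momentum conservation), so each two-electron integral
is one kernel value over the cell volume, and the partial sums E_c,n are
exact MP2 energies of the truncated virtual space.  Virtuals are ordered
by (eigenvalue, |m|², lexicographic index) and truncations snap to
eigenvalue-degenerate shell boundaries, making partial sums independent
of intra-shell ordering.  Everything is deterministic; energies are in
hartree, with kcal/mol left to the reporting layer.

In `cbs_demo` the smooth-series window-validity gate is deliberately
disabled: HEG partial sums step at shell closures, so every tail window
contributes and the spread of intercepts across windows is reported as
the extrapolation sigma.

## Basis counting (`cbslab.basiscount`)

Per-element contracted spherical-harmonic counts are embedded as data
(H: 5/14/30/55 cc, 9/23/46/80 aug; first row B–Ne: 14/30/55/91 cc,
23/46/80/127 aug for X = 2…5), cross-checked against the 2945-function
aug-cc-pV5Z worked example for C14H13N.  The growth law per first-row
atom is the polynomial consistent with those compositions,
`(X+1)(X+2)(2X+3)/6` for cc and `+ (X+1)²` for aug-cc (one extra diffuse
function per angular momentum) — chosen over the frequently quoted
`(X+1)(X+2)(X+3)/3`, which does not reproduce the published counts.
The plane-wave estimate is the reciprocal-space sphere volume
`Omega·(2E_cut)^{3/2}/(6π²)`; at E_cut = 0 it returns 0 while the exact
enumeration keeps the single G = 0 state (documented edge).

## Synthetic data (`cbslab.synth`)

The generators emulate the inputs the analysis consumes: cardinal
sequences drawn from a registered law's own form, dimer/monomer/ghost
energy sets with planted interaction energy, BSSE (ghost energies lowered
by half the BSSE per fragment) and BSIE, 1/n virtual series with an
eigenvalue schedule eps_n = n^{2/3} (which makes the two abscissas
coincide exactly), and Gaussian charge fixtures.  Noise is Gaussian by
default (Student-t with 3 degrees of freedom behind a flag) from NumPy's
PCG64 generator; identical configurations give bit-identical output, and
seeds are recorded in outputs.  What the generators do **not** emulate:
realistic electronic-structure noise (which is systematic, not
Gaussian), method dependence of the decay exponents, or quantitative
energetics of real noncovalent complexes — so passing tests demonstrate
the correctness of the machinery, not the accuracy of any particular
extrapolation on real molecules.

## Problem sizes and tolerances used in the tests

Scheme round-trips demand |E_CBS − truth| ≤ 1e-9 at exact-solve point
counts.  The electron-gas oracle equivalence (streamed versus quadruple
loop, ≤ 1e-12 relative) runs on all bases with at most 40 plane waves;
the convergence-law demonstration uses the 14-electron gas in a 2π-bohr
box with cutoffs of 6/8/14 hartree (179/257/619 plane waves) — sizes
chosen so the full suite completes in seconds while the 1/n tail is
already clean (last-quartile r² ≥ 0.99).  Coulomb-kernel oracles use a
24-bohr cubic cell at 30 hartree cutoff (~1e5 G vectors), where the
Martyna-Tuckerman kernel matches analytic Gaussian electrostatics to
1e-4 hartree with orders of magnitude to spare.

## Known limitations

* Only orthorhombic cells and Γ-point sampling; no surface/wire boundary
  conditions, no other Poisson solvers.
* The simulator covers closed-shell, spin-restricted MP2 of the
  homogeneous gas; no pseudopotentials, no real-molecule Hartree-Fock.
* Fixed-density volume doubling cannot keep a closed shell in a cubic
  cell (magic counts 2, 14, 38 share no factor of two), so finite-size
  consistency is checked qualitatively, not at exactly doubled volume.
* The Varandas-family and tied-coefficient forms, the generic-family
  shift grid, and the window-validity thresholds are documented package
  choices (see above), configurable where they matter.
* No uncertainty quantification on E_CBS beyond the window spread; no
  automatic scheme recommendation; no relativistic or core-correlation
  corrections.
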