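# cbslab

Complete-basis-set (CBS) convergence machinery for correlated interaction
energies, for quantum chemists comparing Gaussian-basis and plane-wave
MP2 calculations of weakly bound complexes.

Correlated energies converge painfully slowly with the one-electron basis.
On the Gaussian side, correlation-consistent (aug-)cc-pVXZ sequences
(cardinal number X = D, T, Q, 5) are extrapolated to the CBS limit with
laws of the form

    E(X) = E_CBS + A (X + s)^-alpha [+ B (X + t)^-beta]   or
    E(X) = E_CBS + A exp(-B X),

and interaction energies additionally need counterpoise (CP) bookkeeping
to remove the basis-set superposition error (BSSE).  On the plane-wave
side there is no BSSE, but the MP2 partial sum E_c,n over the lowest n
virtual orbitals approaches its limit like 1/n (equivalently like
eps_n^(-3/2)), the supercell volume Omega leaves a finite-size error
~1/Omega, and the G = 0 Coulomb singularity of an isolated system must be
screened (bare truncation, auxiliary-function correction, or the
Martyna-Tuckerman kernel).  `cbslab` implements all of these pieces as a
tested library plus CLI, together with a finite-cell homogeneous-electron-gas
(HEG) MP2 simulator whose Hartree-Fock orbitals are exact plane waves —
the desk-scale system on which every convergence law can be exercised
end to end against brute-force oracles.

## Modules

| module | contents |
| --- | --- |
| `cbslab.schemes` | registry of 16 named extrapolation laws (Feller, Peterson, Truhlar, Martin, Wilson, Helgaker, Varandas, Rovibi34/45, …), generic shifted-power family, exact-solve/least-squares fitting engine |
| `cbslab.counterpoise` | uncorrected / CP / half-CP interaction energies; MAE, signed max-dev, 1.5×IQR outlier statistics |
| `cbslab.pw_converge` | virtual-space linear extrapolation (1/n or eps^-3/2 abscissa) with multi-window averaging; 1/Omega supercell extrapolation |
| `cbslab.coulomb` | reciprocal-space Coulomb kernels for isolated systems: bare (G=0 dropped), auxiliary-function (BAP) correction, Martyna-Tuckerman |
| `cbslab.hegmp2` | Gamma-point plane-wave MP2 of the finite-cell HEG, partial sums, quadruple-loop oracle |
| `cbslab.basiscount` | (aug-)cc-pVXZ contracted-function counts, cubic growth law, plane-wave count estimate |
| `cbslab.synth` | seeded generators for every input the other modules consume |
| `cbslab.io`, `cbslab.cli` | delimited-table I/O and the `cbslab` command-line surface |

## Worked example

Extrapolating a triple-point correlation-energy sequence (hartree) with
the three-point Rovibi34 law `E_CBS + A X^-3 + B (X+1/2)^-4` and the
two-point X^-3 law:

```python
>>> from cbslab import extrapolate
>>> pts = [(2, -76.194), (3, -76.320), (4, -76.363)]
>>> res = extrapolate(pts, "rovibi34", component="corr")
>>> round(res.e_cbs, 6)
-76.415064
>>> round(extrapolate(pts[1:], "helgaker_corr_x3").e_cbs, 6)
-76.394378
```

Both estimates lie below the largest computed point (-76.363): the fits
attribute the remaining basis-set incompleteness to the X^-3/X^-4 tails
and place the CBS limit 0.03-0.05 hartree lower; with as many points as
parameters the laws interpolate the data exactly (residuals ~1e-14).

Counterpoise bookkeeping on a toy dimer (kcal/mol), with ghost-basis
monomer energies 0.05 kcal/mol below their own-basis values:

```python
>>> from cbslab import DimerEnergySet, interaction_energies
>>> e = interaction_energies(DimerEnergySet(-2.0, -0.7, -0.9, -0.75, -0.95, unit="kcal/mol"))
>>> {k: round(v, 6) for k, v in e.items()}
{'uncorr': -0.4, 'cp': -0.3, 'half_cp': -0.35}
```

The uncorrected interaction energy overbinds by 0.1 kcal/mol — exactly
the planted BSSE — and the half-CP value is the mean of the two.

The same pipelines from the shell:

```sh
cbslab simulate cardinal --seed 42 --out series.csv
cbslab extrapolate --scheme helgaker_corr_x3 --in table.csv --component corr --per-subsystem
cbslab heg --l-bohr 6.2832 --ecut-ha 8 --nelec 14 --out heg.csv
cbslab pwfit --in heg.csv --mode n
cbslab kernel --treatment mt --cell 24,24,24 --ecut-ha 50
cbslab count --formula C14H13N --basis aug-cc --x 5
```

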