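# xtbu

Self-consistent extended tight-binding (GFN2-style) with **spin
polarization**, an on-site **Hubbard +U** correction in three formulations
(FLL, AMF, pSIC), **Fermi smearing**, and two interchangeable SCF drivers:
Pulay **DIIS** extrapolation and **geometric direct minimization (GDM)** on
the manifold of orthonormal orbitals.

The package is aimed at the electronic structure of open-shell
transition-metal complexes, where semi-empirical tight-binding methods
struggle on two fronts: near-degenerate frontier orbitals make DIIS-type
SCF acceleration oscillate or diverge, and the self-interaction error (SIE)
over-delocalizes metal d electrons, biasing spin-state energy gaps.  GDM
addresses the first problem by minimizing the energy directly instead of
extrapolating Fock matrices; the +U correction addresses the second by
penalizing fractional occupation of localized shells.

## The model

The total electronic free energy is a sum of terms

```
E_tot = E_rep + E_EHT + E_IES + E_IXC + E_AES + E_AXC + E_spin + E_Fermi + E_U
```

pairwise repulsion, an extended-Hückel band term over a minimal Slater-type
basis (expanded in 6 Gaussians per shell), isotropic second/third-order
shell-charge electrostatics+XC, anisotropic electrostatics from cumulative
atomic dipoles and quadrupoles with damped kernels, on-site multipole XC,
the spin-polarization energy

```
E_spin = 1/2 Σ_A Σ_{l,l'∈A} p_Al p_Al' W_All'
```

with `p_Al` the α−β Mulliken shell population and `W_All'` element-wise spin
constants, the electronic-entropy term from Fermi smearing, and the on-site
Hubbard correction.  The +U term acts on shell-block occupation matrices

```
n^σ_{μν} = 1/2 (S P^σ + P^σ S)_{μν},   μ, ν in one atomic shell,
```

with three energy functionals (shell Hubbard parameter `U_l`, scaling
`α = 0.5`):

| variant | energy per shell and spin channel         |
|---------|-------------------------------------------|
| FLL     | −α U/2 · [tr(n²) − tr(n)]                 |
| pSIC    | −α U/2 · tr(n²)                           |
| AMF     | −α U/2 · tr(δn²), δn = n − tr(n)/(2l+1)·I |

All Fock contributions are the exact density-matrix derivatives of their
energy expressions (verified against finite differences in the test-suite),
folded through the symmetric Mulliken chain rule `F = 1/2 (S V + V S)`.

On top of the solver sit diagnostic and parameter workflows:

- **fractional-occupation linearity**: E(q) as a fraction q of an electron
  is pinned into the frontier orbital; the deviation
  `E_dev(q) = E(q) − q ΔE − E(0)` measures SIE (exact theory is piecewise
  linear, SIE makes it convex; increasing U flattens it),
- **linear-response U**: `U = ε^HOMO(N+1) − ε^LUMO(N)`, optionally iterated
  to self-consistency,
- **spin gaps** `ΔE_HS−LS` in kcal/mol with RMSE/sign-count objectives,
  **Sobol sensitivity** (Saltelli sampling, Jansen estimators) of those
  objectives to the `W_ll'` and `U_l` parameters, and a **two-stage
  Powell → L-BFGS-B** parameter optimizer.

Element parameters (Hückel levels, Slater exponents, hardnesses,
third-order, repulsion, multipole kernels, spin constants, Hubbard U) ship
as a TOML table for H, C, N, O, F, Li and Fe (`src/xtbu/data/`).

## Worked example

Single-point energy of LiF at 1.25 Å (the `fixtures` subcommand writes
generated geometries):

```
$ xtbu fixtures lif --out fx --bond-length 1.25
$ xtbu energy fx/lif_1.25.xyz --solver diis
E_rep     0.12969367
E_EHT    -5.26603574
E_IES     0.02167511
E_IXC    -0.00135103
E_AES     0.01062423
E_AXC    -0.00434268
E_spin    0.00000000
E_Fermi  -0.00000000
E_U       0.00000000
E_tot    -5.10973645
converged True after 5 iterations (diis)
```

The breakdown shows the bond is held by the Hückel term against the
repulsion, with a small ionic (IES) contribution; spin polarization and the
entropy term vanish for this closed-shell singlet at 300 K.

A sextet–quartet spin gap of high-spin [Fe(NH₃)₆]³⁺ (generated octahedral
fixture, Fe–N 2.2 Å), solved with GDM because plain DIIS oscillates on this
open-shell complex:

```
$ xtbu fixtures hexammine --out fx
$ xtbu spin-gap fx/fe_hexammine.xyz --hs 6 --ls 4 --solver gdm --max-iter 800
{
  "system": "Fe-complex",
  "multiplicity_hs": 6,
  "multiplicity_ls": 4,
  "E_hs": -29.01697526449403,
  "E_ls": -29.092014078262842,
  "gap_kcal": 47.0875685086612,
  "reference_kcal": null,
  "sign_correct": null,
  "converged": true
}
```

The positive gap means the quartet is predicted more stable than the sextet
at this (idealized) geometry.  Adding a d-shell Hubbard term
(`--uvariant fll --ud 0.1`) widens the HOMO–LUMO gap and reduces the
fractional-charge nonlinearity; `xtbu linearity` and `xtbu lr-u` expose
those diagnostics, and `xtbu optimize-params` / `xtbu sobol` drive the
parameter workflows from a spin-gap task table.

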