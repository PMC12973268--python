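# Methods

This note records the model implemented in `xtbu`, the numerical choices
behind it, what the generated fixtures do and do not emulate, and the known
limitations.  Energies are Hartree, lengths Bohr internally (Å at the XYZ
interface), temperatures Kelvin; spin gaps are converted with
1 Hartree = 627.5095 kcal/mol.

## Hamiltonian

The energy is assembled from independent terms, each a functional of the
spin-channel density matrices `P^α, P^β` through Mulliken-symmetrized
moments; every term's Fock contribution is its exact derivative, so the SCF
is strictly variational at fixed occupations.

**Basis.** A minimal shell basis of Slater-type orbitals, each expanded in
6 Gaussian primitives.  The ζ=1 expansion tables are generated by an
in-repo overlap-maximization fit (`xtbu.slater.fit_sto_ng`, the classic
STO-nG construction; achieved radial overlaps ≥ 0.999999) and frozen;
exponents scale as ζ².  Shell ordering is atoms in input order, then
increasing angular momentum, with real-spherical components m = −l…+l.
Overlap, dipole and second-moment integrals come from 1-D Obara–Saika
recurrences with analytic origin shifting; the overlap condition number is
checked against 1e12.

**Terms.**

- *Repulsion*: `Σ_{A<B} Z^eff_A Z^eff_B / R · exp(−√(α_A α_B) R^k)` with
  k = 3/2 (k = 1 for H/He pairs).
- *Extended Hückel*: `H⁰_{μν} = ½ K_{ll'} (h_l + h_l') S_{μν} X(ΔEN) Π_l Π_l'`
  with shell-pair constants K (s 1.85, p/d 2.23, cross terms averaged),
  electronegativity scaling `X = 1 + 0.02 ΔEN²`, a distance polynomial per
  shell, and coordination-number-shifted levels
  `h_l = H_l − k^CN_l · CN'` (CN' from a double-logistic counting function
  over scaled covalent radii).  CN depends only on geometry, so it
  contributes no Fock terms.
- *Isotropic SCC*: `E = ½ Σ q_k γ_kk' q_k' + ⅓ Σ Γ_k q_k³` over shell
  charges `q_k = n⁰_k − tr(P M_k)`, with the damped kernel
  `γ = (R² + η̄⁻²)^{−1/2}`, η̄ the harmonic mean of shell hardnesses, and
  shell-scaled third-order constants (s/p/d scaling 1.0/0.5/0.25).
- *Anisotropic electrostatics*: cumulative atomic dipoles μ_A and traceless
  quadrupoles θ_A (Mulliken-partitioned moment integrals with per-atom
  origins) interacting through damped `f₃ = 1/[R³(1+6(R₀/R)³)]` and
  `f₅ = 1/[R³(1+6(R₀/R)⁴) R²]` kernels; the critical radius R₀ grows
  logistically with coordination number between the element value and
  5 Bohr.  On-site multipole XC adds `f_d|μ_A|² + f_q‖θ_A‖²`.
- *Spin polarization*: `E = ½ Σ_A Σ_{ll'} p_Al p_Al' W_All'` on α−β Mulliken
  shell populations; the shell potential `V_Al = Σ_l' W_All' p_Al'` enters
  the two Fock matrices with opposite signs.
- *Hubbard +U* (FLL / pSIC / AMF): see below.
- *Fermi entropy*: `E_Fermi = kT Σ_{σi} [f ln f + (1−f) ln(1−f)]`, i.e. the
  −TS term of the electronic free energy, per spin channel at fixed channel
  electron counts.

**Mulliken chain rule.** Every density-dependent scalar is written as
`m = tr(P M)` with a symmetric moment matrix (shell selectors give
`M_k = ½(J_k S + S J_k)`; multipoles use origin-shifted moment integrals
symmetrized the same way), so Fock contributions are
`F = Σ_k (∂E/∂m_k) M_k`.  The +U term works at the matrix level: the
occupation-space potential `V = ∂E/∂n` is embedded block-diagonally and
mapped by `F = ½(S V + V S)`.  The test-suite checks every variant against
central finite differences at 1e-6.

**+U conventions.** The occupation matrix is the symmetrized Mulliken
projection `n^σ = ½(S P^σ + P^σ S)` restricted to same-atom, same-shell
blocks.  The FLL linear term is applied to the diagonal only (equivalently,
as tr(n)), which makes the energy rotationally invariant and its derivative
the familiar `−αU(n − ½I)` potential.  For pSIC the potential consistent
with the energy `−αU/2 tr(n²)` is `−αU·n`; a convention in which the
potential is written with the ½ pre-factor would not pass the
finite-difference variational test, so the derivative convention is used
throughout.  δn in the AMF variant subtracts the same-channel shell average,
`δn = n − tr(n)/(2l+1)·I`.  U is shell- and element-resolved, default 0;
α defaults to 0.5.

## SCF drivers

All drivers are unrestricted, run under Fermi smearing (default 300 K,
0 K available), and treat non-convergence as data (flagged state with a
per-iteration trace), never as an exception.

- *DIIS*: Pulay extrapolation on the commutator error `X†(FPS−SPF)X` in the
  symmetrically orthogonalized basis, both channels stacked; history 8,
  oldest-first pruning, restart when the B-matrix condition number exceeds
  1e12, single-entry history returns the bare Fock.
- *GDM*: direct minimization over orbital rotations `C ← C exp(−κ)` among
  pairs with occupation difference > 1e-8.  The gradient is
  `2(f_p − f_q) F^MO_{pq}`; search directions come from L-BFGS (history 12)
  with a diagonal preconditioner `max(2|Δf||Δε|, 0.05)` built from
  orbital-energy gaps, and an Armijo backtracking line search guarantees a
  non-increasing accepted-energy sequence at fixed occupations.  Occupations
  are re-resolved from Fermi smearing at each macro-iteration; from the
  third macro-iteration on the new occupations are mixed 50/50 with the
  previous ones, which damps the occupation/SCC feedback loop that
  open-shell complexes with near-degenerate d levels otherwise enter (the
  Fe²⁺ quintet fixture needs ~350 total inner iterations with this scheme).
  Inner minimization is capped at 50 iterations per macro-cycle so
  occupations update before the orbitals over-converge.
- *Damped fixed-point*: plain diagonalize-and-mix (mixing 0.4), kept as an
  independent oracle for solver-equivalence tests.
- Convergence requires both |ΔE| and the error/gradient max-norm below
  1e-6 (the threshold is not attributed to one quantity, so both are
  enforced); iteration cap 250 by default.  Analysis workflows raise the cap
  to 800 because the hardest open-shell fixtures legitimately need it.

The chemical potential is bisected to machine resolution at finite T; at
T = 0 an aufbau filling is used, with electrons remaining at an exactly
degenerate frontier (tolerance 1e-9) split symmetrically.

## Diagnostics

*Fractional charge.* The scan pins occupations: the accepting channel is
aufbau-filled and the fractional remainder q sits in the frontier orbital
(the lowest-index orbital among any near-degenerate set — a convention,
chosen for determinism and logged as such), so q is exact and
`E_dev(0) = E_dev(1) = 0` by construction.  The accepting spin channel is
inferred from the endpoint multiplicities.

*Linear-response U.* `U = ε^HOMO(N+1) − ε^LUMO(N)` from two SCF solutions.
On a one-orbital charging parabola this equals the second difference
`E(N−1) − 2E(N) + E(N+1)` exactly (the oracle used in the tests; with more
orbitals the second difference additionally contains the HOMO–LUMO level
spacing, which is why the oracle model is single-orbital).  The
self-consistent mode feeds the estimate back into the metal's d-shell U
with a 50 % damped update (the undamped map oscillates with period 2 on the
Fe fixture) until |ΔU| < 1e-4 or 20 iterations.

*Frontier gaps.* At finite temperature occupied/virtual edges are split at
occupation ½; the overall gap is global LUMO minus global HOMO across both
channels (it can be negative for open shells when the minority-channel LUMO
dips below the majority HOMO).

## Parameter workflows

The spin-gap objective is `RMSE = √(mean((gap_i − ref_i)²))` in kcal/mol
plus a sign-agreement count; SCF failures contribute a fixed 100 kcal/mol
penalty and are counted separately, so the objective stays defined during
optimization.  Free parameters are addressed as `El.W.ll'` / `El.U.l`;
default search boxes are W ∈ [−0.05, 0] Ha and U ∈ [0, 0.5] Ha.  Because W
and U do not touch the precomputed geometry/basis quantities, objective
evaluations reuse each task's integrals and warm-start each SCF from the
previous converged orbitals.

Sensitivity analysis uses Saltelli radial sampling on a scrambled Sobol
sequence (scipy.stats.qmc) with the Saltelli-2010 first-order and Jansen
total-order estimators and 200-resample bootstrap confidence intervals; the
base sample count must be a power of two.  The sampler, estimators and
bootstrap are implemented in-package and validated against the analytic
Ishigami indices.  The optimizer is a bounded Powell coarse search followed
by L-BFGS-B with numerical gradients; the best point ever evaluated is
returned, so the final objective cannot exceed the starting one.  All
stochastic stages take explicit seeds (default 42).

## Fixtures and what they show

Generated fixtures are pure functions of their arguments: the LiF series
(1.25–4.00 Å), ideal octahedral/square-planar/linear Fe-ammine complexes
(N–H 1.012 Å, H–N–H 106.7°, Fe–N 2.2 Å unless stated — idealized, not
relaxed), template small molecules at standard geometries with seeded
jitter, and toy model Hamiltonians (two-level, mean-field Hubbard dimer
with full-CI reference, linear- and quadratic-in-N models) that plug into
the same SCF drivers.  Property tests on the Fe complexes check
*mechanisms* — gap widening and E_dev flattening with U, DIIS instability
vs GDM robustness, parameter recovery — not literature values; the
idealized geometries and the element table below are not accurate enough
for quantitative spin-state predictions of real complexes, and passing
tests should be read accordingly.

Problem sizes used by the shipped tests and the acceptance script: LiF
(8 AOs), Fe-ammine fixtures with 2/4/6 ligands (23/37/51 AOs), 7-point
fractional-charge grids, Sobol at 2¹² base samples, and a two-task planted
recovery; these keep the full suite within a few minutes on one core while
exercising every code path.

## Limitations

- The shipped element table (H, C, N, O, F, Li, Fe) is a best-effort
  transcription of the published GFN2-style element constants; individual
  entries (levels, repulsion parameters, multipole kernels, shell
  polynomials — the latter currently neutral) carry transcription
  uncertainty.  Absolute total energies therefore deviate at the ~1–2 %
  level from the published dispersion-free reference values for LiF, while
  curve shapes, iteration behavior and all mechanism-level results are
  insensitive to this.  The parameter file format makes replacing the table
  with a higher-fidelity transcription a data-only change.
- No dispersion correction of any kind is included, matching the
  dispersion-free comparison protocol the benchmark targets.
- Spin constants W are representative atomic-scale defaults, not fitted
  values; they matter only through the trend tests and the optimizer, which
  treats them as free parameters anyway.
- Single-point energies only (no nuclear gradients), no f shells, no
  effective core potentials, no periodic boundary conditions, no
  restricted-open-shell formalism.
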