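# Methods

## The problem

Semilocal and standard hybrid Kohn-Sham (KS) density functionals
over-stabilize fractional, spread-out charge distributions (the
self-interaction / delocalization error).  For isolated biomolecules with
charged groups — the zwitterionic termini of a gas-phase polypeptide are
the canonical case — this shows up as three coupled artifacts: electron
density leaks from anionic groups (-CO2-) into cationic or even neutral
acceptors, the HOMO-LUMO gap collapses toward zero, and conventional
diagonalization-based SCF solvers oscillate or fail outright.  ndokit
implements the diagnostic chain for this failure mode: where the spurious
charge goes (deformation orbitals and fragment attribution), when it can
happen (frontier-level screening), and how to prepare both the
charge-localized and charge-delocalized SCF solutions that bracket the
phenomenon.

## Natural deformation orbitals

Given two converged one-particle density matrices `P_ref` and `P_cmp` on
the same geometry and AO basis (reference = a method with qualitatively
correct charge localization, in practice Hartree-Fock; comparison = the KS
functional under scrutiny), the difference is diagonalized in an
orthonormalized basis:

    D = X^T S (P_ref - P_cmp) S X,   D u_k = q_k u_k,   v_k = X u_k,

with `S` the AO overlap and `X` a Loewdin orthonormalizer (`X^T S X = 1`).
The `v_k` are the natural deformation orbitals (NDOs) and the eigenvalues
`q_k` their deformation charges: `q_k > 0` marks density the comparison
method lost relative to the reference, `q_k < 0` density it gained.  Key
algebraic facts, all enforced by tests:

* `sum_k q_k = Tr((P_ref - P_cmp) S)`, the electron-count difference;
* the `q_k` multiset is invariant to the orthonormalization choice
  (Loewdin vs canonical) as long as no near-null overlap directions are
  dropped;
* for spin-summed closed-shell densities `|q_k| <= 2`;
* a single occupied->virtual rotation by angle `theta` between
  S-orthonormal orbitals gives exactly one `+/- occ*sin(theta)` pair
  (`occ` = 1 or 2 electrons per orbital), and transfers
  `occ*sin^2(theta)` electrons.

Loewdin is chosen over canonical orthogonalization because the symmetric
square root stays closest to the original AOs, keeping NDO coefficients
atom-attributable; the spectrum itself does not depend on the choice.
Near-degenerate eigenvalues are ordered by descending eigenvalue with
stable ties broken by larger leading-fragment population, then original
index, so output is deterministic.

NDOs with `|q_k|` at or above a significance threshold are called
frontier NDOs (FNDOs); the threshold defaults to 0.2 electrons, below
which deformation orbitals describe diffuse polarization rather than
discrete charge transfer.

## Fragment attribution

Fragments are named, disjoint atom groups (1-based atom indices in files,
0-based in memory); atoms left over are collected into an automatic
`rest` fragment.  An NDO `v` is attributed via Mulliken fractions
`pop_F(v) = sum_{mu in F} v_mu (S v)_mu`, which sum to one and may be
slightly negative (the standard Mulliken artifact; values are reported
as-is).  Loewdin populations are offered as a non-negative alternative,
but Mulliken is the default because it respects the AO support structure
of block-separated fragments exactly.

A fragment is a *donor* if it carries at least a membership cutoff
(default 0.25) of the population of any positive-q FNDO, an *acceptor*
likewise for negative-q FNDOs; `N_d` and `N_a` count such fragments.
Population unclaimed at the cutoff is reported as a per-FNDO
"delocalized remainder" instead of being assigned a qualitative label.
The per-fragment deformation charge `dq_F` (Mulliken charges of
`P_ref - P_cmp`) obeys the exact identity
`dq_F = sum_k q_k pop_F(v_k)`, asserted to 1e-8 in the tests, and
`sum_F dq_F` equals the electron-count difference.

One algebraic caveat the synthetic fixtures make visible: for a partial
transfer by angle `theta`, the two NDOs of the pair are not localized on
donor and acceptor separately — each carries a fraction
`(1 - sin(theta))/2` on the other fragment, approaching clean
localization only as the transfer approaches a full electron.  The
membership cutoff of 0.25 therefore counts both end-point fragments for
strongly developed transfers and degrades gracefully (toward "both
fragments named") for weak ones.

## Frontier-level screening

For two fragments at non-interacting separation, a non-Aufbau-filled
supersystem solution exists whenever the HOMO of one lies above the LUMO
of the other; energy minimization will instead delocalize charge across
the pair.  The screen therefore flags every admissible ordered
(donor, acceptor) pair with

    gap = eps_LUMO(acceptor) - eps_HOMO(donor) < 0     (strictly),

a zero gap is not flagged.  Counts are aggregated by the fragments'
charge states (Q_d, Q_a).  The default exclusion rule screens ordered
pairs of *distinct* species only — records sharing a parent-species
label (e.g. the protonation states of one amino acid) are never paired,
which makes the saturated cell of an s-species table exactly s(s-1).
Records computed with different functionals are refused by default
(an explicit override exists), since orbital energies are not comparable
across functionals.

## Solution preparation

The quasi-Newton solver minimizes the total energy over occupied-virtual
orbital rotations `C' = C exp(K)` (K antisymmetric), with L-BFGS and
the following robustness rules:

* history size `m = 15`;
* the history is cleared whenever the RMS orbital gradient crosses
  1e-6 in either direction;
* the history is trimmed oldest-first while the smallest eigenvalue of
  `V^T V` (V = the stored s and y update vectors) lies below -1e-15;
* steps are clipped so no rotation element exceeds `t_r = 0.15`.  This
  step-clipping rule is a deliberate simplification of a full
  trust-region regularizer; it bounds orbital rotations per step without
  modelling the Hessian spectrum.

The two-loop recursion is seeded with a diagonal preconditioner
`|2 (occ_i - occ_a)(F_aa - F_ii)|` floored at 0.2 hartree, which is what
makes the nearly-degenerate frontier modes of charge-transfer systems
converge in tens rather than hundreds of iterations.  A backtracking
Armijo line search guarantees monotone energy descent over accepted
steps; convergence is RMS gradient below `conv_tol` (default 1e-7).
Exhausting `max_iter` returns an unconverged solution object, never an
exception.

Occupation policies:

* `fixed` — occupations stay attached to the continuously evolving guess
  orbitals.  With a fragment-disjoint guess on block-separated fragments
  the inter-fragment rotation gradient is identically zero, so the
  minimizer preserves each fragment's own filling even when the global
  pattern is non-Aufbau (an occupied level above an empty one, i.e. a
  negative global HOMO-LUMO gap).
* `aufbau` — at each iteration the occupied set may be re-assigned to
  the lowest-energy orbitals; a re-assignment is accepted only if it
  lowers the energy (it then clears the quasi-Newton history).

Guesses: `build_disjoint_guess` block-embeds separately converged
fragment orbitals after verifying that all inter-fragment overlap
elements are below 1e-10 (the operational definition of
"noninteracting"); `perturb_orbitals` applies `C exp(K)` with K entries
drawn uniformly from `[-magnitude, +magnitude]` (default 0.01) by a
seeded generator, mixing all orbitals across fragments.

## The built-in SCF engine

ndokit ships a compact restricted HF/KS engine over contracted Cartesian
Gaussians (s, p, 6d) so the whole pipeline runs end to end without any
external quantum-chemistry installation:

* integrals by the McMurchie-Davidson Hermite expansion (numba-compiled),
  full in-memory ERI tensor; practical up to roughly 120 basis functions;
* basis sets: STO-3G and the 6-31G family with polarization
  (6-31G*, 6-31G**) for H, C, N, O, from the published parameters;
* functionals: HF, LDA (Slater + VWN5), BLYP and B3LYP
  (0.80 LDA_x + 0.72 dB88 + 0.20 HF_x + 0.19 VWN3(RPA) + 0.81 LYP);
  GGA potentials are obtained by centered numerical differentiation of
  the energy density (accurate to ~1e-9, ample at SCF tolerance 1e-8);
* quadrature: Mura-Knowles radial grids with Becke fuzzy-cell atomic
  partitioning (Bragg-Slater size adjustment) and Gauss-Legendre x
  uniform-phi angular product grids.  Defaults (75 radial x 20x40
  angular on heavy atoms, lighter on H) integrate the glycine-ion
  electron count to ~1e-7 and leave orbital energies converged to well
  under 0.01 eV; the supersystem workflow uses a documented lighter grid
  (60 x 16x32) whose gap error is below 0.01 eV;
* ground-state SCF by DIIS over Roothaan-Hall iterations (core guess,
  two damped start-up steps); the direct-minimization solver above is
  used for the prepared-guess experiments;
* analytic nuclear gradients for all supported functionals (used to
  produce the shipped geometries); the xc term neglects
  quadrature-weight derivatives, a standard approximation that leaves
  residual force errors ~1e-5 hartree/bohr at the default grids.

Validation is entirely against independent oracles, enforced in the test
suite: closed-form s-type integrals; the identities "a p function is the
center-derivative of an s function" and "a Cartesian d function is its
second derivative", applied to overlap, kinetic, nuclear-attraction and
repulsion integrals; an analytically integrable model density for the
grid; finite-difference checks of xc potentials and nuclear gradients;
and the textbook restricted HF energy of H2 in a minimal basis at
R = 1.4 bohr (-1.1167 hartree).

## The far-field supersystem

Fragments separated by tens of angstroms have identically vanishing
inter-fragment AO products in double precision, so overlap, kinetic and
exchange couplings are exactly zero and the Fock matrix is
block-diagonal.  The remaining couplings are classical: electron-nucleus
attraction across fragments is evaluated exactly with point-charge
integrals, and the inter-fragment electron-electron repulsion through
Mulliken atomic monopoles of the other fragment's current density.  At
the 200-angstrom separation of the worked example the neglected
dipole-and-higher terms are of relative order (a/R)^2 ~ 1e-4 of an
already ~0.07 eV coupling, i.e. orders of magnitude below the 0.01 eV
digit being reported, while keeping memory at two fragment-sized ERI
tensors instead of one supersystem-sized one.  The energy responds
exactly (within the monopole model) to charge flowing between fragments,
which is the quantity the delocalized solutions probe; a geometric guard
refuses fragments closer than 20 bohr.

## The glycine worked example

The shipped geometries of deprotonated (charge -1) and protonated
(charge +1) glycine were optimized at B3LYP/6-31G* with the built-in
engine's analytic gradients, starting from force-field structures
(`scripts/optimize_geometries.py` reproduces them; the protonation-state
geometry protocol for the level tables is the same).  The experiment
then runs LDA(SVWN5)/6-31G** throughout: both ions in isolation, then
the 200-angstrom supersystem converged (a) from the untouched disjoint
guess with fixed occupations — preserving the physically correct
charge-localized, *non-Aufbau* solution whose global gap is the large
negative eps_LUMO(cation) - eps_HOMO(anion), shifted by the mutual
~1/R electrostatic potentials (2 x 0.072 eV at 200 angstrom) — and (b)
from a seeded random perturbation with aufbau occupations, which lets
LDA's delocalization error mix the frontier orbitals across fragments
and collapse the gap to nearly zero while lowering the total energy.
The supersystem runs use convergence 3e-6 RMS gradient, which pins the
reported gaps to well under 0.01 eV.  Problem sizes: 95 (gly-) and 105
(gly+) basis functions for the fragments, 200 for the supersystem; the
whole experiment takes a few minutes on one CPU.

## What the synthetic generators do and do not emulate

The generators reproduce the *algebraic* structure the analysis relies
on — block-separated SPD overlaps (random SPD blocks built as
`A^T A + n I` scaled to unit diagonal: well-conditioned, realistically
non-orthogonal, never linearly dependent), idempotent spin-summed
densities, planted occupied->virtual rotations with closed-form ground
truths, level tables with band structure or an exactly planted number of
negative-gap pairs (constructed as a staircase over disjoint donor and
acceptor species, verified by a brute-force double loop at generation
time).  They deliberately do not emulate molecular physics: no nuclear
framework, no basis-set or correlation effects, no geometry dependence.
Passing the synthetic suites therefore certifies the linear algebra,
bookkeeping and combinatorics, not chemical realism; the engine-based
worked example and the cluster-scale scripts cover the physical side.

The toy charge-transfer model `E(x) = -delta*x + gamma*x*(1-x)` over the
transferred fraction `x = sin^2(theta)` is the minimal surrogate for the
energy-vs-fractional-charge curve: `gamma < 0` bends the segment below
the line joining integer transfers (the delocalization-error signature),
placing the minimum at the interior point `x* = 1/2 - delta/(2 gamma)`
when `gamma < -delta`; `gamma > 0` pushes it to an integer endpoint.  It
is wired through the same engine protocol as the real Fock build, so the
quasi-Newton solver is tested against its closed form and a grid-search
oracle.  Note the `x = 0` guess is a stationary point (zero gradient) of
the rotation parameterization — the toy-model mirror of why the
unperturbed disjoint guess converges to the non-Aufbau solution and only
the perturbed guess finds the delocalized one.

## Numerical choices and degenerate inputs

* Unit conventions: hartree and bohr internally; eV (1 hartree =
  27.211386245988 eV) and angstrom at all reporting interfaces.
* Overlap eigenvalues below `lindep_tol = 1e-8` are dropped with a
  count; an indefinite overlap is an error.
* Matrices read from archives are symmetrized as `(M + M^T)/2`, with a
  warning when the asymmetry exceeded 1e-8.
* Electron-count mismatches between compared densities warn but do not
  fail (ionized comparisons are legitimate); the q_nd sum then tracks
  the difference.
* Equal densities yield an all-zero spectrum; zero-length frontier
  subsets produce empty, well-formed reports.
* `P S P = 2P` is asserted to 1e-6 for closed-shell sources only; the
  single-spin-channel synthetic fixtures (occupation 1) are exempt by
  construction.

## Known limitations

* Spin-restricted, closed-shell only; spin-polarized file blocks are
  rejected explicitly rather than silently spin-summed.
* The built-in engine covers H/C/N/O and s/p/6d shells; sulfur-bearing
  peptides (methionine, disulfides) need an external engine behind the
  adapter or an extended basis table.  Any engine exposing
  `overlap()`/`energy_and_fock(P)`/`solve_ground_state()` drops in, and
  all analysis modules work from matrix archives produced elsewhere.
* The far-field composite is valid only in the non-overlapping regime;
  it refuses close fragments rather than degrading silently.
* Molden support is Cartesian-d, alpha-spin, single-solution files (the
  subset the package writes); spherical-harmonic files are rejected.
* The membership cutoff and FNDO threshold are tunable conventions, not
  physical constants; reported N_d/N_a counts depend on them in the
  weak-transfer regime discussed above.
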