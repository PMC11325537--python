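# ndokit

Diagnostics for unphysical charge delocalization in approximate
Kohn-Sham (KS) density-functional calculations.

Semilocal and standard hybrid functionals over-stabilize fractional,
spread-out charges (the self-interaction / delocalization error).  For
gas-phase biomolecules with charged groups — a zwitterionic polypeptide
with -NH3+ and -CO2- termini is the textbook case — this produces
spurious charge transfer between distant groups, a vanishing HOMO-LUMO
gap, and SCF solvers that oscillate or fail.  ndokit is a toolkit for
dissecting this failure mode, aimed at quantum chemists and simulators
who see "atypical SCF convergence" or suspiciously small gaps and want
to know what the functional is doing to the density.

## What it computes

**Natural deformation orbitals (NDOs).**  Given density matrices from
two methods on the same geometry (say Hartree-Fock as the
charge-localized reference and LDA as the suspect), diagonalize the
difference in a Loewdin-orthonormalized basis,

    X^T S (P_HF - P_KS) S X  u_k = q_k u_k,        v_k = X u_k.

Each eigenvalue `q_k` is a *deformation charge*: `q_k` electrons moved
out of orbital `v_k` going from HF to KS (negative values mark density
the KS functional gained).  `sum_k q_k = Tr((P_HF - P_KS) S)` exactly.
NDOs with `|q_k| >= 0.2` ("frontier NDOs") flag discrete charge
transfer.

**Fragment attribution.**  Mulliken populations of each NDO over named
atom groups turn pictures into numbers: how many fragments donate
(`N_d`) and accept (`N_a`) density, per-fragment deformation charges
`dq_F`, and the exact identity `dq_F = sum_k q_k pop_F(v_k)`.

**Non-Aufbau pair screening.**  From a CSV of per-fragment frontier
levels, flag every ordered (donor, acceptor) pair with
`eps_LUMO(a) < eps_HOMO(d)` — the condition under which a
non-interacting pair admits a non-Aufbau solution and energy
minimization delocalizes charge instead — and aggregate counts by charge
states and functional.

**Solution preparation.**  A quasi-Newton direct-minimization SCF solver
(L-BFGS over orbital rotations with history-reset/trim rules and step
clipping) plus fragment-disjoint and randomly perturbed guesses and
fixed/aufbau occupation policies, to converge *both* the physically
correct non-Aufbau solution and the delocalized vanishing-gap solution
of the same system.

**Built-in engine.**  A compact restricted HF / LDA(SVWN5) / BLYP /
B3LYP engine (McMurchie-Davidson integrals, numba-compiled; STO-3G and
6-31G-family bases for H/C/N/O; Becke-partitioned grids; analytic
nuclear gradients) runs everything end to end with no external quantum
chemistry installed.  All analysis modules equally accept matrix
archives, Molden or formatted-checkpoint files produced by any other
engine.

## Worked example: the separated glycine zwitterion

Deprotonated (gly-) and protonated (gly+) glycine, 200 angstrom apart,
LDA(SVWN5)/6-31G** on shipped B3LYP/6-31G*-optimized geometries:

```python
from ndokit.workflows import glycine_zwitterion_pair

result = glycine_zwitterion_pair(seed=1)
print(result.summary())
```

prints (fragment 0 = gly-, fragment 1 = gly+):

```
fragment 0: HOMO     1.14 eV  LUMO     6.18 eV  gap    5.04 eV
fragment 1: HOMO   -11.66 eV  LUMO    -6.01 eV  gap    5.65 eV
supersystem (unperturbed, fixed occupations): gap   -7.00 eV  [non-Aufbau]
supersystem (perturbed, aufbau): gap   -0.01 eV
delocalized solution lies 0.058488 hartree below the non-Aufbau one
```

Reading this: each isolated ion is perfectly well-behaved (positive
gaps; the *positive* anion HOMO is the usual unbound-anion artifact of a
finite basis).  But the anion's HOMO sits ~7.1 eV above the cation's
LUMO, so the pair is globally non-Aufbau.  Converged from the untouched
fragment-disjoint guess with frozen occupations, the supersystem keeps
the correct integer charges and shows that negative -7.00 eV gap — the
isolated-fragment level difference shifted by the two ions' mutual
1/R potentials (2 x 0.07 eV at this separation).  One small random
rotation of the guess later, aufbau minimization finds the solution LDA
actually prefers: ~half an electron delocalized across 200 angstrom, a
gap collapsed to essentially zero, and a total energy ~0.06 hartree
*lower* than the physical solution.  That inverted energy ordering is
the delocalization error in one number.

NDO analysis of any such pair of densities, and screening of level
tables, work the same way from files:

    ndokit synth ct --theta 30 --seed 1 --out ct.h5
    ndokit ndo --archive ct.h5 --json-out ndo.json
    ndokit synth levels --k 7 --seed 3 --out levels.csv
    ndokit screen --levels levels.csv --out counts.csv

(A 30-degree planted rotation gives leading deformation charges of
exactly +/- sin 30 deg = +/- 0.5 per spin channel — the synthetic
fixtures have closed-form ground truths throughout.)

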