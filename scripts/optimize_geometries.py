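"""Reproduce the shipped B3LYP/6-31G* glycine-ion geometries.

Optimizes deprotonated glycine (charge -1) and protonated glycine
(charge +1) with the built-in engine's analytic B3LYP gradients, starting
from force-field-quality structures, and writes the results to
src/ndokit/data/.  Runtime is a few hours on one CPU; the optimized
geometries are committed to the repository so nothing downstream needs to
rerun this.

Usage: python scripts/optimize_geometries.py [--molecule anion|cation]
"""

from __future__ import annotations

import argparse
import pathlib
import sys

import numpy as np
import scipy.optimize

from ndokit.engine.grad import nuclear_gradient
from ndokit.engine.rks import RestrictedSCFEngine
from ndokit.io import write_xyz

BOHR = 0.52917721092

# Force-field (MMFF94) starting structures, Angstrom.
START = {
    "anion": ("""N -1.375933 0.142179 -0.158428
C -0.091967 -0.621708 -0.235542
C 1.103483 0.277027 0.229707
O 2.186036 -0.338609 0.439078
O 0.832882 1.511567 0.342643
H -1.120440 1.052907 -0.570870
H -1.448831 0.418945 0.825314
H -0.163230 -1.510175 0.398910
H 0.078000 -0.932133 -1.270811""", -1),
    "cation": ("""N -1.410457 0.228250 -0.213740
C -0.224172 -0.458451 0.400739
C 1.066825 0.144498 -0.117001
O 1.104959 1.061787 -0.922655
O 2.168238 -0.422264 0.391301
H -1.379860 1.237392 -0.009009
H -1.368351 0.155346 -1.240449
H -2.305652 -0.152326 0.112299
H -0.305520 -0.317231 1.480590
H -0.292816 -1.511866 0.121019
H 2.946805 0.034864 -0.003093""", +1),
}


def optimize(name, out_path, gtol=2.5e-4, grid=None):
    text, charge = START[name]
    rows = [ln.split() for ln in text.strip().splitlines()]
    elements = [r[0] for r in rows]
    x0 = np.array([[float(v) for v in r[1:4]] for r in rows]) / BOHR
    grid = grid or dict(n_rad_heavy=65, n_theta_heavy=16,
                        n_rad_h=50, n_theta_h=13)
    state = {"C": None, "n": 0}

    def make_engine(x):
        return RestrictedSCFEngine(elements, x.reshape(-1, 3), charge=charge,
                                   functional="b3lyp", basis="6-31g*",
                                   grid_params=grid)

    def fun(x):
        eng = make_engine(x)
        sol = eng.solve_ground_state(conv_tol=1e-9, guess=state["C"])
        state["C"] = sol.C
        g = nuclear_gradient(eng, sol)
        state["n"] += 1
        print(f"  step {state['n']:3d}  E = {sol.energy:.8f}  "
              f"max|g| = {np.abs(g).max():.2e}", flush=True)
        # keep the latest geometry on disk so long runs are resumable;
        # forces carry ~1e-4 hartree/bohr noise from the neglected
        # grid-weight derivatives, so gtol below ~2e-4 just dithers
        write_xyz(str(out_path) + ".last", elements,
                  x.reshape(-1, 3) * BOHR,
                  comment=f"optimization snapshot, E = {sol.energy:.8f}")
        return sol.energy, g.ravel()

    res = scipy.optimize.minimize(fun, x0.ravel(), jac=True, method="BFGS",
                                  options={"gtol": gtol, "maxiter": 80})
    coords = res.x.reshape(-1, 3)
    write_xyz(out_path, elements, coords * BOHR,
              comment=f"glycine {name} optimized at B3LYP/6-31G* "
                      f"(built-in engine), E = {res.fun:.8f} hartree")
    print(f"{name}: done, E = {res.fun:.8f}, wrote {out_path}", flush=True)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--molecule", choices=["anion", "cation", "both"],
                    default="both")
    ap.add_argument("--outdir", default=None)
    args = ap.parse_args()
    outdir = pathlib.Path(args.outdir) if args.outdir else \
        pathlib.Path(__file__).resolve().parents[1] / "src/ndokit/data"
    names = ["anion", "cation"] if args.molecule == "both" else [args.molecule]
    for name in names:
        optimize(name, outdir / f"gly_{name}_b3lyp_631gs.xyz")


if __name__ == "__main__":
    sys.exit(main())
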