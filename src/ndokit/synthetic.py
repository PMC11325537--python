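"""Synthetic inputs with the exact algebraic structure the analysis assumes.

Three generators:

* make_ct_pair / make_multi_ct: pairs of idempotent densities on
  block-separated fragments differing by occupied->virtual rotations of
  known angle theta.  A rotation by theta moves sin^2(theta) electrons per
  spin channel from donor to acceptor, and the density difference has the
  exact eigenvalue pair +/- occ*sin(theta) per transfer — so every stage
  of the deformation-orbital pipeline has a closed-form ground truth.

* make_levels_table: frontier-level tables emulating the structure of
  per-fragment HOMO/LUMO scans, either drawn from per-charge-state energy
  bands or with an exactly planted number of non-Aufbau pairs; ground
  truths are computed by a brute-force double loop at generation time,
  independent of the screening implementation.

* make_toy_ct_model: a two-level charge-transfer energy model
  E(x) = -delta*x + gamma*x*(1-x) over the transferred fraction
  x = sin^2(theta), expressed through the same orbital-rotation
  parameterization the real SCF minimizer uses.  Concave gamma mimics the
  fractional-charge preference of semilocal functionals: for
  gamma < -delta the minimum sits at the interior point
  x* = 1/2 - delta/(2*gamma) instead of an integer electron transfer.

The generators are algebraic by design; they emulate the structure of
real electronic-structure data (block separation, idempotency, level
misalignment), not its physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fragments import FragmentPartition
from .io import AOBasisMeta, MatrixArchive
from .screen import FrontierLevels, PairScreenResult


@dataclass
class SyntheticCTSpec:
    """Single charge-transfer fixture: fragment sizes, angle, overlap mode."""

    n1: int = 6
    n2: int = 6
    theta: float = np.pi / 6
    spin_channels: int = 2
    seed: int = 0
    overlap_mode: str = "identity"  # or 'random_spd_block'

    def __post_init__(self):
        if not 0.0 <= self.theta <= np.pi / 2:
            raise ValueError("theta must lie in [0, pi/2]")
        if self.spin_channels not in (1, 2):
            raise ValueError("spin_channels must be 1 or 2")
        if self.overlap_mode not in ("identity", "random_spd_block"):
            raise ValueError(f"unknown overlap_mode {self.overlap_mode!r}")


@dataclass
class SyntheticCTResult:
    archive: MatrixArchive
    partition: FragmentPartition
    truth: dict


def _random_spd_block(n, rng):
    """Well-conditioned SPD overlap block scaled to unit diagonal."""
    A = rng.normal(size=(n, n))
    S = A.T @ A + n * np.eye(n)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def _s_orthonormal_columns(S, k, rng):
    """k random S-orthonormal vectors (Gram-Schmidt in the S metric)."""
    n = S.shape[0]
    V = np.empty((n, k))
    for j in range(k):
        v = rng.normal(size=n)
        for i in range(j):
            v -= V[:, i] * (V[:, i] @ S @ v)
        V[:, j] = v / np.sqrt(v @ S @ v)
    return V


def make_multi_ct(fragment_sizes: Sequence[int],
                  transfers: Sequence[tuple],
                  spin_channels: int = 2,
                  seed: int = 0,
                  overlap_mode: str = "identity") -> SyntheticCTResult:
    """General fixture: several transfers (donor_frag, acceptor_frag, theta).

    Each transfer consumes a fresh donor orbital (occupied in P_ref) on its
    donor fragment and a fresh acceptor orbital (virtual in P_ref) on its
    acceptor fragment; in P_cmp the donor orbital is rotated by theta into
    the acceptor orbital.  Fragments are block-separated: the overlap has
    exactly zero inter-fragment elements.
    """
    rng = np.random.default_rng(seed)
    nf = len(fragment_sizes)
    offsets = np.cumsum([0] + list(fragment_sizes))
    n = offsets[-1]
    S = np.eye(n)
    if overlap_mode == "random_spd_block":
        for f in range(nf):
            sl = slice(offsets[f], offsets[f + 1])
            S[sl, sl] = _random_spd_block(fragment_sizes[f], rng)
    # per-fragment orthonormal orbital pools
    pools = []
    for f in range(nf):
        sl = slice(offsets[f], offsets[f + 1])
        need = sum(1 for d, a, _ in transfers if d == f or a == f)
        if need > fragment_sizes[f]:
            raise ValueError(f"fragment {f} too small for its transfers")
        Vf = np.zeros((n, need))
        Vf[sl] = _s_orthonormal_columns(S[sl, sl], need, rng)
        pools.append({"V": Vf, "used": 0})

    def take(f):
        p = pools[f]
        v = p["V"][:, p["used"]]
        p["used"] += 1
        return v

    occ = float(spin_channels)
    P_ref = np.zeros((n, n))
    P_cmp = np.zeros((n, n))
    frag_dq = np.zeros(nf)
    q_truth = []
    for (fd, fa, theta) in transfers:
        if not 0.0 <= theta <= np.pi / 2:
            raise ValueError("theta must lie in [0, pi/2]")
        vd, va = take(fd), take(fa)
        P_ref += occ * np.outer(vd, vd)
        w = np.cos(theta) * vd + np.sin(theta) * va
        P_cmp += occ * np.outer(w, w)
        s = occ * np.sin(theta)
        if s > 0:
            q_truth.extend([s, -s])
        frag_dq[fd] += occ * np.sin(theta) ** 2
        frag_dq[fa] -= occ * np.sin(theta) ** 2
    q_truth = np.array(sorted(q_truth, reverse=True))
    names = [f"frag{f}" for f in range(nf)]
    partition = FragmentPartition.from_dict(
        {names[f]: list(range(offsets[f] + 1, offsets[f + 1] + 1))
         for f in range(nf)})
    meta = AOBasisMeta(n_basis=n, atom_of_basis=np.arange(n),
                       atom_elements=["X"] * n)
    archive = MatrixArchive(S=S, P_ref=P_ref, P_cmp=P_cmp, meta=meta,
                            labels=("ref", "cmp"))
    truth = {
        "q_nd": q_truth,
        "fragment_delta_q": dict(zip(names, frag_dq)),
        "transfers": [(names[fd], names[fa], float(th))
                      for fd, fa, th in transfers],
        "transferred_per_channel": [float(np.sin(th) ** 2)
                                    for _, _, th in transfers],
        "spin_channels": spin_channels,
    }
    return SyntheticCTResult(archive=archive, partition=partition,
                             truth=truth)


def make_ct_pair(spec: SyntheticCTSpec) -> SyntheticCTResult:
    """Single occupied->virtual rotation between two fragments.

    Ground truth: leading q_nd = +/- spin_channels * sin(theta);
    donor/acceptor deformation charge +/- spin_channels * sin^2(theta).
    """
    res = make_multi_ct([spec.n1, spec.n2], [(0, 1, spec.theta)],
                        spin_channels=spec.spin_channels, seed=spec.seed,
                        overlap_mode=spec.overlap_mode)
    res.truth["theta"] = spec.theta
    res.partition.names[0] = "donor"
    res.partition.names[1] = "acceptor"
    res.truth["fragment_delta_q"] = {
        "donor": res.truth["fragment_delta_q"]["frag0"],
        "acceptor": res.truth["fragment_delta_q"]["frag1"]}
    return res


# ---------------------------------------------------------------------------
# frontier-level tables
# ---------------------------------------------------------------------------

DEFAULT_BANDS = {
    # charge: (HOMO band, LUMO band), eV.  Emulates the qualitative layout
    # of semilocal-functional levels: anion HOMOs unbound (positive),
    # cation LUMOs deep, neutral levels in between.
    -1: ((0.0, 1.0), (5.0, 6.0)),
    0: ((-7.0, -6.0), (-1.0, 0.0)),
    1: ((-13.0, -12.0), (-7.0, -6.5)),
    2: ((-19.0, -18.0), (-13.0, -12.5)),
}


@dataclass
class SyntheticLevelsSpec:
    """Frontier-level table layout: species, charge states, planted pairs.

    k = None draws every level from its charge-state band (the counts are
    whatever the bands imply); an integer k plants exactly k non-Aufbau
    ordered pairs under the distinct-species rule on top of an otherwise
    gap-safe table.
    """

    n_species: int = 20
    charge_states: tuple = (-1, 0, 1)
    k: Optional[int] = None
    seed: int = 0
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    functional: str = "synthetic"


def _brute_force_screen(levels, functional) -> PairScreenResult:
    """Independent O(n^2) double loop used for generator ground truth."""
    charges = sorted({r.charge for r in levels})
    counts = pd.DataFrame(0, index=charges, columns=charges, dtype=int)
    counts.index.name = "Q_d"
    counts.columns.name = "Q_a"
    flagged = []
    for d in levels:
        for a in levels:
            if d.species == a.species:
                continue
            gap = a.lumo_ev - d.homo_ev
            if gap < 0.0:
                flagged.append((d.fragment_id, a.fragment_id, float(gap)))
                counts.loc[d.charge, a.charge] += 1
    return PairScreenResult(flagged=flagged, counts=counts,
                            functional=functional)


def make_levels_table(spec: SyntheticLevelsSpec):
    """Generate a levels table plus its brute-force screening ground truth.

    Returns (records, truth: PairScreenResult).
    """
    rng = np.random.default_rng(spec.seed)
    state_name = {-1: "minus", 0: "neutral", 1: "plus", 2: "plus2"}
    records = []
    index = {}
    for s in range(spec.n_species):
        species = f"aa{s:02d}"
        for q in spec.charge_states:
            if spec.k is None:
                (h0, h1), (l0, l1) = spec.bands[q]
                homo = rng.uniform(h0, h1)
                lumo = rng.uniform(l0, l1)
            else:
                # gap-safe base table: every LUMO above every HOMO
                homo = rng.uniform(-10.5, -10.0)
                lumo = rng.uniform(-8.0, -7.5)
            rec = FrontierLevels(
                fragment_id=f"{species}_{state_name.get(q, q)}",
                charge=q, homo_ev=homo, lumo_ev=lumo,
                functional=spec.functional, amino_acid=species)
            records.append(rec)
            index[(s, q)] = len(records) - 1
    if spec.k is not None and spec.k > 0:
        records = _plant_pairs(records, index, spec, rng)
    truth = _brute_force_screen(records, spec.functional)
    if spec.k is not None and truth.total != spec.k:
        raise RuntimeError(
            f"planting failed: requested {spec.k}, produced {truth.total}")
    return records, truth


def _plant_pairs(records, index, spec, rng):
    """Raise donor HOMOs / lower acceptor LUMOs in a staircase so that
    exactly k ordered distinct-species pairs acquire a negative gap."""
    k = spec.k
    qd = spec.charge_states[0]
    qa = spec.charge_states[-1]
    if qd == qa:
        raise ValueError("need at least two charge states to plant pairs")
    # staircase row lengths: p donors, rows c_i <= q_cols each
    max_cols = 14  # keeps the raised band inside (-9.5, -8.0)
    best = None
    for q_cols in range(1, min(max_cols, spec.n_species - 1) + 1):
        p_rows = -(-k // q_cols)  # ceil
        if p_rows + q_cols <= spec.n_species and p_rows * q_cols >= k:
            best = (p_rows, q_cols)
            break
    if best is None:
        raise ValueError(
            f"cannot plant k={k} non-Aufbau pairs with "
            f"{spec.n_species} species (increase n_species or lower k)")
    p_rows, q_cols = best
    species_ids = rng.permutation(spec.n_species)
    donors = species_ids[:p_rows]
    acceptors = species_ids[p_rows:p_rows + q_cols]
    remaining = k
    rows = []
    for _ in range(p_rows):
        c = min(q_cols, remaining)
        rows.append(c)
        remaining -= c
    for j, sa in enumerate(acceptors, start=1):
        idx = index[(sa, qa)]
        r = records[idx]
        records[idx] = FrontierLevels(
            fragment_id=r.fragment_id, charge=r.charge, homo_ev=r.homo_ev,
            lumo_ev=-9.5 + 0.1 * j, functional=r.functional,
            amino_acid=r.amino_acid)
    for c_i, sd in zip(rows, donors):
        idx = index[(sd, qd)]
        r = records[idx]
        records[idx] = FrontierLevels(
            fragment_id=r.fragment_id, charge=r.charge,
            homo_ev=-9.5 + 0.1 * c_i + 0.05, lumo_ev=r.lumo_ev,
            functional=r.functional, amino_acid=r.amino_acid)
    return records


# ---------------------------------------------------------------------------
# two-level charge-transfer toy model
# ---------------------------------------------------------------------------

class ToyCTModel:
    """Engine-protocol object for E(x) = -delta*x + gamma*x*(1-x).

    Two orthonormal levels; one electron (single spin channel) occupies
    v(theta) = cos(theta) e1 + sin(theta) e2, so the transferred fraction
    is x = P[1, 1].  energy_and_fock returns the exact derivative
    F = dE/dP, making the model a drop-in for the quasi-Newton solver.
    """

    def __init__(self, delta, gamma):
        if gamma == 0.0:
            raise ValueError("gamma must be nonzero")
        self.delta = float(delta)
        self.gamma = float(gamma)

    def overlap(self):
        return np.eye(2)

    def energy(self, x):
        return -self.delta * x + self.gamma * x * (1.0 - x)

    def energy_and_fock(self, P):
        x = float(P[1, 1])
        F = np.zeros((2, 2))
        F[1, 1] = -self.delta + self.gamma * (1.0 - 2.0 * x)
        return self.energy(x), F

    @property
    def x_star(self):
        """Argmin of E over [0, 1] (closed form).

        gamma < 0 makes E(x) dip below the straight line between integer
        transfers (the delocalization-error signature); for gamma < -delta
        the stationary point x* = 1/2 - delta/(2*gamma) lies inside (0, 1)
        and is the global minimum.  gamma > 0 pushes the minimum to an
        integer endpoint.
        """
        candidates = [0.0, 1.0]
        if self.gamma < 0.0:
            xs = 0.5 - self.delta / (2.0 * self.gamma)
            if 0.0 < xs < 1.0:
                candidates.append(xs)
        return min(candidates, key=self.energy)

    def grid_minimum(self, n=2_000_001):
        """Brute-force grid search over x, an independent oracle."""
        xs = np.linspace(0.0, 1.0, n)
        es = self.energy(xs)
        i = int(np.argmin(es))
        return xs[i], es[i]

    def guess(self, x0=0.0):
        th = np.arcsin(np.sqrt(x0))
        C = np.array([[np.cos(th), -np.sin(th)],
                      [np.sin(th), np.cos(th)]])
        return C, np.array([1.0, 0.0])


def make_toy_ct_model(delta, gamma) -> ToyCTModel:
    return ToyCTModel(delta, gamma)
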