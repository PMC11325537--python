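"""Readers and writers for every on-disk representation.

Atom indices are 1-based in all external files (fragment definitions,
reports) and 0-based in memory; energies are stored in hartree and
reported in eV.
"""

from __future__ import annotations

import json
import pathlib
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

HARTREE_EV = 27.211386245988
BOHR_ANGSTROM = 0.52917721092


class ArchiveFormatError(ValueError):
    """A required dataset is missing or malformed."""


class DimensionError(ValueError):
    """Matrix dimensions in an archive are inconsistent."""


class UnsupportedFeatureError(ValueError):
    """The file uses a feature outside this package's scope."""


# ---------------------------------------------------------------------------
# geometry files
# ---------------------------------------------------------------------------

def read_xyz(path):
    """Read an XYZ file; returns (elements, coords_bohr)."""
    lines = pathlib.Path(path).read_text().splitlines()
    n = int(lines[0].split()[0])
    elements, coords = [], []
    for ln in lines[2:2 + n]:
        t = ln.split()
        elements.append(t[0])
        coords.append([float(v) for v in t[1:4]])
    return elements, np.asarray(coords) / BOHR_ANGSTROM


def write_xyz(path, elements, coords_angstrom, comment=""):
    with open(path, "w") as fh:
        fh.write(f"{len(elements)}\n{comment}\n")
        for el, (x, y, z) in zip(elements, np.asarray(coords_angstrom)):
            fh.write(f"{el} {x:15.8f} {y:15.8f} {z:15.8f}\n")


def read_pdb(path):
    """Read elements and coordinates (bohr) from a PDB file via gemmi."""
    import gemmi

    st = gemmi.read_structure(str(path))
    elements, coords = [], []
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    elements.append(atom.element.name)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        break  # first model only
    return elements, np.asarray(coords) / BOHR_ANGSTROM


def read_geometry(path):
    p = pathlib.Path(path)
    if p.suffix.lower() in (".pdb", ".ent"):
        return read_pdb(p)
    return read_xyz(p)


# ---------------------------------------------------------------------------
# basis metadata and matrix archive
# ---------------------------------------------------------------------------

@dataclass
class ShellMeta:
    """Metadata for one contracted shell, sufficient for Molden export.

    Coefficients are publication-style (relative to normalized primitives
    of the shell's angular momentum).
    """

    atom: int       # 0-based
    l: int          # 0=s, 1=p, 2=d (Cartesian)
    exps: np.ndarray
    coefs: np.ndarray


@dataclass
class AOBasisMeta:
    """Atom map and (optionally) full shell metadata of an AO basis."""

    n_basis: int
    atom_of_basis: np.ndarray        # 0-based atom per AO
    atom_elements: list              # element symbol per atom
    atom_coords_bohr: Optional[np.ndarray] = None
    shells: Optional[list] = None    # list[ShellMeta]

    def __post_init__(self):
        self.atom_of_basis = np.asarray(self.atom_of_basis, dtype=np.int64)
        if len(self.atom_of_basis) != self.n_basis:
            raise DimensionError("atom_of_basis length != n_basis")
        if self.atom_of_basis.min(initial=0) < 0 or \
                self.atom_of_basis.max(initial=-1) >= len(self.atom_elements):
            raise ArchiveFormatError(
                "atom_of_basis references atoms outside atom_elements")

    @classmethod
    def from_basis_set(cls, bs):
        """Extract metadata from an engine BasisSet."""
        from .engine.basis import _primitive_norm, _contracted_selfoverlap

        shells = []
        for sh in bs.shells:
            norms = np.array([_primitive_norm(sh.l, a) for a in sh.exps])
            shells.append(ShellMeta(atom=sh.atom, l=sh.l,
                                    exps=sh.exps.copy(),
                                    coefs=sh.coefs / norms))
        return cls(n_basis=bs.n_basis, atom_of_basis=bs.atom_of_basis,
                   atom_elements=list(bs.elements),
                   atom_coords_bohr=bs.coords.copy(), shells=shells)

    def to_basis_set(self):
        """Rebuild an engine BasisSet (needed to evaluate integrals)."""
        from .engine.basis import BasisSet, Shell, _primitive_norm, \
            _contracted_selfoverlap

        if self.shells is None:
            raise ArchiveFormatError("no shell metadata stored")
        if self.atom_coords_bohr is None:
            raise ArchiveFormatError("no atom coordinates stored")
        bs = BasisSet(name="from-meta", elements=list(self.atom_elements),
                      coords=np.asarray(self.atom_coords_bohr, float))
        for sm in self.shells:
            norms = np.array([_primitive_norm(sm.l, a) for a in sm.exps])
            coefs = sm.coefs * norms
            selfov = _contracted_selfoverlap(sm.l, sm.exps, coefs)
            coefs = coefs / np.sqrt(selfov)
            bs.shells.append(Shell(l=sm.l, atom=sm.atom,
                                   origin=bs.coords[sm.atom],
                                   exps=np.asarray(sm.exps, float),
                                   coefs=coefs))
        ao = 0
        for sh in bs.shells:
            sh.first_ao = ao
            ao += sh.ncomp
        return bs


@dataclass
class MatrixArchive:
    """In-memory form of the single-file matrix container.

    Fixed dataset names: S, P_ref, P_cmp (required), C, eps, occ
    (optional), plus the AO basis metadata.  All matrices share one
    dimension; S must be symmetric to 1e-10 after the read-time
    symmetrization.
    """

    S: np.ndarray
    P_ref: np.ndarray
    P_cmp: np.ndarray
    meta: AOBasisMeta
    C: Optional[np.ndarray] = None
    eps: Optional[np.ndarray] = None
    occ: Optional[np.ndarray] = None
    labels: tuple = ("ref", "cmp")
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.S.shape[0]
        for name in ("S", "P_ref", "P_cmp"):
            M = getattr(self, name)
            if M.shape != (n, n):
                raise DimensionError(
                    f"dataset {name} has shape {M.shape}, expected {(n, n)}")
        if self.meta.n_basis != n:
            raise DimensionError(
                f"basis metadata says n_basis={self.meta.n_basis}, "
                f"matrices are {n}x{n}")
        asym = np.abs(self.S - self.S.T).max()
        if asym > 1e-10:
            raise ArchiveFormatError(
                f"overlap not symmetric (dev {asym:.2e})")

    @property
    def n_basis(self):
        return self.S.shape[0]


def write_matrix_archive(archive: MatrixArchive, path):
    """Write the archive as a single HDF5 file with fixed dataset names."""
    import h5py

    with h5py.File(path, "w") as fh:
        for name in ("S", "P_ref", "P_cmp"):
            fh.create_dataset(name, data=getattr(archive, name))
        for name in ("C", "eps", "occ"):
            v = getattr(archive, name)
            if v is not None:
                fh.create_dataset(name, data=v)
        fh.create_dataset("atom_of_basis", data=archive.meta.atom_of_basis)
        fh.create_dataset(
            "atom_elements",
            data=np.array(archive.meta.atom_elements, dtype="S4"))
        if archive.meta.atom_coords_bohr is not None:
            fh.create_dataset("atom_coords_bohr",
                              data=archive.meta.atom_coords_bohr)
        fh.attrs["labels"] = list(archive.labels)
        if archive.meta.shells is not None:
            g = fh.create_group("shells")
            g.create_dataset("atom", data=np.array(
                [s.atom for s in archive.meta.shells]))
            g.create_dataset("l", data=np.array(
                [s.l for s in archive.meta.shells]))
            g.create_dataset("nprim", data=np.array(
                [len(s.exps) for s in archive.meta.shells]))
            g.create_dataset("exps", data=np.concatenate(
                [s.exps for s in archive.meta.shells]))
            g.create_dataset("coefs", data=np.concatenate(
                [s.coefs for s in archive.meta.shells]))
        if archive.extras:
            ge = fh.create_group("extras")
            for k, v in archive.extras.items():
                ge.create_dataset(k, data=v)


def read_matrix_archive(path) -> MatrixArchive:
    """Read a matrix archive; symmetrizes S/P_ref/P_cmp as (M + M^T)/2 and
    warns when the asymmetry exceeded 1e-8."""
    import h5py

    with h5py.File(path, "r") as fh:
        data = {}
        for name in ("S", "P_ref", "P_cmp"):
            if name not in fh:
                raise ArchiveFormatError(f"missing required dataset {name!r}")
            M = fh[name][()]
            asym = np.abs(M - M.T).max()
            if asym > 1e-8:
                warnings.warn(
                    f"dataset {name} asymmetric by {asym:.2e}; symmetrized",
                    stacklevel=2)
            data[name] = (M + M.T) / 2.0
        n = data["S"].shape[0]
        for name in ("S", "P_ref", "P_cmp"):
            if data[name].shape != (n, n):
                raise DimensionError(
                    f"dataset {name} has shape {data[name].shape}, "
                    f"expected {(n, n)}")
        if "atom_of_basis" not in fh:
            raise ArchiveFormatError("missing required dataset 'atom_of_basis'")
        atom_of_basis = fh["atom_of_basis"][()]
        elements = [e.decode() for e in fh["atom_elements"][()]] \
            if "atom_elements" in fh else \
            ["X"] * (int(atom_of_basis.max()) + 1)
        coords = fh["atom_coords_bohr"][()] if "atom_coords_bohr" in fh else None
        shells = None
        if "shells" in fh:
            g = fh["shells"]
            nprim = g["nprim"][()]
            exps = g["exps"][()]
            coefs = g["coefs"][()]
            shells = []
            p = 0
            for atom, l, np_ in zip(g["atom"][()], g["l"][()], nprim):
                shells.append(ShellMeta(atom=int(atom), l=int(l),
                                        exps=exps[p:p + np_],
                                        coefs=coefs[p:p + np_]))
                p += np_
        meta = AOBasisMeta(n_basis=n, atom_of_basis=atom_of_basis,
                           atom_elements=elements, atom_coords_bohr=coords,
                           shells=shells)
        extras = {}
        if "extras" in fh:
            for k in fh["extras"]:
                extras[k] = fh["extras"][k][()]
        labels = tuple(fh.attrs.get("labels", ("ref", "cmp")))
        return MatrixArchive(
            S=data["S"], P_ref=data["P_ref"], P_cmp=data["P_cmp"], meta=meta,
            C=fh["C"][()] if "C" in fh else None,
            eps=fh["eps"][()] if "eps" in fh else None,
            occ=fh["occ"][()] if "occ" in fh else None,
            labels=labels, extras=extras)


# ---------------------------------------------------------------------------
# Molden
# ---------------------------------------------------------------------------

_MOLDEN_LTYPE = {0: "s", 1: "p", 2: "d"}
_MOLDEN_LNUM = {"s": 0, "p": 1, "d": 2}
_NCOMP_L = {0: 1, 1: 3, 2: 6}
_Z_OF = {"H": 1, "C": 6, "N": 7, "O": 8, "X": 0}


class ExportError(ValueError):
    pass


def _write_molden(path, meta: AOBasisMeta, coeff_columns, occ_like, ene_like,
                  labels=None):
    if meta.shells is None or meta.atom_coords_bohr is None:
        raise ExportError(
            "shell metadata or coordinates missing; write a matrix archive "
            "instead (write_matrix_archive) for purely algebraic data")
    with open(path, "w") as fh:
        fh.write("[Molden Format]\n[Atoms] AU\n")
        for ia, (el, xyz) in enumerate(zip(meta.atom_elements,
                                           meta.atom_coords_bohr), start=1):
            z = _Z_OF.get(el, 0)
            fh.write(f"{el:4s} {ia:4d} {z:4d} "
                     f"{xyz[0]:18.10f} {xyz[1]:18.10f} {xyz[2]:18.10f}\n")
        fh.write("[GTO]\n")
        for ia in range(len(meta.atom_elements)):
            fh.write(f"{ia + 1} 0\n")
            for sm in meta.shells:
                if sm.atom != ia:
                    continue
                fh.write(f" {_MOLDEN_LTYPE[sm.l]} {len(sm.exps):3d} 1.00\n")
                for e, c in zip(sm.exps, sm.coefs):
                    fh.write(f"  {e:20.10e} {c:20.10e}\n")
            fh.write("\n")
        fh.write("[MO]\n")
        for k in range(coeff_columns.shape[1]):
            fh.write(" Sym= A\n")
            fh.write(f" Ene= {ene_like[k]:.10f}\n")
            fh.write(" Spin= Alpha\n")
            fh.write(f" Occup= {occ_like[k]:.10f}\n")
            for mu in range(coeff_columns.shape[0]):
                fh.write(f" {mu + 1:4d} {coeff_columns[mu, k]:20.12e}\n")


def write_ndo_molden(ndos, meta: AOBasisMeta, path):
    """Export NDOs as Molden 'orbitals' whose occupation field carries q_nd.

    Visualizers then display the deformation charge next to each orbital;
    negative values mark density gained by the compared (cmp) method.
    Ordering is by descending q_nd (the NDOSet order).
    """
    _write_molden(path, meta, ndos.vectors, ndos.q_nd,
                  ene_like=np.zeros(len(ndos)))


def write_orbitals_molden(solution, meta: AOBasisMeta, path):
    """Export an SCF solution's orbitals (occupations and energies)."""
    _write_molden(path, meta, solution.C, solution.occ, solution.eps)


def read_molden(path) -> MatrixArchive:
    """Read a Molden file written by this package (or compatible subset).

    Supports s/p/Cartesian-d GTOs and restricted (Alpha-only) orbitals;
    spherical-harmonic flags and Beta spins raise UnsupportedFeatureError.
    The density P = C diag(occ) C^T is stored as both P_ref and P_cmp (a
    single-solution archive); S is rebuilt from the shell metadata.
    """
    text = pathlib.Path(path).read_text()
    if any(tag in text for tag in ("[5D", "[7F", "[9G")):
        raise UnsupportedFeatureError(
            "spherical-harmonic Molden files are not supported (Cartesian "
            "d only)")
    lines = text.splitlines()
    sec = None
    atoms, shells, mos = [], [], []
    unit = 1.0
    i = 0
    while i < len(lines):
        ln = lines[i].strip()
        low = ln.lower()
        if low.startswith("[atoms]"):
            sec = "atoms"
            unit = 1.0 if "au" in low else 1.0 / BOHR_ANGSTROM
            i += 1
            continue
        if low.startswith("[gto]"):
            sec = "gto"
            i += 1
            continue
        if low.startswith("[mo]"):
            sec = "mo"
            i += 1
            continue
        if low.startswith("["):
            sec = None
            i += 1
            continue
        if sec == "atoms" and ln:
            t = ln.split()
            atoms.append((t[0], [float(v) * unit for v in t[3:6]]))
        elif sec == "gto":
            if ln:
                t = ln.split()
                if len(t) >= 1 and t[0].isdigit() and \
                        (len(t) == 1 or t[-1].replace(".", "").isdigit()):
                    cur_atom = int(t[0]) - 1
                elif t[0].lower() in _MOLDEN_LNUM:
                    ltyp = t[0].lower()
                    if ltyp == "sp":
                        raise UnsupportedFeatureError("sp shells in Molden")
                    nprim = int(t[1])
                    exps, coefs = [], []
                    for k in range(nprim):
                        i += 1
                        a, c = lines[i].replace("D", "E").split()[:2]
                        exps.append(float(a))
                        coefs.append(float(c))
                    shells.append(ShellMeta(atom=cur_atom,
                                            l=_MOLDEN_LNUM[ltyp],
                                            exps=np.array(exps),
                                            coefs=np.array(coefs)))
        elif sec == "mo" and ln:
            if ln.lower().startswith("sym="):
                mos.append({"coef": {}})
            elif ln.lower().startswith("ene="):
                mos[-1]["ene"] = float(ln.split("=")[1])
            elif ln.lower().startswith("spin="):
                spin = ln.split("=")[1].strip().lower()
                if spin != "alpha":
                    raise UnsupportedFeatureError(
                        "spin-polarized (Beta) Molden blocks are not "
                        "supported")
                mos[-1]["spin"] = spin
            elif ln.lower().startswith("occup="):
                mos[-1]["occ"] = float(ln.split("=")[1])
            else:
                t = ln.split()
                if len(t) == 2:
                    mos[-1]["coef"][int(t[0]) - 1] = float(t[1])
        i += 1
    elements = [a[0] for a in atoms]
    coords = np.array([a[1] for a in atoms])
    n_basis = sum(_NCOMP_L[s.l] for s in shells)
    atom_of_basis = np.concatenate(
        [[s.atom] * _NCOMP_L[s.l] for s in shells]).astype(np.int64)
    meta = AOBasisMeta(n_basis=n_basis, atom_of_basis=atom_of_basis,
                       atom_elements=elements, atom_coords_bohr=coords,
                       shells=shells)
    C = np.zeros((n_basis, len(mos)))
    occ = np.array([m.get("occ", 0.0) for m in mos])
    eps = np.array([m.get("ene", 0.0) for m in mos])
    for k, m in enumerate(mos):
        for mu, v in m["coef"].items():
            C[mu, k] = v
    bs = meta.to_basis_set()
    from .engine import integrals as ints
    S = ints.overlap_kinetic(bs)[0]
    P = (C * occ) @ C.T
    return MatrixArchive(S=S, P_ref=P, P_cmp=P, meta=meta, C=C, eps=eps,
                         occ=occ)


# ---------------------------------------------------------------------------
# formatted checkpoint (fchk)
# ---------------------------------------------------------------------------

def _fchk_array(lines, i):
    head = lines[i]
    n = int(head.split("N=")[1])
    vals = []
    j = i + 1
    while len(vals) < n:
        vals.extend(float(v) for v in lines[j].split())
        j += 1
    return np.array(vals), j


def read_fchk(path) -> MatrixArchive:
    """Read a Gaussian-style formatted checkpoint (restricted only).

    Rebuilds the basis from the shell blocks (s, p, sp, Cartesian d),
    reconstructs P from the MO coefficients and occupation count, and
    computes the overlap from the basis (fchk stores none).  Files with
    beta MO coefficients raise UnsupportedFeatureError (no silent spin
    summing); spherical-harmonic shells (-2) are not supported.
    """
    lines = pathlib.Path(path).read_text().splitlines()
    scal, arrays = {}, {}
    i = 0
    while i < len(lines):
        ln = lines[i]
        if "N=" in ln:
            name = ln[:43].strip()
            arr, i = _fchk_array(lines, i)
            arrays[name] = arr
            continue
        if len(ln) > 43 and ln[43] in "IR":
            name = ln[:43].strip()
            try:
                scal[name] = float(ln.split()[-1])
            except ValueError:
                pass
        i += 1
    if "Beta MO coefficients" in arrays:
        raise UnsupportedFeatureError(
            "spin-polarized fchk (Beta MO coefficients present); "
            "spin-summed reading is deliberately not attempted")
    for req in ("Shell types", "Primitive exponents",
                "Contraction coefficients", "Alpha MO coefficients"):
        if req not in arrays:
            raise ArchiveFormatError(f"missing fchk block {req!r}")
    shell_types = arrays["Shell types"].astype(int)
    if np.any(shell_types < -1) or np.any(shell_types > 2):
        raise UnsupportedFeatureError(
            f"unsupported shell types {sorted(set(shell_types))} "
            "(only s, p, sp, Cartesian d)")
    nprim = arrays["Number of primitives per shell"].astype(int)
    shell_atom = arrays["Shell to atom map"].astype(int) - 1
    exps = arrays["Primitive exponents"]
    coefs = arrays["Contraction coefficients"]
    sp_coefs = arrays.get("P(S=P) Contraction coefficients")
    zs = arrays["Atomic numbers"].astype(int)
    inv_z = {1: "H", 6: "C", 7: "N", 8: "O"}
    elements = [inv_z.get(z, f"Z{z}") for z in zs]
    coords = arrays["Current cartesian coordinates"].reshape(-1, 3)
    shells = []
    p = 0
    for st, npr, ia in zip(shell_types, nprim, shell_atom):
        e = exps[p:p + npr]
        c = coefs[p:p + npr]
        if st == -1:  # sp
            shells.append(ShellMeta(atom=ia, l=0, exps=e, coefs=c))
            shells.append(ShellMeta(atom=ia, l=1, exps=e,
                                    coefs=sp_coefs[p:p + npr]))
        else:
            shells.append(ShellMeta(atom=ia, l=st, exps=e, coefs=c))
        p += npr
    n_basis = sum(_NCOMP_L[s.l] for s in shells)
    atom_of_basis = np.concatenate(
        [[s.atom] * _NCOMP_L[s.l] for s in shells]).astype(np.int64)
    meta = AOBasisMeta(n_basis=n_basis, atom_of_basis=atom_of_basis,
                       atom_elements=elements, atom_coords_bohr=coords,
                       shells=shells)
    C = arrays["Alpha MO coefficients"].reshape(-1, n_basis).T
    eps = arrays.get("Alpha Orbital Energies")
    n_alpha = int(scal.get("Number of alpha electrons", 0))
    occ = np.zeros(C.shape[1])
    occ[:n_alpha] = 2.0
    bs = meta.to_basis_set()
    from .engine import integrals as ints
    S = ints.overlap_kinetic(bs)[0]
    P = (C * occ) @ C.T
    return MatrixArchive(S=S, P_ref=P, P_cmp=P, meta=meta, C=C, eps=eps,
                         occ=occ)


def write_fchk(path, solution, meta: AOBasisMeta, title="ndokit export"):
    """Write a minimal restricted fchk (round-trips through read_fchk)."""
    if meta.shells is None:
        raise ExportError("shell metadata required for fchk export")
    z_of = dict(_Z_OF)
    lines = [title, "SP        RHF       generic"]

    def int_scalar(name, v):
        lines.append(f"{name:<43}I {v:16d}")

    def arr(name, typ, vals):
        vals = np.asarray(vals).ravel()
        lines.append(f"{name:<43}{typ}   N= {len(vals):11d}")
        per = 5 if typ == "R" else 6
        fmt = "{:16.8E}" if typ == "R" else "{:12d}"
        for k in range(0, len(vals), per):
            chunk = vals[k:k + per]
            lines.append("".join(
                fmt.format(float(v) if typ == "R" else int(v))
                for v in chunk))

    n_alpha = int(round(solution.occ.sum() / 2))
    int_scalar("Number of atoms", len(meta.atom_elements))
    int_scalar("Number of alpha electrons", n_alpha)
    int_scalar("Number of basis functions", meta.n_basis)
    arr("Atomic numbers", "I", [z_of.get(e, 0) for e in meta.atom_elements])
    arr("Current cartesian coordinates", "R", meta.atom_coords_bohr)
    arr("Shell types", "I", [s.l for s in meta.shells])
    arr("Number of primitives per shell", "I",
        [len(s.exps) for s in meta.shells])
    arr("Shell to atom map", "I", [s.atom + 1 for s in meta.shells])
    arr("Primitive exponents", "R",
        np.concatenate([s.exps for s in meta.shells]))
    arr("Contraction coefficients", "R",
        np.concatenate([s.coefs for s in meta.shells]))
    arr("Alpha Orbital Energies", "R", solution.eps)
    arr("Alpha MO coefficients", "R", solution.C.T)
    pathlib.Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# frontier-level tables (CSV)
# ---------------------------------------------------------------------------

def read_levels_csv(path):
    """Read a frontier-levels table into FrontierLevels records.

    Required columns: fragment_id, charge, homo_ev, lumo_ev; optional:
    functional, amino_acid.  Energies are in eV.  Duplicate
    (fragment_id, charge, functional) keys and non-numeric energies are
    rejected with the offending row number (1-based, excluding header).
    """
    import pandas as pd

    from .screen import FrontierLevels

    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    required = ["fragment_id", "charge", "homo_ev", "lumo_ev"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ArchiveFormatError(f"levels CSV missing columns {missing}")
    records = []
    seen = {}
    for irow, row in df.iterrows():
        try:
            charge = int(row["charge"])
            homo = float(row["homo_ev"])
            lumo = float(row["lumo_ev"])
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"levels CSV row {irow + 1}: non-numeric field ({exc})") \
                from None
        functional = str(row["functional"]) if "functional" in df.columns \
            and not pd.isna(row["functional"]) else "unspecified"
        amino = str(row["amino_acid"]) if "amino_acid" in df.columns \
            and not pd.isna(row["amino_acid"]) else None
        key = (row["fragment_id"], charge, functional)
        if key in seen:
            raise ValueError(
                f"levels CSV row {irow + 1}: duplicate key {key} "
                f"(first seen at row {seen[key] + 1})")
        seen[key] = irow
        records.append(FrontierLevels(
            fragment_id=str(row["fragment_id"]), charge=charge,
            homo_ev=homo, lumo_ev=lumo, functional=functional,
            amino_acid=amino))
    return records


def write_levels_csv(records, path):
    import pandas as pd

    rows = [{"fragment_id": r.fragment_id, "charge": r.charge,
             "homo_ev": r.homo_ev, "lumo_ev": r.lumo_ev,
             "functional": r.functional, "amino_acid": r.amino_acid}
            for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fragment definitions (YAML / JSON)
# ---------------------------------------------------------------------------

def read_fragments(path, n_atoms=None):
    """Read {fragment name: [1-based atom indices]} from YAML or JSON."""
    from .fragments import FragmentPartition

    p = pathlib.Path(path)
    if p.suffix.lower() in (".yaml", ".yml"):
        import yaml

        mapping = yaml.safe_load(p.read_text())
    else:
        mapping = json.loads(p.read_text())
    if not isinstance(mapping, dict):
        raise ArchiveFormatError(
            "fragment file must map names to atom-index lists")
    return FragmentPartition.from_dict(mapping, n_atoms=n_atoms)


def write_json_report(obj, path):
    data = obj.to_dict() if hasattr(obj, "to_dict") else obj
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)


def read_qc_orbitals(path, dialect) -> MatrixArchive:
    """Read orbitals/densities from an external-engine file.

    dialect: 'molden' or 'fchk'.  The density is reconstructed as
    P = C diag(occ) C^T when not stored directly, and the overlap is
    rebuilt from the shell metadata.
    """
    readers = {"molden": read_molden, "fchk": read_fchk}
    if dialect not in readers:
        raise ValueError(f"unknown dialect {dialect!r}; "
                         f"choose from {sorted(readers)}")
    return readers[dialect](path)
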