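"""Gaussian basis sets and their construction.

Contains the published Pople basis-set parameters (STO-3G and the 6-31G
family with polarization) for H, C, N, O — the elements needed for the
amino-acid workflows — transcribed from the original literature
(Hehre/Stewart/Pople 1969; Ditchfield/Hehre/Pople 1971; Hariharan/Pople
1973).  Cartesian (6d) components are used throughout, matching the common
convention for the 6-31G family.

All lengths are in bohr and exponents in bohr^-2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# double factorial (2n-1)!! for n = 0..4
_DFACT = {0: 1.0, 1: 1.0, 2: 3.0, 3: 15.0, 4: 105.0}

# Cartesian component exponent triples per angular momentum, Molden ordering.
CART_COMPONENTS = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    2: [(2, 0, 0), (0, 2, 0), (0, 0, 2), (1, 1, 0), (1, 0, 1), (0, 1, 1)],
}

# ---------------------------------------------------------------------------
# Published basis data.  Shell entries are (type, [(exponent, coeff...), ...]);
# 'sp' rows carry (exponent, s-coeff, p-coeff).
# ---------------------------------------------------------------------------

STO3G = {
    "H": [("s", [(3.42525091, 0.15432897),
                 (0.62391373, 0.53532814),
                 (0.16885540, 0.44463454)])],
    "C": [("s", [(71.616837, 0.15432897),
                 (13.045096, 0.53532814),
                 (3.5305122, 0.44463454)]),
          ("sp", [(2.9412494, -0.09996723, 0.15591627),
                  (0.6834831, 0.39951283, 0.60768372),
                  (0.2222899, 0.70011547, 0.39195739)])],
    "N": [("s", [(99.106169, 0.15432897),
                 (18.052312, 0.53532814),
                 (4.8856602, 0.44463454)]),
          ("sp", [(3.7804559, -0.09996723, 0.15591627),
                  (0.8784966, 0.39951283, 0.60768372),
                  (0.2857144, 0.70011547, 0.39195739)])],
    "O": [("s", [(130.70932, 0.15432897),
                 (23.808861, 0.53532814),
                 (6.4436083, 0.44463454)]),
          ("sp", [(5.0331513, -0.09996723, 0.15591627),
                  (1.1695961, 0.39951283, 0.60768372),
                  (0.3803890, 0.70011547, 0.39195739)])],
}

G631 = {
    "H": [("s", [(18.7311370, 0.03349460),
                 (2.8253937, 0.23472695),
                 (0.6401217, 0.81375733)]),
          ("s", [(0.1612778, 1.0)])],
    "C": [("s", [(3047.5249, 0.0018347),
                 (457.36951, 0.0140373),
                 (103.94869, 0.0688426),
                 (29.210155, 0.2321844),
                 (9.2866630, 0.4679413),
                 (3.1639270, 0.3623120)]),
          ("sp", [(7.8682724, -0.1193324, 0.0689991),
                  (1.8812885, -0.1608542, 0.3164240),
                  (0.5442493, 1.1434564, 0.7443083)]),
          ("sp", [(0.1687144, 1.0, 1.0)])],
    "N": [("s", [(4173.5110, 0.0018348),
                 (627.45790, 0.0139950),
                 (142.90210, 0.0685870),
                 (40.234330, 0.2322410),
                 (12.820210, 0.4690700),
                 (4.3904370, 0.3604550)]),
          ("sp", [(11.626358, -0.1149612, 0.0675800),
                  (2.7162800, -0.1691180, 0.3239070),
                  (0.7722180, 1.1458520, 0.7408950)]),
          ("sp", [(0.2120313, 1.0, 1.0)])],
    "O": [("s", [(5484.6717, 0.0018311),
                 (825.23495, 0.0139501),
                 (188.04696, 0.0684451),
                 (52.964500, 0.2327143),
                 (16.897570, 0.4701930),
                 (5.7996353, 0.3585209)]),
          ("sp", [(15.539616, -0.1107775, 0.0708743),
                  (3.5999336, -0.1480263, 0.3397528),
                  (1.0137618, 1.1307670, 0.7271586)]),
          ("sp", [(0.2700058, 1.0, 1.0)])],
}

# polarization exponents for 6-31G*/6-31G**
POLARIZATION_D = {"C": 0.8, "N": 0.8, "O": 0.8}
POLARIZATION_P_H = 1.1

ELEMENT_Z = {"H": 1, "C": 6, "N": 7, "O": 8}


@dataclass
class Shell:
    """One contracted Cartesian shell."""

    l: int
    atom: int
    origin: np.ndarray
    exps: np.ndarray
    coefs: np.ndarray  # primitive coefficients incl. primitive norms
    first_ao: int = 0

    @property
    def ncomp(self) -> int:
        return len(CART_COMPONENTS[self.l])


@dataclass
class BasisSet:
    """A molecule-attached set of contracted Cartesian Gaussian shells."""

    name: str
    elements: list[str]
    coords: np.ndarray  # (natom, 3) bohr
    shells: list[Shell] = field(default_factory=list)

    @property
    def n_basis(self) -> int:
        return sum(sh.ncomp for sh in self.shells)

    @property
    def atom_of_basis(self) -> np.ndarray:
        out = np.empty(self.n_basis, dtype=np.int64)
        for sh in self.shells:
            out[sh.first_ao:sh.first_ao + sh.ncomp] = sh.atom
        return out

    @property
    def charges(self) -> np.ndarray:
        return np.array([ELEMENT_Z[e] for e in self.elements], dtype=float)

    def flatten(self):
        """Pack shells into flat arrays for the numba kernels.

        Returns (shell_l, shell_atom, shell_first_ao, prim_ptr, exps, coefs,
        origins) with prim_ptr[i]:prim_ptr[i+1] delimiting shell i's
        primitives.
        """
        nsh = len(self.shells)
        shell_l = np.array([sh.l for sh in self.shells], dtype=np.int64)
        shell_atom = np.array([sh.atom for sh in self.shells], dtype=np.int64)
        first = np.array([sh.first_ao for sh in self.shells], dtype=np.int64)
        ptr = np.zeros(nsh + 1, dtype=np.int64)
        for i, sh in enumerate(self.shells):
            ptr[i + 1] = ptr[i] + len(sh.exps)
        exps = np.concatenate([sh.exps for sh in self.shells])
        coefs = np.concatenate([sh.coefs for sh in self.shells])
        origins = np.array([sh.origin for sh in self.shells])
        return shell_l, shell_atom, first, ptr, exps, coefs, origins


def _primitive_norm(l: int, alpha: float) -> float:
    # Norm of the axial Cartesian component (l,0,0).
    return ((2.0 * alpha / np.pi) ** 0.75
            * (4.0 * alpha) ** (l / 2.0)
            / np.sqrt(_DFACT[l]))


def _contracted_selfoverlap(l: int, exps, coefs) -> float:
    s = 0.0
    for a, ca in zip(exps, coefs):
        for b, cb in zip(exps, coefs):
            p = a + b
            s += ca * cb * (np.pi / p) ** 1.5 * _DFACT[l] / (2.0 * p) ** l
    return s


def component_norm_factors(l: int) -> np.ndarray:
    """Per-component scaling so every Cartesian AO is unit-normalized.

    The contraction coefficients normalize the axial component (e.g. xx);
    off-axis components (e.g. xy) need sqrt((2l-1)!!/prod (2i-1)!!).
    """
    out = []
    for (i, j, k) in CART_COMPONENTS[l]:
        out.append(np.sqrt(_DFACT[l] / (_DFACT[i] * _DFACT[j] * _DFACT[k])))
    return np.array(out)


def _make_shell(l: int, atom: int, origin, rows, col: int) -> Shell:
    exps = np.array([r[0] for r in rows], dtype=float)
    raw = np.array([r[col] for r in rows], dtype=float)
    coefs = raw * np.array([_primitive_norm(l, a) for a in exps])
    norm = _contracted_selfoverlap(l, exps, coefs)
    coefs = coefs / np.sqrt(norm)
    return Shell(l=l, atom=atom, origin=np.asarray(origin, float),
                 exps=exps, coefs=coefs)


def build_basis(elements, coords_bohr, name: str = "6-31g**") -> BasisSet:
    """Construct a BasisSet for a molecule.

    Parameters
    ----------
    elements : sequence of element symbols
    coords_bohr : (natom, 3) positions in bohr
    name : one of 'sto-3g', '6-31g', '6-31g*', '6-31g**'
    """
    key = name.lower().replace("(d,p)", "**").replace("(d)", "*")
    if key == "sto-3g":
        table, pol_d, pol_ph = STO3G, False, False
    elif key == "6-31g":
        table, pol_d, pol_ph = G631, False, False
    elif key == "6-31g*":
        table, pol_d, pol_ph = G631, True, False
    elif key == "6-31g**":
        table, pol_d, pol_ph = G631, True, True
    else:
        raise ValueError(f"unknown basis set {name!r}")

    coords_bohr = np.asarray(coords_bohr, dtype=float)
    bs = BasisSet(name=key, elements=list(elements), coords=coords_bohr)
    for ia, el in enumerate(elements):
        if el not in table:
            raise ValueError(f"element {el!r} not available in {name}")
        origin = coords_bohr[ia]
        for typ, rows in table[el]:
            if typ == "s":
                bs.shells.append(_make_shell(0, ia, origin, rows, 1))
            elif typ == "sp":
                bs.shells.append(_make_shell(0, ia, origin, rows, 1))
                bs.shells.append(_make_shell(1, ia, origin, rows, 2))
            else:  # pragma: no cover - data is fixed above
                raise ValueError(typ)
        if pol_d and el in POLARIZATION_D:
            bs.shells.append(
                _make_shell(2, ia, origin, [(POLARIZATION_D[el], 1.0)], 1))
        if pol_ph and el == "H":
            bs.shells.append(
                _make_shell(1, ia, origin, [(POLARIZATION_P_H, 1.0)], 1))

    ao = 0
    for sh in bs.shells:
        sh.first_ao = ao
        ao += sh.ncomp
    return bs
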