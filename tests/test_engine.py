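"""Validation of the built-in Gaussian-basis HF/KS engine.

Independent oracles only: closed-form s-type formulas, center-derivative
identities (a p function is the A-derivative of an s function, a d
function its second derivative), an analytically integrable model density
for the grid, and the textbook H2/minimal-basis Hartree-Fock energy.
"""

import numpy as np
import pytest

from ndokit.engine import integrals as ints
from ndokit.engine.basis import BasisSet, Shell, build_basis
from ndokit.engine.grid import MolecularGrid
from ndokit.engine.rks import HARTREE_EV, RestrictedSCFEngine
from ndokit.engine.xc import get_functional, slater_e


def prim_basis(shelldefs):
    """Bare primitive shells (coefficient 1, no normalization)."""
    bs = BasisSet("raw", ["H"] * len(shelldefs),
                  np.array([d[2] for d in shelldefs], dtype=float))
    for i, (l, ex, org) in enumerate(shelldefs):
        bs.shells.append(Shell(l=l, atom=i, origin=np.array(org, float),
                               exps=np.array([ex]), coefs=np.array([1.0])))
    ao = 0
    for sh in bs.shells:
        sh.first_ao = ao
        ao += sh.ncomp
    return bs


A = np.array([0.1, -0.2, 0.3])
B = np.array([1.0, 0.8, -0.5])
C = np.array([-0.7, 0.4, 0.9])
D = np.array([0.3, -1.1, 0.2])
EXPS = (1.3, 0.47, 2.1, 0.8)


class TestOverlapKinetic:
    def test_s_overlap_closed_form(self):
        a, b = 1.3, 0.47
        bs = prim_basis([(0, a, A), (0, b, B)])
        S, T = ints.overlap_kinetic(bs)
        p = a + b
        mu = a * b / p
        r2 = float((A - B) @ (A - B))
        exact = (np.pi / p) ** 1.5 * np.exp(-mu * r2)
        assert S[0, 1] == pytest.approx(exact, rel=1e-12)
        # s-s kinetic closed form: mu*(3 - 2*mu*r2) * S
        exact_t = mu * (3.0 - 2.0 * mu * r2) * exact
        assert T[0, 1] == pytest.approx(exact_t, rel=1e-12)

    @pytest.mark.parametrize("l,row", [(1, 0), (2, 0)])
    def test_higher_l_from_center_derivatives(self, l, row):
        """p_x = (1/2a) dA_x (s); d_xx = (1/4a^2)(dA_x^2 + 2a)(s)."""
        a, b = 1.3, 0.47
        h = 2e-3

        def s_elem(Ax, which):
            bs = prim_basis([(0, a, Ax), (0, b, B)])
            M = ints.overlap_kinetic(bs)[which]
            return M[0, 1]

        for which in (0, 1):  # overlap and kinetic alike
            e = np.zeros(3)
            e[0] = 1.0
            d1 = (8 * (s_elem(A + h * e, which) - s_elem(A - h * e, which))
                  - (s_elem(A + 2 * h * e, which)
                     - s_elem(A - 2 * h * e, which))) / (12 * h)
            d2 = (-(s_elem(A + 2 * h * e, which)
                    + s_elem(A - 2 * h * e, which))
                  + 16 * (s_elem(A + h * e, which)
                          + s_elem(A - h * e, which))
                  - 30 * s_elem(A, which)) / (12 * h * h)
            bs = prim_basis([(l, a, A), (0, b, B)])
            M = ints.overlap_kinetic(bs)[which]
            col = bs.shells[1].first_ao
            if l == 1:
                assert M[0, col] == pytest.approx(d1 / (2 * a), abs=1e-9)
            else:
                want = (d2 + 2 * a * s_elem(A, which)) / (4 * a * a)
                assert M[0, col] == pytest.approx(want, abs=1e-8)

    def test_contracted_aos_unit_normalized(self):
        bs = build_basis(["C", "H"], [[0, 0, 0], [0, 0, 2.0]], "6-31g**")
        S = ints.overlap_kinetic(bs)[0]
        np.testing.assert_allclose(np.diag(S), 1.0, atol=1e-12)


class TestCoulombIntegrals:
    def test_ssss_eri_closed_form(self):
        a, b, c, d = EXPS
        bs = prim_basis([(0, a, A), (0, b, B), (0, c, C), (0, d, D)])
        eri = ints.eri(bs)
        p, q = a + b, c + d
        P = (a * A + b * B) / p
        Q = (c * C + d * D) / q
        from scipy.special import erf

        def F0(x):
            x = max(x, 1e-16)
            return 0.5 * np.sqrt(np.pi / x) * erf(np.sqrt(x))

        K1 = np.exp(-a * b / p * float((A - B) @ (A - B)))
        K2 = np.exp(-c * d / q * float((C - D) @ (C - D)))
        alpha = p * q / (p + q)
        exact = (2 * np.pi ** 2.5 / (p * q * np.sqrt(p + q)) * K1 * K2
                 * F0(alpha * float((P - Q) @ (P - Q))))
        assert eri[0, 1, 2, 3] == pytest.approx(exact, rel=1e-12)

    def test_p_function_eri_from_center_derivative(self):
        a, b, c, d = EXPS
        h = 2e-3

        def base(Cx):
            bs = prim_basis([(0, a, A), (0, b, B), (0, c, Cx), (0, d, D)])
            return ints.eri(bs)[0, 1, 2, 3]

        e = np.zeros(3)
        e[1] = 1.0
        d1 = (8 * (base(C + h * e) - base(C - h * e))
              - (base(C + 2 * h * e) - base(C - 2 * h * e))) / (12 * h)
        bs = prim_basis([(0, a, A), (0, b, B), (1, c, C), (0, d, D)])
        # p shell occupies AOs 2..4; p_y is its second component
        val = ints.eri(bs)[0, 1, 3, 5]
        assert val == pytest.approx(d1 / (2 * c), abs=1e-10)

    def test_nuclear_attraction_p_from_center_derivative(self):
        a, b = 1.1, 0.6
        Zc, Rc = 1.7, np.array([0.4, 0.2, -0.6])
        h = 2e-3

        def base(Ax):
            bs = prim_basis([(0, a, Ax), (0, b, B)])
            return ints.nuclear_attraction(bs, [Zc], [Rc])[0, 1]

        e = np.zeros(3)
        e[2] = 1.0
        d1 = (8 * (base(A + h * e) - base(A - h * e))
              - (base(A + 2 * h * e) - base(A - 2 * h * e))) / (12 * h)
        bs = prim_basis([(1, a, A), (0, b, B)])
        assert ints.nuclear_attraction(bs, [Zc], [Rc])[2, 3] == \
            pytest.approx(d1 / (2 * a), abs=1e-9)


class TestGridAndXC:
    def test_model_density_integrals_closed_form(self):
        """rho = exp(-2 r^2): both the norm and the Slater-exchange
        integral have closed forms."""
        g = MolecularGrid(["C"], [[0.0, 0.0, 0.0]])
        r2 = (g.points ** 2).sum(axis=1)
        rho = np.exp(-2.0 * r2)
        assert g.weights @ rho == pytest.approx((np.pi / 2) ** 1.5,
                                                rel=1e-8)
        Cx = 0.75 * (3 / np.pi) ** (1 / 3)
        exact = -Cx * (np.pi / (8.0 / 3.0)) ** 1.5
        assert g.weights @ slater_e(rho) == pytest.approx(exact, rel=1e-8)

    def test_lda_potential_is_energy_derivative(self):
        f = get_functional("lda")
        rho = np.array([1e-3, 0.05, 0.4, 2.0, 11.0])
        e, vr, _ = f.e_and_potential(rho)
        h = rho * 1e-6
        num = (f.energy_density(rho + h) - f.energy_density(rho - h)) / (2 * h)
        np.testing.assert_allclose(vr, num, rtol=1e-6)

    def test_gga_potentials_consistent(self):
        f = get_functional("b3lyp")
        rho = np.array([0.05, 0.4, 2.0])
        sigma = np.array([0.01, 0.3, 4.0])
        e, vr, vs = f.e_and_potential(rho, sigma)
        h = rho * 1e-5
        num = (f.energy_density(rho + h, sigma)
               - f.energy_density(rho - h, sigma)) / (2 * h)
        np.testing.assert_allclose(vr, num, rtol=1e-4)
        hs = sigma * 1e-5
        num_s = (f.energy_density(rho, sigma + hs)
                 - f.energy_density(rho, sigma - hs)) / (2 * hs)
        np.testing.assert_allclose(vs, num_s, rtol=1e-4)


class TestSCF:
    def test_h2_minimal_basis_hartree_fock_anchor(self, h2_engines):
        """Textbook value: E(RHF/STO-3G, R = 1.4 a0) = -1.1167 hartree."""
        _, sol = h2_engines["hf"]
        assert sol.energy == pytest.approx(-1.1167, abs=2e-4)
        assert sol.converged

    def test_converged_solution_contracts(self, h2_engines):
        for key in ("hf", "lda"):
            eng, sol = h2_engines[key]
            S = eng.overlap()
            sol.validate(S)
            P = sol.density
            assert np.trace(P @ S) == pytest.approx(2.0, abs=1e-8)
            assert np.abs(P @ S @ P - 2 * P).max() < 1e-6
            # stationarity: F C_occ = S C_occ eps_occ
            _, F = eng.energy_and_fock(P)
            res = F @ sol.C[:, :1] - S @ sol.C[:, :1] * sol.eps[0]
            assert np.abs(res).max() < 1e-6

    def test_grid_integrates_scf_density_to_electron_count(self, h2_engines):
        eng, sol = h2_engines["lda"]
        g, ao, _ = eng._grid_ao()
        P = sol.density
        rho = np.einsum("pi,ij,pj->p", ao, P, ao)
        assert g.weights @ rho == pytest.approx(2.0, abs=1e-6)

    def test_odd_electron_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            RestrictedSCFEngine(["H"], [[0, 0, 0]], functional="hf",
                                basis="sto-3g")

    def test_engine_adapter_capability_error(self):
        from ndokit.scf import EngineCapabilityError, engine_adapter

        with pytest.raises(EngineCapabilityError):
            engine_adapter((["H"], [[0, 0, 0]]), basis="sto-3g",
                           functional="hf")  # odd electron count

    def test_h2_sanity_gap_positive(self, h2_engines):
        _, sol = h2_engines["hf"]
        assert sol.homo_lumo_gap_ev > 0.0


class TestFarFieldComposite:
    def test_neutral_fragments_reproduce_isolated_energies(self):
        from ndokit.engine.composite import FarFieldComposite
        from ndokit.scf import build_disjoint_guess

        f1 = RestrictedSCFEngine(["H", "H"], [[0, 0, 0], [0, 0, 1.4]],
                                 functional="lda", basis="sto-3g")
        f2 = RestrictedSCFEngine(["H", "H"], [[0, 0, 120], [0, 0, 121.4]],
                                 functional="lda", basis="sto-3g")
        comp = FarFieldComposite([f1, f2])
        s1, s2 = f1.solve_ground_state(), f2.solve_ground_state()
        C, occ, _ = build_disjoint_guess([s1, s2], comp.overlap())
        E, F = comp.energy_and_fock((C * occ) @ C.T)
        assert E == pytest.approx(s1.energy + s2.energy, abs=1e-5)
        # Fock stays block-diagonal
        assert np.abs(F[:2, 2:]).max() == 0.0

    def test_too_close_fragments_rejected(self):
        from ndokit.engine.composite import FarFieldComposite, SeparationError

        f1 = RestrictedSCFEngine(["H", "H"], [[0, 0, 0], [0, 0, 1.4]],
                                 functional="hf", basis="sto-3g")
        f2 = RestrictedSCFEngine(["H", "H"], [[0, 0, 5], [0, 0, 6.4]],
                                 functional="hf", basis="sto-3g")
        with pytest.raises(SeparationError):
            FarFieldComposite([f1, f2])
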