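"""Exchange-correlation functionals (closed-shell / spin-restricted).

Provides Slater exchange, VWN5 and VWN3(RPA) correlation, the B88 exchange
correction and LYP correlation, and the LDA(SVWN5), BLYP and B3LYP
combinations.  Each piece is an energy density per unit volume e(rho, sigma),
sigma = |grad rho|^2.  Potentials (vrho, vsigma) come analytically for the
LDA pieces and from centered numerical differentiation for the GGA pieces;
with steps scaled to the variable this is accurate to ~1e-9, ample for SCF
convergence at 1e-8.
"""

from __future__ import annotations

import numpy as np

_TINY = 1e-30

# --- Slater exchange --------------------------------------------------------

_CX = (3.0 / 4.0) * (3.0 / np.pi) ** (1.0 / 3.0)


def slater_e(rho):
    return -_CX * rho ** (4.0 / 3.0)


def slater_v(rho):
    return -(4.0 / 3.0) * _CX * rho ** (1.0 / 3.0)


# --- VWN correlation (unpolarized) -----------------------------------------

_VWN5 = (0.0310907, -0.10498, 3.72744, 12.9352)
_VWN3 = (0.0310907, -0.409286, 13.0720, 42.7198)  # RPA fit used in B3LYP


def _vwn_eps(rho, A, x0, b, c):
    rs = (3.0 / (4.0 * np.pi * np.maximum(rho, _TINY))) ** (1.0 / 3.0)
    x = np.sqrt(rs)
    X = x * x + b * x + c
    X0 = x0 * x0 + b * x0 + c
    Q = np.sqrt(4.0 * c - b * b)
    atn = np.arctan(Q / (2.0 * x + b))
    eps = A * (np.log(x * x / X) + 2.0 * b / Q * atn
               - b * x0 / X0 * (np.log((x - x0) ** 2 / X)
                                + 2.0 * (b + 2.0 * x0) / Q * atn))
    deps = A * (2.0 / x - (2.0 * x + b) / X
                - 4.0 * b / (Q * Q + (2.0 * x + b) ** 2)
                - b * x0 / X0 * (2.0 / (x - x0) - (2.0 * x + b) / X
                                 - 4.0 * (b + 2.0 * x0)
                                 / (Q * Q + (2.0 * x + b) ** 2)))
    return eps, deps, x


def vwn5_e(rho):
    eps, _, _ = _vwn_eps(rho, *_VWN5)
    return eps * rho


def vwn5_v(rho):
    eps, deps, x = _vwn_eps(rho, *_VWN5)
    return eps - x / 6.0 * deps  # v = eps - (rs/3) deps/drs


def vwn3_e(rho):
    eps, _, _ = _vwn_eps(rho, *_VWN3)
    return eps * rho


def vwn3_v(rho):
    eps, deps, x = _vwn_eps(rho, *_VWN3)
    return eps - x / 6.0 * deps


# --- B88 exchange correction ------------------------------------------------

_BETA = 0.0042


def b88_corr_e(rho, sigma):
    """Becke 88 gradient correction to exchange (both spin channels)."""
    rho_s = np.maximum(rho, _TINY) / 2.0
    sig_s = np.maximum(sigma, 0.0) / 4.0
    x = np.sqrt(sig_s) / rho_s ** (4.0 / 3.0)
    D = 1.0 + 6.0 * _BETA * x * np.arcsinh(x)
    return 2.0 * (-_BETA * rho_s ** (4.0 / 3.0) * x * x / D)


# --- LYP correlation --------------------------------------------------------

_LYP_A, _LYP_B, _LYP_C, _LYP_D = 0.04918, 0.132, 0.2533, 0.349
_CF = 0.3 * (3.0 * np.pi ** 2) ** (2.0 / 3.0)


def lyp_e(rho, sigma):
    """LYP correlation energy density, closed shell (rho_a = rho_b = rho/2)."""
    rho = np.maximum(rho, _TINY)
    sigma = np.maximum(sigma, 0.0)
    a, b, c, d = _LYP_A, _LYP_B, _LYP_C, _LYP_D
    r13 = rho ** (-1.0 / 3.0)
    denom = 1.0 + d * r13
    omega = np.exp(-c * r13) / denom * rho ** (-11.0 / 3.0)
    delta = c * r13 + d * r13 / denom
    rr = 0.25 * rho * rho             # rho_a rho_b
    gaa = 0.25 * sigma                # |grad rho_a|^2 = |grad rho_b|^2
    inner = (2.0 ** (11.0 / 3.0) * _CF * 2.0 * (0.5 * rho) ** (8.0 / 3.0)
             + (47.0 / 18.0 - 7.0 * delta / 18.0) * sigma
             - (2.5 - delta / 18.0) * 2.0 * gaa
             - (delta - 11.0) / 9.0 * 0.25 * sigma)
    outer = (-2.0 / 3.0 * rho * rho * sigma
             + 2.0 * (2.0 / 3.0 * rho * rho - rr) * gaa)
    return -4.0 * a / denom * rr / rho - a * b * omega * (rr * inner + outer)


# --- compositions -----------------------------------------------------------

_ANALYTIC_V = {slater_e: slater_v, vwn5_e: vwn5_v, vwn3_e: vwn3_v}


class Functional:
    """A weighted combination of functional pieces plus exact exchange.

    pieces: list of (weight, callable, needs_sigma).
    """

    def __init__(self, name, exact_exchange, pieces):
        self.name = name
        self.exact_exchange = exact_exchange
        self.pieces = pieces
        self.needs_sigma = any(ns for _, _, ns in pieces)

    def energy_density(self, rho, sigma=None):
        e = np.zeros_like(rho)
        for w, f, ns in self.pieces:
            e += w * (f(rho, sigma) if ns else f(rho))
        return e

    def e_and_potential(self, rho, sigma=None):
        """Return (e, vrho, vsigma); vsigma is None for pure-LDA mixes."""
        e = self.energy_density(rho, sigma)
        vrho = np.zeros_like(rho)
        vsigma = np.zeros_like(rho) if self.needs_sigma else None
        for w, f, ns in self.pieces:
            if f in _ANALYTIC_V:
                vrho += w * _ANALYTIC_V[f](rho)
            elif not ns:
                h = np.maximum(rho * 1e-6, 1e-14)
                vrho += w * (f(rho + h) - f(rho - h)) / (2.0 * h)
            else:
                h = np.maximum(rho * 1e-6, 1e-14)
                vrho += w * (f(rho + h, sigma) - f(rho - h, sigma)) / (2.0 * h)
                hs = np.maximum(sigma * 1e-6, 1e-14)
                vsigma += w * (f(rho, sigma + hs) - f(rho, sigma - hs)) / (2.0 * hs)
        return e, vrho, vsigma


def get_functional(name) -> Functional:
    if isinstance(name, Functional):
        return name
    key = name.lower()
    if key in ("hf", "hartree-fock"):
        return Functional("hf", 1.0, [])
    if key in ("lda", "svwn", "svwn5"):
        return Functional("lda", 0.0, [(1.0, slater_e, False),
                                       (1.0, vwn5_e, False)])
    if key == "blyp":
        return Functional("blyp", 0.0, [(1.0, slater_e, False),
                                        (1.0, b88_corr_e, True),
                                        (1.0, lyp_e, True)])
    if key == "b3lyp":
        # 0.80 LDA_x + 0.72 dB88 + 0.20 HF_x + 0.19 VWN3(RPA) + 0.81 LYP
        return Functional("b3lyp", 0.20, [(0.80, slater_e, False),
                                          (0.72, b88_corr_e, True),
                                          (0.19, vwn3_e, False),
                                          (0.81, lyp_e, True)])
    raise ValueError(f"unknown functional {name!r}")
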