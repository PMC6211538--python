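"""Mass-fractal description of random oligomers.

Small oligomer fractions in a solution of otherwise monodisperse particles
are modelled as mass fractals of the particle itself: N subunits arranged
with pair correlations g(r) ~ r^(D-3) exp(-r/xi), giving the Teixeira (1988)
structure factor

    S(q) = 1 + [D Gamma(D-1) / (q r)^D]
               * sin[(D-1) arctan(q xi)] / [(D-1) (1 + 1/(q xi)^2)^((D-1)/2)]

with fractal dimension D (1 < D < 3), mean subunit distance r and
correlation length xi.  xi is tied to the oligomer radius of gyration by
xi = R_g sqrt(2 / (D (D+1))), and the subunit count follows the fractal
scaling N = k (R_g / r)^D.

Because the subunits are anisotropic and randomly oriented, interference
between them is damped by the decoupling approximation:
S'(q) = 1 + beta(q) (S(q) - 1) with beta = A00^2 / P.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gamma as _gamma

from .structure import AtomRecord
from . import tables

__all__ = [
    "FractalModel",
    "teixeira_sq",
    "xi_from_rg",
    "rg_from_xi",
    "oligomer_count",
    "subunit_radius_from_volume",
    "effective_sq",
]


def _check_d(D: float) -> None:
    if not 1.0 < D < 3.0:
        raise ValueError(f"fractal dimension must satisfy 1 < D < 3, got {D}")


def xi_from_rg(rg_olig: float, D: float = 2.0) -> float:
    """Correlation length xi from the oligomer radius of gyration."""
    _check_d(D)
    return rg_olig * np.sqrt(2.0 / (D * (D + 1.0)))


def rg_from_xi(xi: float, D: float = 2.0) -> float:
    """Inverse of :func:`xi_from_rg`."""
    _check_d(D)
    return xi / np.sqrt(2.0 / (D * (D + 1.0)))


def oligomer_count(rg_olig: float, r: float, D: float = 2.0, k: float = 1.0) -> float:
    """Subunits per oligomer from the fractal scaling N = k (R_g/r)^D.

    N is a real-valued derived scale, not rounded to an integer.
    """
    _check_d(D)
    if r <= 0:
        raise ValueError("subunit distance r must be positive")
    return k * (rg_olig / r) ** D


def teixeira_sq(q_grid, D: float, r: float, xi: float) -> np.ndarray:
    """Teixeira mass-fractal structure factor on ``q_grid`` (1/A).

    q = 0 (and q xi << 1) is evaluated through the analytic limit
    S(0) = 1 + Gamma(D+1)/(D-1) * (xi/r)^D, since the raw expression is 0/0
    there.  D = 2 is regular (Gamma(1) = 1).
    """
    _check_d(D)
    if r <= 0 or xi <= 0:
        raise ValueError("r and xi must be positive")
    q = np.atleast_1d(np.asarray(q_grid, dtype=float))
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    s = np.empty_like(q)
    s0 = 1.0 + _gamma(D + 1.0) / (D - 1.0) * (xi / r) ** D
    small = q * xi < 1e-8
    s[small] = s0
    qs = q[~small]
    num = np.sin((D - 1.0) * np.arctan(qs * xi))
    den = (D - 1.0) * (1.0 + 1.0 / (qs * xi) ** 2) ** ((D - 1.0) / 2.0)
    s[~small] = 1.0 + D * _gamma(D - 1.0) / (qs * r) ** D * num / den
    return s


def effective_sq(P, A00, S) -> np.ndarray:
    """Decoupled structure factor S'(q) = 1 + (A00^2/P) (S(q) - 1)."""
    P = np.asarray(P, dtype=float)
    A00 = np.asarray(A00, dtype=float)
    S = np.asarray(S, dtype=float)
    beta = A00**2 / P
    return 1.0 + beta * (S - 1.0)


def subunit_radius_from_volume(atoms: list[AtomRecord]) -> float:
    """Equivalent-sphere radius of the subunit, from summed vdW volumes.

    The fractal's mean subunit distance r is fixed to the radius of the
    sphere whose volume equals the subunit's total atomic van der Waals
    volume (implicit hydrogens included).
    """
    if not atoms:
        raise ValueError("empty atom list")
    v_tab = tables.vdw_volumes_a3()
    h_tab = tables.residue_hydrogens()
    total = 0.0
    for atom in atoms:
        n_h = h_tab.get((atom.residue_name, atom.atom_name), (0, 0))[0]
        total += v_tab[atom.element] + n_h * v_tab["H"]
    return float((3.0 * total / (4.0 * np.pi)) ** (1.0 / 3.0))


@dataclass(frozen=True)
class FractalModel:
    """Parameter bundle for the fractal oligomer component.

    D and k default to 2 and 1: with the limited information a dilute
    oligomer tail leaves in a scattering curve, the fractal dimension cannot
    be refined, and k ~ 1 holds for D ~ 2.
    """

    r: float
    rg_olig: float = 300.0
    D: float = 2.0
    k: float = 1.0

    def __post_init__(self):
        _check_d(self.D)
        if self.r <= 0:
            raise ValueError("subunit distance r must be positive")

    @property
    def xi(self) -> float:
        return xi_from_rg(self.rg_olig, self.D)

    @property
    def N(self) -> float:
        return oligomer_count(self.rg_olig, self.r, self.D, self.k)

    def sq(self, q_grid) -> np.ndarray:
        return teixeira_sq(q_grid, self.D, self.r, self.xi)
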