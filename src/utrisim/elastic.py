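"""Plane elasticity of a pressurized disk in a two-material surround.

The sensory epithelium is modelled as a disk exerting hydrostatic pressure
``p`` at radius ``R1`` on a band of transitional epithelium (Young's modulus
``E1``, outer radius ``R2``) embedded in an infinite elastic matrix
(``E2``); both share Poisson ratio ``nu``.  Radial symmetry gives
displacements ``u_i(r) = a_i*r + b_i/r`` in each material with plane-strain
radial stress

``sigma_rr = E/((1+nu)(1-2nu)) * (a - (1-2nu)*b/r**2)``.

Boundary conditions: ``u2`` decays at infinity (``a2 = 0``), displacement and
radial stress are continuous at ``R2``, and ``sigma_rr(R1) = -p``.  The two
materials are equivalent to a single band of *effective* modulus ``E_eff``
chosen so the band's inner-radius displacement matches ``u1(R1)``; the
equilibrium expansion of the tissue against that band is
``dR = P_H*R1*(1+nu)/E_eff``, proportional to ``1/E_eff`` (so the area change
scales as ``1/E_eff**2``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LayeredAnnulus:
    """Geometry and elastic constants of the band + matrix system (SI)."""

    E1: float          # transitional-epithelium Young's modulus, Pa
    E2: float          # matrix Young's modulus, Pa
    R1: float          # band inner radius, m
    R2: float          # band outer radius, m
    nu: float = 0.45   # shared Poisson ratio (nearly incompressible tissue)
    p: float = 0.0     # internal pressure at R1, Pa

    def __post_init__(self):
        if self.E1 <= 0 or self.E2 <= 0:
            raise ValueError("Young's moduli must be positive")
        if not (0 <= self.nu < 0.5):
            raise ValueError("Poisson ratio must be in [0, 0.5)")
        if not (0 < self.R1 < self.R2):
            raise ValueError("need 0 < R1 < R2")


@dataclass
class ElasticSolution:
    """Integration constants and derived fields of the two-material solve."""

    annulus: LayeredAnnulus
    a1: float
    b1: float
    b2: float
    a2: float = 0.0  # decay at infinity

    def u(self, r):
        """Radial displacement; band solution for r < R2, matrix beyond."""
        r = np.asarray(r, dtype=float)
        band = self.a1 * r + self.b1 / r
        matrix = self.a2 * r + self.b2 / r
        return np.where(r <= self.annulus.R2, band, matrix)

    def sigma_rr(self, r):
        """Radial stress (plane strain)."""
        an = self.annulus
        r = np.asarray(r, dtype=float)

        def srr(E, a, b):
            return E / ((1 + an.nu) * (1 - 2 * an.nu)) * (a - (1 - 2 * an.nu) * b / r**2)

        return np.where(
            r <= an.R2, srr(an.E1, self.a1, self.b1), srr(an.E2, self.a2, self.b2)
        )


def solve_layers(annulus: LayeredAnnulus) -> ElasticSolution:
    """Integration constants of the band + infinite-matrix problem.

    Closed form (symbolically derived and verified against the boundary
    conditions; the homogeneous limit ``E1 = E2`` reduces to the classical
    pressurized-hole solution ``u = p*R1**2*(1+nu)/(E*r)``):

    with ``Q = E1+E2-2*E2*nu`` and ``den = E1*(R1**2*(E2-E1) + R2**2*Q)``,

    * ``a1 = p*R1**2*(1+nu)*(1-2*nu)*(E1-E2) / den``
    * ``b1 = p*R1**2*R2**2*(1+nu)*Q / den``
    * ``b2 = 2*p*R1**2*R2**2*(1-nu**2)*E1 / den``
    """
    an = annulus
    if an.R2 <= an.R1:
        raise ValueError("degenerate band: R2 must exceed R1")
    Q = an.E1 + an.E2 - 2 * an.E2 * an.nu
    den = an.E1 * (an.R1**2 * (an.E2 - an.E1) + an.R2**2 * Q)
    if den == 0:
        raise ZeroDivisionError("degenerate elastic parameters")
    pref = an.p * an.R1**2
    a1 = pref * (1 + an.nu) * (1 - 2 * an.nu) * (an.E1 - an.E2) / den
    b1 = pref * an.R2**2 * (1 + an.nu) * Q / den
    b2 = 2 * pref * an.R2**2 * (1 - an.nu**2) * an.E1 / den
    return ElasticSolution(annulus=an, a1=a1, b1=b1, b2=b2)


def effective_modulus(annulus: LayeredAnnulus) -> float:
    """Young's modulus of the single equivalent band.

    ``E_eff = E1*(R1**2*(E1-E2) - R2**2*Q) / (R1**2*(E1-E2)*(2*nu-1) - R2**2*Q)``
    with ``Q = E1+E2-2*E2*nu``; defined so that the band's inner displacement
    ``u_eff(R1) = p*R1*(1+nu)/E_eff`` equals ``u1(R1)`` of the two-material
    system.  Reduces to ``E1 = E2`` in the homogeneous limit.
    """
    an = annulus
    Q = an.E1 + an.E2 - 2 * an.E2 * an.nu
    den = an.R1**2 * (an.E1 - an.E2) * (2 * an.nu - 1) - an.R2**2 * Q
    if den == 0:
        raise ZeroDivisionError(
            "effective-modulus denominator vanishes for these parameters"
        )
    return float(an.E1 * (an.R1**2 * (an.E1 - an.E2) - an.R2**2 * Q) / den)


def u_eff(r, annulus: LayeredAnnulus, E: float):
    """Displacement of the single equivalent band of modulus ``E`` under the
    annulus' internal pressure: ``u_eff(r) = p*R1**2*(1+nu)/(r*E)``."""
    r = np.asarray(r, dtype=float)
    return annulus.p * annulus.R1**2 * (1 + annulus.nu) / (r * E)


def thin_band_modulus(annulus: LayeredAnnulus) -> float:
    """First-order thin-band expansion of the effective modulus.

    Taylor expansion of :func:`effective_modulus` in the band width
    ``R2 - R1`` (derived symbolically):

    ``E_eff ~ E2 + (R2-R1)*(E1-E2)*(E1+E2-2*E2*nu) / (E1*R1*(1-nu))``

    exact at ``R2 = R1`` (where the band vanishes and only the matrix acts)
    and whenever ``E1 = E2``.
    """
    an = annulus
    Q = an.E1 + an.E2 - 2 * an.E2 * an.nu
    return float(an.E2 + (an.R2 - an.R1) * (an.E1 - an.E2) * Q / (an.E1 * an.R1 * (1 - an.nu)))


def equilibrium_expansion(PH: float, R1: float, nu: float, E_eff: float) -> float:
    """Equilibrium radius change ``dR = P_H*R1*(1+nu)/E_eff``.

    ``P_H`` is the homeostatic pressure at which net cell division stops;
    the tissue expands until the band's restoring pressure balances it.
    """
    if E_eff <= 0:
        raise ValueError("E_eff must be positive")
    return PH * R1 * (1 + nu) / E_eff
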