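"""Mooney-Rivlin / neo-Hookean material law and deformation invariants.

The strain-energy density is

    U = (mu1/2) (I - 3) + (mu2/2) (K - 3) + (kappa/2) (J - 1)^2

with the reduced invariants of the right Cauchy-Green tensor C = F^T F:

    J = det F,   I = tr(C) J^(-2/3),   K = 1/2 (tr(C)^2 - tr(C^2)) J^(-4/3).

The deviatoric coefficients are parameterized by the shear modulus mu and a
weight w in [0, 1]:  mu1 = w mu, mu2 = (1-w) mu.  w = 1 recovers the
compressible neo-Hookean law; decreasing w strengthens the second invariant
term and produces more pronounced strain hardening at large stretch.  For
consistency with linear elasticity at small strain, mu = E / (2 (1 + nu)) and
kappa = E / (3 (1 - 2 nu)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MaterialParams",
    "InvariantSet",
    "material_from_E_nu",
    "invariants_of",
    "strain_energy_density",
]


@dataclass(frozen=True)
class MaterialParams:
    """Elastic parameters: (E, nu, w) plus the derived moduli."""

    E: float      # Young's modulus [Pa]
    nu: float     # Poisson ratio
    w: float      # Mooney-Rivlin weight, mu1 = w*mu
    mu: float     # shear modulus [Pa]
    kappa: float  # bulk modulus [Pa]
    mu1: float    # [Pa]
    mu2: float    # [Pa]


def material_from_E_nu(E: float, nu: float, w: float = 1.0) -> MaterialParams:
    """Build :class:`MaterialParams` from Young's modulus, Poisson ratio and w.

    Raises
    ------
    ValueError
        For E <= 0, nu outside (-1, 0.5) (nu = 0.5 is the incompressible
        limit, kappa diverges), or w outside [0, 1].
    """
    if E <= 0:
        raise ValueError("Young's modulus must be positive")
    if nu >= 0.5:
        raise ValueError("incompressible limit not supported (nu must be < 0.5)")
    if nu <= -1.0:
        raise ValueError("Poisson ratio must exceed -1")
    if not 0.0 <= w <= 1.0:
        raise ValueError("Mooney-Rivlin weight w must lie in [0, 1]")
    mu = E / (2.0 * (1.0 + nu))
    kappa = E / (3.0 * (1.0 - 2.0 * nu))
    return MaterialParams(E=float(E), nu=float(nu), w=float(w), mu=mu,
                          kappa=kappa, mu1=w * mu, mu2=(1.0 - w) * mu)


@dataclass(frozen=True)
class InvariantSet:
    """Invariants of one deformation gradient (all dimensionless)."""

    J: float    # det F
    I: float    # tr(C) J^(-2/3)
    K: float    # 1/2 (tr(C)^2 - tr(C^2)) J^(-4/3)
    TC: float   # tr C
    TC2: float  # tr(C^2)


def invariants_of(F: np.ndarray) -> InvariantSet:
    """Reduced invariants of a single 3x3 deformation gradient.

    Raises
    ------
    ValueError
        If det F <= 0 (element inversion).
    """
    F = np.asarray(F, dtype=np.float64)
    J = float(np.linalg.det(F))
    if J <= 0:
        raise ValueError(f"element inversion: det F = {J:.3e} <= 0")
    C = F.T @ F
    TC = float(np.trace(C))
    TC2 = float(np.trace(C @ C))
    I = TC * J ** (-2.0 / 3.0)
    K = 0.5 * (TC * TC - TC2) * J ** (-4.0 / 3.0)
    return InvariantSet(J=J, I=I, K=K, TC=TC, TC2=TC2)


def strain_energy_density(inv: InvariantSet, mat: MaterialParams) -> float:
    """Mooney-Rivlin strain-energy density U [Pa] for one element.

    With w = 1 (mu2 = 0) this is the compressible neo-Hookean energy
    (mu/2)(I-3) + (kappa/2)(J-1)^2.
    """
    return (
        0.5 * mat.mu1 * (inv.I - 3.0)
        + 0.5 * mat.mu2 * (inv.K - 3.0)
        + 0.5 * mat.kappa * (inv.J - 1.0) ** 2
    )
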