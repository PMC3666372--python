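"""Strain-energy functions and stress resultants for the lesion wall.

Energies are per unit *reference* area (J·m⁻²); the deformed-thickness factor
``H/lam^2`` is kept inside the energy.  Stress resultants are membrane
tensions (N·m⁻¹).

Four constitutive layers are provided:

1. the full Denny–Schroter pseudo-strain-energy ``w`` (log + linear in the
   Green strain ``E11 = (lam^2-1)/2``),
2. its second-order Taylor expansion about ``E11 = 0`` (the form used by the
   dynamics and by the image-based fits),
3. an energy-limited form ``Psi = H*Phi*(1 - exp(-w/(H*Phi)))`` that saturates
   at the finite failure energy ``H*Phi`` and therefore produces a stress
   maximum — the material rupture point,
4. a collagen–elastin mixture: ``Ac`` times the (collagen-only)
   Denny–Schroter energy plus ``Ae`` times a neo-Hookean-like elastin energy
   ``b H/lam^2 (lam - log lam - 1)``.

Note: the elastin stiffness ``elastin_b`` (N·m⁻²) is a *material* constant
and is unrelated to the inertia ratio ``b`` of the nondimensional groups —
the two merely share a symbol in the field's notation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Geometry, MaterialParameters, MembraneProperties, taylor_coefficients

__all__ = [
    "StrainState",
    "EnergyLimiterConfig",
    "ConstitutiveDomainError",
    "green_strain",
    "strain_energy_full",
    "strain_energy_taylor",
    "stress_resultant",
    "elastic_stress",
    "elastic_stress_limited",
    "limited_energy",
    "stress_resultant_limited",
    "combined_energy",
    "rupture_stretch",
    "default_phi",
]


class ConstitutiveDomainError(ValueError):
    """The strain state is beyond the validity of the constitutive law."""


@dataclass(frozen=True)
class StrainState:
    """Stretch ratio ``lam > 0`` and stretch rate ``lam_dot`` (s⁻¹)."""

    lam: float
    lam_dot: float = 0.0

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError(f"lam must be > 0, got {self.lam}")


@dataclass(frozen=True)
class EnergyLimiterConfig:
    """Failure-energy density ``phi`` (J·m⁻³); the stored energy saturates at H*phi."""

    phi: float

    def __post_init__(self) -> None:
        if not self.phi > 0:
            raise ValueError(f"phi must be > 0, got {self.phi}")


def green_strain(lam: float) -> float:
    """Radial Green–Lagrange strain ``E11 = (lam^2 - 1)/2``."""
    return (lam * lam - 1.0) / 2.0


def strain_energy_full(s: StrainState, mat: MaterialParameters, geom: Geometry) -> float:
    """Full Denny–Schroter energy per reference area.

    ``w = (H/lam^2) (c1 log[1 - (e^{E11}-1)/c2] + c3 E11)``.

    Raises :class:`ConstitutiveDomainError` when the log argument is
    non-positive (``e^{E11} - 1 >= c2``), i.e. beyond constitutive validity.
    """
    E11 = green_strain(s.lam)
    arg = 1.0 - (math.exp(E11) - 1.0) / mat.c2
    if arg <= 0.0:
        raise ConstitutiveDomainError(
            f"log argument {arg} <= 0 at lam={s.lam}: beyond constitutive validity"
        )
    return geom.H / s.lam**2 * (mat.c1 * math.log(arg) + mat.c3 * E11)


def strain_energy_taylor(s: StrainState, mat: MaterialParameters, geom: Geometry) -> float:
    """Second-order Taylor energy ``a0 E11 + a1 E11^2`` (per reference area)."""
    a0, a1 = taylor_coefficients(mat, geom)
    E11 = green_strain(s.lam)
    return a0 * E11 + a1 * E11 * E11


def elastic_stress(lam, mat: MaterialParameters, geom: Geometry):
    """Elastic (rate-independent) Taylor stress resultant ``a0 + a1(lam^2-1)``.

    Accepts scalars or numpy arrays.
    """
    a0, a1 = taylor_coefficients(mat, geom)
    return a0 + a1 * (np.asarray(lam) ** 2 - 1.0)


def stress_resultant(
    s: StrainState,
    mat: MaterialParameters,
    geom: Geometry,
    mem: MembraneProperties,
) -> float:
    """Isotropic stress resultant ``T`` (N·m⁻¹): Taylor elastic part + viscous term.

    ``T = a0 + a1 (lam^2 - 1) + 2 mu_m H lam_dot / lam^3``.
    """
    visc = 2.0 * mem.mu_m * geom.H * s.lam_dot / s.lam**3
    return float(elastic_stress(s.lam, mat, geom)) + visc


def limited_energy(w: float, geom: Geometry, lim: EnergyLimiterConfig):
    """Energy-limited form ``Psi = H*Phi*(1 - exp(-w/(H*Phi)))``.

    Strictly increasing in ``w`` and bounded above by ``H*Phi``; ``Psi ≈ w``
    when ``w << H*Phi``.  Accepts scalars or arrays.
    """
    cap = geom.H * lim.phi
    return cap * (-np.expm1(-np.asarray(w) / cap))


def _attenuation(lam, mat: MaterialParameters, geom: Geometry, lim: EnergyLimiterConfig):
    """exp(-w_taylor/(H*Phi)) — the softening factor of the limited stress."""
    a0, a1 = taylor_coefficients(mat, geom)
    E11 = (np.asarray(lam) ** 2 - 1.0) / 2.0
    w = a0 * E11 + a1 * E11 * E11
    # clip the exponent: beyond ~700 the factor is numerically inf/0 anyway
    return np.exp(np.clip(-w / (geom.H * lim.phi), -745.0, 700.0))


def elastic_stress_limited(lam, mat: MaterialParameters, geom: Geometry, lim: EnergyLimiterConfig):
    """Elastic part of the limited stress: Taylor stress times the attenuation factor."""
    return elastic_stress(lam, mat, geom) * _attenuation(lam, mat, geom, lim)


def stress_resultant_limited(
    s: StrainState,
    mat: MaterialParameters,
    geom: Geometry,
    mem: MembraneProperties,
    lim: EnergyLimiterConfig,
) -> float:
    """Limited stress resultant ``T'``: attenuated elastic part + unchanged viscous term."""
    visc = 2.0 * mem.mu_m * geom.H * s.lam_dot / s.lam**3
    return float(elastic_stress_limited(s.lam, mat, geom, lim)) + visc


def combined_energy(
    s: StrainState,
    mat: MaterialParameters,
    geom: Geometry,
    elastin_b: float,
    Ac: float,
    Ae: float,
    quadratic: bool = False,
) -> float:
    """Collagen–elastin mixture energy per reference area.

    ``w' = Ac * w_DS(lam) + Ae * (b H/lam^2)(lam - log lam - 1)`` with the
    collagen part the full Denny–Schroter energy.  With ``quadratic=True``
    the printed second-order approximation is returned instead:

    ``w' ≈ (-Ac c1 H/c2 + Ac c3 H) E11
          + (Ae b H/2 - Ac c1 H/(2c2^2) + 3 Ac c1 H/(2c2) - 2 Ac c3 H) E11^2``
    """
    if Ac < 0 or Ae < 0:
        raise ValueError("protein numbers Ac, Ae must be >= 0")
    H, lam = geom.H, s.lam
    if quadratic:
        a0, a1 = taylor_coefficients(mat, geom)
        E11 = green_strain(lam)
        return Ac * (a0 * E11 + a1 * E11 * E11) + Ae * elastin_b * H / 2.0 * E11 * E11
    collagen = strain_energy_full(s, mat, geom)
    elastin = elastin_b * H / lam**2 * (lam - math.log(lam) - 1.0)
    return Ac * collagen + Ae * elastin


def combined_taylor_coefficients(
    mat: MaterialParameters, geom: Geometry, elastin_b: float, Ac: float, Ae: float
) -> tuple[float, float]:
    """(A0, A1) of the quadratic mixture energy ``A0 E11 + A1 E11^2``."""
    a0, a1 = taylor_coefficients(mat, geom)
    return Ac * a0, Ac * a1 + Ae * elastin_b * geom.H / 2.0


def rupture_stretch(
    mat: MaterialParameters,
    geom: Geometry,
    lim: EnergyLimiterConfig,
    lam_max: float = 20.0,
    n_grid: int = 20000,
) -> float:
    """Stretch at which the limited elastic stress attains its maximum.

    Softening sets in beyond this point; it defines the material rupture
    stretch.  Located by a dense grid search on ``[1, lam_max]``.  When the
    maximum sits at ``lam = 1`` the stress has no limiter-induced interior
    peak (the material softens from the start, as the reference parameters
    do) and ``inf`` is returned: no rupture point exists.
    """
    lam = np.linspace(1.0, lam_max, n_grid)
    with np.errstate(over="ignore"):
        t = elastic_stress_limited(lam, mat, geom, lim)
    k = int(np.argmax(t))
    if k == 0:
        return math.inf
    return float(lam[k])


def default_phi(mat: MaterialParameters, geom: Geometry, scale: float = 3.0) -> float:
    """Failure-energy density such that ``H*Phi = scale × w_taylor(lam=2)``.

    A mid-expansion rupture calibration: no measured value for the failure
    energy of pleural tissue is asserted; this is a package default and a
    required knob for any quantitative rupture study.
    """
    w2 = strain_energy_taylor(StrainState(lam=2.0), mat, geom)
    return scale * abs(w2) / geom.H
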