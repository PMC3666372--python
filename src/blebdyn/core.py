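"""Domain types, unit conversion, and nondimensional groups.

The model describes a quasi-spherical, thin-walled parenchymal lesion (bleb)
on the visceral pleura.  Its single kinematic degree of freedom is the stretch
ratio ``lam = r(t)/R``.  Everything downstream — the ODE system, the stability
criteria, the image-based fits — is parameterized by the objects defined here:

* :class:`MaterialParameters` — the three Denny–Schroter wall constants
  ``c1 < 0`` (N·m⁻²), ``c2 > 0`` (dimensionless), ``c3 < 0`` (N·m⁻²).
* :class:`Geometry` — undeformed thickness ``H`` and radius ``R`` (m).
* :class:`MembraneProperties` / :class:`FluidProperties` — densities and
  dynamic viscosities of the wall and of the pleural fluid, plus the far-field
  pressure ``p_inf``.
* :class:`NondimensionalGroups` — the dimensionless numbers of the reduced
  system::

      b   = rho_f R / (rho_m H)        fluid/membrane inertia ratio
      d   = H / R                      thickness ratio
      m_f = mu_f / (H sqrt(rho_m|c1|)) fluid viscosity number
      m   = mu_m / (H sqrt(rho_m|c1|)) membrane viscosity number
      F   = (P_inner - p_inf) R/(c1 H) forcing (negative for physical input)

  with dimensionless time ``tau = t * sqrt(|c1| / (rho_m R^2))``.  The
  viscosity numbers and the time scale are reconstructed so that the
  dimensional momentum balance maps term-by-term onto the nondimensional
  system; see ``docs/derivation.md``.
* :class:`DerivedCoefficients` — the equilibrium-quadratic coefficients::

      alpha = c1 c2^2 F,
      beta  = -c1 + 5 c1 c2 - 6 c2^2 c3,
      gamma =  c1 - 3 c1 c2 + 4 c2^2 c3.

For physical material parameters ``beta`` and ``gamma`` are never
simultaneously positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MMHG_TO_PA",
    "MaterialParameters",
    "Geometry",
    "MembraneProperties",
    "FluidProperties",
    "NondimensionalGroups",
    "DerivedCoefficients",
    "convert_pressure",
    "derived_coefficients",
    "nondimensional_groups",
    "time_scale",
    "taylor_coefficients",
    "default_material",
    "default_geometry",
    "default_membrane",
    "default_fluid",
    "default_transmural_pressure",
]

#: Exact conversion factor: one standard atmosphere is 760 mmHg = 101325 Pa.
MMHG_TO_PA = 101325.0 / 760.0


class ValidationError(ValueError):
    """Raised when an input violates a physical-parameter invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class MaterialParameters:
    """Denny–Schroter wall constants.  ``c1 < 0``, ``c2 > 0``, ``c3 < 0``."""

    c1: float
    c2: float
    c3: float

    def __post_init__(self) -> None:
        _require(math.isfinite(self.c1) and self.c1 < 0, f"c1 must be finite and < 0, got {self.c1}")
        _require(math.isfinite(self.c2) and self.c2 > 0, f"c2 must be finite and > 0, got {self.c2}")
        _require(math.isfinite(self.c3) and self.c3 < 0, f"c3 must be finite and < 0, got {self.c3}")


@dataclass(frozen=True)
class Geometry:
    """Undeformed membrane thickness ``H`` and lesion radius ``R``, in metres.

    ``H << R`` (membrane assumption) is advisory and not enforced.
    """

    H: float
    R: float

    def __post_init__(self) -> None:
        _require(self.H > 0, f"H must be > 0, got {self.H}")
        _require(self.R > 0, f"R must be > 0, got {self.R}")


@dataclass(frozen=True)
class MembraneProperties:
    """Membrane density (kg·m⁻³) and dynamic viscosity (Pa·s)."""

    rho_m: float
    mu_m: float

    def __post_init__(self) -> None:
        _require(self.rho_m > 0, f"rho_m must be > 0, got {self.rho_m}")
        _require(self.mu_m >= 0, f"mu_m must be >= 0, got {self.mu_m}")


@dataclass(frozen=True)
class FluidProperties:
    """Pleural-fluid density (kg·m⁻³), viscosity (Pa·s) and far-field pressure (Pa)."""

    rho_f: float
    mu_f: float
    p_inf: float = 0.0

    def __post_init__(self) -> None:
        _require(self.rho_f > 0, f"rho_f must be > 0, got {self.rho_f}")
        _require(self.mu_f >= 0, f"mu_f must be >= 0, got {self.mu_f}")


@dataclass(frozen=True)
class NondimensionalGroups:
    """Dimensionless numbers of the reduced air–tissue–pleural-fluid system."""

    b: float
    d: float
    m_f: float
    m: float
    F_bar: float

    def __post_init__(self) -> None:
        _require(self.b > 0, f"b must be > 0, got {self.b}")
        _require(self.d > 0, f"d must be > 0, got {self.d}")
        _require(self.m_f >= 0, f"m_f must be >= 0, got {self.m_f}")
        _require(self.m >= 0, f"m must be >= 0, got {self.m}")


@dataclass(frozen=True)
class DerivedCoefficients:
    """Coefficients of the equilibrium quadratic ``gamma lam^2 + alpha lam + beta = 0``."""

    alpha: float
    beta: float
    gamma: float


def convert_pressure(value_mmhg: float) -> float:
    """Convert a pressure from mmHg to Pa (exact ratio 101325/760)."""
    if not math.isfinite(value_mmhg):
        raise ValidationError(f"pressure must be finite, got {value_mmhg}")
    return value_mmhg * MMHG_TO_PA


def derived_coefficients(mat: MaterialParameters, F_bar: float) -> DerivedCoefficients:
    """Equilibrium-quadratic coefficients (alpha, beta, gamma).

    ``alpha = c1 c2^2 F`` is positive whenever ``F_bar < 0`` (the physical
    sign of the forcing, since ``c1 < 0``).
    """
    if not math.isfinite(F_bar):
        raise ValidationError(f"F_bar must be finite, got {F_bar}")
    c1, c2, c3 = mat.c1, mat.c2, mat.c3
    alpha = c1 * c2**2 * F_bar
    beta = -c1 + 5.0 * c1 * c2 - 6.0 * c2**2 * c3
    gamma = c1 - 3.0 * c1 * c2 + 4.0 * c2**2 * c3
    return DerivedCoefficients(alpha=alpha, beta=beta, gamma=gamma)


def time_scale(geom: Geometry, mem: MembraneProperties, mat: MaterialParameters) -> float:
    """Characteristic time ``Ts = R sqrt(rho_m/|c1|)`` such that ``tau = t/Ts``."""
    return geom.R * math.sqrt(mem.rho_m / abs(mat.c1))


def nondimensional_groups(
    geom: Geometry,
    mem: MembraneProperties,
    fluid: FluidProperties,
    mat: MaterialParameters,
    P_transmural: float,
) -> NondimensionalGroups:
    """Form the dimensionless groups (b, d, m_f, m, F_bar) from SI inputs.

    ``P_transmural`` is the mean inner minus far-field pressure in Pa; with
    ``c1 < 0`` the resulting forcing ``F_bar`` is negative.
    """
    visc_scale = geom.H * math.sqrt(mem.rho_m * abs(mat.c1))
    return NondimensionalGroups(
        b=fluid.rho_f * geom.R / (mem.rho_m * geom.H),
        d=geom.H / geom.R,
        m_f=fluid.mu_f / visc_scale,
        m=mem.mu_m / visc_scale,
        F_bar=P_transmural * geom.R / (mat.c1 * geom.H),
    )


def taylor_coefficients(mat: MaterialParameters, geom: Geometry) -> tuple[float, float]:
    """Coefficients (a0, a1) of the second-order elastic stress resultant.

    ``T_el(lam) = a0 + a1 (lam^2 - 1)`` with ``a0 = -c1 H/c2 + c3 H`` and
    ``a1 = -c1 H/(2 c2^2) + 3 c1 H/(2 c2) - 2 c3 H`` (N·m⁻¹).
    """
    c1, c2, c3 = mat.c1, mat.c2, mat.c3
    H = geom.H
    a0 = -c1 * H / c2 + c3 * H
    a1 = -c1 * H / (2.0 * c2**2) + 3.0 * c1 * H / (2.0 * c2) - 2.0 * c3 * H
    return a0, a1


# --- reference parameter set -------------------------------------------------
# Normal lung parenchymal tissue and pleural-fluid values.  The fluid
# viscosity is quoted in the literature as a range 1.39–1.57e-3 Pa·s; the
# midpoint is used as the default.


def default_material() -> MaterialParameters:
    return MaterialParameters(c1=-22.5e5, c2=1.26, c3=-7.8e5)


def default_geometry() -> Geometry:
    return Geometry(H=1.0e-3, R=1.0e-2)


def default_membrane() -> MembraneProperties:
    return MembraneProperties(rho_m=1050.0, mu_m=7.0e-2)


def default_fluid() -> FluidProperties:
    return FluidProperties(rho_f=980.3, mu_f=1.48e-3, p_inf=0.0)


def default_transmural_pressure() -> float:
    """Mean transmural pressure in Pa: atmospheric 760 mmHg against p_inf = 0."""
    return convert_pressure(760.0)
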