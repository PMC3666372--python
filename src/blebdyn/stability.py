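"""Closed-form equilibria, Jacobian, and instability criteria.

With the autonomous forcing ``F = R P/(c1 H)`` the equilibria of the lesion
system solve the quadratic ``gamma lam^2 + alpha lam + beta = 0`` with::

    alpha = c1 c2^2 F,
    beta  = -c1 + 5 c1 c2 - 6 c2^2 c3,
    gamma =  c1 - 3 c1 c2 + 4 c2^2 c3,

i.e. ``lam_eq = (-alpha ± sqrt(alpha^2 - 4 beta gamma)) / (2 gamma)``.

The Jacobian of the reduced system about the ``(-alpha + sqrt(...))/(2 gamma)``
branch has the closed form (``s = sqrt(alpha^2 - 4 beta gamma)``, ``D`` the
inertial denominator at the equilibrium)::

    J = [[0, 1],
         [F (gamma - beta/lam^2) / (alpha D),
          -(4 m_f/lam + 4 m d/lam^4) / D]]

and instability is prescribed for ``det J < 0`` or ``tr J > 0``.  Two
closed-form criteria follow for physical parameters (``c1<0, c2>0, c3<0``,
hence ``alpha > 0`` and never ``beta > 0 and gamma > 0`` simultaneously):

* determinant criterion: ``gamma < 0``, ``beta > 0`` and
  ``gamma < b^{1/3} alpha - b^{2/3} beta``  =>  ``det J < 0``;
* trace criterion: ``gamma < 0``, ``beta > 0``,
  ``gamma > b^{1/3} alpha - b^{2/3} beta`` and a fourth inequality in
  ``(d m / m_f)`` — available in two algebraic forms, see
  :func:`theorem7_unstable`  =>  ``tr J > 0``.

Classification always cross-checks the closed-form signs against a central
finite-difference linearization of the right-hand side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    DerivedCoefficients,
    FluidProperties,
    Geometry,
    MaterialParameters,
    MembraneProperties,
    NondimensionalGroups,
    derived_coefficients,
    nondimensional_groups,
)
from .dynamics import State, make_stress_fn, rhs

__all__ = [
    "EquilibriumError",
    "Equilibria",
    "StabilityVerdict",
    "equilibrium_stretch",
    "jacobian_at_equilibrium",
    "numeric_jacobian",
    "theorem1_unstable",
    "theorem7_unstable",
    "classify",
    "region_scan",
]


class EquilibriumError(ValueError):
    """No real or well-defined equilibrium for the given coefficients."""


@dataclass(frozen=True)
class Equilibria:
    """The two roots of the equilibrium quadratic.

    ``lam_star`` is the ``(-alpha + s)/(2 gamma)`` branch — the one the
    closed-form Jacobian and the instability criteria refer to; it is
    positive when ``gamma > 0`` but negative in the ``gamma < 0, beta > 0``
    instability region.  ``lam_plus`` is whichever root is positive (the
    physically meaningful equilibrium stretch), or None when neither is.
    """

    lam_star: float
    lam_other: float

    @property
    def lam_plus(self) -> float | None:
        for r in (self.lam_star, self.lam_other):
            if r > 0:
                return r
        return None


def equilibrium_stretch(coeffs: DerivedCoefficients) -> Equilibria:
    """Solve ``gamma lam^2 + alpha lam + beta = 0`` in closed form."""
    a, b_, g = coeffs.alpha, coeffs.beta, coeffs.gamma
    if g == 0.0:
        raise EquilibriumError("gamma = 0: degenerate equilibrium quadratic")
    disc = a * a - 4.0 * b_ * g
    if disc < 0.0:
        raise EquilibriumError(f"alpha^2 - 4 beta gamma = {disc} < 0: no real equilibrium")
    s = math.sqrt(disc)
    return Equilibria(lam_star=(-a + s) / (2.0 * g), lam_other=(-a - s) / (2.0 * g))


def _denominator(lam: float, groups: NondimensionalGroups) -> float:
    return groups.b * lam + lam**-2


def jacobian_at_equilibrium(
    coeffs: DerivedCoefficients,
    groups: NondimensionalGroups,
    lam_e: float | None = None,
) -> np.ndarray:
    """Closed-form 2x2 Jacobian about an equilibrium (default: the star branch)."""
    if lam_e is None:
        lam_e = equilibrium_stretch(coeffs).lam_star
    if lam_e == 0.0:
        raise EquilibriumError("equilibrium at lam = 0 is degenerate")
    a, b_, g = coeffs.alpha, coeffs.beta, coeffs.gamma
    F = groups.F_bar
    D = _denominator(lam_e, groups)
    j21 = F * (g - b_ / lam_e**2) / (a * D)
    j22 = -(4.0 * groups.m_f / lam_e + 4.0 * groups.m * groups.d / lam_e**4) / D
    return np.array([[0.0, 1.0], [j21, j22]])


def numeric_jacobian(
    coeffs: DerivedCoefficients,
    groups: NondimensionalGroups,
    mat: MaterialParameters,
    geom: Geometry,
    lam_e: float | None = None,
    eps: float = 1e-6,
) -> np.ndarray:
    """Central finite-difference linearization of the rhs at the equilibrium."""
    if lam_e is None:
        lam_e = equilibrium_stretch(coeffs).lam_star
    f = make_stress_fn(mat, geom)
    F = groups.F_bar

    def g(y0, y1):
        num = F - 1.5 * groups.b * y1 * y1 - 4.0 * groups.m_f * y1 / y0 \
            - 2.0 * f(y0) / y0 - 4.0 * groups.m * groups.d * y1 / y0**4
        return num / (groups.b * y0 + y0**-2)

    h0 = eps * max(1.0, abs(lam_e))
    h1 = eps
    j21 = (g(lam_e + h0, 0.0) - g(lam_e - h0, 0.0)) / (2.0 * h0)
    j22 = (g(lam_e, h1) - g(lam_e, -h1)) / (2.0 * h1)
    return np.array([[0.0, 1.0], [j21, j22]])


def theorem1_unstable(coeffs: DerivedCoefficients, groups: NondimensionalGroups) -> bool:
    """Determinant instability criterion.

    True iff ``gamma < 0``, ``beta > 0`` and
    ``gamma < b^{1/3} alpha - b^{2/3} beta``, in which case ``det J < 0``.
    """
    a, b_, g = coeffs.alpha, coeffs.beta, coeffs.gamma
    b = groups.b
    return g < 0.0 and b_ > 0.0 and g < b ** (1.0 / 3.0) * a - b ** (2.0 / 3.0) * b_


def theorem7_unstable(
    coeffs: DerivedCoefficients,
    groups: NondimensionalGroups,
    form: str = "printed",
) -> bool:
    """Trace instability criterion.

    Both forms require ``gamma < 0``, ``beta > 0`` and
    ``gamma > b^{1/3} alpha - b^{2/3} beta``.  The fourth inequality exists
    in two algebraic variants (``q = (d m / m_f)^{1/3}``):

    * ``form="printed"``: ``beta > alpha gamma^2 q + gamma q^2`` — the
      criterion exactly as stated in the source analysis;
    * ``form="derived"``: ``beta < alpha q - gamma q^2`` — what the
      underlying lemma's algebra yields when re-derived (this form is exactly
      equivalent to ``tr J > 0`` under the premises).

    The two are not equivalent; classification cross-checks the numeric
    trace sign and reports disagreements rather than resolving them.
    """
    if groups.m_f == 0.0:
        raise ZeroDivisionError("m_f = 0: the ratio d*m/m_f is undefined")
    a, b_, g = coeffs.alpha, coeffs.beta, coeffs.gamma
    b = groups.b
    if not (g < 0.0 and b_ > 0.0 and g > b ** (1.0 / 3.0) * a - b ** (2.0 / 3.0) * b_):
        return False
    q = (groups.d * groups.m / groups.m_f) ** (1.0 / 3.0)
    if form == "printed":
        return b_ > a * g * g * q + g * q * q
    if form == "derived":
        return b_ < a * q - g * q * q
    raise ValueError(f"unknown form {form!r}")


@dataclass(frozen=True)
class StabilityVerdict:
    """Equilibrium value and theorem-based classification."""

    lambda_eq_plus: float | None
    is_unstable: bool
    criterion: str  # "determinant", "trace", or "none"
    det_sign: int
    tr_sign: int
    lam_star: float | None = None
    consistent: bool = True  # closed-form signs agree with finite differences

    def __post_init__(self) -> None:
        if self.is_unstable != (self.criterion != "none"):
            raise ValueError("is_unstable must mirror criterion")


def classify(
    mat: MaterialParameters,
    geom: Geometry,
    mem: MembraneProperties,
    fluid: FluidProperties,
    P: float,
    theorem7_form: str = "printed",
) -> StabilityVerdict:
    """Full stability classification of a parameter point.

    ``P`` is the mean inner pressure (Pa); the transmural pressure
    ``P - p_inf`` forms the autonomous forcing.  The closed-form det/tr signs
    are always cross-checked against a finite-difference linearization.
    """
    groups = nondimensional_groups(geom, mem, fluid, mat, P - fluid.p_inf)
    coeffs = derived_coefficients(mat, groups.F_bar)
    try:
        eq = equilibrium_stretch(coeffs)
    except EquilibriumError:
        # No real equilibrium: reported as its own verdict state rather than
        # silently stable.
        return StabilityVerdict(
            lambda_eq_plus=None,
            is_unstable=False,
            criterion="none",
            det_sign=0,
            tr_sign=0,
            lam_star=None,
            consistent=False,
        )
    J = jacobian_at_equilibrium(coeffs, groups, eq.lam_star)
    det = float(np.linalg.det(J))
    tr = float(np.trace(J))
    Jn = numeric_jacobian(coeffs, groups, mat, geom, eq.lam_star)
    consistent = (np.sign(np.linalg.det(Jn)) == np.sign(det)) and (
        np.sign(np.trace(Jn)) == np.sign(tr)
    )
    t1 = theorem1_unstable(coeffs, groups)
    t7 = theorem7_unstable(coeffs, groups, form=theorem7_form)
    criterion = "determinant" if t1 else ("trace" if t7 else "none")
    return StabilityVerdict(
        lambda_eq_plus=eq.lam_plus,
        is_unstable=criterion != "none",
        criterion=criterion,
        det_sign=int(np.sign(det)),
        tr_sign=int(np.sign(tr)),
        lam_star=eq.lam_star,
        consistent=bool(consistent),
    )


def region_scan(
    x_param: str,
    y_param: str,
    x_range: tuple[float, float],
    y_range: tuple[float, float],
    n: int = 50,
    mat: MaterialParameters | None = None,
    geom: Geometry | None = None,
    mem: MembraneProperties | None = None,
    fluid: FluidProperties | None = None,
    P: float | None = None,
) -> pd.DataFrame:
    """Instability map over two of the material parameters.

    Returns a tidy frame with columns ``(x_param, y_param, unstable,
    criterion)`` on an ``n x n`` grid; the third material parameter is held
    at its value in ``mat``.  Cells whose parameters violate the physical
    sign constraints, or that have no real equilibrium, are marked
    ``criterion='invalid'``.
    """
    from .core import (
        default_fluid,
        default_geometry,
        default_material,
        default_membrane,
        default_transmural_pressure,
    )

    if n < 50:
        raise ValueError("grid resolution must be at least 50x50")
    mat = mat or default_material()
    geom = geom or default_geometry()
    mem = mem or default_membrane()
    fluid = fluid or default_fluid()
    P = default_transmural_pressure() if P is None else P
    valid = {"c1", "c2", "c3"}
    if x_param not in valid or y_param not in valid or x_param == y_param:
        raise ValueError("axes must be two distinct parameters among c1, c2, c3")
    xs = np.linspace(*x_range, n)
    ys = np.linspace(*y_range, n)
    rows = []
    base = {"c1": mat.c1, "c2": mat.c2, "c3": mat.c3}
    for yv in ys:
        for xv in xs:
            p = dict(base)
            p[x_param] = xv
            p[y_param] = yv
            try:
                m = MaterialParameters(**p)
                v = classify(m, geom, mem, fluid, P)
                rows.append((xv, yv, v.is_unstable, v.criterion))
            except (ValueError, ZeroDivisionError):
                rows.append((xv, yv, False, "invalid"))
    return pd.DataFrame(rows, columns=[x_param, y_param, "unstable", "criterion"])
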