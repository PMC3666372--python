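"""Collagen–elastin remodeling coupled to the lesion dynamics.

The wall energy becomes a protein-weighted mixture ``w' = Ac * w_collagen +
Ae * w_elastin`` (quadratic form, see :mod:`blebdyn.constitutive`), limited
by the failure energy ``H*Phi``.  The active protein numbers evolve by
first-order kinetics driven by the *remodeling signal* — the gap between the
hyperelastic mixture energy and its energy-limited counterpart::

    sig   = |w' - Psi'| / (H*Phi)        (dimensionless)
    dAc/dt = +k1 * Ac * sig^n            (collagen laid down under stress)
    dAe/dt = -k2 * Ae * sig^n            (elastin degraded near rupture)

The signal is essentially zero far from rupture (``w' << H*Phi`` makes
``Psi' ≈ w'``) and grows as the stored energy approaches the failure energy,
so the protein matrix is quiescent for benign orbits and remodels rapidly as
the wall nears failure.  The signal is normalized by ``H*Phi`` so the rate
constants ``k1``, ``k2`` are in s⁻¹.

The changing protein mass feeds back on the momentum balance through a mass
flux term ``-m_p y1/y0^2`` with::

    m_p = R * (rho_c dAc/dt + rho_e dAe/dt) / sqrt(rho_m |c1|)

(the nondimensionalization that renders the term dimensionless under the
core time scale; see docs/derivation.md).

Escape from a stable orbit is declared when the stretch exceeds 1.5 times
the frozen-protein (k1 = k2 = 0) orbit maximum for at least one unit of
dimensionless time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .breathing import BreathingModel
from .constitutive import EnergyLimiterConfig, combined_taylor_coefficients
from .core import (
    FluidProperties,
    Geometry,
    MaterialParameters,
    MembraneProperties,
    nondimensional_groups,
    taylor_coefficients,
    time_scale,
)
from .dynamics import Trajectory, make_forcing

__all__ = [
    "ProteinState",
    "RemodelingSignal",
    "RemodelingResult",
    "remodeling_signal",
    "protein_rates",
    "rhs_extended",
    "simulate_remodeling",
]


@dataclass(frozen=True)
class ProteinState:
    """Active protein numbers and remodeling kinetics.

    ``Ac``/``Ae`` are the dimensionless collagen/elastin numbers; ``k1``,
    ``k2`` are rate constants (s⁻¹, acting on the normalized signal);
    ``n`` the signal exponent; ``rho_c``/``rho_e`` the protein densities
    (kg·m⁻³).
    """

    Ac: float
    Ae: float
    k1: float = 0.0
    k2: float = 0.0
    n: float = 1.0
    rho_c: float = 5.10
    rho_e: float = 5.10
    #: saturation of collagen packing: accretion stops once Ac reaches this
    Ac_max: float = 1.0e6

    def __post_init__(self) -> None:
        if self.Ac < 0 or self.Ae < 0:
            raise ValueError("protein numbers must be >= 0")
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("rate constants must be >= 0")
        if not self.n > 0:
            raise ValueError("exponent n must be > 0")


@dataclass(frozen=True)
class RemodelingSignal:
    """Normalized energy gap ``|w' - Psi'|/(H*Phi) >= 0``."""

    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("signal must be >= 0")


def _signal_value(w: float, cap: float) -> float:
    """(w - Psi(w))/cap with Psi = cap*(1 - exp(-w/cap)), for tensile energy.

    The limiter (and hence the signal) concerns the approach to the tensile
    failure energy: compressive states (w < 0) are far from rupture and
    produce no signal.
    """
    x = w / cap
    if x <= 0.0:
        return 0.0
    if x > 700.0:  # exp underflow guard
        return x - 1.0
    return x - 1.0 + math.exp(-x)


def remodeling_signal(
    lam: float,
    mat: MaterialParameters,
    geom: Geometry,
    elastin_b: float,
    Ac: float,
    Ae: float,
    lim: EnergyLimiterConfig,
) -> RemodelingSignal:
    """Remodeling signal at stretch ``lam`` for the quadratic mixture energy."""
    A0, A1 = combined_taylor_coefficients(mat, geom, elastin_b, Ac, Ae)
    E = (lam * lam - 1.0) / 2.0
    w = A0 * E + A1 * E * E
    cap = geom.H * lim.phi
    return RemodelingSignal(value=_signal_value(w, cap))


def protein_rates(p: ProteinState, sig: RemodelingSignal) -> tuple[float, float]:
    """(dAc/dt, dAe/dt) in s⁻¹: collagen grows (up to saturation), elastin decays."""
    drive = sig.value**p.n
    dAc = 0.0 if p.Ac >= p.Ac_max else p.k1 * p.Ac * drive
    return dAc, -p.k2 * p.Ae * drive


@dataclass
class RemodelingResult:
    """Trajectory with protein channels plus escape/rupture annotations."""

    traj: Trajectory
    escaped: bool
    escape_tau: float | None
    base_orbit_max: float


def rhs_extended(
    tau: float,
    y: tuple[float, float, float, float],
    groups,
    mat: MaterialParameters,
    geom: Geometry,
    elastin_b: float,
    p: ProteinState,
    lim: EnergyLimiterConfig,
    F,
    Ts: float,
    rho_m: float,
) -> tuple[float, float, float, float]:
    """Right-hand side of the 4-state system (d/dtau of y0, y1, Ac, Ae).

    Reduces exactly to the base dynamics with frozen proteins when
    ``k1 = k2 = 0`` (the mass-flux term vanishes with the rates).
    """
    y0, y1, Ac, Ae = y
    a0, a1 = taylor_coefficients(mat, geom)
    A0 = Ac * a0
    A1 = Ac * a1 + Ae * elastin_b * geom.H / 2.0
    E = (y0 * y0 - 1.0) / 2.0
    w = A0 * E + A1 * E * E
    cap = geom.H * lim.phi
    atten = math.exp(-min(max(w / cap, 0.0), 700.0))
    T_el = (A0 + 2.0 * A1 * E) * atten
    f = T_el / (mat.c1 * geom.H)
    sig = _signal_value(w, cap)
    drive = sig**p.n
    saturated = Ac >= p.Ac_max
    dAc_dt = 0.0 if saturated else p.k1 * Ac * drive  # per second
    dAe_dt = -p.k2 * Ae * drive
    m_p = geom.R * (p.rho_c * dAc_dt + p.rho_e * dAe_dt) / math.sqrt(rho_m * abs(mat.c1))
    Ft = F(tau) if callable(F) else F
    b, d, m_f, m = groups.b, groups.d, groups.m_f, groups.m
    # The mass-flux term accompanies the inertia in the momentum balance and
    # therefore maps through the same sign convention as the inertial group
    # when the balance is reduced: it enters the numerator with a plus sign.
    # See docs/derivation.md for the reduction.
    num = (
        Ft
        - 1.5 * b * y1 * y1
        - 4.0 * m_f * y1 / y0
        - 2.0 * f / y0
        - 4.0 * m * d * y1 / y0**4
        + m_p * y1 / (y0 * y0)
    )
    den = b * y0 + y0**-2
    return y1, num / den, Ts * dAc_dt, Ts * dAe_dt


def simulate_remodeling(
    mat: MaterialParameters,
    geom: Geometry,
    mem: MembraneProperties,
    fluid: FluidProperties,
    elastin_b: float,
    protein: ProteinState,
    lim: EnergyLimiterConfig,
    bm: BreathingModel | None = None,
    P_const: float | None = None,
    ic: tuple[float, float] = (1.0, 0.0),
    tau_end: float = 50.0,
    step: float = 1e-3,
    record_every: int = 10,
    escape_margin: float = 0.5,
    escape_hold: float = 1.0,
) -> RemodelingResult:
    """Integrate the 4-ODE collagen–elastin system by fixed-step RK4.

    The frozen-protein twin (``k1 = k2 = 0``) is integrated first over the
    same window to establish the stable-orbit envelope ``[y_min, y_max]``.
    Escape is declared when the remodeling run's stretch leaves the band
    ``[y_min - escape_margin*a, y_max + escape_margin*a]`` (``a`` the orbit
    half peak-to-trough) and either stays outside for ``escape_hold`` units
    of tau, departs by a decade, or never returns before the run ends —
    the departure is two-sided because the remodeling-driven breakdown can
    exit through violent expansion or through collapse, depending on the
    oscillation phase at which the protein flux peaks.  Integration halts at
    escape, on nonphysical collapse, or on non-finite state.
    """
    P_mean = P_const
    if P_mean is None and bm is not None:
        from .core import MMHG_TO_PA

        P_mean = bm.baseline * MMHG_TO_PA
    groups = nondimensional_groups(geom, mem, fluid, mat, (P_mean or 0.0) - fluid.p_inf)
    F = make_forcing(bm, geom, mat, mem, fluid, P_const=P_const)
    Ts = time_scale(geom, mem, mat)

    frozen = ProteinState(
        Ac=protein.Ac, Ae=protein.Ae, k1=0.0, k2=0.0, n=protein.n,
        rho_c=protein.rho_c, rho_e=protein.rho_e, Ac_max=protein.Ac_max,
    )
    base = _integrate_extended(
        mat, geom, mem, elastin_b, frozen, lim, groups, F, Ts, ic, tau_end, step,
        record_every, escape_band=None, escape_hold=escape_hold,
    )
    base_max = float(np.max(base.y0)) if len(base.y0) else float(ic[0])
    base_min = float(np.min(base.y0)) if len(base.y0) else float(ic[0])

    if protein.k1 == 0.0 and protein.k2 == 0.0:
        return RemodelingResult(traj=base, escaped=False, escape_tau=None, base_orbit_max=base_max)

    amp = 0.5 * (base_max - base_min)
    band = (base_min - escape_margin * amp, base_max + escape_margin * amp)
    traj = _integrate_extended(
        mat, geom, mem, elastin_b, protein, lim, groups, F, Ts, ic, tau_end, step,
        record_every, escape_band=band, escape_hold=escape_hold,
    )
    escape_tau = traj.channels.pop("_escape_tau", None)
    return RemodelingResult(
        traj=traj,
        escaped=escape_tau is not None,
        escape_tau=escape_tau,
        base_orbit_max=base_max,
    )


def _integrate_extended(
    mat, geom, mem, elastin_b, p, lim, groups, F, Ts, ic, tau_end, step, record_every,
    escape_band, escape_hold,
):
    y = (float(ic[0]), float(ic[1]), float(p.Ac), float(p.Ae))
    n_steps = int(round(tau_end / step))
    taus = [0.0]
    recs = [y]
    h, h2 = step, 0.5 * step
    tau = 0.0
    nonphysical = False
    above_since: float | None = None
    escape_tau: float | None = None

    def fun(t, s):
        return rhs_extended(t, s, groups, mat, geom, elastin_b, p, lim, F, Ts, mem.rho_m)

    for i in range(1, n_steps + 1):
        try:
            k1 = fun(tau, y)
            s2 = tuple(y[j] + h2 * k1[j] for j in range(4))
            k2 = fun(tau + h2, s2)
            s3 = tuple(y[j] + h2 * k2[j] for j in range(4))
            k3 = fun(tau + h2, s3)
            s4 = tuple(y[j] + h * k3[j] for j in range(4))
            k4 = fun(tau + h, s4)
            y = tuple(
                y[j] + h * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j]) / 6.0 for j in range(4)
            )
        except (OverflowError, ValueError):
            nonphysical = True
            break
        tau = i * h
        ok_state = all(math.isfinite(v) for v in y) and y[0] > 0.0
        if escape_band is not None:
            lo, hi = escape_band
            outside = (not ok_state) or y[0] > hi or y[0] < lo
            departed = (not ok_state) or y[0] > 10.0 * hi or y[0] < 0.1 * lo
            if outside:
                if above_since is None:
                    above_since = tau
                if departed or tau - above_since >= escape_hold:
                    # breakdown, decade-scale departure, or held outside
                    escape_tau = above_since
                    if ok_state and i % record_every != 0:
                        taus.append(tau)
                        recs.append(y)
                    break
            else:
                above_since = None
        if not ok_state:
            nonphysical = True
            break
        if i % record_every == 0:
            taus.append(tau)
            recs.append(y)
    # A run that ends (window or breakdown) while still outside the envelope
    # never returned to the orbit: count the crossing as the escape.
    if escape_band is not None and escape_tau is None and above_since is not None:
        escape_tau = above_since
    arr = np.array(recs)
    traj = Trajectory(
        tau=np.array(taus),
        y0=arr[:, 0],
        y1=arr[:, 1],
        nonphysical=nonphysical,
        channels={"Ac": arr[:, 2], "Ae": arr[:, 3]},
    )
    if escape_tau is not None:
        traj.channels["_escape_tau"] = escape_tau
    return traj
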