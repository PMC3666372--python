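"""Governing ODE system for the lesion wall and its fixed-step RK4 integration.

Nondimensional system (state ``y0 = lam``, ``y1 = dlam/dtau``)::

    dy0/dtau = y1
    dy1/dtau = [F(tau) - 3 b y1^2/2 - 4 m_f y1/y0 - 2 f(y0)/y0
                - 4 m d y1/y0^4] / (b y0 + y0^-2)

with ``f = T_elastic/(c1 H)`` the nondimensional elastic stress and
``F(tau) = (P_inner - p_inf) R/(c1 H)`` the forcing (both negative for
physical inputs, since ``c1 < 0``).  The dimensional twin — the same balance
multiplied back by ``|c1| H / R`` —::

    (rho_m H R/lam^2 + rho_f R^2 lam) lam'' =
        2 T(lam)/(lam R) - (P - p_inf) - 3/2 rho_f R^2 lam'^2
        - 4 mu_f lam'/lam - 4 mu_m H lam'/(R lam^4)

is provided for the dimensional/nondimensional equivalence check.

Integration is a classical fixed-step fourth-order Runge-Kutta scheme; the
integrator halts early on nonphysical collapse (``y0 <= 0``), on NaN/Inf, or
on a caller-supplied halt condition (used for rupture detection with the
energy-limited stress).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .breathing import BreathingModel, inner_pressure_pa
from .constitutive import EnergyLimiterConfig, rupture_stretch
from .core import (
    FluidProperties,
    Geometry,
    MaterialParameters,
    MembraneProperties,
    NondimensionalGroups,
    nondimensional_groups,
    taylor_coefficients,
    time_scale,
)

__all__ = [
    "State",
    "Trajectory",
    "make_stress_fn",
    "make_forcing",
    "rhs",
    "integrate_rk4",
    "simulate",
    "simulate_dimensional",
    "oscillation_metrics",
    "force_proportions",
    "detect_rupture",
    "sweep_c2",
]


@dataclass(frozen=True)
class State:
    """Instantaneous nondimensional state (stretch, stretch rate, time)."""

    y0: float
    y1: float
    tau: float = 0.0

    def __post_init__(self) -> None:
        if not self.y0 > 0:
            raise ValueError(f"y0 (stretch) must be > 0, got {self.y0}")


@dataclass
class Trajectory:
    """Time series of the integration, with rupture/collapse annotations."""

    tau: np.ndarray
    y0: np.ndarray
    y1: np.ndarray
    ruptured: bool = False
    rupture_tau: float | None = None
    nonphysical: bool = False
    channels: dict = field(default_factory=dict)  # extra series, e.g. proteins

    def __post_init__(self) -> None:
        if not (len(self.tau) == len(self.y0) == len(self.y1)):
            raise ValueError("tau, y0, y1 must have equal length")
        if len(self.tau) > 1 and not np.all(np.diff(self.tau) > 0):
            raise ValueError("tau must be strictly increasing")
        if self.ruptured != (self.rupture_tau is not None):
            raise ValueError("rupture_tau must be present iff ruptured")


def make_stress_fn(
    mat: MaterialParameters,
    geom: Geometry,
    lim: EnergyLimiterConfig | None = None,
) -> Callable[[float], float]:
    """Nondimensional elastic stress ``f(y0) = T_el/(c1 H)``.

    With an energy limiter the Taylor stress is attenuated by
    ``exp(-w_taylor/(H Phi))``.  Works on scalars and arrays.
    """
    a0, a1 = taylor_coefficients(mat, geom)
    scale = mat.c1 * geom.H
    A = a0 / scale
    B = a1 / scale
    if lim is None:

        def f(y0):
            return A + B * (y0 * y0 - 1.0)

    else:
        cap = geom.H * lim.phi

        def f(y0):
            E = (y0 * y0 - 1.0) / 2.0
            w = a0 * E + a1 * E * E
            # The limiter models the approach to the tensile failure energy;
            # it attenuates only positive stored energy (no amplification at
            # compressive states, where the exp form would be an artifact).
            return (A + B * (y0 * y0 - 1.0)) * np.exp(-np.maximum(w, 0.0) / cap)

    return f


def make_forcing(
    bm: BreathingModel | None,
    geom: Geometry,
    mat: MaterialParameters,
    mem: MembraneProperties,
    fluid: FluidProperties,
    P_const: float | None = None,
) -> Callable[[float], float]:
    """Nondimensional forcing ``F(tau)``.

    With a breathing model the inner pressure is evaluated at the dimensional
    time ``t = tau * Ts``; with ``bm=None`` a constant transmural pressure
    ``P_const`` (Pa) is used, yielding the autonomous forcing ``F_bar``.
    """
    scale = geom.R / (mat.c1 * geom.H)
    if bm is None:
        if P_const is None:
            raise ValueError("either a breathing model or P_const is required")
        F_bar = (P_const - fluid.p_inf) * scale
        return lambda tau: F_bar
    Ts = time_scale(geom, mem, mat)
    amps = bm.amplitudes * bm.R_b  # mmHg contributions
    freqs = bm.frequencies
    phases = bm.phases
    from .core import MMHG_TO_PA

    base_pa = bm.baseline * MMHG_TO_PA
    amp_pa = amps * MMHG_TO_PA
    p_inf = fluid.p_inf
    two_pi = 2.0 * math.pi

    def F(tau: float) -> float:
        t = tau * Ts
        p = base_pa
        for A, f0, ph in zip(amp_pa, freqs, phases):
            p += A * math.cos(two_pi * f0 * t + ph)
        return (p - p_inf) * scale

    return F


def rhs(
    state: State,
    groups: NondimensionalGroups,
    f: Callable[[float], float],
    F: Callable[[float], float] | float,
) -> tuple[float, float]:
    """Right-hand side of the nondimensional system at ``state``."""
    y0, y1, tau = state.y0, state.y1, state.tau
    Ft = F(tau) if callable(F) else F
    b, d, m_f, m = groups.b, groups.d, groups.m_f, groups.m
    num = Ft - 1.5 * b * y1 * y1 - 4.0 * m_f * y1 / y0 - 2.0 * f(y0) / y0 - 4.0 * m * d * y1 / y0**4
    den = b * y0 + y0**-2
    return y1, num / den


def _rhs_scalar(tau, y0, y1, b, d, m_f, m, f, F):
    Ft = F(tau) if callable(F) else F
    num = Ft - 1.5 * b * y1 * y1 - 4.0 * m_f * y1 / y0 - 2.0 * f(y0) / y0 - 4.0 * m * d * y1 / y0**4
    return y1, num / (b * y0 + y0**-2)


def integrate_rk4(
    fun: Callable[[float, float, float], tuple[float, float]],
    ic: tuple[float, float] = (1.0, 0.0),
    tau0: float = 0.0,
    tau_end: float = 100.0,
    step: float = 1e-3,
    record_every: int = 1,
    halt: Callable[[float, float, float], bool] | None = None,
) -> Trajectory:
    """Classical fixed-step RK4 for a generic 2-state system.

    ``fun(tau, y0, y1) -> (dy0, dy1)``.  Halts early (flagging the
    trajectory) on ``y0 <= 0`` (nonphysical collapse), non-finite state, or
    when ``halt`` first returns True (recorded as rupture).
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if tau_end <= tau0:
        raise ValueError("tau_end must exceed tau0")
    n_steps = int(round((tau_end - tau0) / step))
    taus = [tau0]
    ys0 = [ic[0]]
    ys1 = [ic[1]]
    y0, y1 = float(ic[0]), float(ic[1])
    tau = tau0
    ruptured = False
    rupture_tau = None
    nonphysical = False
    h = step
    h2 = 0.5 * h
    for i in range(1, n_steps + 1):
        k10, k11 = fun(tau, y0, y1)
        k20, k21 = fun(tau + h2, y0 + h2 * k10, y1 + h2 * k11)
        k30, k31 = fun(tau + h2, y0 + h2 * k20, y1 + h2 * k21)
        k40, k41 = fun(tau + h, y0 + h * k30, y1 + h * k31)
        y0 += h * (k10 + 2.0 * k20 + 2.0 * k30 + k40) / 6.0
        y1 += h * (k11 + 2.0 * k21 + 2.0 * k31 + k41) / 6.0
        tau = tau0 + i * h
        if not (math.isfinite(y0) and math.isfinite(y1)):
            nonphysical = True
            break
        if y0 <= 0.0:
            nonphysical = True
            break
        if i % record_every == 0:
            taus.append(tau)
            ys0.append(y0)
            ys1.append(y1)
        if halt is not None and halt(tau, y0, y1):
            ruptured = True
            rupture_tau = tau
            if i % record_every != 0:
                taus.append(tau)
                ys0.append(y0)
                ys1.append(y1)
            break
    return Trajectory(
        tau=np.array(taus),
        y0=np.array(ys0),
        y1=np.array(ys1),
        ruptured=ruptured,
        rupture_tau=rupture_tau,
        nonphysical=nonphysical,
    )


def simulate(
    mat: MaterialParameters,
    geom: Geometry,
    mem: MembraneProperties,
    fluid: FluidProperties,
    bm: BreathingModel | None = None,
    P_const: float | None = None,
    lim: EnergyLimiterConfig | None = None,
    ic: tuple[float, float] = (1.0, 0.0),
    tau_end: float = 100.0,
    step: float = 1e-3,
    record_every: int = 1,
) -> Trajectory:
    """Integrate the nondimensional lesion system.

    With an energy limiter the attenuated stress is used and rupture is
    declared at the first time the stretch exceeds the softening-onset
    stretch (the maximum of the limited elastic stress) while still
    expanding (``y1 > 0``).
    """
    P_mean = P_const
    if P_mean is None and bm is not None:
        from .core import MMHG_TO_PA

        P_mean = bm.baseline * MMHG_TO_PA
    groups = nondimensional_groups(geom, mem, fluid, mat, (P_mean or 0.0) - fluid.p_inf)
    f = make_stress_fn(mat, geom, lim)
    F = make_forcing(bm, geom, mat, mem, fluid, P_const=P_const)
    b, d, m_f, m = groups.b, groups.d, groups.m_f, groups.m

    def fun(tau, y0, y1):
        return _rhs_scalar(tau, y0, y1, b, d, m_f, m, f, F)

    halt = None
    if lim is not None:
        lam_rup = rupture_stretch(mat, geom, lim)

        def halt(tau, y0, y1, _lr=lam_rup):
            return y0 > _lr and y1 > 0.0

    return integrate_rk4(fun, ic=ic, tau_end=tau_end, step=step, record_every=record_every, halt=halt)


def simulate_dimensional(
    mat: MaterialParameters,
    geom: Geometry,
    mem: MembraneProperties,
    fluid: FluidProperties,
    bm: BreathingModel | None = None,
    P_const: float | None = None,
    ic: tuple[float, float] = (1.0, 0.0),
    t_end: float = 0.01,
    dt: float = 1e-7,
    record_every: int = 1,
) -> Trajectory:
    """Integrate the dimensional momentum balance (SI units).

    ``ic`` is ``(lam, dlam/dt)`` with the rate in s⁻¹; the returned
    trajectory carries dimensional time in ``tau`` and ``dlam/dt`` in ``y1``.
    Used to certify the nondimensionalization: mapping through
    ``tau = t/Ts``, ``y1 = Ts * dlam/dt`` must reproduce the nondimensional
    trajectory.
    """
    H, R = geom.H, geom.R
    rho_m, mu_m = mem.rho_m, mem.mu_m
    rho_f, mu_f, p_inf = fluid.rho_f, fluid.mu_f, fluid.p_inf
    a0, a1 = taylor_coefficients(mat, geom)

    if bm is None:
        if P_const is None:
            raise ValueError("either a breathing model or P_const is required")

        def P(t):
            return P_const

    else:

        def P(t):
            return inner_pressure_pa(t, bm)

    def fun(t, lam, lam_dot):
        T_el = a0 + a1 * (lam * lam - 1.0)
        num = (
            2.0 * T_el / (lam * R)
            - (P(t) - p_inf)
            - 1.5 * rho_f * R * R * lam_dot * lam_dot
            - 4.0 * mu_f * lam_dot / lam
            - 4.0 * mu_m * H * lam_dot / (R * lam**4)
        )
        den = rho_m * H * R / (lam * lam) + rho_f * R * R * lam
        return lam_dot, num / den

    return integrate_rk4(fun, ic=ic, tau0=0.0, tau_end=t_end, step=dt, record_every=record_every)


@dataclass(frozen=True)
class OscillationMetrics:
    amplitude: float
    frequency: float | None  # cycles per unit tau; None when non-oscillatory


def oscillation_metrics(
    traj: Trajectory,
    transient_fraction: float = 0.2,
    amplitude_floor: float = 1e-6,
) -> OscillationMetrics:
    """Amplitude (half peak-to-trough) and dominant frequency of ``y0``.

    The leading ``transient_fraction`` of the record is discarded; the
    frequency is the spectral peak of the mean-removed, Hann-windowed tail,
    refined by parabolic interpolation.  Ties break to the lowest frequency.
    Non-oscillatory records (amplitude below the floor) report frequency
    ``None``.
    """
    n = len(traj.tau)
    start = int(n * transient_fraction)
    y = traj.y0[start:]
    t = traj.tau[start:]
    if len(y) < 16:
        raise ValueError("trajectory too short after transient discard")
    amp = 0.5 * (float(np.max(y)) - float(np.min(y)))
    if amp < amplitude_floor:
        return OscillationMetrics(amplitude=amp, frequency=None)
    dt = float(t[1] - t[0])
    z = y - np.mean(y)
    win = np.hanning(len(z))
    spectrum = np.abs(np.fft.rfft(z * win))
    freqs = np.fft.rfftfreq(len(z), d=dt)
    spectrum[0] = 0.0
    k = int(np.argmax(spectrum))  # argmax returns the first (lowest-f) maximum
    if 0 < k < len(spectrum) - 1 and spectrum[k] > 0:
        s0, s1, s2 = spectrum[k - 1], spectrum[k], spectrum[k + 1]
        denom = s0 - 2.0 * s1 + s2
        delta = 0.5 * (s0 - s2) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    freq = float(freqs[k] + delta * (freqs[1] - freqs[0]))
    return OscillationMetrics(amplitude=amp, frequency=freq)


def force_proportions(
    traj: Trajectory,
    groups: NondimensionalGroups,
    f: Callable[[float], float],
    F: Callable[[float], float] | float,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-term force series along a trajectory, plus mean |magnitude| ranking.

    Terms follow the numerator of the nondimensional balance: pressure
    ``F(tau)``, fluid structure ``-3 b y1^2/2``, radial stress
    ``-4 m_f y1/y0``, internal membrane ``-2 f(y0)/y0`` and viscoelastic
    ``-4 m d y1/y0^4``.  Their sum equals ``dy1/dtau`` times the inertial
    denominator at every sample.
    """
    y0, y1, tau = traj.y0, traj.y1, traj.tau
    Ft = np.array([F(tt) if callable(F) else F for tt in tau])
    terms = pd.DataFrame(
        {
            "pressure": Ft,
            "fluid_structure": -1.5 * groups.b * y1**2,
            "radial_stress": -4.0 * groups.m_f * y1 / y0,
            "internal_membrane": -2.0 * np.asarray(f(y0)) / y0,
            "viscoelastic": -4.0 * groups.m * groups.d * y1 / y0**4,
        },
        index=pd.Index(tau, name="tau"),
    )
    means = {c: float(np.mean(np.abs(terms[c]))) for c in terms.columns}
    return terms, means


def detect_rupture(
    traj: Trajectory,
    mat: MaterialParameters,
    geom: Geometry,
    lim: EnergyLimiterConfig,
) -> tuple[bool, float | None]:
    """Post-hoc rupture scan: first sample past softening onset while expanding."""
    lam_rup = rupture_stretch(mat, geom, lim)
    mask = (traj.y0 > lam_rup) & (traj.y1 > 0.0)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return False, None
    return True, float(traj.tau[idx[0]])


def sweep_c2(
    c2_values: np.ndarray,
    mat: MaterialParameters,
    geom: Geometry,
    mem: MembraneProperties,
    fluid: FluidProperties,
    bm: BreathingModel | None = None,
    P_const: float | None = None,
    ic: tuple[float, float] = (1.0, 0.0),
    tau_end: float = 4000.0,
    step: float = 5e-3,
    record_every: int = 10,
    transient_fraction: float = 0.2,
) -> pd.DataFrame:
    """Amplitude/frequency sweep over the stiffness constant ``c2``.

    All runs share every parameter except ``c2`` and are advanced together
    as one vectorized RK4 batch.  Returns a tidy frame with columns
    ``c2, amplitude, frequency``.
    """
    c2_values = np.asarray(c2_values, dtype=float)
    c1, c3, H, R = mat.c1, mat.c3, geom.H, geom.R
    # per-run nondimensional stress coefficients f(y0) = A + B (y0^2-1)
    A = (-c1 * H / c2_values + c3 * H) / (c1 * H)
    B = (-c1 * H / (2 * c2_values**2) + 3 * c1 * H / (2 * c2_values) - 2 * c3 * H) / (c1 * H)
    P_mean = P_const
    if P_mean is None and bm is not None:
        from .core import MMHG_TO_PA

        P_mean = bm.baseline * MMHG_TO_PA
    groups = nondimensional_groups(geom, mem, fluid, mat, (P_mean or 0.0) - fluid.p_inf)
    b, d, m_f, m = groups.b, groups.d, groups.m_f, groups.m
    F = make_forcing(bm, geom, mat, mem, fluid, P_const=P_const)

    def deriv(tau, y0, y1):
        Ft = F(tau) if callable(F) else F
        num = Ft - 1.5 * b * y1 * y1 - 4.0 * m_f * y1 / y0 - 2.0 * (A + B * (y0 * y0 - 1.0)) / y0 \
            - 4.0 * m * d * y1 / y0**4
        return y1, num / (b * y0 + y0**-2)

    n = len(c2_values)
    n_steps = int(round(tau_end / step))
    n_rec = n_steps // record_every + 1
    rec0 = np.empty((n_rec, n))
    y0 = np.full(n, float(ic[0]))
    y1 = np.full(n, float(ic[1]))
    rec0[0] = y0
    h, h2 = step, 0.5 * step
    tau = 0.0
    j = 1
    for i in range(1, n_steps + 1):
        k10, k11 = deriv(tau, y0, y1)
        k20, k21 = deriv(tau + h2, y0 + h2 * k10, y1 + h2 * k11)
        k30, k31 = deriv(tau + h2, y0 + h2 * k20, y1 + h2 * k21)
        k40, k41 = deriv(tau + h, y0 + h * k30, y1 + h * k31)
        y0 = y0 + h * (k10 + 2 * k20 + 2 * k30 + k40) / 6.0
        y1 = y1 + h * (k11 + 2 * k21 + 2 * k31 + k41) / 6.0
        tau = i * h
        if i % record_every == 0:
            rec0[j] = y0
            j += 1
    taus = np.arange(n_rec) * (step * record_every)
    rows = []
    for k in range(n):
        traj = Trajectory(tau=taus, y0=rec0[:, k], y1=np.zeros(n_rec))
        mtr = oscillation_metrics(traj, transient_fraction=transient_fraction)
        rows.append((c2_values[k], mtr.amplitude, mtr.frequency))
    return pd.DataFrame(rows, columns=["c2", "amplitude", "frequency"])
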