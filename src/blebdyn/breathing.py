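"""Pulsatile breathing forcing.

The driven air flow through the bronchiole network is a seven-component
Fourier series ``Q(t) = sum_i A_i cos(2 pi f_i t + phi_i)`` (L·s⁻¹); the
inner (airway) pressure follows from the respiratory resistance ``R_b`` as
``P_inner = baseline + R_b * Q(t)`` (mmHg; ``R_b = 1 mmHg·s·L⁻¹``, baseline
atmospheric 760 mmHg).  The packaged component table has all frequencies as
integer multiples of 0.078125 Hz, so the series has a common period of
12.8 s.  Phases are radians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MMHG_TO_PA

__all__ = [
    "BreathingModel",
    "default_breathing",
    "load_breathing_csv",
    "driven_flow",
    "inner_pressure",
    "inner_pressure_pa",
    "common_period",
]


@dataclass(frozen=True)
class BreathingModel:
    """Fourier flow components plus respiratory resistance and baseline pressure.

    ``components`` is a sequence of ``(A_i, f_i, phi_i)`` triples with the
    amplitude in L·s⁻¹, the frequency in Hz and the phase in radians.
    ``R_b`` is in mmHg·s·L⁻¹ and ``baseline`` in mmHg.
    """

    components: tuple[tuple[float, float, float], ...]
    R_b: float = 1.0
    baseline: float = 760.0

    def __post_init__(self) -> None:
        if self.R_b <= 0:
            raise ValueError(f"R_b must be > 0, got {self.R_b}")
        for A, f, _ in self.components:
            if A < 0:
                raise ValueError(f"amplitudes must be >= 0, got {A}")
            if f <= 0:
                raise ValueError(f"frequencies must be > 0, got {f}")

    # convenience views
    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([c[0] for c in self.components])

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([c[1] for c in self.components])

    @property
    def phases(self) -> np.ndarray:
        return np.array([c[2] for c in self.components])

    def scaled(self, amplitude_factor: float) -> "BreathingModel":
        """Copy with all amplitudes multiplied by ``amplitude_factor``."""
        comps = tuple((A * amplitude_factor, f, p) for A, f, p in self.components)
        return BreathingModel(components=comps, R_b=self.R_b, baseline=self.baseline)


def load_breathing_csv(path: str | Path, R_b: float = 1.0, baseline: float = 760.0) -> BreathingModel:
    """Read a component table with columns ``A`` (L/s), ``f`` (Hz), ``phi`` (rad)."""
    df = pd.read_csv(path)
    comps = tuple(
        (float(r.A), float(r.f), float(r.phi)) for r in df.itertuples(index=False)
    )
    return BreathingModel(components=comps, R_b=R_b, baseline=baseline)


def default_breathing() -> BreathingModel:
    """The packaged seven-component table (common period 12.8 s)."""
    with resources.as_file(
        resources.files("blebdyn.data").joinpath("breathing_fourier.csv")
    ) as p:
        return load_breathing_csv(p)


def driven_flow(t, bm: BreathingModel):
    """Air flow Q(t) in L·s⁻¹; ``t`` may be a scalar or array (seconds)."""
    t = np.asarray(t, dtype=float)
    arg = 2.0 * np.pi * t[..., None] * bm.frequencies + bm.phases
    out = np.sum(bm.amplitudes * np.cos(arg), axis=-1)
    return float(out) if out.ndim == 0 else out


def inner_pressure(t, bm: BreathingModel):
    """Inner (airway) pressure in mmHg: ``baseline + R_b * Q(t)``."""
    q = driven_flow(t, bm)
    return bm.baseline + bm.R_b * q


def inner_pressure_pa(t, bm: BreathingModel):
    """Inner pressure converted to Pa."""
    return inner_pressure(t, bm) * MMHG_TO_PA


def common_period(bm: BreathingModel, max_multiple: int = 100000, rtol: float = 1e-9) -> float:
    """Least ``T`` with ``f_i * T`` an integer for every component.

    Uses the rational structure of the frequencies: each ``f_i/f_min`` must be
    (close to) a ratio of small integers.  Raises ``ValueError`` when no
    common period exists within ``max_multiple`` base periods (incommensurate
    frequencies).
    """
    freqs = bm.frequencies
    if len(freqs) == 0:
        raise ValueError("breathing model has no components")
    # Express every frequency as an integer multiple of a common base.
    from fractions import Fraction

    fracs = []
    for f in freqs:
        fr = Fraction(f).limit_denominator(max_multiple)
        if abs(float(fr) - f) > rtol * f:
            raise ValueError(f"frequency {f} is not commensurate within tolerance")
        fracs.append(fr)
    # common period T = L / G where the fundamental frequency is gcd of fracs
    num_gcd = math.gcd(*[fr.numerator for fr in fracs])
    den_lcm = math.lcm(*[fr.denominator for fr in fracs])
    base = Fraction(num_gcd, den_lcm)  # gcd of the rational frequencies
    T = 1.0 / float(base)
    # verify all f_i*T integral and T within bound
    if T > max_multiple / float(min(freqs)):
        raise ValueError("no common period within the configured bound")
    for f in freqs:
        k = f * T
        if abs(k - round(k)) > 1e-6:
            raise ValueError(f"frequency {f} is not commensurate (f*T={k})")
    return T
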