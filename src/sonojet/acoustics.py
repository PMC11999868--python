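"""Driving ultrasound pulse and ambient medium.

The bubble is driven by a single short ultrasound pulse (default: 1 MHz
carrier, 20 cycles, ramped envelope).  The pulse is modelled as a plane
travelling wave, so the spatial pressure gradient follows from the time
derivative, ``grad p = (1/c_l) dp/dt``, projected onto the substrate
normal by the cosine of the incidence angle.  The same gradient feeds the
primary Bjerknes force and the ultrasound Kelvin impulse downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "Medium",
    "UltrasoundPulse",
    "build_pulse",
    "evaluate_pulse",
    "read_envelope",
    "write_envelope",
    "WATER",
]


@dataclass(frozen=True)
class Medium:
    """Ambient liquid (water at lab temperature).

    Parameters
    ----------
    rho_l : float
        Liquid density (kg m^-3).
    mu_l : float
        Dynamic viscosity (Pa s).
    c_l : float
        Speed of sound (m s^-1).
    p0 : float
        Ambient static pressure (Pa).
    p_v : float
        Vapour pressure (Pa).
    sigma_w : float
        Clean gas-water surface tension (N m^-1).
    T_l : float
        Temperature (degrees C, metadata only).
    """

    rho_l: float = 998.0
    mu_l: float = 1.0e-3
    c_l: float = 1482.0
    p0: float = 101_325.0
    p_v: float = 2330.0
    sigma_w: float = 0.072
    T_l: float = 22.0

    def __post_init__(self) -> None:
        for name in ("rho_l", "mu_l", "c_l", "p0", "p_v", "sigma_w"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Medium.{name} must be strictly positive")
        if self.p0 <= self.p_v:
            raise ValueError("ambient pressure must exceed vapour pressure")


#: Water at ~22 degrees C, the default bath.
WATER = Medium()


@dataclass(frozen=True)
class UltrasoundPulse:
    """Single ramped ultrasound pulse.

    The instantaneous driving pressure is ``p_d(t) = p_a env(t) sin(2 pi f t)``
    with ``env`` a unitless envelope in [0, 1] that starts at zero.  Outside
    the pulse window the pressure is exactly zero.

    ``angle_deg`` is the angle between the propagation direction and the
    substrate normal; the default 15 degrees corresponds to a transducer
    inclined at 75 degrees to the horizontal substrate plane.
    """

    f: float
    p_a: float
    n_cycles: int
    angle_deg: float = 15.0
    ramp_cycles: float = 5.0
    envelope_t: np.ndarray | None = field(default=None, repr=False)
    envelope_a: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("carrier frequency must be positive")
        if self.p_a < 0:
            raise ValueError("pressure amplitude must be non-negative")
        if self.n_cycles < 1:
            raise ValueError("need at least one carrier cycle")

    @property
    def omega(self) -> float:
        """Angular driving frequency (rad s^-1)."""
        return 2.0 * np.pi * self.f

    @property
    def duration(self) -> float:
        """Pulse length n_cycles / f (s)."""
        return self.n_cycles / self.f

    def envelope(self, t):
        """Unitless envelope on [0, 1]; zero outside the pulse window."""
        t = np.asarray(t, dtype=float)
        if self.envelope_t is not None:
            env = np.interp(t, self.envelope_t, self.envelope_a, left=0.0, right=0.0)
        else:
            ramp_T = self.ramp_cycles / self.f
            if ramp_T > 0:
                env = np.clip(t / ramp_T, 0.0, 1.0)
            else:
                env = np.ones_like(t)
        inside = (t >= 0.0) & (t <= self.duration)
        return np.where(inside, env, 0.0)

    def pressure(self, t):
        """Driving pressure p_d(t) (Pa)."""
        t = np.asarray(t, dtype=float)
        return self.p_a * self.envelope(t) * np.sin(self.omega * t)

    def with_amplitude(self, p_a: float) -> "UltrasoundPulse":
        """Copy of this pulse at a different pressure amplitude."""
        return UltrasoundPulse(
            f=self.f,
            p_a=p_a,
            n_cycles=self.n_cycles,
            angle_deg=self.angle_deg,
            ramp_cycles=self.ramp_cycles,
            envelope_t=self.envelope_t,
            envelope_a=self.envelope_a,
        )


def build_pulse(
    f: float,
    p_a: float,
    n_cycles: int,
    ramp_cycles: float = 5.0,
    angle_deg: float = 15.0,
    envelope_file: str | Path | None = None,
    envelope_table: tuple[np.ndarray, np.ndarray] | None = None,
) -> UltrasoundPulse:
    """Assemble an :class:`UltrasoundPulse` from a parametric ramp or a
    sampled (hydrophone) envelope.

    Parameters
    ----------
    ramp_cycles : float
        Length of the linear rise of the parametric envelope, in carrier
        cycles; ignored when a sampled envelope is supplied.
    envelope_file, envelope_table : optional
        Sampled envelope as a two-column CSV file (time_s, amplitude) or an
        in-memory ``(t, a)`` pair.  The time axis must be strictly
        increasing and cover the pulse window ``[0, n_cycles/f]``.
    """
    env_t = env_a = None
    if envelope_file is not None and envelope_table is not None:
        raise ValueError("give either envelope_file or envelope_table, not both")
    if envelope_file is not None:
        envelope_table = read_envelope(envelope_file)
    if envelope_table is not None:
        env_t = np.asarray(envelope_table[0], dtype=float)
        env_a = np.asarray(envelope_table[1], dtype=float)
        if env_t.ndim != 1 or env_t.size < 2 or env_t.size != env_a.size:
            raise ValueError("envelope table must be two equal-length 1-D columns")
        if np.any(np.diff(env_t) <= 0):
            raise ValueError("envelope time axis must be strictly increasing")
        if env_t[0] > 0.0 or env_t[-1] < n_cycles / f:
            raise ValueError("envelope table must cover the pulse window")
        if np.any(env_a < 0.0) or np.any(env_a > 1.0):
            raise ValueError("envelope samples must lie in [0, 1]")
    return UltrasoundPulse(
        f=f,
        p_a=p_a,
        n_cycles=int(n_cycles),
        angle_deg=angle_deg,
        ramp_cycles=ramp_cycles,
        envelope_t=env_t,
        envelope_a=env_a,
    )


def evaluate_pulse(pulse: UltrasoundPulse, medium: Medium, t):
    """Driving pressure and its axial spatial gradient at the bubble.

    Returns
    -------
    p_d : ndarray
        Driving pressure (Pa), zero outside the pulse window.
    grad_p_us : ndarray
        Spatial pressure gradient (Pa m^-1) signed along the substrate
        normal: for a plane travelling wave ``p(x, t) = p_hat(t - x/c_l)``
        one has ``dp/dx = -(1/c_l) dp/dt`` along the propagation direction;
        the component along the substrate normal carries an extra
        ``cos(angle)`` projection.  The sign convention follows the axis
        pointing from the bubble towards the substrate (the propagation
        direction), so ``grad_p_us = -(cos angle / c_l) dp_d/dt``.
    """
    t = np.asarray(t, dtype=float)
    p_d = pulse.pressure(t)
    # dp/dt by analytic product rule on the carrier, envelope slope by
    # finite differences of the (piecewise-linear) envelope.
    w = pulse.omega
    env = pulse.envelope(t)
    h = 1.0 / (pulse.f * 1e4)  # 1e-4 carrier periods
    denv = (pulse.envelope(t + h) - pulse.envelope(t - h)) / (2.0 * h)
    dpdt = pulse.p_a * (denv * np.sin(w * t) + env * w * np.cos(w * t))
    proj = np.cos(np.deg2rad(pulse.angle_deg))
    grad = -(proj / medium.c_l) * dpdt
    return p_d, grad


def read_envelope(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a hydrophone envelope CSV (columns: time_s, amplitude)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError("envelope file needs two columns: time_s, amplitude")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    a = df.iloc[:, 1].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("envelope time axis must be strictly increasing")
    return t, a


def write_envelope(path: str | Path, t: np.ndarray, a: np.ndarray) -> None:
    """Write an envelope CSV understood by :func:`read_envelope`."""
    pd.DataFrame({"time_s": t, "amplitude": a}).to_csv(path, index=False)
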