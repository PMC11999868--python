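"""Cell-stress mechanisms of an ultrasound-driven microbubble.

Six mechanisms are compared: the water-hammer pressure of the piercing
microjet, the jet Bernoulli stagnation pressure, the impact/suction
pressure of the oscillating bubble wall, the oscillatory viscous shear in
the acoustic boundary layer, the steady acoustic-streaming shear, and the
average cross-section pressures of the primary and secondary Bjerknes
forces.

The wall-motion channels are evaluated on the bubble motion sampled at an
observation frame rate (default 1e7 frames per second), the way the
stress comparison is inferred from recorded bubble motion: the spherical
model's sub-frame collapse spike coincides with the instants where the
real interface goes aspherical and feeds the jet, so it acts on the cell
as the jet hammer (accounted for through ``u_jet``), not as a wall
stagnation pressure.  Pass ``frame_rate=None`` to use the native solver
grid instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acoustics import Medium, UltrasoundPulse, evaluate_pulse
from .radial_dynamics import EXPANSION_THRESHOLD, RadialSolution
from .translation_dynamics import TranslationSolution

__all__ = [
    "JetParams",
    "StressTimeSeries",
    "jet_stresses",
    "flow_stresses",
    "bjerknes_pressures",
    "stress_report",
    "boundary_layer_thickness",
]


@dataclass(frozen=True)
class JetParams:
    """Microjet kinematics.

    u_jet : jet speed (m s^-1).  Default 60, the lower bound implied by a
        jet traversing a 6-um bubble within one 0.1-us frame.
    R_jet : jet head radius (m).  Not directly observable; defaults to
        R0/4 when built via :func:`JetParams.for_bubble`.
    """

    u_jet: float = 60.0
    R_jet: float = 0.75e-6

    def __post_init__(self) -> None:
        if self.u_jet < 0 or self.R_jet <= 0:
            raise ValueError("jet speed must be >= 0 and head radius > 0")

    @classmethod
    def for_bubble(cls, R0: float, u_jet: float = 60.0) -> "JetParams":
        return cls(u_jet=u_jet, R_jet=0.25 * R0)


@dataclass
class StressTimeSeries:
    """All stress channels on a common (observation) time grid.

    ``p_jet`` is an event series: zero except at the tagged jet instants.
    ``p_stag`` and ``tau_stream`` are constant levels, broadcast for
    convenience.  Signed channels follow the convention positive towards
    the substrate / outwards from the bubble.
    """

    t: np.ndarray
    p_jet: np.ndarray
    p_stag: np.ndarray
    p_impact: np.ndarray
    tau_shear: np.ndarray
    tau_stream: np.ndarray
    p_B1: np.ndarray
    p_B2: np.ndarray
    delta: float
    rho_contact: float
    varsigma: float
    jet_times: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "p_jet_pa": self.p_jet,
                "p_stag_pa": self.p_stag,
                "p_impact_pa": self.p_impact,
                "tau_shear_pa": self.tau_shear,
                "tau_stream_pa": self.tau_stream,
                "p_B1_pa": self.p_B1,
                "p_B2_pa": self.p_B2,
            }
        )


def boundary_layer_thickness(medium: Medium, omega: float) -> float:
    """Oscillatory (Stokes) boundary-layer thickness (2 mu / rho omega)^1/2."""
    if omega <= 0:
        raise ValueError("angular frequency must be positive")
    return math.sqrt(2.0 * medium.mu_l / (medium.rho_l * omega))


def jet_stresses(jet: JetParams, medium: Medium) -> dict:
    """Water-hammer and stagnation pressures plus jet contact geometry.

    p_jet = 1/2 rho c u_jet (hammer, sustained for the rarefaction transit
    time varsigma = R_jet u_jet / c^2 across the contact zone of radius
    rho_contact = R_jet u_jet / c); p_stag = 1/2 rho u_jet^2.
    """
    u, Rj = jet.u_jet, jet.R_jet
    return {
        "p_jet": 0.5 * medium.rho_l * medium.c_l * u,
        "p_stag": 0.5 * medium.rho_l * u**2,
        "rho_contact": Rj * u / medium.c_l,
        "varsigma": Rj * u / medium.c_l**2,
    }


def _observe(R_sol: RadialSolution, translation: TranslationSolution | None,
             frame_rate: float | None):
    """Sample R(t) (and x(t)) at the observation frame rate; derivatives by
    centered finite differences, as extracted from recorded tracks."""
    if frame_rate is None:
        t = R_sol.t
        return t, R_sol.R, R_sol.Rdot, R_sol.Vddot, (
            None if translation is None else np.interp(t, translation.t, translation.x))
    t_end = R_sol.t[-1]
    t = np.arange(0.0, t_end + 0.5 / frame_rate, 1.0 / frame_rate)
    R = np.interp(t, R_sol.t, R_sol.R)
    Rdot = np.gradient(R, t)
    V = (4.0 / 3.0) * np.pi * R**3
    Vddot = np.gradient(np.gradient(V, t), t)
    x = None if translation is None else np.interp(t, translation.t, translation.x)
    return t, R, Rdot, Vddot, x


def flow_stresses(
    R_sol: RadialSolution,
    pulse: UltrasoundPulse | None = None,
    medium: Medium | None = None,
    u_stream: float = 0.1,
    frame_rate: float | None = 1.0e7,
) -> dict:
    """Wall impact pressure, oscillatory shear and streaming shear.

    p_impact = 1/2 rho |Rdot| Rdot (signed: positive when the wall pushes
    towards the cell), tau_shear = mu Rdot / delta, tau_stream =
    mu u_stream / delta with delta the oscillatory boundary-layer
    thickness at the driving frequency.
    """
    pulse = pulse or R_sol.pulse
    medium = medium or R_sol.medium
    if u_stream < 0:
        raise ValueError("streaming speed must be non-negative")
    delta = boundary_layer_thickness(medium, pulse.omega)
    t, _R, Rdot, _Vdd, _x = _observe(R_sol, None, frame_rate)
    return {
        "t": t,
        "p_impact": 0.5 * medium.rho_l * np.abs(Rdot) * Rdot,
        "tau_shear": medium.mu_l * Rdot / delta,
        "tau_stream": medium.mu_l * u_stream / delta,
        "delta": delta,
    }


def bjerknes_pressures(
    R_sol: RadialSolution,
    pulse: UltrasoundPulse | None = None,
    medium: Medium | None = None,
    h: np.ndarray | float = None,
    frame_rate: float | None = 1.0e7,
) -> dict:
    """Average cross-section pressures of the Bjerknes forces.

    p_B1 = -(4/3) R dp_d/dx and p_B2 = -rho R Vddot / (12 pi h^2) with h
    the bubble-substrate distance (series or scalar, > 0).
    """
    pulse = pulse or R_sol.pulse
    medium = medium or R_sol.medium
    t, R, _Rdot, Vddot, _x = _observe(R_sol, None, frame_rate)
    if h is None:
        raise ValueError("bubble-substrate distance h is required")
    h = np.broadcast_to(np.asarray(h, dtype=float), t.shape)
    if np.any(h <= 0):
        raise ValueError("bubble-substrate distance must be positive")
    _, grad_us = evaluate_pulse(pulse, medium, t)
    return {
        "t": t,
        "p_B1": -(4.0 / 3.0) * R * grad_us,
        "p_B2": -medium.rho_l * R * Vddot / (12.0 * np.pi * h**2),
    }


def stress_report(
    radial: RadialSolution,
    translation: TranslationSolution | None = None,
    pulse: UltrasoundPulse | None = None,
    medium: Medium | None = None,
    jet: JetParams | None = None,
    u_stream: float = 0.1,
    frame_rate: float | None = 1.0e7,
    expansion_threshold: float = EXPANSION_THRESHOLD,
    L: float | None = None,
) -> tuple[StressTimeSeries, dict]:
    """Assemble all stress channels and the peak-comparison table.

    The hammer pressure is tagged as an event series at the jet instants:
    driving-pressure compression peaks occurring after the radial
    expansion first exceeds the jetting threshold (no jets are tagged if
    it never does, in which case the jet channels are zero).

    Returns the :class:`StressTimeSeries` and a peak table with the
    maximum absolute value of each channel, the ratio of the hammer
    pressure to each other peak, their minimum
    (``jet_dominance``), and ``stag_over_impact``.
    """
    pulse = pulse or radial.pulse
    medium = medium or radial.medium
    jet = jet or JetParams.for_bubble(radial.bubble.R0)

    t, R, Rdot, Vddot, x = _observe(radial, translation, frame_rate)
    flow = flow_stresses(radial, pulse, medium, u_stream, frame_rate)
    if x is not None:
        h = (translation.L if L is None else L) - x
    else:
        h = (L if L is not None else 12.0e-6) * np.ones_like(t)
    # the mirror-image closure behind p_B2 requires the bubble centre to
    # stay at least one radius from the wall; floor h there so the
    # channel stays within the model's geometric validity near contact
    h = np.maximum(h, R)
    bj = bjerknes_pressures(radial, pulse, medium, h, frame_rate)
    js = jet_stresses(jet, medium)

    # jet instants: compression peaks of the driving pressure after the
    # expansion threshold is first crossed
    R0 = radial.bubble.R0
    jetting = np.any(R - R0 >= expansion_threshold)
    p_jet_series = np.zeros_like(t)
    p_stag_series = np.zeros_like(t)
    jet_times = np.array([])
    if jetting and jet.u_jet > 0:
        t_first = t[np.argmax(R - R0 >= expansion_threshold)]
        p_d = pulse.pressure(t)
        peaks = np.flatnonzero(
            (p_d[1:-1] > p_d[:-2]) & (p_d[1:-1] >= p_d[2:]) & (p_d[1:-1] > 0)
        ) + 1
        peaks = peaks[t[peaks] >= t_first]
        jet_times = t[peaks]
        p_jet_series[peaks] = js["p_jet"]
        p_stag_series[peaks] = js["p_stag"]

    series = StressTimeSeries(
        t=t,
        p_jet=p_jet_series,
        p_stag=p_stag_series,
        p_impact=flow["p_impact"],
        tau_shear=flow["tau_shear"],
        tau_stream=np.full_like(t, flow["tau_stream"]),
        p_B1=bj["p_B1"],
        p_B2=bj["p_B2"],
        delta=flow["delta"],
        rho_contact=js["rho_contact"],
        varsigma=js["varsigma"],
        jet_times=jet_times,
    )

    peaks = {
        "p_jet": js["p_jet"] if jet_times.size else 0.0,
        "p_stag": js["p_stag"] if jet_times.size else 0.0,
        "p_impact": float(np.max(np.abs(series.p_impact))),
        "tau_shear": float(np.max(np.abs(series.tau_shear))),
        "tau_stream": float(flow["tau_stream"]),
        "p_B1": float(np.max(np.abs(series.p_B1))),
        "p_B2": float(np.max(np.abs(series.p_B2))),
    }
    others = {k: v for k, v in peaks.items() if k not in ("p_jet", "p_stag")}
    ratios = {f"p_jet_over_{k}": (peaks["p_jet"] / v if v > 0 else math.inf)
              for k, v in others.items()}
    table = {
        "peaks": peaks,
        "ratios": ratios,
        "jet_dominance": min(ratios.values()) if ratios else math.inf,
        "stag_over_impact": (peaks["p_stag"] / peaks["p_impact"]
                             if peaks["p_impact"] > 0 else math.inf),
        "n_jets": int(jet_times.size),
    }
    # algebraic ordering check: hammer > stagnation > wall impact whenever
    # the observed wall speed stays below the jet speed
    if jet_times.size and float(np.max(np.abs(Rdot))) < jet.u_jet:
        assert peaks["p_jet"] > peaks["p_stag"] > peaks["p_impact"]
    return series, table
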