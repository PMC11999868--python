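"""Synthetic inputs emulating the experimental observables.

Every generator is a pure function of its parameters and a seed, so all
pipeline stages are testable without any deposited data.  The generators
emulate:

* radius/centroid tracks sampled at the ultra-high-speed camera rate
  (10 Mfps) with half-pixel (80 nm) quantization noise, modelled as
  uniform on +-80 nm because it originates from pixel quantization;
* jetting-event tables over the experimental bubble size range
  (equilibrium radii 1-4 um) and a pressure-amplitude grid;
* Hertzian AFM force curves with baseline offset, contact-point jitter
  and multiplicative force noise, on the 3 samples x 4-5 locations x
  5x5-point grid layout of the hydrogel characterization;
* ramped pulse-envelope files standing in for hydrophone recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acoustics import Medium, UltrasoundPulse, write_envelope
from .afm import ForceCurve, hertz_force
from .radial_dynamics import (
    BubbleParams,
    RadialCollapseError,
    RadialSolution,
    ShellParams,
    classify_event,
    expansion_metrics,
    solve_radial,
)
from .translation_dynamics import CellLayer, solve_translation

__all__ = [
    "SyntheticSpec",
    "gen_radius_track",
    "gen_event_dataset",
    "gen_afm_curves",
    "gen_pulse_envelope",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Observation model: camera frame rate, pixel size and event grid."""

    seed: int = 0
    frame_rate: float = 1.0e7
    pixel: float = 160.0e-9
    duration: float | None = None
    R0_range: tuple[float, float] = (1.0e-6, 4.0e-6)
    p_a_grid: tuple[float, ...] = (20e3, 40e3, 60e3, 100e3, 160e3, 250e3)

    @property
    def half_pixel(self) -> float:
        return 0.5 * self.pixel

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


def gen_radius_track(
    bubble: BubbleParams,
    shell: ShellParams,
    pulse: UltrasoundPulse,
    medium: Medium,
    spec: SyntheticSpec,
    include_position: bool = False,
    cell: CellLayer | None = None,
    noise: bool = True,
) -> tuple[RadialSolution, pd.DataFrame]:
    """Forward-simulate and sample a radius (and optionally centroid) track.

    The clean solution is sampled at the camera frame rate and uniform
    quantization noise of +- half a pixel is added to R (and x).  Returns
    the clean :class:`RadialSolution` and the noisy sampled track.
    """
    t_end = spec.duration or (pulse.duration + 5.0 / pulse.f)
    sol = solve_radial(pulse, bubble, shell, medium, t_end=t_end)
    ts = np.arange(0.0, t_end + 0.5 / spec.frame_rate, 1.0 / spec.frame_rate)
    Rs = np.interp(ts, sol.t, sol.R)
    rng = spec.rng(salt=1)
    if noise:
        Rs = Rs + rng.uniform(-spec.half_pixel, spec.half_pixel, Rs.shape)
    data = {"t_s": ts, "R_m": Rs}
    if include_position:
        tr = solve_translation(sol, pulse, medium, cell or CellLayer())
        xs = np.interp(ts, tr.t, tr.x)
        if noise:
            xs = xs + rng.uniform(-spec.half_pixel, spec.half_pixel, xs.shape)
        data["x_m"] = xs
    return sol, pd.DataFrame(data)


def gen_event_dataset(
    n_events: int,
    spec: SyntheticSpec,
    pulse_template: UltrasoundPulse,
    shell: ShellParams | None = None,
    medium: Medium | None = None,
) -> pd.DataFrame:
    """Simulated jetting-event table over the bubble size range.

    Each event draws an equilibrium radius uniformly from ``R0_range``
    and a pressure amplitude from ``p_a_grid``, simulates the radial
    response, and records the expansion metrics and the jetting /
    sonoporation / inertial-cavitation labels.  Events whose integration
    collapses are flagged (``solved = False``) with NaN metrics.
    """
    if n_events < 1:
        raise ValueError("need at least one event")
    shell = shell or ShellParams()
    medium = medium or Medium()
    rng = spec.rng(salt=2)
    lo, hi = spec.R0_range
    R0s = rng.uniform(lo, hi, n_events)
    pas = rng.choice(np.asarray(spec.p_a_grid, dtype=float), n_events)
    rows = []
    for R0, pa in zip(R0s, pas):
        pulse = pulse_template.with_amplitude(float(pa))
        row = {"R0_m": float(R0), "p_a_pa": float(pa), "solved": True}
        try:
            sol = solve_radial(pulse, BubbleParams(R0=float(R0)), shell, medium)
            m = expansion_metrics(sol)
            row["max_expansion_m"] = m["max_expansion"]
            row["accel_proxy_m_s2"] = m["accel_proxy"]
            row.update(classify_event(m["max_expansion"], float(R0)))
        except RadialCollapseError:
            row.update(
                solved=False, max_expansion_m=np.nan, accel_proxy_m_s2=np.nan,
                jetting=True, sonoporation_predicted=True,
                inertial_cavitation=True,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def gen_afm_curves(
    E_true: float = 530.0,
    noise_frac: float = 0.05,
    n_samples: int = 3,
    n_locations: int = 5,
    n_points: int = 25,
    seed: int = 0,
    Rbead: float = 5.0e-6,
    theta: float = 0.5,
    max_indent: float = 1.0e-6,
    n_z: int = 160,
    location_spread: float = 0.05,
) -> list[ForceCurve]:
    """Synthetic Hertzian force curves with realistic nuisance structure.

    Per curve: a pre-contact baseline segment, a jittered contact point, a
    small constant force offset, multiplicative force noise of relative
    magnitude ``noise_frac``, and a per-location modulus spread of
    relative sd ``location_spread`` around ``E_true``.
    """
    if E_true <= 0:
        raise ValueError("E_true must be positive")
    rng = np.random.default_rng(seed)
    curves = []
    for s in range(n_samples):
        for l in range(n_locations):
            E_loc = E_true * (1.0 + location_spread * rng.standard_normal())
            for _p in range(n_points):
                z0 = 0.4e-6 + rng.uniform(-0.1e-6, 0.1e-6)
                z = np.linspace(0.0, z0 + max_indent, n_z)
                baseline = rng.uniform(-0.02e-9, 0.02e-9)
                F = baseline + hertz_force(z - z0, E_loc, theta, Rbead)
                F = F * (1.0 + noise_frac * rng.standard_normal(F.shape))
                F = F + noise_frac * 0.02e-9 * rng.standard_normal(F.shape)
                curves.append(
                    ForceCurve(
                        displacement=z, force=F, Rbead=Rbead, theta=theta,
                        location_id=f"loc{l}", sample_id=f"gel{s}",
                    )
                )
    return curves


def gen_pulse_envelope(
    f: float = 1.0e6,
    n_cycles: int = 20,
    ramp_cycles: float = 5.0,
    samples_per_cycle: int = 50,
    path=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled ramp envelope standing in for a hydrophone recording.

    Linear rise over ``ramp_cycles`` carrier cycles, then constant at 1;
    a zero-length ramp yields a rectangular envelope.  Optionally writes
    the CSV understood by :func:`sonojet.acoustics.build_pulse`.
    """
    if samples_per_cycle < 50:
        raise ValueError("need at least 50 samples per cycle")
    duration = n_cycles / f
    t = np.linspace(0.0, duration, int(samples_per_cycle * n_cycles) + 1)
    if ramp_cycles > 0:
        a = np.clip(t * f / ramp_cycles, 0.0, 1.0)
    else:
        a = np.ones_like(t)
    if path is not None:
        write_envelope(path, t, a)
    return t, a
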