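"""Translational dynamics of a bubble pressing into a viscoelastic cell layer.

The bubble centroid displacement x(t) (positive towards the substrate) obeys
the force balance

    m x'' = F_B1 + F_B2 + F_AM + F_VD + F_CR

with the primary Bjerknes force from the travelling ultrasound wave, the
secondary Bjerknes force from the rigid substrate behind the cell (mirror
bubble of potential-flow theory), an added-mass force, quasi-steady viscous
drag, and the resistive force of the cell layer modelled as a single
spring-pot (fractional viscoelastic element): the stress is proportional to
the Caputo fractional derivative of the compressive strain eps = x/L of
order beta in (0, 1), discretized with the L1 scheme on a uniform grid.

The added-mass force is implemented as the time derivative of the
added-mass momentum, F_AM = -d/dt[(1/2) rho_l V x'] =
-(1/2) rho_l (V' x' + V x''), which is dimensionally consistent; the
displacement-based variant -(1/2) rho_l (V' x + V x') is kept behind a
flag for comparison.  The Basset history force is neglected, which is
justified at the translational Reynolds numbers of these experiments
(time-averaged Re of order 1-10).  Gravity/buoyancy is likewise neglected
on the 20-us pulse time scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn

from .acoustics import Medium, UltrasoundPulse, evaluate_pulse
from .radial_dynamics import RadialSolution

__all__ = [
    "CellLayer",
    "TranslationSolution",
    "ForceBreakdown",
    "caputo_l1",
    "drag_coefficient",
    "solve_translation",
    "GeometricContactError",
]

#: Gas density used for the (near-vanishing) bubble mass, kg m^-3.
RHO_GAS = 10.0


class GeometricContactError(RuntimeError):
    """Bubble centroid reached the substrate plane (x >= L)."""


@dataclass(frozen=True)
class CellLayer:
    """Fractional-viscoelastic (spring-pot) cell layer.

    L : initial layer thickness (m); ~12 um for an endothelial cell.
    beta : fractional order in (0, 1); 0 -> spring, 1 -> dashpot.  The
        default 0.8 targets the high-deformation-rate branch of cell
        microrheology.
    c_beta : spring-pot coefficient (Pa s^beta), default 1.
    """

    L: float = 12.0e-6
    beta: float = 0.8
    c_beta: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.beta < 1.0:
            raise ValueError("fractional order beta must lie in (0, 1)")
        if self.L <= 0 or self.c_beta <= 0:
            raise ValueError("L and c_beta must be positive")


@dataclass
class ForceBreakdown:
    """Per-term force time series (N), signed along the substrate normal."""

    F_I: np.ndarray
    F_B1: np.ndarray
    F_B2: np.ndarray
    F_AM: np.ndarray
    F_VD: np.ndarray
    F_CR: np.ndarray
    m: np.ndarray
    Re: np.ndarray
    U_ratio: np.ndarray

    def residual(self) -> np.ndarray:
        """Force-balance residual F_I - (F_B1+F_B2+F_AM+F_VD+F_CR)."""
        return self.F_I - (self.F_B1 + self.F_B2 + self.F_AM + self.F_VD + self.F_CR)


@dataclass
class TranslationSolution:
    """Centroid trajectory, strain and force breakdown on a uniform grid."""

    t: np.ndarray
    x: np.ndarray
    xdot: np.ndarray
    xddot: np.ndarray
    L: float
    forces: ForceBreakdown = field(repr=False)
    ultimate_compression: bool = False
    Re_avg: float = 0.0
    URe_avg: float = 0.0

    @property
    def eps(self) -> np.ndarray:
        """Compressive strain of the cell layer, x/L."""
        return self.x / self.L

    def to_frame(self) -> pd.DataFrame:
        f = self.forces
        return pd.DataFrame(
            {
                "t_s": self.t,
                "x_m": self.x,
                "xdot_m_s": self.xdot,
                "eps": self.eps,
                "F_I_N": f.F_I,
                "F_B1_N": f.F_B1,
                "F_B2_N": f.F_B2,
                "F_AM_N": f.F_AM,
                "F_VD_N": f.F_VD,
                "F_CR_N": f.F_CR,
            }
        )


def caputo_l1(eps_samples: np.ndarray, beta: float, tau: float) -> np.ndarray:
    """Caputo fractional derivative of order beta on a uniform grid (L1 scheme).

    D^beta eps(t_k) = tau^-beta / Gamma(2-beta) * sum_{j=1..k}
    b_{k-j} (eps_j - eps_{j-1}),  b_i = (i+1)^(1-beta) - i^(1-beta).

    The scheme converges at order tau^(2-beta) for smooth inputs.  The
    output has the same length as the input, with a zero first entry.
    """
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must lie in (0, 1)")
    if tau <= 0:
        raise ValueError("step tau must be positive")
    eps_samples = np.asarray(eps_samples, dtype=float)
    if eps_samples.ndim != 1:
        raise ValueError("eps_samples must be one-dimensional")
    n = eps_samples.size
    if n < 2:
        return np.zeros(n)
    i = np.arange(n, dtype=float)
    b = (i + 1.0) ** (1.0 - beta) - i ** (1.0 - beta)
    d_eps = np.diff(eps_samples)
    conv = np.convolve(d_eps, b)[: n - 1]
    out = np.empty(n)
    out[0] = 0.0
    out[1:] = conv * tau ** (-beta) / gamma_fn(2.0 - beta)
    return out


def drag_coefficient(Re):
    """Drag coefficient C_D = 24/Re + 6/(1 + sqrt(Re)) + 0.4.

    Valid for Re > 0; strictly decreasing, with the Stokes asymptote
    24/Re at small Re and the constant 0.4 at large Re.
    """
    Re = np.asarray(Re, dtype=float)
    if np.any(Re <= 0):
        raise ValueError("Reynolds number must be positive")
    return 24.0 / Re + 6.0 / (1.0 + np.sqrt(Re)) + 0.4


def _drag_force(R, xdot, medium: Medium):
    """F_VD = -1/2 rho_l pi R^2 xdot |xdot| C_D, with the Stokes linear
    limit used below a tiny Reynolds cutoff so the Re -> 0 singularity of
    C_D cancels analytically."""
    Re = 2.0 * medium.rho_l * R * abs(xdot) / medium.mu_l
    if Re < 1e-12:
        return -6.0 * np.pi * medium.mu_l * R * xdot
    cd = 24.0 / Re + 6.0 / (1.0 + math.sqrt(Re)) + 0.4
    return -0.5 * medium.rho_l * np.pi * R**2 * xdot * abs(xdot) * cd


def solve_translation(
    R_sol: RadialSolution,
    pulse: UltrasoundPulse | None = None,
    medium: Medium | None = None,
    cell: CellLayer | None = None,
    as_printed_added_mass: bool = False,
    stop_at_contact: bool = True,
) -> TranslationSolution:
    """Integrate the translational force balance on the radial solution grid.

    The radial solution must be on a uniform grid (it defines the fixed
    step tau of the L1 memory scheme; 200 samples per carrier period by
    default upstream).  A second-order predictor-corrector (Heun) step is
    used, with the fractional memory term evaluated on the full history at
    every stage.  Terms proportional to x'' (bubble inertia and added
    mass) are collected on the left-hand side before inversion.

    If the centroid reaches the substrate plane (x >= L, the
    transendothelial-tunnel scenario) the run stops and the solution is
    flagged ``ultimate_compression`` (or raises
    :class:`GeometricContactError` when ``stop_at_contact=False``).

    Returns
    -------
    TranslationSolution
        With per-force breakdown and time-averaged diagnostics Re_avg and
        URe_avg (plain time averages over the pulse window of the
        |xdot|-based translational Reynolds number and of U * Re with
        U = Rdot/xdot).
    """
    pulse = pulse or R_sol.pulse
    medium = medium or R_sol.medium
    cell = cell or CellLayer()

    t = R_sol.t
    tau = R_sol.dt
    if not np.allclose(np.diff(t), tau, rtol=1e-6):
        raise ValueError("radial solution must be on a uniform time grid")
    n = t.size
    R = R_sol.R
    Rdot = R_sol.Rdot
    V = R_sol.V
    Vdot = R_sol.Vdot
    Vddot = R_sol.Vddot
    _, grad_us = evaluate_pulse(pulse, medium, t)

    rho = medium.rho_l
    L = cell.L
    beta = cell.beta
    cb = cell.c_beta
    pref = tau ** (-beta) / gamma_fn(2.0 - beta)
    i = np.arange(n, dtype=float)
    b_w = (i + 1.0) ** (1.0 - beta) - i ** (1.0 - beta)

    x = np.zeros(n)
    xdot = np.zeros(n)
    xddot = np.zeros(n)
    d_eps = np.zeros(n)  # strain increments eps_j - eps_{j-1}

    F_I = np.zeros(n)
    F_B1 = np.zeros(n)
    F_B2 = np.zeros(n)
    F_AM = np.zeros(n)
    F_VD = np.zeros(n)
    F_CR = np.zeros(n)
    m_arr = RHO_GAS * V
    Re_arr = np.zeros(n)
    U_arr = np.zeros(n)

    def caputo_at(k: int, inc_k: float) -> float:
        """L1 fractional derivative at step k with current increment inc_k."""
        if k == 0:
            return 0.0
        hist = float(np.dot(b_w[1:k], d_eps[k - 1 : 0 : -1])) if k > 1 else 0.0
        return pref * (inc_k + hist)

    def accel(k: int, xk: float, vk: float, dcap: float) -> tuple:
        """x'' and explicit force terms at grid index k."""
        gap = L - xk
        if gap <= 0:
            raise GeometricContactError(
                f"centroid reached the substrate at t = {t[k]:.3e} s"
            )
        fb1 = -V[k] * grad_us[k]
        fb2 = -rho * V[k] * Vddot[k] / (16.0 * np.pi * gap**2)
        fvd = _drag_force(R[k], vk, medium)
        fcr = -np.pi * R[k] ** 2 * cb * dcap
        if as_printed_added_mass:
            fam_expl = -0.5 * rho * (Vdot[k] * xk + V[k] * vk)
            am_coeff = 0.0
        else:
            fam_expl = -0.5 * rho * Vdot[k] * vk
            am_coeff = 0.5 * rho * V[k]
        m_eff = m_arr[k] + am_coeff
        a = (fb1 + fb2 + fam_expl + fvd + fcr) / m_eff
        return a, fb1, fb2, fam_expl, fvd, fcr, am_coeff

    contact = False
    k_stop = n - 1
    try:
        # forces at t=0 (bubble at rest)
        a0, fb1, fb2, fam, fvd, fcr, amc = accel(0, 0.0, 0.0, 0.0)
        xddot[0] = a0
        F_B1[0], F_B2[0], F_VD[0], F_CR[0] = fb1, fb2, fvd, fcr
        F_AM[0] = fam - amc * a0
        F_I[0] = m_arr[0] * a0
        for k in range(1, n):
            xp, vp = x[k - 1], xdot[k - 1]
            # predictor (explicit Euler) using the previous-step derivative
            a1 = xddot[k - 1]
            x_pred = xp + tau * vp
            v_pred = vp + tau * a1
            inc_pred = (x_pred - xp) / L
            dcap_pred = caputo_at(k, inc_pred)
            a2, *_ = accel(k, x_pred, v_pred, dcap_pred)
            # corrector (trapezoidal)
            x[k] = xp + 0.5 * tau * (vp + v_pred)
            xdot[k] = vp + 0.5 * tau * (a1 + a2)
            d_eps[k] = (x[k] - x[k - 1]) / L
            dcap = caputo_at(k, d_eps[k])
            a_k, fb1, fb2, fam, fvd, fcr, amc = accel(k, x[k], xdot[k], dcap)
            xddot[k] = a_k
            F_B1[k], F_B2[k], F_VD[k], F_CR[k] = fb1, fb2, fvd, fcr
            F_AM[k] = fam - amc * a_k
            F_I[k] = m_arr[k] * a_k
            Re_arr[k] = 2.0 * rho * R[k] * abs(xdot[k]) / medium.mu_l
            U_arr[k] = Rdot[k] / xdot[k] if xdot[k] != 0.0 else np.nan
    except GeometricContactError:
        contact = True
        k_stop = k - 1
        if not stop_at_contact:
            raise

    sl = slice(0, k_stop + 1)
    forces = ForceBreakdown(
        F_I=F_I[sl], F_B1=F_B1[sl], F_B2=F_B2[sl], F_AM=F_AM[sl],
        F_VD=F_VD[sl], F_CR=F_CR[sl], m=m_arr[sl], Re=Re_arr[sl],
        U_ratio=U_arr[sl],
    )
    in_pulse = t[sl] <= pulse.duration
    Re_avg = float(np.mean(Re_arr[sl][in_pulse])) if np.any(in_pulse) else 0.0
    with np.errstate(invalid="ignore"):
        ure = np.abs(U_arr[sl][in_pulse] * Re_arr[sl][in_pulse])
    URe_avg = float(np.nanmean(ure)) if np.any(in_pulse) else 0.0
    return TranslationSolution(
        t=t[sl], x=x[sl], xdot=xdot[sl], xddot=xddot[sl], L=L,
        forces=forces, ultimate_compression=contact,
        Re_avg=Re_avg, URe_avg=URe_avg,
    )
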