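"""Kelvin impulse, Rayleigh prefactor and the anisotropy-parameter chain."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.special import beta as beta_fn

from sonojet.acoustics import Medium, build_pulse
from sonojet.impulse import (
    equivalent_dp,
    kelvin_impulse,
    rayleigh_prefactor,
    zeta_per_cycle,
)
from sonojet.radial_dynamics import solve_radial


def rayleigh_growth_collapse(R0, dp, rho, n=20000, r_floor=1e-3):
    """Independent oracle: dimensionful vapour-bubble growth+collapse
    volume history under constant driving pressure jump dp.

    Integrates R R'' + 3/2 R'^2 = -dp/rho for the collapse from (R0, 0)
    and mirrors it in time for the growth phase.
    """
    def rhs(t, y):
        R, U = y
        return (U, -(1.5 * U * U + dp / rho) / R)

    def floor_ev(t, y):
        return y[0] - r_floor * R0

    floor_ev.terminal = True
    floor_ev.direction = -1
    t_c = 0.915 * R0 * math.sqrt(rho / dp)
    sol = solve_ivp(rhs, (0.0, 2.0 * t_c), (R0, 0.0), method="Radau",
                    rtol=1e-10, atol=1e-14 * R0, dense_output=True,
                    events=floor_ev)
    t_half = sol.t_events[0][0]
    th = np.linspace(0.0, t_half, n // 2)
    Rh = sol.sol(th)[0]
    t = np.concatenate([th, t_half + th[1:]])
    R = np.concatenate([Rh[::-1], Rh[1:]])  # growth is the time mirror
    return t, (4.0 / 3.0) * np.pi * R**3


class TestRayleighPrefactor:
    def test_printed_value(self):
        assert rayleigh_prefactor() == pytest.approx(4.789, abs=0.005)

    def test_collapse_half(self):
        assert rayleigh_prefactor("collapse") == pytest.approx(2.394, abs=0.003)

    def test_beta_function_closed_form(self):
        exact = 2.0 * (4.0 / 3.0) * math.pi * math.sqrt(1.5) * (1.0 / 3.0) \
            * beta_fn(11.0 / 6.0, 0.5)
        assert rayleigh_prefactor() == pytest.approx(exact, rel=1e-6)


class TestKelvinImpulse:
    def test_zero_gradient(self):
        t = np.linspace(0, 1e-6, 500)
        assert kelvin_impulse(t, np.full_like(t, 1e-16), np.zeros_like(t)) == 0.0

    def test_constant_volume_full_period(self):
        t = np.linspace(0.0, 1.0e-6, 20001)
        grad = np.sin(2 * np.pi * 1e6 * t)
        I = kelvin_impulse(t, np.full_like(t, 1e-16), grad)
        assert abs(I) < 1e-26

    def test_window_outside_data_raises(self):
        t = np.linspace(0, 1e-6, 100)
        with pytest.raises(ValueError):
            kelvin_impulse(t, np.ones_like(t), np.ones_like(t),
                           window=(0.5e-6, 2e-6))

    def test_vapour_collapse_matches_closed_form(self, medium):
        """Quadrature of -int V grad dt over a Rayleigh growth+collapse
        reproduces the 4.789 R0^4 grad sqrt(rho/dp) closed form."""
        R0, dp = 100.0e-6, 99.0e3
        t, V = rayleigh_growth_collapse(R0, dp, medium.rho_l)
        grad = medium.rho_l * 9.81  # gravity-like constant gradient
        I = kelvin_impulse(t, V, np.full_like(t, grad))
        expected = -4.789 * R0**4 * grad * math.sqrt(medium.rho_l / dp)
        assert I == pytest.approx(expected, rel=5e-3)


class TestEquivalentDpAndZeta:
    def test_dp_recovery_and_zeta_chain(self, medium):
        """Full chain: virtual impulse -> dp_bar -> zeta reproduces the
        definitional zeta = -grad p R0/dp within 1% for the constant-dp
        vapour collapse."""
        R0, dp = 50.0e-6, 101.0e3 - 2.33e3
        t, V = rayleigh_growth_collapse(R0, dp, medium.rho_l)
        I_hat = kelvin_impulse(t, V, np.ones_like(V))
        dp_rec = equivalent_dp(R0, abs(I_hat), medium)
        assert dp_rec == pytest.approx(dp, rel=0.01)
        grad = medium.rho_l * 9.81
        I = kelvin_impulse(t, V, np.full_like(t, grad))
        C = rayleigh_prefactor()
        zeta = I / (C * R0**3 * math.sqrt(medium.rho_l * dp_rec))
        assert zeta == pytest.approx(-grad * R0 / dp, rel=0.01)

    def test_r0_power_law(self, medium):
        assert equivalent_dp(2.0e-6, 1e-15, medium) == pytest.approx(
            256.0 * equivalent_dp(1.0e-6, 1e-15, medium))

    def test_zero_virtual_impulse_raises(self, medium):
        with pytest.raises(ValueError):
            equivalent_dp(1e-6, 0.0, medium)

    @pytest.mark.parametrize("s", [0.5, 2.0, 7.0])
    def test_zeta_chain_dimensionless_across_scales(self, s, medium):
        """The impulse-chain zeta reproduces the definitional
        zeta = -grad p R0/dp at every joint rescaling R -> sR, t -> st of
        the vapour-collapse input (their ratio is scale invariant)."""
        R0, dp, grad = 80.0e-6, 97.0e3, 5.0e3
        t, V = rayleigh_growth_collapse(R0, dp, medium.rho_l, n=8000)

        def chain_over_definition(ts, Vs, R0s):
            I = kelvin_impulse(ts, Vs, np.full_like(ts, grad))
            Ih = kelvin_impulse(ts, Vs, np.ones_like(ts))
            dpb = equivalent_dp(R0s, abs(Ih), medium)
            zeta = I / (rayleigh_prefactor() * R0s**3
                        * math.sqrt(medium.rho_l * dpb))
            return zeta / (-grad * R0s / dp)

        r1 = chain_over_definition(t, V, R0)
        r2 = chain_over_definition(s * t, s**3 * V, s * R0)
        assert r1 == pytest.approx(1.0, rel=0.01)
        assert r2 == pytest.approx(r1, rel=1e-6)


class TestZetaPerCycle:
    def test_zero_driving_gives_zero_zeta(self, bubble, shell, medium, cell):
        pulse = build_pulse(1.0e6, 0.0, 4)
        sol = solve_radial(pulse, bubble, shell, medium, t_end=pulse.duration)
        cycles = zeta_per_cycle(sol, None, pulse, medium, cell)
        assert len(cycles) == 4
        for c in cycles:
            assert abs(c.zeta_us) < 1e-12
            assert abs(c.zeta_sub) < 1e-9
            assert c.dp_bar > 0.0

    def test_decomposition_sums_and_ratio_growth(self, sol_high, tr_high,
                                                 pulse_high, medium, cell):
        cycles = zeta_per_cycle(sol_high, tr_high, pulse_high, medium, cell)
        assert len(cycles) >= 5
        for c in cycles:
            assert c.I_total == pytest.approx(c.I_us + c.I_sub)
            assert c.dp_bar > 0.0
            assert np.isfinite(c.zeta_total)
        # substrate dominance grows as the bubble approaches the substrate
        ratios = [c.ratio_sub_us for c in cycles[2:]]
        assert np.all(np.diff(ratios) > 0)

    def test_analytic_quadrature_refinement(self):
        """kelvin_impulse converges to the exact integral under grid
        doubling (analytic volume and gradient histories)."""
        w = 2 * np.pi * 1.0e6
        window = (0.1e-6, 0.83e-6)  # partial cycle: no periodic cancellation
        vals = []
        for n in (201, 401, 80001):
            t = np.linspace(0.0, 1.0e-6, n)
            V = 1e-16 * (1.0 + 0.4 * np.sin(w * t + 0.7)) ** 3
            grad = 1e9 * np.cos(w * t)
            vals.append(kelvin_impulse(t, V, grad, window=window))
        exact = vals[-1]
        assert vals[1] == pytest.approx(exact, rel=1e-3)
        # ~4x error reduction per doubling (second-order quadrature)
        assert abs(vals[1] - exact) < 0.35 * abs(vals[0] - exact)

    def test_per_cycle_impulse_grid_refinement(self, bubble, shell, medium,
                                               cell):
        """Doubling the sampling rate leaves the per-cycle impulses
        unchanged to 0.1% wherever the collapse is resolved (at most the
        single sharpest-collapse cycle may exceed it)."""
        pulse = build_pulse(1.0e6, 60.0e3, 6, ramp_cycles=0.0)
        vals = []
        for spc in (200, 400):
            sol = solve_radial(pulse, bubble, shell, medium,
                               t_end=pulse.duration, samples_per_cycle=spc)
            cycles = zeta_per_cycle(sol, None, pulse, medium, cell)
            vals.append(np.array([c.I_sub for c in cycles[1:]]))
        rel = np.abs(vals[0] - vals[1]) / np.abs(vals[1])
        assert np.sum(rel < 1e-3) >= rel.size - 1
        assert rel.max() < 0.03
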