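"""Stress-mechanism channels, jet-contact geometry and the peak table."""

import numpy as np
import pytest

from sonojet.acoustics import Medium, build_pulse
from sonojet.radial_dynamics import BubbleParams, RadialSolution, solve_radial
from sonojet.stress import (
    JetParams,
    bjerknes_pressures,
    boundary_layer_thickness,
    flow_stresses,
    jet_stresses,
    stress_report,
)


class TestJetStresses:
    def test_reference_values(self, medium):
        js = jet_stresses(JetParams(u_jet=60.0, R_jet=0.75e-6), medium)
        # water hammer 1/2 rho c u and stagnation 1/2 rho u^2
        assert js["p_jet"] == pytest.approx(44.4e6, rel=0.01)
        assert js["p_stag"] == pytest.approx(1.80e6, rel=0.01)

    def test_contact_geometry_consistency(self, medium):
        # rho_contact = 30 nm implies varsigma = rho_contact / c ~ 20 ps
        R_jet = 30.0e-9 * medium.c_l / 60.0
        js = jet_stresses(JetParams(u_jet=60.0, R_jet=R_jet), medium)
        assert js["rho_contact"] == pytest.approx(30.0e-9, rel=1e-12)
        assert js["varsigma"] == pytest.approx(js["rho_contact"] / medium.c_l)
        assert js["varsigma"] == pytest.approx(20.0e-12, rel=0.02)

    def test_zero_jet_speed(self, medium):
        js = jet_stresses(JetParams(u_jet=0.0, R_jet=1e-6), medium)
        assert all(v == 0.0 for v in js.values())

    def test_hammer_exceeds_stagnation_below_sonic(self, medium):
        for u in (1.0, 60.0, 500.0):
            js = jet_stresses(JetParams(u_jet=u, R_jet=1e-6), medium)
            assert js["p_jet"] > js["p_stag"]


def _synthetic_radial(medium, pulse, R0=3.0e-6, amp=0.0, f=1.0e6):
    """Analytic radius history R = R0 (1 + amp sin wt) for channel checks."""
    t = np.linspace(0.0, 20.0e-6, 4001)
    w = 2 * np.pi * f
    R = R0 * (1.0 + amp * np.sin(w * t))
    Rdot = R0 * amp * w * np.cos(w * t)
    Rddot = -R0 * amp * w**2 * np.sin(w * t)
    return RadialSolution(t=t, R=R, Rdot=Rdot, Rddot=Rddot,
                          bubble=BubbleParams(R0=R0), medium=medium,
                          pulse=pulse)


class TestFlowStresses:
    def test_boundary_layer_thickness(self, medium):
        pulse = build_pulse(1.0e6, 0.0, 20)
        delta = boundary_layer_thickness(medium, pulse.omega)
        assert delta == pytest.approx(0.565e-6, rel=0.01)

    def test_streaming_stress_magnitude(self, medium):
        pulse = build_pulse(1.0e6, 0.0, 20)
        sol = _synthetic_radial(medium, pulse)
        fs = flow_stresses(sol, pulse, medium, u_stream=0.1)
        # ~1.8e2 Pa: "below a few hundreds of pascals"
        assert fs["tau_stream"] == pytest.approx(1.8e2, rel=0.02)

    def test_static_wall_produces_no_stress(self, medium):
        pulse = build_pulse(1.0e6, 0.0, 20)
        sol = _synthetic_radial(medium, pulse, amp=0.0)
        fs = flow_stresses(sol, pulse, medium, u_stream=0.0)
        assert np.allclose(fs["p_impact"], 0.0)
        assert np.allclose(fs["tau_shear"], 0.0)
        assert fs["tau_stream"] == 0.0

    def test_impact_pressure_signed_square(self, medium):
        pulse = build_pulse(1.0e6, 0.0, 20)
        sol = _synthetic_radial(medium, pulse, amp=0.1)
        fs = flow_stresses(sol, pulse, medium, frame_rate=None)
        np.testing.assert_allclose(
            fs["p_impact"], 0.5 * medium.rho_l * np.abs(sol.Rdot) * sol.Rdot,
            rtol=1e-12)

    def test_density_scaling(self):
        """Normal-stress channels scale with rho, shear channels with
        sqrt(rho) (through the boundary layer)."""
        pulse = build_pulse(1.0e6, 0.0, 20)
        m1 = Medium(rho_l=998.0)
        m2 = Medium(rho_l=4 * 998.0)
        js1 = jet_stresses(JetParams(), m1)
        js2 = jet_stresses(JetParams(), m2)
        assert js2["p_jet"] == pytest.approx(4 * js1["p_jet"])
        assert js2["p_stag"] == pytest.approx(4 * js1["p_stag"])
        s1 = _synthetic_radial(m1, pulse, amp=0.1)
        s2 = _synthetic_radial(m2, pulse, amp=0.1)
        f1 = flow_stresses(s1, pulse, m1, frame_rate=None)
        f2 = flow_stresses(s2, pulse, m2, frame_rate=None)
        assert f2["tau_stream"] == pytest.approx(2 * f1["tau_stream"])
        np.testing.assert_allclose(f2["tau_shear"], 2 * f1["tau_shear"],
                                   rtol=1e-12)


class TestBjerknesPressures:
    def test_inverse_square_distance(self, medium):
        pulse = build_pulse(1.0e6, 0.0, 20)
        sol = _synthetic_radial(medium, pulse, amp=0.1)
        b1 = bjerknes_pressures(sol, pulse, medium, h=4.5e-6, frame_rate=None)
        b2 = bjerknes_pressures(sol, pulse, medium, h=9.0e-6, frame_rate=None)
        np.testing.assert_allclose(b1["p_B2"], 4 * b2["p_B2"], rtol=1e-12)

    def test_rebound_pushes_away_from_substrate(self, medium):
        """Vddot > 0 (rebound) gives p_B2 < 0, directed away from the
        substrate, matching the mirror-bubble sign convention."""
        pulse = build_pulse(1.0e6, 0.0, 20)
        t = np.linspace(0.0, 1.0e-6, 501)
        R = 3.0e-6 + 0.5e-6 * (t / t[-1]) ** 2  # accelerating expansion
        Rdot = np.gradient(R, t)
        Rddot = np.gradient(Rdot, t)
        sol = RadialSolution(t=t, R=R, Rdot=Rdot, Rddot=Rddot,
                             bubble=BubbleParams(), medium=medium, pulse=pulse)
        assert np.all(sol.Vddot[10:] > 0)
        bj = bjerknes_pressures(sol, pulse, medium, h=9.0e-6, frame_rate=None)
        assert np.all(bj["p_B2"][10:] < 0)

    def test_zero_gradient_zero_primary(self, medium):
        pulse = build_pulse(1.0e6, 0.0, 20)
        sol = _synthetic_radial(medium, pulse, amp=0.1)
        bj = bjerknes_pressures(sol, pulse, medium, h=9.0e-6)
        assert np.allclose(bj["p_B1"], 0.0)

    def test_nonpositive_distance_raises(self, medium):
        pulse = build_pulse(1.0e6, 0.0, 20)
        sol = _synthetic_radial(medium, pulse, amp=0.1)
        with pytest.raises(ValueError):
            bjerknes_pressures(sol, pulse, medium, h=0.0)


class TestStressReport:
    def test_successful_sonoporation_case(self, sol_high, tr_high,
                                          pulse_high, medium):
        """Jet hammer dominates every other mechanism >= 30-fold and the
        stagnation pressure exceeds the wall-impact peak >= 4-fold."""
        series, table = stress_report(sol_high, tr_high, pulse_high, medium,
                                      JetParams.for_bubble(3.0e-6))
        assert table["n_jets"] > 0
        assert table["jet_dominance"] >= 30.0
        assert table["stag_over_impact"] >= 4.0
        peaks = table["peaks"]
        assert peaks["p_jet"] > peaks["p_stag"] > peaks["p_impact"]
        assert series.varsigma == pytest.approx(
            series.rho_contact / medium.c_l)

    def test_zero_driving_only_streaming(self, bubble, shell, medium, cell):
        pulse = build_pulse(1.0e6, 0.0, 20)
        sol = solve_radial(pulse, bubble, shell, medium)
        series, table = stress_report(sol, None, pulse, medium,
                                      JetParams(), u_stream=0.1)
        assert table["n_jets"] == 0
        assert table["peaks"]["p_jet"] == 0.0
        assert table["peaks"]["p_impact"] < 1.0  # numerically quiescent
        assert table["peaks"]["tau_stream"] == pytest.approx(1.8e2, rel=0.02)
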