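"""Shared fixtures: default physical setup and the (expensive) coupled
solutions of the paired case-study amplitudes, solved once per session."""

import numpy as np
import pytest

from sonojet.acoustics import Medium, build_pulse
from sonojet.radial_dynamics import BubbleParams, ShellParams, solve_radial
from sonojet.translation_dynamics import CellLayer, solve_translation


@pytest.fixture(scope="session")
def medium():
    return Medium()


@pytest.fixture(scope="session")
def shell():
    return ShellParams()


@pytest.fixture(scope="session")
def bubble():
    return BubbleParams()


@pytest.fixture(scope="session")
def cell():
    return CellLayer()


@pytest.fixture(scope="session")
def pulse_low():
    return build_pulse(1.0e6, 60.0e3, 20)


@pytest.fixture(scope="session")
def pulse_high():
    return build_pulse(1.0e6, 160.0e3, 20)


@pytest.fixture(scope="session")
def sol_low(pulse_low, bubble, shell, medium):
    return solve_radial(pulse_low, bubble, shell, medium)


@pytest.fixture(scope="session")
def sol_high(pulse_high, bubble, shell, medium):
    return solve_radial(pulse_high, bubble, shell, medium)


@pytest.fixture(scope="session")
def tr_low(sol_low, pulse_low, medium, cell):
    return solve_translation(sol_low, pulse_low, medium, cell)


@pytest.fixture(scope="session")
def tr_high(sol_high, pulse_high, medium, cell):
    return solve_translation(sol_high, pulse_high, medium, cell)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
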