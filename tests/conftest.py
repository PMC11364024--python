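"""Shared fixtures for the secswaxs test suite."""

import numpy as np
import pytest
from hypothesis import settings

from secswaxs.composition import SolutionConditions
from secswaxs.species_data import builtin_species

# Deterministic, CI-friendly hypothesis profile.
settings.register_profile("ci", deadline=None, max_examples=40,
                          derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def serf():
    return builtin_species("SERF1a")


@pytest.fixture(scope="session")
def nt17():
    return builtin_species("NT17")


@pytest.fixture(scope="session")
def htt3():
    return builtin_species("Htt-3")


@pytest.fixture(scope="session")
def cond():
    return SolutionConditions()


@pytest.fixture()
def exact_guinier_curve():
    """Noiseless curve that obeys the Guinier law exactly everywhere."""
    from secswaxs.curves import ScatteringCurve
    q = np.linspace(0.008, 0.3, 200)
    Rg, I0 = 25.0, 1.3e-3
    return ScatteringCurve(q, I0 * np.exp(-(q * Rg) ** 2 / 3.0),
                           np.zeros_like(q)), Rg, I0


def sphere_curve(R=30.0, qmax=0.3, n=200, sigma_rel=0.0, seed=0):
    from secswaxs.curves import ScatteringCurve
    q = np.linspace(0.008, qmax, n)
    x = q * R
    P = (3.0 * (np.sin(x) - x * np.cos(x)) / x ** 3) ** 2
    sigma = sigma_rel * P
    I = P.copy()
    if sigma_rel > 0:
        I = I + np.random.default_rng(seed).normal(0.0, sigma)
    return ScatteringCurve(q, I, sigma)
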