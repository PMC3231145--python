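"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import pytest
from hypothesis import HealthCheck, settings
from scipy.integrate import quad

from photonbudget.calibration import OpticalTrain
from photonbudget.fixtures import build_train

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def quadrature_circle_strip_area(radius: float, half_width: float) -> float:
    """Independent 1-D quadrature oracle for area(circle & |x| <= a).

    Integrates the chord length 2*sqrt(r^2 - x^2) over the strip, without
    using the package's closed form.
    """
    a = min(half_width, radius)
    val, _ = quad(lambda x: 2.0 * math.sqrt(max(0.0, radius**2 - x**2)), -a, a)
    return val


@pytest.fixture
def lens_channel_sipm() -> OpticalTrain:
    """Lens-coupled microchannel with the SiPM: the workhorse train."""
    return build_train("lens", "microchannel", "blue10", "sipm")


@pytest.fixture
def linear_sipm_train() -> OpticalTrain:
    """The same train with the optically-thin (strictly linear) sample model."""
    train = build_train("lens", "microchannel", "blue10", "sipm")
    return train.model_copy(update={"thin_approximation": True})


@pytest.fixture
def coaxial_train() -> OpticalTrain:
    return build_train("fiber", "coaxial", "blue10", "sipm")
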