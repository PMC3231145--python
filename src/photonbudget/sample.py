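"""Absorption and fluorescence physics in the analyte volume.

Beer-Lambert attenuation is written base-e throughout, ``P_T = P_c *
exp(-eps*C*l)`` with the molar absorption coefficient eps in
L mol^-1 cm^-1, concentration C in mol/L and path length l in cm.  Datasheet
(decadic) coefficients can be converted by setting ``decadic=True`` on the
analyte, which multiplies eps by ln(10) internally.

Fluorescence is isotropic: absorbed photons times the quantum yield, emitted
into 4 pi steradians.  For fibers coupled coaxially into the ends of a
microchannel the excitation decays along the channel while the capture solid
angle of the collection fiber grows toward the exit, so the response requires
a single integration over the channel length; this is done by trapezoidal
quadrature on a uniform axial grid.
"""

from __future__ import annotations

import math
from typing import Literal, Optional, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .coupling import FiberSpec, fiber_capture_fraction
from .exceptions import InvalidParameterError, ResolutionError

__all__ = [
    "AVOGADRO",
    "AnalyteSpec",
    "SampleSpec",
    "transmitted_photons",
    "absorbed_photons",
    "fluorescence_rate",
    "coaxial_channel_response",
    "molecule_count",
]

#: Avogadro's number, molecules per mole.
AVOGADRO = 6.022e23


class AnalyteSpec(BaseModel):
    """Photophysics of the analyte.

    ``epsilon`` is the molar absorption coefficient in L mol^-1 cm^-1,
    interpreted base-e by default; set ``decadic=True`` for a conventional
    base-10 datasheet value (converted by ln 10).  ``quantum_yield`` is the
    fluorescence quantum yield in [0, 1].
    """

    model_config = ConfigDict(extra="forbid")

    name: str = "analyte"
    epsilon: float = Field(ge=0.0)
    quantum_yield: float = Field(ge=0.0, le=1.0)
    decadic: bool = False

    @property
    def epsilon_base_e(self) -> float:
        """Base-e molar absorption coefficient, L mol^-1 cm^-1."""
        return self.epsilon * math.log(10.0) if self.decadic else self.epsilon


class SampleSpec(BaseModel):
    """Geometry of the analyte volume plus its photophysics.

    A ``microchannel`` is a rectangular channel (width x depth cross-section,
    the given length along the flow axis); a ``thin_film`` is a uniform layer
    (thickness, lateral extent ``film_area``).  All lengths cm, areas cm^2.
    """

    model_config = ConfigDict(extra="forbid")

    kind: Literal["microchannel", "thin_film"]
    width: Optional[float] = Field(default=None, gt=0.0)
    depth: Optional[float] = Field(default=None, gt=0.0)
    length: Optional[float] = Field(default=None, gt=0.0)
    thickness: Optional[float] = Field(default=None, gt=0.0)
    film_area: Optional[float] = Field(default=None, gt=0.0)
    analyte: AnalyteSpec

    @model_validator(mode="after")
    def _check_geometry(self) -> "SampleSpec":
        if self.kind == "microchannel":
            missing = [
                f for f in ("width", "depth", "length") if getattr(self, f) is None
            ]
            if missing:
                raise ValueError(f"microchannel sample requires {missing}")
        else:
            missing = [
                f for f in ("thickness", "film_area") if getattr(self, f) is None
            ]
            if missing:
                raise ValueError(f"thin-film sample requires {missing}")
        return self

    def path_length(self, axis: Literal["normal", "cross", "axial"]) -> float:
        """Optical path length (cm) through the sample along an axis.

        ``normal``: illumination perpendicular to the chip plane (through the
        channel depth or film thickness); ``cross``: across the channel
        width; ``axial``: along the channel length.
        """
        if self.kind == "thin_film":
            if axis != "normal":
                raise InvalidParameterError(
                    "thin-film samples are only probed normal to the film"
                )
            return float(self.thickness)  # type: ignore[arg-type]
        if axis == "normal":
            return float(self.depth)  # type: ignore[arg-type]
        if axis == "cross":
            return float(self.width)  # type: ignore[arg-type]
        if axis == "axial":
            return float(self.length)  # type: ignore[arg-type]
        raise InvalidParameterError(f"unknown axis {axis!r}")

    @property
    def channel_volume_L(self) -> float:
        """Full geometric volume of the sample in litres (1 cm^3 = 1 mL)."""
        if self.kind == "microchannel":
            vol_cm3 = self.width * self.depth * self.length  # type: ignore
        else:
            vol_cm3 = self.thickness * self.film_area  # type: ignore
        return vol_cm3 * 1e-3


def transmitted_photons(
    p_c: float, analyte: AnalyteSpec, c: float, path: float
) -> float:
    """Photon rate transmitted through the sample, ``P_c * exp(-eps*C*l)``."""
    _check_nonneg(p_c=p_c, c=c, path=path)
    return p_c * math.exp(-analyte.epsilon_base_e * c * path)


def absorbed_photons(
    p_c: float,
    analyte: AnalyteSpec,
    c: float,
    path: float,
    mode: Literal["exact", "thin"] = "exact",
) -> float:
    """Photon rate absorbed in the sample.

    ``exact``: ``P_c * (1 - exp(-eps*C*l))``; ``thin``: the optically-thin
    linearisation ``P_c * eps*C*l``, valid for eps*C*l << 1 and always an
    upper bound on the exact value.
    """
    _check_nonneg(p_c=p_c, c=c, path=path)
    tau = analyte.epsilon_base_e * c * path
    if mode == "exact":
        return p_c * -math.expm1(-tau)
    if mode == "thin":
        return p_c * tau
    raise InvalidParameterError(f"unknown absorption mode {mode!r}")


def fluorescence_rate(p_abs: float, qy: float) -> float:
    """Fluorescent photon emission rate, absorbed rate times quantum yield."""
    if not 0.0 <= qy <= 1.0:
        raise InvalidParameterError(f"quantum yield must be in [0, 1], got {qy}")
    if p_abs < 0.0:
        raise InvalidParameterError("absorbed rate must be >= 0")
    return p_abs * qy


def coaxial_channel_response(
    p0: float,
    sample: SampleSpec,
    c: float,
    collect_fiber: FiberSpec,
    gap: float,
    n_slices: int = 1000,
) -> Tuple[float, float]:
    """Fluorescence captured by a coaxial collection fiber, and transmission.

    Excitation enters one end of a microchannel of length L and decays as
    ``p(x) = p0 * exp(-eps*C*x)``.  Each slice dx absorbs
    ``p(x) * eps*C * dx``, re-emits isotropically with the quantum yield, and
    the collection fiber at the far end (face set back by ``gap`` from the
    channel exit) captures the line-of-sight solid-angle fraction
    ``min(pi R_F^2, Omega_F d^2) / (4 pi d^2)`` with ``d = (L - x) + gap``.
    The axial integral is evaluated by the trapezoidal rule on ``n_slices``
    uniform slices.

    Returns ``(fluor_captured, transmitted)`` photon rates.  The captured
    rate saturates at high concentration (all absorption happens near the
    entrance, far from the fiber), which is what makes coaxial calibration
    curves non-linear at high C.
    """
    if sample.kind != "microchannel":
        raise InvalidParameterError("coaxial coupling requires a microchannel")
    if n_slices < 100:
        raise ResolutionError(
            f"n_slices={n_slices} is too coarse for the axial integral; "
            "use at least 100"
        )
    if gap <= 0.0:
        raise InvalidParameterError(f"fiber-channel gap must be > 0, got {gap}")
    _check_nonneg(p0=p0, c=c)

    length = sample.path_length("axial")
    eps = sample.analyte.epsilon_base_e
    qy = sample.analyte.quantum_yield
    x = np.linspace(0.0, length, n_slices + 1)
    d = (length - x) + gap
    omega_f = collect_fiber.solid_angle
    core_area = math.pi * collect_fiber.core_radius**2
    capture = np.minimum(core_area, omega_f * d**2) / (4.0 * math.pi * d**2)
    # emission density per unit length: p(x) * eps * C, times QY and capture
    integrand = p0 * np.exp(-eps * c * x) * eps * c * qy * capture
    captured = float(np.trapezoid(integrand, x))
    captured *= collect_fiber.transmission_efficiency
    transmitted = p0 * math.exp(-eps * c * length)
    return captured, transmitted


def molecule_count(c: float, volume: float) -> float:
    """Number of analyte molecules at molarity ``c`` in ``volume`` litres."""
    if volume <= 0.0:
        raise InvalidParameterError(f"volume must be > 0 L, got {volume}")
    if c < 0.0:
        raise InvalidParameterError("concentration must be >= 0")
    return c * volume * AVOGADRO


def _check_nonneg(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value < 0.0:
            raise InvalidParameterError(f"{name} must be >= 0, got {value}")
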