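"""Spectral filtering, detector conversion and analog amplification.

The tail of the photon budget: an interference filter passes a band-limited
fraction of the fluorescence line, the detector converts incident photons to
electrons (quantum efficiency times internal gain) or directly to current via
a responsivity, a transimpedance stage turns current into voltage, and an
optional analog amplifier scales the result.  The output voltage is hard-
clipped at the detector saturation.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .exceptions import ConfigurationError, InvalidParameterError
from .sources import PHOTONS_PER_WATT_NM

__all__ = [
    "ELECTRON_CHARGE",
    "FilterSpec",
    "DetectorSpec",
    "AmplifierSpec",
    "filter_transmission_factor",
    "detector_area_fraction",
    "electron_rate",
    "output_signal",
]

#: Elementary charge, coulombs.
ELECTRON_CHARGE = 1.602e-19


class FilterSpec(BaseModel):
    """A narrow-band interference filter in front of the detector.

    ``fwhm``: filter pass-band width (nm); ``transmission_efficiency``: peak
    in-band transmission; ``emission_bandwidth``: width (nm) of the
    fluorescence line (or transmitted band) reaching the filter.
    """

    model_config = ConfigDict(extra="forbid")

    fwhm: float = Field(gt=0.0)
    transmission_efficiency: float = Field(ge=0.0, le=1.0)
    emission_bandwidth: float = Field(gt=0.0)


class DetectorSpec(BaseModel):
    """A photodetector plus its electrical envelope.

    Either the electron path (``quantum_efficiency`` x ``gain`` ->
    electrons/s -> current -> ``transimpedance`` -> volts) or the
    responsivity path (``responsivity`` in A/W at gain 1, times ``gain`` and
    ``transimpedance``) can be used; ``noise_floor`` and ``saturation`` (both
    volts) bound the usable output.
    """

    model_config = ConfigDict(extra="forbid")

    name: str = "detector"
    active_area: float = Field(gt=0.0)
    quantum_efficiency: float = Field(gt=0.0, le=1.0)
    gain: float = Field(default=1.0, ge=1.0)
    responsivity: Optional[float] = Field(default=None, gt=0.0)
    transimpedance: Optional[float] = Field(default=None, gt=0.0)
    noise_floor: float = Field(gt=0.0)
    saturation: float = Field(gt=0.0)

    @model_validator(mode="after")
    def _check_range(self) -> "DetectorSpec":
        if self.noise_floor >= self.saturation:
            raise ValueError(
                f"noise floor ({self.noise_floor} V) must be below "
                f"saturation ({self.saturation} V)"
            )
        return self


class AmplifierSpec(BaseModel):
    """Analog post-detection amplification (dimensionless, >= 1)."""

    model_config = ConfigDict(extra="forbid")

    amplification: float = Field(default=1.0, ge=1.0)


def filter_transmission_factor(f: FilterSpec) -> float:
    """Fraction of the emission line passed by the filter.

    Band ratio ``fwhm / emission_bandwidth`` capped at 1 (a filter wider than
    the line passes all of it), times the peak transmission efficiency.
    """
    return min(1.0, f.fwhm / f.emission_bandwidth) * f.transmission_efficiency


def detector_area_fraction(active_area: float, exposed_area: float) -> float:
    """Fraction of photons in the detection plane striking the active area."""
    if exposed_area <= 0.0:
        raise InvalidParameterError(
            f"exposed area must be > 0, got {exposed_area}"
        )
    if active_area < 0.0:
        raise InvalidParameterError("active area must be >= 0")
    return min(1.0, active_area / exposed_area)


def electron_rate(p_d: float, det: DetectorSpec) -> float:
    """Electrons per second out of the detector, ``P_D * QE * G``."""
    if p_d < 0.0:
        raise InvalidParameterError("photon rate must be >= 0")
    return p_d * det.quantum_efficiency * det.gain


def output_signal(
    p_d: float,
    wavelength: float,
    det: DetectorSpec,
    amp: Optional[AmplifierSpec] = None,
    *,
    clip: bool = True,
) -> float:
    """Analog output voltage for a photon rate ``p_d`` at ``wavelength`` nm.

    Responsivity path (preferred when ``responsivity`` is set): the incident
    optical power is ``P_D / (5.03e15 * lambda)`` watts, converted to current
    by the responsivity (A/W at gain 1) times the gain, then to volts by the
    transimpedance.  Electron path otherwise: ``P_D * QE * G`` electrons/s
    times the elementary charge gives the current.  The amplifier scales the
    voltage; with ``clip=True`` the result is hard-limited at the detector
    saturation.
    """
    if p_d < 0.0:
        raise InvalidParameterError("photon rate must be >= 0")
    if wavelength <= 0.0:
        raise InvalidParameterError("wavelength must be > 0")
    amplification = amp.amplification if amp is not None else 1.0
    if det.transimpedance is None:
        raise ConfigurationError(
            f"detector {det.name!r} has no transimpedance; cannot convert "
            "current to volts"
        )
    if det.responsivity is not None:
        watts = p_d / (PHOTONS_PER_WATT_NM * wavelength)
        current = watts * det.responsivity * det.gain
    else:
        current = electron_rate(p_d, det) * ELECTRON_CHARGE
    volts = current * det.transimpedance * amplification
    if clip:
        volts = min(volts, det.saturation)
    return volts
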