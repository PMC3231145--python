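"""Photometric/radiometric unit conversions and source photon rates.

The photon budget starts from a light source described the way a datasheet
describes it: lasers in watts, LEDs often in lumens plus a luminous efficacy,
both with a nominal wavelength and a full conical emission angle.  This module
converts those specifications into the two quantities the rest of the chain
consumes: a photon emission rate (photons/s) and an emission solid angle
(steradians).

Conversions
-----------
* lumens -> watts via the 683 lm/W peak photopic efficacy scaled by the
  wavelength-dependent luminous efficacy fraction V(lambda);
* watts -> photons/s via ``5.03e15 * P(W) * lambda(nm)``, the rounded form of
  ``P * lambda / (h c)``;
* full emission cone angle (degrees) -> solid angle ``2*pi*(1 - cos(theta))``
  with theta the half-angle.

The rounded 5.03e15 constant is the default for arithmetic compatibility with
hand/spreadsheet calculations in this field; ``exact=True`` switches to the
CODATA ``1/(h c)`` value (they differ by less than 0.1%).
"""

from __future__ import annotations

import math
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .exceptions import ConfigurationError, InvalidParameterError

__all__ = [
    "LUMENS_PER_WATT",
    "PHOTONS_PER_WATT_NM",
    "PHOTONS_PER_WATT_NM_EXACT",
    "FULL_SPHERE_SR",
    "SourceSpec",
    "lumens_to_watts",
    "watts_to_photon_rate",
    "cone_to_solid_angle",
    "source_photon_rate",
]

#: Peak photopic luminous efficacy, lumens per watt at 555 nm.
LUMENS_PER_WATT = 683.0

#: Rounded photons-per-second per (watt * nm) conversion constant.
PHOTONS_PER_WATT_NM = 5.03e15

#: Exact 1/(h*c) in photons per (watt * nm): lambda[nm]*1e-9 / (h*c).
_PLANCK = 6.62607015e-34  # J s
_C_LIGHT = 2.99792458e8  # m/s
PHOTONS_PER_WATT_NM_EXACT = 1e-9 / (_PLANCK * _C_LIGHT)

#: Solid angle of the full sphere, steradians.
FULL_SPHERE_SR = 4.0 * math.pi


class SourceSpec(BaseModel):
    """A light source as specified on a datasheet.

    Exactly one of ``power`` (watts) or ``lumens`` must be given; when
    ``lumens`` is given a ``luminous_efficacy`` fraction is required for
    conversion to watts.

    Attributes
    ----------
    power : float, optional
        Radiometric output power in watts.
    lumens : float, optional
        Photometric output in lumens.
    luminous_efficacy : float, optional
        Dimensionless V(lambda) fraction in (0, 1]; required with ``lumens``.
    wavelength : float
        Nominal emission wavelength in nm.
    full_emission_angle : float
        Full conical emission beam angle (the "2 theta" of a datasheet) in
        degrees, in (0, 360].
    emitting_area : float
        Emitting area A_S in cm^2.
    """

    model_config = ConfigDict(extra="forbid")

    name: str = "source"
    power: Optional[float] = Field(default=None, ge=0.0)
    lumens: Optional[float] = Field(default=None, ge=0.0)
    luminous_efficacy: Optional[float] = Field(default=None, gt=0.0, le=1.0)
    wavelength: float = Field(gt=0.0)
    full_emission_angle: float = Field(gt=0.0, le=360.0)
    emitting_area: float = Field(gt=0.0)

    @model_validator(mode="after")
    def _check_power_xor_lumens(self) -> "SourceSpec":
        if (self.power is None) == (self.lumens is None):
            raise ValueError(
                "exactly one of 'power' (W) or 'lumens' must be specified"
            )
        if self.lumens is not None and self.luminous_efficacy is None:
            raise ValueError(
                "'luminous_efficacy' is required when the source is "
                "specified in lumens"
            )
        return self

    @property
    def solid_angle(self) -> float:
        """Emission solid angle Omega_S in steradians."""
        return cone_to_solid_angle(self.full_emission_angle)


def lumens_to_watts(lumens: float, luminous_efficacy: float) -> float:
    """Convert a photometric lumen rating to radiometric watts.

    ``watts = lumens / (683 * luminous_efficacy)`` where the efficacy is the
    dimensionless V(lambda) fraction at the source wavelength.
    """
    if luminous_efficacy <= 0.0 or luminous_efficacy > 1.0:
        raise InvalidParameterError(
            f"luminous_efficacy must be in (0, 1], got {luminous_efficacy}"
        )
    if lumens < 0.0:
        raise InvalidParameterError(f"lumens must be >= 0, got {lumens}")
    return lumens / (LUMENS_PER_WATT * luminous_efficacy)


def watts_to_photon_rate(
    power: float, wavelength: float, *, exact: bool = False
) -> float:
    """Photon emission rate (photons/s) of a monochromatic source.

    ``rate = 5.03e15 * power(W) * wavelength(nm)``; with ``exact=True`` the
    constant is replaced by 1/(h c) in the same units.
    """
    if power < 0.0:
        raise InvalidParameterError(f"power must be >= 0, got {power}")
    if wavelength <= 0.0:
        raise InvalidParameterError(f"wavelength must be > 0, got {wavelength}")
    k = PHOTONS_PER_WATT_NM_EXACT if exact else PHOTONS_PER_WATT_NM
    return k * power * wavelength


def cone_to_solid_angle(full_angle: float) -> float:
    """Solid angle (sr) of a cone with the given full apex angle in degrees.

    ``Omega = 2*pi*(1 - cos(full_angle/2))``; 360 degrees maps to the full
    sphere 4*pi exactly.
    """
    if not 0.0 < full_angle <= 360.0:
        raise InvalidParameterError(
            f"full emission angle must be in (0, 360] degrees, got {full_angle}"
        )
    half = math.radians(full_angle) / 2.0
    return 2.0 * math.pi * (1.0 - math.cos(half))


def source_photon_rate(src: SourceSpec, *, exact: bool = False) -> float:
    """Photon rate P_S (photons/s) of a source spec.

    Applies the lumens-to-watts conversion first when the source is rated in
    lumens, then the watts-to-photons conversion.
    """
    if src.power is not None:
        watts = src.power
    elif src.lumens is not None:
        if src.luminous_efficacy is None:  # pragma: no cover - validated
            raise ConfigurationError(
                "lumen-rated source requires luminous_efficacy"
            )
        watts = lumens_to_watts(src.lumens, src.luminous_efficacy)
    else:  # pragma: no cover - validated at construction
        raise ConfigurationError("source must specify power or lumens")
    return watts_to_photon_rate(watts, src.wavelength, exact=exact)
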