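"""Geometric transport fractions between stages of an optical train.

Every stage-to-stage hop in the photon budget reduces to a dimensionless
fraction: the part of the photons leaving one component that is intercepted by
the next.  This module computes those fractions for

* source -> lens (emission cone vs. lens aperture),
* lens imaging (focal-spot size on the sample plane, thin-lens conjugates),
* focal spot / detector-view / microchannel overlap (the nine relative-size
  cases reduce to circle-strip and concentric-circle intersections),
* sample -> collection lens (isotropic emitter vs. aperture),
* source -> fiber (acceptance cone and core interception),
* fiber capture of isotropic emission at a distance,
* direct (no-optics) coupling, with the receiving aperture taking the place
  of a lens.

All lengths are centimetres, areas cm^2, angles degrees at the interface and
solid angles steradians.  Components are assumed concentric and coaxial
("properly aligned"); the small-angle flat-disk approximation
``Omega_aperture ~ pi R^2 / d^2`` is used where an aperture subtends a small
angle, with an ``exact`` flag available for the spherical-cap form.  Fractions
are always clamped to their physical bounds: [0, 1] generally, and <= 1/2 for
one-sided collection from an isotropic emitter.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .exceptions import InvalidParameterError, NoRealImageError
from .sources import FULL_SPHERE_SR, SourceSpec, cone_to_solid_angle

__all__ = [
    "LensSpec",
    "FiberSpec",
    "GeometryLayout",
    "OverlapFractions",
    "source_to_lens_fraction",
    "conjugate_distance",
    "image_spot",
    "circle_strip_overlap_area",
    "overlap_fractions",
    "sample_to_lens_fraction",
    "fiber_half_angle",
    "fiber_solid_angle",
    "source_to_fiber_rate",
    "fiber_capture_fraction",
    "no_optics_fraction",
]


class LensSpec(BaseModel):
    """A thin lens: aperture radius and focal length, both in cm."""

    model_config = ConfigDict(extra="forbid")

    radius: float = Field(gt=0.0)
    focal_length: float = Field(gt=0.0)


class FiberSpec(BaseModel):
    """An optical fiber: core radius (cm), numerical aperture and the
    refractive index of the medium the acceptance cone lives in (1 air,
    1.33 water, 1.36 ethanol)."""

    model_config = ConfigDict(extra="forbid")

    core_radius: float = Field(gt=0.0)
    numerical_aperture: float = Field(gt=0.0)
    medium_refractive_index: float = Field(default=1.0, ge=1.0)
    #: Single scalar transmission efficiency of the fiber at the working
    #: wavelength (attenuation spectra are out of scope).
    transmission_efficiency: float = Field(default=1.0, gt=0.0, le=1.0)

    @model_validator(mode="after")
    def _check_na(self) -> "FiberSpec":
        if self.numerical_aperture > self.medium_refractive_index:
            raise ValueError(
                "numerical aperture cannot exceed the medium refractive "
                f"index (NA={self.numerical_aperture}, "
                f"n={self.medium_refractive_index}): NA = n*sin(theta_F)"
            )
        return self

    @property
    def half_angle(self) -> float:
        """Acceptance half-angle theta_F in degrees."""
        return fiber_half_angle(self)

    @property
    def solid_angle(self) -> float:
        """Acceptance solid angle Omega_F in steradians."""
        return fiber_solid_angle(self)


class GeometryLayout(BaseModel):
    """Axial distances between stages, in cm.

    ``x1``: source -> first lens; ``x2``: first lens -> sample plane (left
    unset to be derived from the thin-lens conjugate relation); ``x3``:
    sample -> collection lens; ``d_source_fiber``: source -> excitation fiber
    face; ``d_no_optics``: stage separation when a side has no optics;
    ``gap``: fiber face -> channel (collection side / coaxial end gap).
    """

    model_config = ConfigDict(extra="forbid")

    x1: Optional[float] = Field(default=None, gt=0.0)
    x2: Optional[float] = Field(default=None, gt=0.0)
    x3: Optional[float] = Field(default=None, gt=0.0)
    d_source_fiber: Optional[float] = Field(default=None, gt=0.0)
    d_no_optics: Optional[float] = Field(default=None, gt=0.0)
    gap: Optional[float] = Field(default=None, gt=0.0)


class OverlapFractions(BaseModel):
    """Spot/view/channel overlap result.

    ``f_into_channel``: fraction of the focal-spot photons landing on analyte
    fluid.  ``f_viewed``: fraction of the illuminated analyte area that the
    detector-view region sees.
    """

    model_config = ConfigDict(extra="forbid")

    f_into_channel: float = Field(ge=0.0, le=1.0)
    f_viewed: float = Field(ge=0.0, le=1.0)


def source_to_lens_fraction(
    omega_s: float, lens: LensSpec, x1: float, *, exact: bool = False
) -> float:
    """Fraction of source photons intercepted by a lens of radius R at x1.

    Flat-disk form ``pi R^2 / (Omega_S x1^2)``, capped at 1 (when the lens
    subtends the whole emission cone every photon hits it).  ``exact=True``
    uses the spherical-cap solid angle ``2*pi*(1 - cos(atan(R/x1)))`` instead
    of the flat-disk numerator.
    """
    if x1 <= 0.0:
        raise InvalidParameterError(f"source-lens distance must be > 0, got {x1}")
    if omega_s <= 0.0:
        raise InvalidParameterError(f"emission solid angle must be > 0, got {omega_s}")
    if exact:
        cap = 2.0 * math.pi * (1.0 - math.cos(math.atan(lens.radius / x1)))
        return min(1.0, cap / omega_s)
    return min(1.0, math.pi * lens.radius**2 / (omega_s * x1**2))


def conjugate_distance(focal_length: float, x1: float) -> float:
    """Image distance x2 from the thin-lens relation 1/F = 1/x1 + 1/x2."""
    if focal_length <= 0.0:
        raise InvalidParameterError(f"focal length must be > 0, got {focal_length}")
    if x1 <= focal_length:
        raise NoRealImageError(
            f"object distance x1={x1} must exceed the focal length "
            f"F={focal_length} for a real image"
        )
    return 1.0 / (1.0 / focal_length - 1.0 / x1)


def image_spot(
    area_source: float,
    x1: float,
    x2: float,
    magnification_mode: Literal["squared", "linear"] = "squared",
) -> float:
    """Area A_C (cm^2) of the focused source spot on the sample plane.

    Default "squared" mode applies the physical area magnification
    ``A_C = A_S * (x2/x1)^2``; "linear" mode uses the linear ratio
    ``A_C = A_S * (x2/x1)``.  The two agree at unit magnification
    (x1 = x2 = 2F).
    """
    if area_source < 0.0:
        raise InvalidParameterError("source area must be >= 0")
    if x1 <= 0.0 or x2 <= 0.0:
        raise InvalidParameterError("conjugate distances must be > 0")
    ratio = x2 / x1
    if magnification_mode == "squared":
        return area_source * ratio**2
    if magnification_mode == "linear":
        return area_source * ratio
    raise InvalidParameterError(
        f"unknown magnification mode {magnification_mode!r}"
    )


def circle_strip_overlap_area(radius: float, half_width: float) -> float:
    """Area of a circle of given radius intersected with the strip |x| <= a.

    Both the circle centre and the strip are on the same axis.  Closed form
    via circular segments:
    ``2*(a*sqrt(r^2 - a^2) + r^2*asin(a/r))`` for a < r, else the full circle.
    """
    if radius < 0.0 or half_width < 0.0:
        raise InvalidParameterError("radius and half-width must be >= 0")
    if radius == 0.0:
        return 0.0
    a = half_width
    r = radius
    if a >= r:
        return math.pi * r * r
    return 2.0 * (a * math.sqrt(r * r - a * a) + r * r * math.asin(a / r))


def overlap_fractions(
    spot_radius: float,
    view_radius: Optional[float],
    channel_width: float,
    sample_kind: Literal["microchannel", "thin_film"] = "microchannel",
) -> OverlapFractions:
    """Spot/view/channel overlap fractions for concentric circles on a strip.

    The focal spot and the detector-view region are concentric circles
    centred on the channel axis, so every pairwise intersection is either a
    circle-strip intersection (closed form via circular segments) or the
    smaller of two concentric circles.  ``view_radius=None`` means the
    detector sees the whole illuminated region.

    For a thin film there is no lateral confinement: ``f_into_channel = 1``
    and ``f_viewed`` is the concentric circle-circle area ratio.  For a
    microchannel, ``f_into_channel = area(spot & strip)/area(spot)`` and
    ``f_viewed = area(spot & strip & view)/area(spot & strip)``.
    """
    if spot_radius <= 0.0:
        raise InvalidParameterError(f"spot radius must be > 0, got {spot_radius}")
    if view_radius is not None and view_radius <= 0.0:
        raise InvalidParameterError(f"view radius must be > 0, got {view_radius}")

    if sample_kind == "thin_film":
        if view_radius is None or view_radius >= spot_radius:
            f_viewed = 1.0
        else:
            f_viewed = (view_radius / spot_radius) ** 2
        return OverlapFractions(f_into_channel=1.0, f_viewed=f_viewed)

    if sample_kind != "microchannel":
        raise InvalidParameterError(f"unknown sample kind {sample_kind!r}")
    if channel_width <= 0.0:
        raise InvalidParameterError(
            f"channel width must be > 0, got {channel_width}"
        )

    half_w = channel_width / 2.0
    spot_area = math.pi * spot_radius**2
    illuminated = circle_strip_overlap_area(spot_radius, half_w)
    f_into = min(1.0, illuminated / spot_area)
    if view_radius is None or view_radius >= spot_radius:
        f_viewed = 1.0
    else:
        # spot & view = the smaller concentric circle
        seen = circle_strip_overlap_area(view_radius, half_w)
        f_viewed = min(1.0, seen / illuminated)
    return OverlapFractions(f_into_channel=f_into, f_viewed=f_viewed)


def sample_to_lens_fraction(lens: LensSpec, x3: float) -> float:
    """Fraction of isotropic (4 pi) sample emission collected by a lens.

    ``R_L2^2 / (4 x3^2)``, capped at 1/2: a single lens on one side of the
    sample can never collect more than a hemisphere's worth.
    """
    if x3 <= 0.0:
        raise InvalidParameterError(f"sample-lens distance must be > 0, got {x3}")
    return min(0.5, lens.radius**2 / (4.0 * x3**2))


def fiber_half_angle(fiber: FiberSpec) -> float:
    """Acceptance half-angle theta_F (degrees) from NA = n*sin(theta_F)."""
    ratio = fiber.numerical_aperture / fiber.medium_refractive_index
    if ratio > 1.0:
        raise InvalidParameterError(
            "numerical aperture exceeds medium refractive index"
        )
    return math.degrees(math.asin(ratio))


def fiber_solid_angle(fiber: FiberSpec) -> float:
    """Acceptance solid angle Omega_F (sr) of a fiber."""
    return cone_to_solid_angle(2.0 * fiber_half_angle(fiber))


def source_to_fiber_rate(
    p_s: float, src: SourceSpec, fiber: FiberSpec, d: float
) -> float:
    """Photon rate P_F entering a fiber core facing a source at distance d.

    Two factors: the fraction of the source area within the fiber acceptance
    cone, ``min(1, Omega_F d^2 / A_S)``, and the fraction of the photons from
    that area that land on the core, ``pi R_F^2 / (Omega_S d^2)``.  The
    product is additionally capped so the fiber never accepts more photons
    than the source emits.  While the acceptance region under-fills the
    source, the d^2 factors cancel and moving the fiber back does not change
    P_F.
    """
    if d <= 0.0:
        raise InvalidParameterError(f"source-fiber distance must be > 0, got {d}")
    if p_s < 0.0:
        raise InvalidParameterError("photon rate must be >= 0")
    omega_f = fiber_solid_angle(fiber)
    omega_s = src.solid_angle
    area_factor = min(1.0, omega_f * d**2 / src.emitting_area)
    core_factor = math.pi * fiber.core_radius**2 / (omega_s * d**2)
    frac = min(1.0, area_factor * core_factor)
    return p_s * frac * fiber.transmission_efficiency


def fiber_capture_fraction(fiber: FiberSpec, d: float) -> float:
    """Fraction of isotropic emission at distance d captured by a fiber core.

    ``min(pi R_F^2, Omega_F d^2) / (4 pi d^2)``: solid-angle interception by
    the core, saturating at the acceptance-cone bound ``Omega_F / (4 pi)`` as
    the emitter approaches the fiber face.
    """
    if d <= 0.0:
        raise InvalidParameterError(f"distance must be > 0, got {d}")
    omega_f = fiber_solid_angle(fiber)
    core_area = math.pi * fiber.core_radius**2
    return min(core_area, omega_f * d**2) / (FULL_SPHERE_SR * d**2)


def no_optics_fraction(
    active_area: float,
    d: float,
    emission: Literal["cone", "isotropic"] = "isotropic",
    omega_s: Optional[float] = None,
) -> float:
    """Direct coupling fraction with the receiving aperture in place of a lens.

    For a conical emitter (solid angle ``omega_s``) the aperture intercepts
    ``active_area / (Omega_S d^2)``, capped at 1; for an isotropic emitter
    ``active_area / (4 pi d^2)``, capped at the one-sided bound 1/2.
    """
    if d <= 0.0:
        raise InvalidParameterError(f"distance must be > 0, got {d}")
    if active_area < 0.0:
        raise InvalidParameterError("active area must be >= 0")
    if emission == "cone":
        if omega_s is None or omega_s <= 0.0:
            raise InvalidParameterError(
                "cone emission requires a positive omega_s"
            )
        return min(1.0, active_area / (omega_s * d**2))
    if emission == "isotropic":
        return min(0.5, active_area / (FULL_SPHERE_SR * d**2))
    raise InvalidParameterError(f"unknown emission pattern {emission!r}")
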