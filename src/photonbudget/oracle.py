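"""Seeded Monte-Carlo photon sampler for auditing geometric coupling factors.

The algebraic coupling fractions use small-angle (flat-disk) approximations
of aperture solid angles.  This module provides the brute-force check: emit
photons uniformly over the emitting area and uniformly over the emission
solid angle (exact spherical-cap measure, not uniform in polar angle),
propagate them in straight lines, and count interceptions by an aperture.
The estimate is unbiased with a binomial standard error, so users can measure
the approximation error of the algebraic forms directly — in particular at
large emission angles or for nearby apertures, where the flat-disk forms
drift.

The sampler is a first-class part of the package (also exposed by the CLI as
``photonbudget oracle``), not test-only code.
"""

from __future__ import annotations

import math
from typing import Literal, Optional, Tuple, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .exceptions import InvalidParameterError

__all__ = [
    "EmitterSpec",
    "DiskTarget",
    "StripTarget",
    "SamplerConfig",
    "estimate_fraction",
]


class EmitterSpec(BaseModel):
    """A uniform emitter: a disk of given radius (0 = point source) emitting
    into a cone of the given full angle (degrees), or isotropically into the
    full sphere when ``full_angle`` is None."""

    model_config = ConfigDict(extra="forbid")

    radius: float = Field(default=0.0, ge=0.0)
    full_angle: Optional[float] = Field(default=None, gt=0.0, le=360.0)


class DiskTarget(BaseModel):
    """A concentric disk aperture at an axial distance.

    ``acceptance_half_angle`` (degrees) additionally requires the photon
    direction to lie within that half-angle of the axis, modelling a fiber
    core with a finite numerical aperture.
    """

    model_config = ConfigDict(extra="forbid")

    kind: Literal["disk"] = "disk"
    radius: float = Field(gt=0.0)
    distance: float = Field(gt=0.0)
    acceptance_half_angle: Optional[float] = Field(default=None, gt=0.0, le=90.0)


class StripTarget(BaseModel):
    """An infinite strip |x| <= half_width in the emitter plane.

    A position-only target: it measures the fraction of the emitting area
    inside the strip (the focal-spot/channel overlap geometry).
    """

    model_config = ConfigDict(extra="forbid")

    kind: Literal["strip"] = "strip"
    half_width: float = Field(gt=0.0)


class SamplerConfig(BaseModel):
    """One Monte-Carlo experiment: emitter, target, sample count and seed."""

    model_config = ConfigDict(extra="forbid")

    n_samples: int = Field(ge=10_000)
    seed: int
    emitter: EmitterSpec
    target: Union[DiskTarget, StripTarget] = Field(discriminator="kind")


def _sample_positions(
    rng: np.random.Generator, n: int, radius: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Uniform points on a disk of the given radius (all zeros for a point)."""
    if radius == 0.0:
        return np.zeros(n), np.zeros(n)
    r = radius * np.sqrt(rng.random(n))
    phi = 2.0 * math.pi * rng.random(n)
    return r * np.cos(phi), r * np.sin(phi)


def _sample_directions(
    rng: np.random.Generator, n: int, full_angle: Optional[float]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Directions uniform over the emission solid angle.

    Cone emission: cos(theta) uniform on [cos(theta_max), 1] (the exact
    spherical-cap measure); isotropic: cos(theta) uniform on [-1, 1].
    """
    if full_angle is None:
        cos_t = rng.uniform(-1.0, 1.0, n)
    else:
        cos_max = math.cos(math.radians(full_angle) / 2.0)
        cos_t = rng.uniform(cos_max, 1.0, n)
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t**2))
    phi = 2.0 * math.pi * rng.random(n)
    return sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t


def estimate_fraction(cfg: SamplerConfig) -> Tuple[float, float]:
    """Hit fraction and its binomial standard error for one experiment.

    Deterministic for a fixed seed.  The standard error is
    ``sqrt(p*(1-p)/n)``; agreement of an algebraic factor with the estimate
    within ~3 standard errors is the expected behaviour in the small-angle
    regime where the flat-disk approximations hold.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    target = cfg.target

    if isinstance(target, StripTarget):
        if cfg.emitter.radius <= 0.0:
            raise InvalidParameterError(
                "a strip target needs an extended emitter (radius > 0)"
            )
        x, _ = _sample_positions(rng, n, cfg.emitter.radius)
        hits = int(np.count_nonzero(np.abs(x) <= target.half_width))
    else:
        x, y = _sample_positions(rng, n, cfg.emitter.radius)
        ux, uy, uz = _sample_directions(rng, n, cfg.emitter.full_angle)
        forward = uz > 0.0
        t = np.where(forward, target.distance / np.where(forward, uz, 1.0), np.inf)
        px = x + t * ux
        py = y + t * uy
        hit = forward & (px**2 + py**2 <= target.radius**2)
        if target.acceptance_half_angle is not None:
            cos_acc = math.cos(math.radians(target.acceptance_half_angle))
            hit &= uz >= cos_acc
        hits = int(np.count_nonzero(hit))

    p = hits / n
    se = math.sqrt(p * (1.0 - p) / n)
    return p, se
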