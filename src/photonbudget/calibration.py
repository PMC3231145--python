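"""End-to-end signal chains, calibration curves, MDL and dynamic range.

An :class:`OpticalTrain` is the declarative description of one complete
instrument: source, excitation coupling (lens, fiber or none), sample,
collection coupling, spectral filter, detector and amplifier, plus the probing
geometry (perpendicular to the chip, fiber across the channel, or fiber
coaxial with the channel).  :func:`signal_at_concentration` concatenates the
per-stage operations into a detector voltage with a full stage-by-stage trace,
and the remaining functions sweep concentration grids and extract the figures
of merit:

* the calibration curve (voltage vs. molarity and vs. molecule number),
* the minimum detection limit (MDL), the concentration at which the curve
  crosses the detector noise floor,
* the dynamic range, the ratio of the saturation-crossing concentration to
  the MDL, and
* normalized parameter sensitivities (logarithmic derivatives of the signal).

Everything upstream of the detector is linear in source power; in the
optically thin regime the signal is also linear in concentration, so
calibration curves have unit slope on log-log axes until Beer-Lambert
saturation bends them over.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.optimize import brentq

from . import coupling as cg
from . import detection as det_mod
from . import sample as sm
from .coupling import FiberSpec, LensSpec
from .detection import AmplifierSpec, DetectorSpec, FilterSpec
from .exceptions import ConfigurationError, InvalidParameterError, UnattainableError
from .sample import AnalyteSpec, SampleSpec  # noqa: F401  (re-export convenience)
from .sources import SourceSpec, source_photon_rate

__all__ = [
    "ExcitationCoupling",
    "CollectionCoupling",
    "OpticalTrain",
    "StageTrace",
    "CalibrationCurve",
    "PerformanceSummary",
    "DynamicRangeResult",
    "SensitivityResult",
    "signal_at_concentration",
    "calibration_curve",
    "find_mdl",
    "dynamic_range",
    "sensitivity",
    "design_sweep",
]

# Concentration search bracket for threshold crossings, mol/L.
_C_LO = 1e-15
_C_HI = 10.0


class ExcitationCoupling(BaseModel):
    """Source-side coupling: a lens, a fiber, or direct illumination.

    For a lens, ``x1`` is the source-lens distance and ``x2`` the lens-sample
    distance (derived from the thin-lens conjugate relation when omitted).
    For a fiber, ``distance`` is the source-to-fiber-face distance.  For no
    optics, ``distance`` separates source and sample directly.
    """

    model_config = ConfigDict(extra="forbid")

    kind: Literal["lens", "fiber", "none"]
    lens: Optional[LensSpec] = None
    fiber: Optional[FiberSpec] = None
    x1: Optional[float] = Field(default=None, gt=0.0)
    x2: Optional[float] = Field(default=None, gt=0.0)
    distance: Optional[float] = Field(default=None, gt=0.0)
    magnification_mode: Literal["squared", "linear"] = "squared"

    @model_validator(mode="after")
    def _check(self) -> "ExcitationCoupling":
        if self.kind == "lens":
            if self.lens is None or self.x1 is None:
                raise ValueError("lens excitation requires 'lens' and 'x1'")
            if self.x1 <= self.lens.focal_length:
                raise ValueError(
                    "lens excitation requires x1 > focal length for a real image"
                )
        elif self.kind == "fiber":
            if self.fiber is None or self.distance is None:
                raise ValueError(
                    "fiber excitation requires 'fiber' and 'distance'"
                )
        elif self.distance is None:
            raise ValueError("no-optics excitation requires 'distance'")
        return self


class CollectionCoupling(BaseModel):
    """Sample-side coupling toward the detector.

    For a lens, ``x3`` is the sample-lens distance.  For a fiber, ``gap`` is
    the sample-to-fiber-face distance.  For no optics, ``distance`` separates
    sample and detector.  ``view_radius`` optionally restricts the region of
    the sample plane the detector sees (cm); by default the whole illuminated
    region is viewed.
    """

    model_config = ConfigDict(extra="forbid")

    kind: Literal["lens", "fiber", "none"]
    lens: Optional[LensSpec] = None
    fiber: Optional[FiberSpec] = None
    x3: Optional[float] = Field(default=None, gt=0.0)
    gap: Optional[float] = Field(default=None, gt=0.0)
    distance: Optional[float] = Field(default=None, gt=0.0)
    view_radius: Optional[float] = Field(default=None, gt=0.0)

    @model_validator(mode="after")
    def _check(self) -> "CollectionCoupling":
        if self.kind == "lens" and (self.lens is None or self.x3 is None):
            raise ValueError("lens collection requires 'lens' and 'x3'")
        if self.kind == "fiber" and (self.fiber is None or self.gap is None):
            raise ValueError("fiber collection requires 'fiber' and 'gap'")
        if self.kind == "none" and self.distance is None:
            raise ValueError("no-optics collection requires 'distance'")
        return self


class OpticalTrain(BaseModel):
    """One complete instrument, source to amplifier.

    ``geometry`` selects how the light meets the sample: ``perpendicular``
    (normal to the channel/film plane), ``cross`` (fiber beam across a
    microchannel) or ``coaxial`` (fibers in the channel ends, requiring the
    axial integration).  ``thin_approximation`` switches the sample
    absorption to the optically-thin linear form, making the whole chain
    strictly linear in concentration.
    """

    model_config = ConfigDict(extra="forbid")

    name: str = "train"
    mode: Literal["fluorescence", "absorption"] = "fluorescence"
    geometry: Literal["perpendicular", "cross", "coaxial"] = "perpendicular"
    source: SourceSpec
    excitation: ExcitationCoupling
    sample: SampleSpec
    collection: CollectionCoupling
    optical_filter: Optional[FilterSpec] = None
    detector: DetectorSpec
    amplifier: AmplifierSpec = AmplifierSpec()
    #: Exposed area in the detection plane (cm^2); defaults to the detector
    #: active area (no geometric loss at the detector).
    exposed_area: Optional[float] = Field(default=None, gt=0.0)
    thin_approximation: bool = False
    #: Axial slices for the coaxial integration.
    n_slices: int = Field(default=1000, ge=100)
    #: Fluorescence emission wavelength (nm) used for the detector response;
    #: defaults to the source wavelength when unset.
    detection_wavelength: Optional[float] = Field(default=None, gt=0.0)

    @model_validator(mode="after")
    def _check_consistency(self) -> "OpticalTrain":
        violations: list[str] = []
        if self.geometry in ("cross", "coaxial"):
            if self.sample.kind != "microchannel":
                violations.append(
                    f"{self.geometry} geometry requires a microchannel sample"
                )
            if self.excitation.kind != "fiber":
                violations.append(
                    f"{self.geometry} geometry requires fiber excitation"
                )
            if self.collection.kind != "fiber":
                violations.append(
                    f"{self.geometry} geometry requires fiber collection"
                )
        if self.geometry == "coaxial" and self.thin_approximation:
            violations.append(
                "the coaxial axial integral always uses exact attenuation; "
                "thin_approximation is not available"
            )
        if violations:
            raise ValueError("; ".join(violations))
        return self

    @property
    def wavelength_at_detector(self) -> float:
        if self.detection_wavelength is not None:
            return self.detection_wavelength
        return self.source.wavelength


#: One (stage name, photon rate or factor, unit) entry of the budget trace.
StageTrace = List[Tuple[str, float, str]]


@dataclass
class _ChainFactors:
    """Concentration-independent pieces of one train's photon budget."""

    p_source: float  # photons/s leaving the source
    f_excitation: float  # fraction of P_S reaching analyte fluid
    illum_radius: Optional[float]  # radius of illuminated region (cm)
    path: float  # absorption path length (cm); 0 for coaxial (integral)
    f_collection: float  # geometric collection fraction (fluorescence)
    f_viewed: float  # fraction of illuminated area seen by detector
    f_filter: float
    f_detector_area: float
    interrogated_volume_L: float


def _excitation_factors(
    train: OpticalTrain,
) -> Tuple[float, Optional[float]]:
    """Fraction of P_S delivered into the analyte, and the illuminated radius."""
    src = train.source
    exc = train.excitation
    samp = train.sample
    if exc.kind == "lens":
        assert exc.lens is not None and exc.x1 is not None
        x2 = exc.x2
        if x2 is None:
            x2 = cg.conjugate_distance(exc.lens.focal_length, exc.x1)
        f_lens = cg.source_to_lens_fraction(src.solid_angle, exc.lens, exc.x1)
        spot_area = cg.image_spot(
            src.emitting_area, exc.x1, x2, exc.magnification_mode
        )
        spot_radius = math.sqrt(spot_area / math.pi)
        ov = cg.overlap_fractions(
            spot_radius, None, samp.width or 0.0, samp.kind
        )
        return f_lens * ov.f_into_channel, spot_radius
    if exc.kind == "none":
        assert exc.distance is not None
        footprint = src.solid_angle * exc.distance**2
        radius = math.sqrt(footprint / math.pi)
        if samp.kind == "thin_film":
            f_into = min(1.0, samp.film_area / footprint)  # type: ignore
            radius = min(radius, math.sqrt(samp.film_area / math.pi))  # type: ignore
        else:
            ov = cg.overlap_fractions(radius, None, samp.width, samp.kind)  # type: ignore
            f_into = ov.f_into_channel
        return f_into, radius
    # fiber
    assert exc.fiber is not None and exc.distance is not None
    f_fiber = cg.source_to_fiber_rate(1.0, src, exc.fiber, exc.distance)
    radius = exc.fiber.core_radius
    if train.geometry == "coaxial":
        # butt-coupled into the channel end; core assumed within the channel
        return f_fiber, radius
    ov = cg.overlap_fractions(radius, None, samp.width or math.inf, samp.kind)
    return f_fiber * ov.f_into_channel, radius


def _collection_factors(
    train: OpticalTrain, illum_radius: Optional[float]
) -> Tuple[float, float]:
    """Geometric collection fraction of isotropic fluorescence, and f_viewed."""
    col = train.collection
    samp = train.sample
    f_viewed = 1.0
    if col.view_radius is not None and illum_radius is not None:
        ov = cg.overlap_fractions(
            illum_radius, col.view_radius, samp.width or math.inf, samp.kind
        )
        f_viewed = ov.f_viewed
    if col.kind == "lens":
        assert col.lens is not None and col.x3 is not None
        return cg.sample_to_lens_fraction(col.lens, col.x3), f_viewed
    if col.kind == "none":
        assert col.distance is not None
        return (
            cg.no_optics_fraction(
                train.detector.active_area, col.distance, "isotropic"
            ),
            f_viewed,
        )
    assert col.fiber is not None and col.gap is not None
    return cg.fiber_capture_fraction(col.fiber, col.gap), f_viewed


def _interrogated_volume_L(
    train: OpticalTrain, illum_radius: Optional[float]
) -> float:
    """Volume (litres) both illuminated and viewed, for molecule counts."""
    samp = train.sample
    col = train.collection
    if train.geometry == "coaxial":
        return samp.channel_volume_L
    radius = illum_radius
    if radius is None:
        return samp.channel_volume_L
    if col.view_radius is not None:
        radius = min(radius, col.view_radius)
    if samp.kind == "thin_film":
        area = min(math.pi * radius**2, samp.film_area)  # type: ignore
        vol_cm3 = area * samp.thickness  # type: ignore
    elif train.geometry == "cross":
        area = cg.circle_strip_overlap_area(radius, samp.width / 2.0)  # type: ignore
        vol_cm3 = area * samp.width  # type: ignore
    else:
        area = cg.circle_strip_overlap_area(radius, samp.width / 2.0)  # type: ignore
        vol_cm3 = area * samp.depth  # type: ignore
    return vol_cm3 * 1e-3


def _chain_factors(train: OpticalTrain) -> _ChainFactors:
    p_source = source_photon_rate(train.source)
    f_exc, illum_radius = _excitation_factors(train)
    f_coll, f_viewed = _collection_factors(train, illum_radius)
    f_filter = (
        det_mod.filter_transmission_factor(train.optical_filter)
        if train.optical_filter is not None
        else 1.0
    )
    f_area = (
        det_mod.detector_area_fraction(
            train.detector.active_area, train.exposed_area
        )
        if train.exposed_area is not None
        else 1.0
    )
    if train.geometry == "coaxial":
        path = 0.0
    elif train.geometry == "cross":
        path = train.sample.path_length("cross")
    else:
        path = train.sample.path_length("normal")
    return _ChainFactors(
        p_source=p_source,
        f_excitation=f_exc,
        illum_radius=illum_radius,
        path=path,
        f_collection=f_coll,
        f_viewed=f_viewed,
        f_filter=f_filter,
        f_detector_area=f_area,
        interrogated_volume_L=_interrogated_volume_L(train, illum_radius),
    )


def signal_at_concentration(
    train: OpticalTrain, c: float, *, clip: bool = True
) -> Tuple[float, StageTrace]:
    """Detector output voltage at molarity ``c``, with a per-stage trace.

    The trace lists every photon rate and conversion along the chain so any
    point of a calibration curve can be audited by hand arithmetic.
    """
    if c < 0.0:
        raise InvalidParameterError(f"concentration must be >= 0, got {c}")
    f = _chain_factors(train)
    samp = train.sample
    trace: StageTrace = [("source", f.p_source, "photons/s")]
    p_c = f.p_source * f.f_excitation
    trace.append(("into_sample", p_c, "photons/s"))

    if train.geometry == "coaxial":
        assert train.collection.fiber is not None
        captured, transmitted = sm.coaxial_channel_response(
            p_c,
            samp,
            c,
            train.collection.fiber,
            train.collection.gap,  # type: ignore[arg-type]
            train.n_slices,
        )
        if train.mode == "fluorescence":
            trace.append(("fluorescence_captured", captured, "photons/s"))
            p_after_geom = captured * f.f_viewed
        else:
            trace.append(("transmitted", transmitted, "photons/s"))
            # transmitted beam confined to the channel cross-section
            core = math.pi * train.collection.fiber.core_radius ** 2
            cross_section = samp.width * samp.depth  # type: ignore[operator]
            p_after_geom = transmitted * min(1.0, core / cross_section)
    elif train.mode == "fluorescence":
        mode = "thin" if train.thin_approximation else "exact"
        p_abs = sm.absorbed_photons(p_c, samp.analyte, c, f.path, mode)
        trace.append(("absorbed", p_abs, "photons/s"))
        p_sa = sm.fluorescence_rate(p_abs, samp.analyte.quantum_yield)
        trace.append(("fluorescence", p_sa, "photons/s"))
        p_after_geom = p_sa * f.f_collection * f.f_viewed
        trace.append(("collected", p_after_geom, "photons/s"))
    else:  # absorption, collinear beam: collection is lossless
        p_after_geom = sm.transmitted_photons(p_c, samp.analyte, c, f.path)
        trace.append(("transmitted", p_after_geom, "photons/s"))

    p_filtered = p_after_geom * f.f_filter
    trace.append(("after_filter", p_filtered, "photons/s"))
    p_d = p_filtered * f.f_detector_area
    trace.append(("at_detector", p_d, "photons/s"))
    trace.append(
        ("electrons", det_mod.electron_rate(p_d, train.detector), "electrons/s")
    )
    volts = det_mod.output_signal(
        p_d,
        train.wavelength_at_detector,
        train.detector,
        train.amplifier,
        clip=clip,
    )
    trace.append(("output", volts, "V"))
    return volts, trace


@dataclass
class CalibrationCurve:
    """A computed calibration curve on a concentration grid."""

    train_name: str
    concentrations: np.ndarray  # mol/L
    molecule_counts: np.ndarray
    outputs: np.ndarray  # volts
    stage_names: List[str] = field(default_factory=list)
    stage_rates: Optional[np.ndarray] = None  # (n_points, n_stages)
    interrogated_volume_L: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        """Tabulate the curve, one row per concentration."""
        data = {
            "concentration_M": self.concentrations,
            "molecule_count": self.molecule_counts,
        }
        if self.stage_rates is not None:
            for j, name in enumerate(self.stage_names):
                data[name] = self.stage_rates[:, j]
        data["output_V"] = self.outputs
        return pd.DataFrame(data)


def calibration_curve(
    train: OpticalTrain,
    c_min: float,
    c_max: float,
    n_points: int = 50,
    spacing: Literal["log", "linear"] = "log",
    *,
    clip: bool = True,
) -> CalibrationCurve:
    """Sweep a concentration grid and compute the calibration curve.

    Molecule counts use the interrogated volume: the intersection of the
    illuminated and viewed regions of the sample, not the full channel.
    """
    if not c_min < c_max:
        raise InvalidParameterError("c_min must be < c_max")
    if n_points < 2:
        raise InvalidParameterError("n_points must be >= 2")
    if spacing == "log":
        if c_min <= 0.0:
            raise InvalidParameterError("log spacing requires c_min > 0")
        grid = np.logspace(math.log10(c_min), math.log10(c_max), n_points)
        grid[0], grid[-1] = c_min, c_max  # endpoints exact
    elif spacing == "linear":
        grid = np.linspace(c_min, c_max, n_points)
    else:
        raise InvalidParameterError(f"unknown spacing {spacing!r}")

    volume = _chain_factors(train).interrogated_volume_L
    outputs = np.empty_like(grid)
    stage_names: List[str] = []
    rates: List[List[float]] = []
    for i, c in enumerate(grid):
        volts, trace = signal_at_concentration(train, float(c), clip=clip)
        outputs[i] = volts
        if not stage_names:
            stage_names = [name for name, _, _ in trace[:-1]]
        rates.append([value for _, value, _ in trace[:-1]])
    counts = np.array([sm.molecule_count(float(c), volume) for c in grid])
    return CalibrationCurve(
        train_name=train.name,
        concentrations=grid,
        molecule_counts=counts,
        outputs=outputs,
        stage_names=stage_names,
        stage_rates=np.array(rates),
        interrogated_volume_L=volume,
    )


def _response(train: OpticalTrain, c: float) -> float:
    """Monotone-increasing detection response in volts.

    The unclipped signal for fluorescence; the transmission *dip*
    ``signal(0) - signal(C)`` for absorption.
    """
    s, _ = signal_at_concentration(train, c, clip=False)
    if train.mode == "absorption":
        s0, _ = signal_at_concentration(train, 0.0, clip=False)
        return s0 - s
    return s


def find_mdl(train: OpticalTrain, noise_floor: Optional[float] = None) -> float:
    """Minimum detection limit: the molarity where the calibration curve
    crosses the detector noise floor.

    Solved by bracketed bisection (Brent) on the unclipped response, seeded
    with the linear-regime closed form ``noise / slope``.  Raises
    :class:`UnattainableError` when the response never reaches the floor
    within [1e-15, 10] mol/L.
    """
    noise = train.detector.noise_floor if noise_floor is None else noise_floor
    if noise <= 0.0:
        raise InvalidParameterError("noise floor must be > 0 V")
    return _crossing(train, noise, "noise floor")


def _crossing(train: OpticalTrain, level: float, what: str) -> float:
    top = _response(train, _C_HI)
    if top < level:
        raise UnattainableError(
            f"{what} of {level} V is never reached: the response tops out at "
            f"{top:.3e} V within [{_C_LO:g}, {_C_HI:g}] mol/L",
            asymptote=top,
        )
    bottom = _response(train, _C_LO)
    if bottom >= level:
        raise UnattainableError(
            f"{what} of {level} V is already exceeded at {_C_LO:g} mol/L "
            f"(response {bottom:.3e} V)"
        )
    # linear-regime slope for the initial guess
    c0 = 1e-12
    slope = _response(train, c0) / c0
    guess = level / slope if slope > 0.0 else math.sqrt(_C_LO * _C_HI)
    guess = min(max(guess, _C_LO * 10.0), _C_HI / 10.0)
    lo, hi = guess / 4.0, guess * 4.0
    while _response(train, lo) > level and lo > _C_LO:
        lo = max(lo / 16.0, _C_LO)
    while _response(train, hi) < level and hi < _C_HI:
        hi = min(hi * 16.0, _C_HI)
    c = brentq(lambda x: _response(train, x) - level, lo, hi, rtol=1e-10)
    return float(c)


@dataclass
class DynamicRangeResult:
    """Dynamic range of a train: saturation concentration over MDL.

    ``saturation_reached`` is False when Beer-Lambert flattening keeps the
    optical signal below the detector saturation at any concentration; the
    range is then open-ended and ``asymptote_V`` reports the limiting signal.
    """

    factor: float
    mdl: float
    c_saturation: Optional[float]
    saturation_reached: bool
    asymptote_V: Optional[float] = None

    def __float__(self) -> float:
        return self.factor


def dynamic_range(
    train: OpticalTrain,
    noise_floor: Optional[float] = None,
    saturation: Optional[float] = None,
) -> DynamicRangeResult:
    """Ratio of the highest assayable concentration to the MDL.

    The saturation crossing is solved on the *unclipped* curve; because the
    exact Beer-Lambert exponential flattens at high concentration, the factor
    can exceed the purely electronic ratio saturation/noise.
    """
    sat = train.detector.saturation if saturation is None else saturation
    mdl = find_mdl(train, noise_floor)
    try:
        c_sat = _crossing(train, sat, "saturation")
    except UnattainableError as err:
        return DynamicRangeResult(
            factor=math.inf,
            mdl=mdl,
            c_saturation=None,
            saturation_reached=False,
            asymptote_V=err.asymptote,
        )
    return DynamicRangeResult(
        factor=c_sat / mdl,
        mdl=mdl,
        c_saturation=c_sat,
        saturation_reached=True,
    )


@dataclass
class SensitivityResult:
    """Partial derivative of the signal with respect to one parameter."""

    parameter: str
    value: float  # the parameter value the derivative is taken at
    derivative: float  # dS/dp, volts per parameter unit
    normalized: float  # (dS/dp) * p / S, dimensionless


def _get_by_path(train: OpticalTrain, path: str):
    parts = path.split(".")
    obj = train
    for part in parts[:-1]:
        obj = getattr(obj, part)
        if obj is None:
            raise InvalidParameterError(
                f"parameter path {path!r}: {part!r} is not set on this train"
            )
    return obj, parts[-1]


def sensitivity(
    train: OpticalTrain,
    parameter_path: str,
    c: float,
    rel_step: float = 1e-4,
) -> SensitivityResult:
    """Central-difference sensitivity of the output to a named parameter.

    ``parameter_path`` is a dotted attribute path into the train, e.g.
    ``"source.power"`` or ``"collection.x3"``.  The normalized sensitivity is
    the logarithmic derivative: 1 for purely multiplicative parameters, -2
    for inverse-square distances.
    """
    parent, attr = _get_by_path(train, parameter_path)
    p0 = getattr(parent, attr)
    if not isinstance(p0, (int, float)) or isinstance(p0, bool) or p0 is None:
        raise InvalidParameterError(
            f"parameter {parameter_path!r} is not numeric (value {p0!r})"
        )
    p0 = float(p0)
    if p0 == 0.0:
        raise InvalidParameterError(
            f"cannot take a relative step at {parameter_path!r} = 0"
        )

    def eval_at(p: float) -> float:
        t = train.model_copy(deep=True)
        par, at = _get_by_path(t, parameter_path)
        setattr(par, at, p)
        s, _ = signal_at_concentration(t, c, clip=False)
        return s

    h = p0 * rel_step
    s_plus = eval_at(p0 + h)
    s_minus = eval_at(p0 - h)
    s0, _ = signal_at_concentration(train, c, clip=False)
    deriv = (s_plus - s_minus) / (2.0 * h)
    normalized = deriv * p0 / s0 if s0 != 0.0 else math.nan
    return SensitivityResult(
        parameter=parameter_path, value=p0, derivative=deriv, normalized=normalized
    )


@dataclass
class PerformanceSummary:
    """MDL, dynamic range and responsivity slope for one train."""

    name: str
    mdl: Optional[float]  # mol/L
    dynamic_range: Optional[float]
    slope: Optional[float]  # volts per mol/L in the linear regime
    error: Optional[str] = None


def design_sweep(
    trains: Sequence[OpticalTrain],
    noise_floor: Optional[float] = None,
) -> pd.DataFrame:
    """Tabulate MDL, dynamic range and linear-regime slope per train.

    Individual train failures are reported in the ``error`` column rather
    than aborting the sweep.
    """
    if len(trains) == 0:
        raise InvalidParameterError("design_sweep requires at least one train")
    rows = []
    for train in trains:
        summary = PerformanceSummary(train.name, None, None, None)
        try:
            c0 = 1e-12
            summary.slope = _response(train, c0) / c0
            summary.mdl = find_mdl(train, noise_floor)
            summary.dynamic_range = dynamic_range(train, noise_floor).factor
        except (UnattainableError, ConfigurationError, InvalidParameterError) as e:
            summary.error = str(e)
        rows.append(
            {
                "name": summary.name,
                "mode": train.mode,
                "geometry": train.geometry,
                "optics": f"{train.excitation.kind}/{train.collection.kind}",
                "sample": train.sample.kind,
                "source": train.source.name,
                "detector": train.detector.name,
                "mdl_M": summary.mdl,
                "dynamic_range": summary.dynamic_range,
                "slope_V_per_M": summary.slope,
                "error": summary.error,
            }
        )
    return pd.DataFrame(rows)
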