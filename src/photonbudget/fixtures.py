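"""Representative example systems: the 36-combination design grid.

The grid crosses three optics options (lens coupling, no optics, fiber
optics), two sample arrangements per optics option (100 um square
microchannel vs. 100 um thin film for lens/no-optics; cross-channel vs.
coaxial fiber coupling for fibers), three LED sources (10 and 150 degree blue
LEDs, a 120 degree UV LED) and two detectors (a SiPM with a 1 mV noise floor
and 500 mV saturation, and an amplified photodiode with a 1 mV floor and 5 V
saturation): 3 x 2 x 3 x 2 = 36 fluorescence systems.

Geometry follows the canonical bench layout: 1.5 cm focal length / 1.5 cm
diameter lenses with the source at 2F, 100 um square channels, 100 um films,
100 um core fibers, and a 1,000 um channel length for the coaxial case.

All component values (LED powers, fluorophore photophysics, filter and
detector electrical parameters, distances) are REPRESENTATIVE datasheet-style
numbers chosen to be realistic for this class of hardware; they are not the
specifications of any particular commercial part.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Union

from .calibration import (
    CollectionCoupling,
    ExcitationCoupling,
    OpticalTrain,
)
from .config import SystemConfig, save_config
from .coupling import FiberSpec, LensSpec
from .detection import DetectorSpec, FilterSpec
from .sample import AnalyteSpec, SampleSpec
from .sources import SourceSpec

__all__ = [
    "blue_led_10deg",
    "blue_led_150deg",
    "uv_led_120deg",
    "fluorescein_like",
    "microchannel_100um",
    "thin_film_100um",
    "standard_lens",
    "standard_fiber",
    "emission_filter",
    "sipm_detector",
    "amplified_photodiode",
    "build_train",
    "fixture_grid",
    "generate_fixtures",
]


def blue_led_10deg() -> SourceSpec:
    """Collimated blue LED: 5 mW at 470 nm into a 10 degree full cone."""
    return SourceSpec(
        name="10deg-blue-led",
        power=5e-3,
        wavelength=470.0,
        full_emission_angle=10.0,
        emitting_area=1e-3,
    )


def blue_led_150deg() -> SourceSpec:
    """The same blue LED die with little collimation: 150 degree full cone."""
    return SourceSpec(
        name="150deg-blue-led",
        power=5e-3,
        wavelength=470.0,
        full_emission_angle=150.0,
        emitting_area=1e-3,
    )


def uv_led_120deg() -> SourceSpec:
    """UV LED: 2 mW at 365 nm into a 120 degree full cone."""
    return SourceSpec(
        name="120deg-uv-led",
        power=2e-3,
        wavelength=365.0,
        full_emission_angle=120.0,
        emitting_area=1e-3,
    )


def fluorescein_like() -> AnalyteSpec:
    """A fluorescein-like dye with representative (not measured) constants."""
    return AnalyteSpec(
        name="fluorescein-like", epsilon=8.0e4, quantum_yield=0.9
    )


def microchannel_100um(length: float = 1.0) -> SampleSpec:
    """100 um square microchannel of the given length (cm)."""
    return SampleSpec(
        kind="microchannel",
        width=0.01,
        depth=0.01,
        length=length,
        analyte=fluorescein_like(),
    )


def thin_film_100um() -> SampleSpec:
    """100 um thick film with 1 cm^2 lateral extent."""
    return SampleSpec(
        kind="thin_film",
        thickness=0.01,
        film_area=1.0,
        analyte=fluorescein_like(),
    )


def standard_lens() -> LensSpec:
    """1.5 cm focal length, 1.5 cm diameter lens."""
    return LensSpec(radius=0.75, focal_length=1.5)


def standard_fiber() -> FiberSpec:
    """100 um core diameter multimode fiber, NA 0.22 in air."""
    return FiberSpec(
        core_radius=0.005, numerical_aperture=0.22, medium_refractive_index=1.0
    )


def emission_filter() -> FilterSpec:
    """40 nm FWHM interference filter, 90% peak transmission, against a
    100 nm wide fluorescence line."""
    return FilterSpec(fwhm=40.0, transmission_efficiency=0.9, emission_bandwidth=100.0)


def sipm_detector() -> DetectorSpec:
    """Silicon photomultiplier: 1 mV noise floor, 500 mV saturation.

    QE, gain and transimpedance are representative readout values.
    """
    return DetectorSpec(
        name="sipm",
        active_area=0.01,
        quantum_efficiency=0.20,
        gain=1e6,
        transimpedance=1e5,
        noise_floor=1e-3,
        saturation=0.5,
    )


def amplified_photodiode() -> DetectorSpec:
    """Amplified photodiode: 1 mV noise floor, 5 V saturation.

    Responsivity 0.25 A/W at gain 1 with a 5e8 V/A transimpedance stage;
    representative values.
    """
    return DetectorSpec(
        name="ampd",
        active_area=0.06,
        quantum_efficiency=0.65,
        gain=1.0,
        responsivity=0.25,
        transimpedance=5e8,
        noise_floor=1e-3,
        saturation=5.0,
    )


# Fluorescein-like emission peak used for the detector response, nm.
_EMISSION_WAVELENGTH = 520.0

_SOURCES = {
    "blue10": blue_led_10deg,
    "blue150": blue_led_150deg,
    "uv120": uv_led_120deg,
}
_DETECTORS = {"sipm": sipm_detector, "ampd": amplified_photodiode}


def build_train(optics: str, sample: str, source: str, detector: str) -> OpticalTrain:
    """Assemble one fluorescence train from grid coordinates.

    ``optics``: lens | none | fiber; ``sample``: microchannel | thin_film
    (lens/none) or cross | coaxial (fiber); ``source``: blue10 | blue150 |
    uv120; ``detector``: sipm | ampd.
    """
    src = _SOURCES[source]()
    detspec = _DETECTORS[detector]()
    if optics == "lens":
        excitation = ExcitationCoupling(kind="lens", lens=standard_lens(), x1=3.0)
        collection = CollectionCoupling(kind="lens", lens=standard_lens(), x3=1.5)
        samp = microchannel_100um() if sample == "microchannel" else thin_film_100um()
        geometry = "perpendicular"
    elif optics == "none":
        excitation = ExcitationCoupling(kind="none", distance=0.5)
        collection = CollectionCoupling(kind="none", distance=0.5)
        samp = microchannel_100um() if sample == "microchannel" else thin_film_100um()
        geometry = "perpendicular"
    elif optics == "fiber":
        if sample == "cross":
            excitation = ExcitationCoupling(
                kind="fiber", fiber=standard_fiber(), distance=0.1
            )
            collection = CollectionCoupling(
                kind="fiber", fiber=standard_fiber(), gap=0.01
            )
            samp = microchannel_100um()
            geometry = "cross"
        elif sample == "coaxial":
            excitation = ExcitationCoupling(
                kind="fiber", fiber=standard_fiber(), distance=0.2
            )
            collection = CollectionCoupling(
                kind="fiber", fiber=standard_fiber(), gap=0.2
            )
            samp = microchannel_100um(length=0.1)
            geometry = "coaxial"
        else:
            raise ValueError(f"fiber optics pair with cross/coaxial, not {sample!r}")
    else:
        raise ValueError(f"unknown optics option {optics!r}")
    return OpticalTrain(
        name=f"{optics}_{sample}_{source}_{detector}",
        mode="fluorescence",
        geometry=geometry,
        source=src,
        excitation=excitation,
        sample=samp,
        collection=collection,
        optical_filter=emission_filter(),
        detector=detspec,
        detection_wavelength=_EMISSION_WAVELENGTH,
    )


def fixture_grid() -> List[SystemConfig]:
    """All 36 grid systems as validated configurations."""
    configs = []
    for optics in ("lens", "none", "fiber"):
        samples = ("cross", "coaxial") if optics == "fiber" else (
            "microchannel",
            "thin_film",
        )
        for sample in samples:
            for source in _SOURCES:
                for detector in _DETECTORS:
                    train = build_train(optics, sample, source, detector)
                    configs.append(SystemConfig(train=train))
    return configs


def generate_fixtures(out_dir: Union[str, Path]) -> List[Path]:
    """Write the 36 grid systems as YAML files into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for cfg in fixture_grid():
        paths.append(save_config(cfg, out / f"{cfg.train.name}.yaml"))
    return paths
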