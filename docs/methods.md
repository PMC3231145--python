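# Methods

## Scope and modelling approach

`photonbudget` models an optical micro-analytical instrument as a chain of
components, each reducing to a small number of datasheet parameters, linked
by dimensionless geometric transport fractions. The approach is deliberately
algebraic: each stage factor is a closed-form expression (solid-angle ratios,
thin-lens conjugates, circle/strip overlaps, Beer–Lambert attenuation),
and the detector output is their product times the source photon rate. The
single exception is coaxial fiber coupling into the ends of a microchannel,
which requires one numerical integration along the channel axis. This trades
fine optical detail (aberrations, diffraction, partial coherence) for
completeness and speed: a full calibration curve costs microseconds, so
large design sweeps are cheap. The methodology is scale-independent and
applies equally to macroscopic trains.

Throughout, components are assumed concentric and coaxial ("properly
aligned"); misalignment is out of scope. Units are fixed: cm, cm², nm,
degrees, steradians, mol/L, volts, A/W, V/A.

## Stage models and assumptions

**Source.** A source is monochromatic at its nominal wavelength, emits
uniformly over its area A_S and uniformly over the solid angle of its full
emission cone 2θ, `Ω_S = 2π(1 − cos θ)`. Lumen ratings convert to watts by
`W = lm / (683 · V(λ))`, where the luminous efficacy is interpreted as the
dimensionless luminosity-function value V(λ) with no additional loss terms.
Watts convert to photons/s with the rounded constant 5.03e15 per (W·nm) by
default — chosen for arithmetic compatibility with spreadsheet-style hand
calculations in this field — with `exact=True` switching to CODATA 1/(hc)
(0.08% difference). Spectral power distributions, temperature/current
dependence and polarization are not modelled.

**Lens coupling.** The intercepted fraction uses the flat-disk aperture
solid angle `πR²/x²` rather than the spherical cap; the `exact` flag enables
the cap form for validation. The flat-disk error is below the Monte-Carlo
resolution (3σ at 10⁶ samples) for apertures subtending half-angles of a
few degrees and grows to ~18% for a 0.75 cm lens at 1.5 cm — users probing
such close-up geometries should audit with the sampler. Lens transmission
losses are ignored. Focal-spot area scales as (x₂/x₁)² by default (the
physical area magnification); a `linear` mode scaling as x₂/x₁ is provided
because simplified treatments sometimes quote the linear ratio, and the two
agree at the unit-magnification layout (x₁ = x₂ = 2F) used by the example
systems.

**Spot/view/channel overlap.** The focal spot and detector-view region are
concentric circles centred on the channel; all nine relative-size cases
then reduce to (i) circle∩strip, closed form via circular segments, and
(ii) concentric circle∩circle, the smaller circle. The triple intersection
is therefore also closed-form; tests verify it against independent
quadrature to 1e-6.

**Sample.** Beer–Lambert is base-e exactly as written (`e^{−εCl}`);
conventional decadic datasheet coefficients are converted via ln 10 with the
analyte's `decadic` flag. Re-absorption of fluorescence at the emission
wavelength (inner-filter effect), photobleaching, quenching and scattering
are neglected: only excitation attenuation is modelled. Fluorescence is
isotropic (4π).

**Collection.** A single lens collects `R²/(4x₃²)` of isotropic emission,
capped at 0.5: one-sided optics cannot exceed a hemisphere. (The uncapped
form is unphysical for x₃ < R/√2.) A bare detector collects
`A/(4πd²)` with the same cap. A fiber collects the line-of-sight fraction
`min(πR_F², Ω_F d²)/(4πd²)`, saturating at Ω_F/4π at the fiber face;
waveguiding of emission along the liquid channel is not modelled.

**Coaxial integration.** Excitation entering a channel end decays as
`p(x) = p₀e^{−εCx}`; each slice absorbs `p(x)εC dx`, re-emits with the
quantum yield, and the collection fiber at the far end captures the
line-of-sight fraction at distance `d(x) = (L−x) + gap`. The integral is
trapezoidal on a uniform grid, default 1000 slices (second-order
convergent; doubling changes the result by <1e-6 relative at the default
settings, and fewer than 100 slices is rejected). Cross-channel fiber
illumination treats the beam as collimated over the ~100 µm crossing. The
source-fiber-to-channel interface is assumed lossless; fiber attenuation is
a single scalar transmission efficiency.

**Detection.** The filter factor is `min(1, FWHM/bandwidth) × peak
transmission` — a top-hat approximation of both the filter band and the
emission line; absolute spectrometer modelling is out of scope. The
detector voltage comes either from a responsivity (A/W at gain 1, scaled by
gain) or from the electron rate `P_D·QE·G` times the elementary charge
(1.602e-19 C); both paths end in a transimpedance (V/A) and optional analog
amplification. The transimpedance parameter is the bridge between a
photon/electron budget and the volt-denominated noise floor and saturation
of real detector modules. Saturation is hard clipping; noise spectra,
dark counts and shot-noise statistics are not modelled, and pulse counting
is represented only by the electron rate in counts/s.

## Figures of merit

The MDL is a deterministic threshold crossing — the concentration at which
the unclipped calibration curve equals the detector noise floor — not a
statistical (3σ/ROC) detection limit. It is solved by Brent bisection to
1e-10 relative tolerance on a bracket grown geometrically from the
linear-regime closed form noise/slope, within [1e-15, 10] mol/L; outside
that bracket an unattainable-MDL error reports the limiting signal. For
absorption mode the monotone response used is the transmission dip
`signal(0) − signal(C)`. The dynamic range divides the saturation crossing
of the *unclipped* curve by the MDL; with exact Beer–Lambert attenuation
the curve flattens at high concentration, so the factor can exceed the
electronic ratio saturation/noise, or the range becomes open-ended (the
result then carries the optical asymptote). Sensitivities are central
finite differences at a relative step of 1e-4, reported also in normalized
(logarithmic-derivative) form.

Molecule counts use the interrogated volume: the intersection of the
illuminated and viewed sample regions (spot∩view∩channel footprint times
the optical depth), not the full channel volume, since only those molecules
contribute signal.

## The Monte-Carlo oracle

The sampler draws photon origins uniformly over the emitting disk and
directions uniformly over the emission solid angle (cosθ uniform over the
spherical cap — the exact steradian measure, not uniform in polar angle),
propagates straight lines, and counts interceptions by a disk (optionally
gated by an acceptance half-angle, modelling a fiber NA) or a strip. The
estimate is an unbiased binomial proportion with standard error
√(p(1−p)/n), bit-reproducible for a fixed seed. It validates solid-angle
interception only: there is no refraction through lens surfaces, so it
checks the *geometric* factors, not imaging.

## Example systems and what they do (not) show

The 36-system grid in `photonbudget.fixtures` crosses lens / no-optics /
fiber coupling, microchannel vs. thin-film samples (cross vs. coaxial for
fibers), three LEDs (10° and 150° blue at 5 mW/470 nm, 120° UV at
2 mW/365 nm) and two detectors (SiPM: 1 mV floor, 500 mV saturation;
amplified photodiode: 1 mV floor, 5 V saturation). Geometry: 1.5 cm
focal-length/diameter lenses with the source at 2F and the collection lens
at 1.5 cm; 0.5 cm stand-off for no-optics; 100 µm square channels; 100 µm
films; 100 µm-core NA-0.22 fibers, with the coaxial fibers set back 0.2 cm
from the source and the 1,000 µm channel end. The fluorophore is
fluorescein-like (ε = 8e4 L·mol⁻¹·cm⁻¹ base-e, QY = 0.9); the filter
passes 40 of 100 nm at 90%.

All of these are *representative* datasheet-style values, not the
specifications of particular commercial parts, and several (detector
transimpedance, fiber set-backs, LED powers) are only order-of-magnitude
realistic. Consequently the grid demonstrates the *relative* behaviour of
designs — thin films beat microchannels (more molecules in the viewed
volume), lens coupling beats no optics beats coaxial fibers, narrow-cone
LEDs beat wide ones — and spans MDLs from ~2 pM to ~40 µM, but its absolute
MDL values should not be read as predictions for any specific instrument.
Passing tests show the budget arithmetic and orderings are right, not that
any particular hardware reaches these numbers; real systems add background
light, autofluorescence, alignment error and detector noise statistics that
this model excludes.

## Numerical choices

- Root finding: Brent on a geometrically expanded bracket, deterministic,
  no randomness anywhere outside the Monte-Carlo oracle.
- Coaxial quadrature: trapezoid, 1000 slices default, minimum 100.
- Concentration grids: default 1e-12 to 1e-3 mol/L, 10 points/decade, log
  spacing with exact endpoints.
- Degenerate inputs: zero concentration gives exactly zero fluorescence and
  full transmission; zero power propagates to zero volts; capped fractions
  reach their bounds exactly (e.g. 360° → 4π, tangent spot → 1).
- Exports format floats at six significant digits so identical inputs give
  byte-identical files; every exported table carries the configuration hash
  and tool version.
- Constants fixed: 683 lm/W, 5.03e15 photons/(W·nm), Avogadro 6.022e23,
  elementary charge 1.602e-19 C.
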