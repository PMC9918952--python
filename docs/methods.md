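# Methods

## Recording model

The instrument is a point-source lensless microscope: a multi-wavelength
coherent point source at distance `d` from a color sensor, the sample at
distance `z` from the sensor (`0 < z < d`, sample close to the source).
For each wavelength λᵢ the sensor-plane intensity is the in-line Gabor
hologram

    I_λ(x, y) = |A_ref + A_obj|²
              = |A_ref|² + |A_obj|² + A_ref·A_obj* + A_ref*·A_obj ,

whose two interference terms carry the object and its conjugate twin.  The
simulator never linearizes this expression: it propagates the full complex
transmittance `t·e^{iφ}` and squares, so the `|A_obj|²` self-interference
term is present and the weak-diffraction condition (`A_ref ≫ A_obj`) is a
*checked assumption* — `forward_hologram` warns when the object-wave RMS
exceeds 0.3 of the reference.

**Point-source handling (Fresnel scaling).**  All fields live on the sensor
grid in a plane-wave-equivalent frame: the spherical-reference recording at
magnification `M = d/(d−z)` is treated as a plane-wave recording of the
M-magnified object propagated by `z_eq = M·z`.  Scenes are generated
directly at the demagnified pitch `p/M` on the sensor's pixel grid, so no
resampling is ever needed, and because simulator and retrieval share the
convention it cancels exactly in round trips.  Chromatic focus shifts from
the sample slide are modelled as per-wavelength additive offsets to `z_eq`
(object-side shifts scale by the longitudinal magnification M², so
millimeter-scale offsets in the working frame correspond to micrometer
slide dispersion).

## Propagation

Two free-space propagators share a zero-padded (factor 2 by default) FFT
pipeline with pixel-centered coordinates and frequencies in cycles/m:

* **Angular spectrum** (default): multiplication by
  `exp(+j2πz·sqrt(1/λ² − f²))`; evanescent components are set to zero, so
  the operator is exactly unitary on the propagating band and forward /
  backward propagation are exact inverses — the property the iterative
  constraints rely on.
* **Rayleigh–Sommerfeld convolution**: FFT convolution with the sampled
  first-kind impulse response `(1/2π)(e^{jkr}/r)(z/r)(1/r − jk)`.  It is
  kept as an independent numerical route and agrees with the angular
  spectrum to better than 1e−6 RMS on band-limited paraxial fields; a
  sampling check warns when the kernel chirp exceeds the grid Nyquist
  frequency (short distances on fine grids).

Sign convention: `exp(+jkr)` diverging from the source; positive distances
propagate object → sensor, reconstruction uses negative distances.

**Background splitting.**  Hologram-plane fields sit on a near-unity
pedestal that physically extends beyond the sensor window.  Propagating
such a field on a zero-padded grid turns the window edge into a diffracting
aperture; the resulting edge wave decays only algebraically and, inside an
iterative loop, accumulates instead of averaging out (measured on the bar
fixture: the object-plane error *grew* per cycle).  The propagator
therefore accepts a `background` argument: the pedestal (a scalar, by
default estimated from an 8-pixel border mean) is subtracted, the deviation
is transformed, and the pedestal is re-added with its exact on-axis phase
`e^{+j2πz/λ}`.  Simulator and retrieval both use this path; with it the
object-plane error decreases monotonically over the iteration cycles.

## Preprocessing

Stages run in recording order, matching the calibration a real instrument
performs once:

* **Demosaic** — mask-weighted (normalized) triangular convolution per
  channel with kernel radius equal to the CFA tile size; CFA sample sites
  keep their raw values exactly, and on Bayer-type 2×2 tiles the fill
  reduces to classic bilinear interpolation (affine intensity ramps are
  reproduced to round-off away from the borders).  Patterns: `mono`,
  `checker2`, Bayer `rggb` (3 channels), and a Truesense-style 4×4 `rgbw`.
* **Background equalization** — against a sample-free flat frame.  Default
  is subtractive (`I − flat + mean(flat)`), matching the view of the flat
  as the measured first term of the hologram expansion; a ratiometric mode
  (`I · max(flat)/flat`) exactly inverts the multiplicative cos⁴ vignette
  of the spherical reference and is used when the illumination profile is
  the dominant nonuniformity.
* **Crosstalk** — the n×n sensor-response matrix L maps true
  per-wavelength intensities to recorded channel intensities.  Calibration
  measures `L[i,j]` as the mean of channel i under illumination j alone and
  normalizes each column to unit sum, which removes the per-source power
  and makes the estimate invariant to global exposure; the per-wavelength
  scale freedom this leaves is absorbed later by the amplitude constraint.
  Demixing applies `L⁻¹` pixelwise; a condition-number bound (default 1e3)
  rejects inseparable channel sets, and negative residuals are clipped at
  zero with the clipped fraction reported (warning above 1 %).
* **Registration** — per-channel similarity correction relative to the
  shortest wavelength (the resolution reference).  Coarse scale from
  log-polar correlation of windowed Fourier magnitudes, sub-pixel shift
  from windowed phase correlation, then both are refined by maximizing the
  normalized cross-correlation of the resampled channel against the
  reference.  Measured accuracy on textured fixtures: shifts to ±0.01 px,
  scales to ±1e−4.  Estimation runs on focused reconstructions; the stored
  parameters are applied to the holograms by bicubic warping (identity
  parameters pass through bit-identically).

## Iterative retrieval

Inputs are the n true holograms and one focus distance per wavelength
(given, or found by autofocus).  One pass:

1. `A0ᵢ = √Iᵢ` at the hologram plane, phase zero;
2. back-propagate each by `−zᵢ`;
3. estimate each field's global background phase (circular median of the
   phase over the lowest-gradient half of the amplitude) and rotate it to
   zero, so the spectra add coherently instead of cancelling;
4. merge: `Õ = IFFT(Σᵢ wᵢ·FFT(Oᵢ))`.

Each of the m cycles then splits `Õ` into n copies, restores the removed
background phases, forward-propagates `+zᵢ`, replaces each modulus with the
measured `A0ᵢ` while keeping the retrieved phase, and repeats steps 2–4.
The object term is reinforced identically by every channel while each twin
defocuses differently, so the twins wash out; analytically the object
coefficient follows 1/2, 3/4, 7/8, … per cycle, and `m = 2` (the default)
captures most of the gain.  The residual log holds `m + 1` rows of
per-wavelength hologram-plane RMS misfits; if the aggregate misfit grows
twice in a row the best iterate is returned with a divergence warning.  An
optional object-support mask resets the amplitude outside the support to
the background level each cycle.

**Weight masks.**  Wavelength λᵢ contributes a passband `|f| ≤ na/λᵢ`,
where `na` is the collection NA expressed in the working frame (geometry
NA divided by M).  At every frequency the weight is the passband indicator
divided by the number of wavelengths covering that frequency: weights sum
to one over the union of passbands and zero outside, so information shared
by several channels is averaged rather than accumulated (no low-frequency
enhancement) and the union — set by the shortest wavelength — fixes the
resolution.  A raised-cosine edge (`mask_softness`) is available to reduce
ringing at the cutoffs; the default is hard edges.

**Autofocus.**  The scan metric is the Tamura coefficient (`√(σ/μ)` of
intensity) of the *scattered* field `|U − median(U)|`, not of the raw
amplitude: a pure phase object has minimal amplitude contrast exactly at
focus and would invert the criterion, whereas the scattered energy is
propagation-invariant and maximally concentrated at focus for amplitude
and phase objects alike.  The discrete peak is refined parabolically; a
flat or boundary-peaked curve raises "focus not bracketed".  Focus
accuracy is limited by the depth of field `λ/na²`, which at the toolkit's
default fixture NA is several coarse steps wide.

## Quality metrics

All metrics first normalize the image by its own maximum, making them
invariant to global rescaling.

* **Background STD** over a user-supplied object-free mask.
* **Profile contrast**: Michelson contrast from the mean detected maxima /
  minima along a linearly interpolated line profile (linear interpolation —
  cubic splines overshoot at bar edges and fake extrema).
* **Finest resolved element**: for each chart element, the profile across
  the three bars must show the bars separated by inter-bar maxima with at
  least a 26.4 % Rayleigh-type dip (configurable); the report returns the
  smallest resolved period or the coarsest failure.
* **Twin-plane ratio**: the hologram-plane field is reconstructed at `−z`
  (object) and `+z` (twin); both high-passed amplitude images are
  correlated with the known chart pattern and the correlations ratioed.
  A raw real-valued hologram scores exactly 1 (conjugate symmetry); twin
  suppression drives the ratio toward 0.  A plain high-passed *energy*
  ratio is kept as a template-free fallback but is insensitive for
  coherent fields, because defocus converts focused structure into
  high-frequency fringes of comparable energy — the template form is the
  meaningful instrument on synthetic data.

## Synthetic study conditions

The test and acceptance fixtures use a scaled-down geometry that preserves
the operating point of the instrument class — magnification 20× and
NA ≈ 0.21 — on a 512² sensor: `d = 2.5 mm`, `z = 2.375 mm`, 2 µm pitch,
giving `z_eq = 47.5 mm`, a 51 µm object field and a 1.9 µm violet
diffraction limit.  Wavelengths follow the four-channel instrument
(405 / 450 / 520 / 630 nm), with per-wavelength focus offsets from a
Cauchy-dispersion model of a 1 mm glass slide.  Bar targets default to
transmittance 0.7 (weak-object RMS well under the checked bound); bead
phantoms are phase disks with an optional transmittance dip standing in
for scattering loss.  Sensor defaults: 12-bit quantization, shot noise at
2500 photoelectrons per unit (reference-level) intensity, Gaussian read
noise of 0.005 intensity units, diagonally dominant crosstalk with ~10 %
adjacent-channel leakage.  Problem sizes were chosen so the full test
suite and the acceptance evaluation each complete in minutes on one CPU.

What the generator does **not** emulate: speckle and other per-channel
coherent noise sources (dust, multiple reflections), partial coherence,
sensor MTF/fill-factor, dark-frame nonuniformity, or spectrally broadband
illumination.  Passing tests therefore demonstrate the geometry, the
algebra and the twin-suppression mechanism — not robustness to the
coherent-artifact budget of a physical instrument.

One consequence is worth stating explicitly: on these noiseless-to-mildly-
noisy fixtures the reconstruction background is dominated by residual twin
terms, which are *correlated* between spectrally close channels.  The
background STD drops steeply from one to three channels (≈ 35 %), but
adding a fourth channel at 450 nm — whose twin correlates ~0.8 with the
405 nm twin and has the largest single-channel twin STD — can leave the
background STD flat or ~2 % higher than the three-channel result.  In
laboratory data the same progression is reported as monotone because the
averaged quantity there is per-channel coherent noise, which decorrelates
across channels; with a coherent-noise term in the generator the monotone
trend would be expected to reappear.

## Numerical choices and degenerate inputs

* Internal units are SI meters throughout; the CLI config is also in
  meters.  `k` in the resolution formula defaults to 1 and is exposed.
* Anisotropic sensors: NA per axis; the scalar NA is the smaller axis
  (conservative).
* Evanescent frequencies are zeroed rather than attenuated, keeping the
  angular-spectrum operator exactly unitary on its band.
* Zero-amplitude pixels have undefined phase: reported as 0 with a flag
  mask.  Uniform (object-free) holograms reconstruct to a uniform field.
* USAF bar widths are rounded to whole pixels; the layout records the
  exact drawn geometry so metrics test what was actually rendered.
* Registration confidence below threshold, inseparable crosstalk matrices
  (condition > 1e3), unresolvable autofocus scans and non-finite fields
  all raise errors rather than degrade silently.

## Known limitations

* The Rayleigh–Sommerfeld route is sampling-limited: forward/backward
  round trips are good to ~1e−4 RMS, not machine precision; the angular
  spectrum is the default for exactly this reason.
* The plane-wave-equivalent convention ignores the slow spatial variation
  of magnification across a very deep sample; only per-wavelength global
  focus offsets are modelled.
* Autofocus on sparse pure-phase scenes carries a bias that is a fraction
  of the depth of field (the conjugate term tilts the sharpness curve);
  bar targets focus noticeably more sharply than bead phantoms.
* The background-phase estimator assumes the object occupies a minority of
  the field; dense scenes would need the pluggable estimator replaced.
* Channel registration assumes a similarity transform (isotropic scale +
  shift); it does not correct rotation or anisotropic distortion.
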