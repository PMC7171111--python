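# Methods

This note documents the models behind `ffsdoct`, their assumptions, the
defaults that matter, and the choices made where the design was open.

## Optical quantities

Reflectivities are normal-incidence Fresnel, single pass, with multiple
reflections neglected — adequate because every ocular interface is weak
(≤ 4%). The corneal stack defaults to air (1.0) | tear (1.336) | cornea
(1.376) | aqueous (1.336); tear and aqueous are physiological values and
the reference attenuator glass is a catalog 1.5, all configurable via
`MediumIndices`. Summing three interfaces gives 2.11%, the "around 2%"
design figure; summing only the air–tear interface would give 2.07%, so
the choice is not critical.

Lateral resolution is the Rayleigh criterion 0.61·λ/NA; axial resolution
is the Gaussian-spectrum coherence length (2 ln 2/π)·λ²/(Δλ·n). Both are
reported at full precision and rounded to two significant figures where a
design number is quoted.

**Defocus geometry.** The paraxial model: corneal displacement *d* toward
the objective puts the geometric focus at depth *n·d* (Snell stretch) and
the unchanged-reference coherence gate at *d/n* (optical-path
shortening), hence an optimal reference extension of (n² − 1)·d in
optical-path micrometres. The NA-averaged refinement of the full
defocus-correction theory is deliberately omitted: at NA 0.3 the paraxial
factor is accurate to well under the stated servo tolerances.

**Spherical aberration.** `aberrated_spot_size` traces a meridional fan
filling the NA, aimed in air at the point whose paraxial image sits at
the requested depth, through a single spherical surface (default
R = 7.8 mm, standard corneal anatomy) into a homogeneous n = 1.376
medium. Sphere intersection is analytic; refraction uses the vector
Snell law. The geometric blur is taken as the **full transverse spot
diameter** at the paraxial focal plane — the statistic a geometric
spot-diagram readout reports — and combined in quadrature with the
diffraction limit. RMS-based statistics were considered and rejected:
for this surface they sit near 2 µm at 550 µm depth, understating the
resolution loss a confocal system observes. At depth 0 the function
returns the diffraction limit exactly. Polarization, chromatic effects
and absorption are out of scope.

## Motion and spectrum

Axial apex motion is a sum of sinusoids plus white noise; the default
physiological components are breathing (0.34 Hz, 33 µm) and heartbeat
(1.1 Hz, 13 µm). Default synthesis is 60 s at 100 Hz when not specified
otherwise. The spectrum estimator removes the mean, applies a Hann
window with amplitude correction (2/Σw), and refines each local maximum
with a 3-point log-parabolic interpolation, which cancels the up-to-15%
Hann scalloping loss to below 1% for well-separated tones. Blink
intervals are excised and the longest blink-free stretch analyzed.
Because interpolated amplitudes of leaky (non-bin-aligned) tones can
overshoot by a few percent, the Parseval bound is exact only in the
bin-aligned regime; the recovery contract (≤ 5% amplitude error) holds
either way.

## SDOCT tracker

The B-scan forward model places Gaussian peaks (FWHM = the 3.9 µm SDOCT
precision bound; the actual source bandwidth behind that number is not
public, so precision is a configurable input rather than a derived
value) at cp₀ + d + e and ref₀ + e on a 2.7 mm window of 1024 pixels.
The 64-line lateral average is folded in as a 1/√64 noise reduction on a
single stored profile. Peaks leaving the window are simply absent — the
blink failure mode. Detection takes the largest local maximum in each
half-window (split defaults to 50%, configurable), with a log-domain
parabolic vertex (exact for Gaussian peaks, hence sub-0.1 µm noiseless
round trips) and a validity threshold of 5× the noise SD.

The state inversion e = ref − ref₀, d = (cp − cp₀) − e makes the corneal
estimate invariant to reference motion — the defining property of the
common-path geometry, tested over the full travel. Error is e − (n²−1)·d.

## Servo loop

The stage model is kinematic: velocity slewed at the acceleration limit
toward the deceleration-safe approach speed, capped at max velocity;
within the 2.2 µm accuracy band it settles at command + a uniform
(± accuracy) error drawn once per command (Gaussian optional).
Tracker measurements fire every 8.2 ± 0.5 ms (jittered), run the full
simulate → detect → invert chain, and add a uniform ± 1.95 µm measurement
error (half the SDOCT precision bound); commands latch the latest
optimal extension at 50 Hz. Simulation step is 1 ms. No predictive
filtering: the instrument commands the latest measurement, and the few-µm
mean |error| under physiological motion reproduces the bench behavior
without it. During blinks no measurement is produced and the last command
is held, which generates the characteristic error spikes; blink samples
are excluded from summaries. The in vivo error figures (≈ 7–11 µm)
include physiological measurement effects not modelled here and are
treated as plausibility context only.

## FFOCT engine

Frames are I_k = B + A·γ·cos(φ + kπ + δ_k): γ a Gaussian gate envelope
(FWHM = the coherence axial resolution), φ = 4π·h/λ from the height map,
δ_k the motion phase 4π·v·(k·Δt)/λ with Δt the 1.75 ms inter-frame time.
Shot noise is Gaussian with variance = signal/full-well (2 Me⁻).
Out-of-gate background is blurred with a Gaussian growing linearly at
0.02 px/µm beyond the ± 35 µm depth of focus — a qualitative stand-in for
the defocused surface view that leaks through when lateral motion breaks
common-mode cancellation. Retrieval divides by 2 so a unit-amplitude
fringe returns unit amplitude.

**Fringe masking.** Fringe peaks are detected as non-DC local maxima of
the magnitude spectrum exceeding 8× the local (15-bin median) spectrum
level, then zeroed with their conjugates over a 3-px disc; DC is always
preserved. A global median + k·MAD threshold on the log spectrum was
tried first and rejected: for band-limited images the statistics are
dominated by the empty high-frequency region, the threshold collapses,
and ordinary scene maxima get masked (scene correlation dropped to 0.74).
The local contrast ratio is scale-free and leaves fringe-free images
untouched to machine precision.

**Registration.** `register_and_average` uses plain (unnormalized)
cross-correlation via `skimage.registration.phase_cross_correlation` with
`normalization=None`: the phase-whitened default amplifies broadband
noise and mis-registered noisy tomographic frames by several pixels,
breaking the √n averaging law the 23-frame endothelial workflow relies
on.

## Angiography

Block matching is dense per-pixel ZNCC of 16 × 16 windows, evaluated for
every integer displacement inside the disc |Δ| ≤ v_max/(f·p) (8.38 px at
the 2 mm/s, 275 fps, 0.868 µm/px defaults; `search_radius` reports the
ceil bounding radius, 9 px). The disc constraint — not the bounding
square — is what guarantees recovered speeds never exceed the cap.
Correlations below 0.3 are discarded; textureless windows are invalid;
ties break toward the smaller displacement (the no-flow null).
Displacement is integer (matching the pixel-level description of the
method); optional parabolic sub-pixel refinement exists behind a flag but
is off by default. Eight frames yield seven fields; a pixel's velocity is
the mean of its valid displacement vectors (≥ 4 votes by default), its
orientation the angle of that mean.

## Phantoms

All generators are seeded (`PhantomSpec.seed`) and bit-exact
reproducible. Default field: 1.25 × 1.25 mm at 0.868 µm/px (1440²).
Particles render as Gaussian blobs of their physical FWHM combined in
quadrature with the 1.7 µm PSF.

* **Endothelial mosaic** — jittered hexagonal lattice at the requested
  density (spacing √(2/(√3·ρ)) ≈ 19.3 µm at 3096 mm⁻²); intensity is the
  margin between first and second nearest-centroid distances, giving
  bright interiors and dark borders.
* **Nerve plexus** — directed random walks (2 µm steps, angular
  diffusion SD 0.06, weak restoring pull toward the vertical axis);
  generation trims the final step so in-field centerline length equals
  density × area exactly.
* **Keratocytes** — per-depth Poisson fields of oval nuclei with a
  decreasing-then-uptick density profile and depth-increasing elongation.
* **Vessel flow** — cells advected along a straight vessel with a
  parabolic transverse speed profile (zero at walls). Defaults model the
  thin marginal-arcade capillaries: 10 µm lumen, 7 µm cells, 60 cells
  over the field (≈ 1 cell per 6 µm — single-file, capillary-hematocrit
  spacing). Sparser cell trains leave the block matcher's windows
  straddling cell-free stretches of static background and bias the
  recovered centerline speed low. A `crossing` option adds a
  perpendicular vessel and flags the overlap region (the
  elevated-apparent-speed artifact of overlaid vessels).
* **Tear film** — particles (1–40 µm) drifting vertically at
  v(t) = v₀·e^(−t/τ), clamped to zero after 9 s. v₀ = 5.63 mm/s and
  τ = 0.513 s are the two-point solution of v(0.15 s) = 4.2 mm/s and
  v(1 s) = 0.8 mm/s. The field is periodic (particles re-enter at the
  bottom edge), standing in for the continuous particle supply of the
  real flow; the total drift (~2.9 mm) would otherwise empty a 1.25 mm
  field within a second.
* **Curved surface** — spherical-cap sag map for fringe and
  partial-visibility simulation.

What the phantoms do **not** emulate: stromal fibril speckle texture,
specular endothelial glare, palisade 3-D anatomy, lateral saccades beyond
a constant shift, or spectrally dependent scattering. Passing recovery
tests therefore demonstrate estimator correctness on clean, known-truth
scenes — not clinical-grade performance on in vivo images, where manual
annotation remains the reference.

## Quantifiers

* `count_cells` — difference-of-Gaussians bandpass at the expected cell
  scale (σ = scale/6 minus scale/1.5) and local-maxima counting at ≥ 0.4
  cell-scale separation. Intensive under tiling; robust to SNR ≥ 5 noise.
* `nerve_length_density` — Sato tubeness at the nerve thickness, Otsu
  threshold, skeletonization, and length by **resampled path traversal**:
  each skeleton arc between junctions is walked pixel-by-pixel and
  measured as the polyline through every 6th pixel. Chain-code weight
  schemes (1/√2 or Kulpa's corrected weights) bias digital straight lines
  by 5–8% at some orientations; the resampled polyline stays within ~1%
  at any angle, meeting the 2% straight-line contract.
* `track_particles` — per-frame blob detection, then frame-to-frame
  **optimal assignment** (Hungarian on the distance matrix, with the link
  cutoff as the unlink cost). Greedy nearest-neighbor linking was
  implemented first and rejected: under coherent drift it leapfrogs
  between particles trailing each other (the wrong link is *shorter* than
  the right one), biasing mean tear-film velocity by ≈ −18%. No motion
  prediction and no gap closing.

## Problem sizes and numerics

The acceptance script uses: 512 rays for the aberration trace (value
stable to < 0.1% vs 4× more rays); 3 seeds × 30 s × 1 ms steps for the
closed loop; the full 1.25 mm field for the mosaic and nerve phantoms;
a 0.5 mm field, 15 particles, 110 frames at 275 fps for the tear film;
and a 0.35 mm field, 8 frames for the vessel — sizes chosen so the whole
recomputation completes in well under a minute while every estimate sits
far from its tolerance edge. Degenerate inputs (flat images, empty
stacks, absent peaks, empty component lists) return zero-valued reports
or validity flags rather than raising, except where a contract violation
(Nyquist, empty stack, too few frames) warrants an error.
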