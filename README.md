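# ffsdoct

Simulator and processing toolkit for a **common-path full-field /
spectral-domain OCT (FF/SD OCT) corneal microscope** — a non-contact
instrument that images the living human cornea, limbus and tear film at
cellular resolution by combining:

* **FFOCT** — en-face interferometric imaging on a 2-D camera under
  spatially incoherent 850 nm illumination, with optical sectioning by
  temporal coherence gating (no beam scanning);
* an **SDOCT rangefinder** that locates the corneal surface and the FFOCT
  reference mirror in every B-scan; and
* a **closed-loop voice-coil servo** that extends the FFOCT reference arm
  in real time so the coherence gate follows the refraction-shifted focus
  inside the moving eye (defocus correction).

The package is aimed at instrument builders and image-analysis developers
who need a desk-scale, fully seeded model of this acquisition chain: every
structure the instrument images (endothelial mosaic, sub-basal nerve
plexus, keratocytes, limbal vessels with flowing blood cells, post-blink
tear-film drift) is available as a synthetic phantom with exact ground
truth, and every processing step (two-phase reconstruction, fringe
removal, registration/averaging, block-matching angiography, clinical
density quantification) is implemented and validated against those
phantoms.

## The model in brief

**Optics.** Interface reflectivities follow the Fresnel relation
R = ((n₁−n₂)/(n₁+n₂))²; the corneal stack air | tear | cornea | aqueous
sums to ≈ 2.1%, matched by a 4% reference mirror (n = 1.5 glass).
Lateral resolution is Rayleigh, 0.61·λ/NA = 1.73 µm at λ = 850 nm,
NA = 0.3; axial resolution is the coherence gate,
(2 ln 2/π)·λ²/(Δλ·n) = 7.7 µm in cornea (Δλ = 30 nm, n = 1.376).
When the cornea moves a distance *d* toward the objective, refraction
stretches the focus to depth *n·d* while the coherence gate moves to
*d/n*; restoring overlap requires a reference-arm extension of
**(n² − 1)·d** — the quantity the servo must track. A meridional ray
trace through the spherical anterior surface (R = 7.8 mm) quantifies the
spherical aberration a conventional scanning microscope would suffer at
depth (≈ 3× resolution loss at 550 µm); FFOCT's incoherent illumination
makes it immune to this, which the package verifies as a design number.

**Tracking.** In the SDOCT depth window the common-path peak sits at
cp₀ + d + e and the reference-mirror peak at ref₀ + e (e = reference
extension), so the pair of detected peak positions inverts to (d, e)
with the corneal estimate invariant to reference motion. The servo
commands e* = (n² − 1)·d at 50 Hz to a stage limited to 2.2 µm accuracy,
1 mm/s and 25 mm/s², fed by tracker updates every 8.2 ± 0.5 ms.

**Reconstruction.** Each tomographic image is the absolute difference of
two camera frames with a π reference phase step, |I₀ − I₁|/2, which
cancels the incoherent background exactly and returns *amplitude* (∝ √R)
rather than intensity. Axial motion multiplies the signal by
|cos(2π·v·Δt/λ)| (phase washout); the signed difference I₀ − I₁ avoids
the two-lobed "doubling artifact" of moving scatterers.

**Angiography.** Dense per-pixel block matching: 16 × 16-pixel windows,
zero-mean normalized cross-correlation over the displacement disc
corresponding to a 2 mm/s speed cap at 275 fps, correlation-thresholded,
averaged over the 7 frame pairs of an 8-frame window, rendered as HSV
maps (hue = speed or orientation, value = the FFOCT image,
saturation = 0.8).

## Worked example

Print the derived optical design quantities:

```bash
$ ffsdoct optics
{
  "lateral_resolution_um": 1.7283333333333333,
  "axial_resolution_cornea_um": 7.723314976273778,
  "axial_resolution_air_um": 10.627281407352719,
  "corneal_stack_reflectivity": 0.02112376604696514,
  "reference_mirror_reflectivity": 0.04000000000000001,
  "aberrated_resolution_550um_um": 5.248110147374782
}
```

The first two are the instrument's 1.7 µm / 7.7 µm resolutions; the stack
reflectivity is the ≈ 2% that motivates the 4% reference mirror; the last
line is the ray-traced effective resolution a conventional confocal/OCT
system would have at the 550 µm paraxial focus (≈ 3× the diffraction
limit).

Run the closed loop on physiological axial eye motion (breathing at
0.34 Hz / 33 µm plus heartbeat at 1.1 Hz / 13 µm):

```python
from ffsdoct.config import SdoctConfig, StageSpec, LoopTiming
from ffsdoct.motion import synthesize_motion, PHYSIOLOGICAL_COMPONENTS
from ffsdoct.servo import run_closed_loop, summarize_error

trace = synthesize_motion(PHYSIOLOGICAL_COMPONENTS, 30.0, 1000.0, seed=1)
loop = run_closed_loop(trace, StageSpec(), LoopTiming(), SdoctConfig(),
                       1.376, seed=1)
s = summarize_error(loop)
print(f"mean |error| = {s.mean_abs_um:.2f} um, sd = {s.sd_abs_um:.2f} um")
```

```
mean |error| = 1.86 um, sd = 1.31 um
```

The simulated positioning error sits well inside the ± 35 µm depth of
focus, in the same few-micrometre regime the bench instrument achieves on
controlled stage motion.

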