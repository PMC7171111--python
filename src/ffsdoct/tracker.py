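"""SDOCT rangefinder simulation and tracking-state arithmetic.

The SDOCT B-scan of the common-path interferometer shows two usable
maxima: the common-path peak (interference between the two FFOCT arms,
upper half of the depth window) and the FFOCT reference-mirror peak
(lower half).  Extending the reference arm by e moves *both* peaks down
by e; moving the cornea toward the objective by d moves only the
common-path peak, by d.  From the two detected positions and the
calibration recorded with the gate on the corneal surface, the tracker
recovers (d, e), the imaging depth, the optimal reference extension for
defocus correction, and the servo error — the quantities plotted live on
the instrument.

All positions are optical-path micrometres on a depth axis increasing
downward from the top of the 2.7 mm SDOCT window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SdoctConfig
from .errors import ConfigurationError, InvalidParameterError
from .optics import defocus_geometry

__all__ = ["BScanProfile", "PeakSet", "TrackingState",
           "simulate_bscan", "detect_peaks", "tracking_state"]


@dataclass
class BScanProfile:
    """Laterally averaged SDOCT axial intensity profile."""

    axial_intensity: np.ndarray
    axial_range_um: float
    lateral_lines: int
    noise_sd: float = 0.0  # effective (post-averaging) noise SD

    def __post_init__(self) -> None:
        if np.any(self.axial_intensity < 0):
            raise InvalidParameterError("intensities must be >= 0")

    @property
    def pixel_pitch_um(self) -> float:
        return self.axial_range_um / len(self.axial_intensity)


@dataclass(frozen=True)
class PeakSet:
    common_path_position_um: float
    reference_mirror_position_um: float
    common_path_amplitude: float
    reference_mirror_amplitude: float
    common_path_valid: bool
    reference_mirror_valid: bool


@dataclass(frozen=True)
class TrackingState:
    corneal_surface_position_um: float
    imaging_depth_in_cornea_um: float
    optimal_reference_position_um: float
    actual_reference_position_um: float
    error_um: float
    valid: bool


def simulate_bscan(cornea_displacement_um: float, reference_extension_um: float,
                   calib: SdoctConfig, noise_sd: float | None = None,
                   seed: int | np.random.Generator = 0) -> BScanProfile:
    """Forward-model the laterally averaged SDOCT profile.

    Gaussian peaks of FWHM = the configured SDOCT precision are placed at

        common-path peak: cp0 + d + e
        reference peak:   ref0 + e

    (d = corneal displacement toward the objective, e = reference
    extension).  Peaks falling outside the axial window are simply absent
    — the blink / out-of-range failure mode.  Additive white noise at
    ``noise_sd`` per lateral line is applied with the 1/sqrt(lateral_lines)
    reduction of the on-instrument lateral averaging folded in.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) \
        else seed
    nsd = calib.noise_sd if noise_sd is None else noise_sd
    n = calib.n_pixels
    pitch = calib.pixel_pitch_um
    z = (np.arange(n) + 0.5) * pitch
    sigma = calib.precision_um / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    profile = np.zeros(n)
    for pos, amp in ((calib.cp_peak0_um + cornea_displacement_um
                      + reference_extension_um, calib.cp_amplitude),
                     (calib.ref_peak0_um + reference_extension_um,
                      calib.ref_amplitude)):
        if 0.0 <= pos <= calib.axial_range_um:
            profile += amp * np.exp(-0.5 * ((z - pos) / sigma) ** 2)
    eff_sd = nsd / np.sqrt(calib.lateral_lines)
    if eff_sd > 0:
        profile += rng.normal(0.0, eff_sd, size=n)
    return BScanProfile(np.clip(profile, 0.0, None), calib.axial_range_um,
                        calib.lateral_lines, noise_sd=eff_sd)


def _find_half_peak(prof: np.ndarray, lo: int, hi: int, pitch: float,
                    threshold: float) -> tuple[float, float, bool]:
    """Largest local maximum in prof[lo:hi] with parabolic sub-pixel vertex."""
    seg = prof[lo:hi]
    if len(seg) < 3:
        return 0.0, 0.0, False
    k = int(np.argmax(seg))
    amp = float(seg[k])
    if amp < threshold:
        return (lo + k + 0.5) * pitch, amp, False
    i = lo + k
    if 0 < i < len(prof) - 1:
        a, b, c = prof[i - 1], prof[i], prof[i + 1]
        if min(a, b, c) > 0:
            # log-domain vertex: exact for Gaussian-shaped peaks
            a, b, c = np.log(a), np.log(b), np.log(c)
        denom = a - 2 * b + c
        delta = 0.5 * (a - c) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return (i + delta + 0.5) * pitch, amp, True


def detect_peaks(profile: BScanProfile, split_boundary_um: float | None = None,
                 amplitude_threshold: float | None = None) -> PeakSet:
    """Locate the common-path (upper half) and reference (lower half) maxima.

    Sub-pixel positions come from a 3-point parabolic vertex.  Peaks below
    the amplitude threshold (default 5x the profile's noise SD) are flagged
    invalid rather than raising — absence is an expected operating state.
    """
    prof = profile.axial_intensity
    pitch = profile.pixel_pitch_um
    split = split_boundary_um if split_boundary_um is not None \
        else profile.axial_range_um / 2.0
    k_split = int(round(split / pitch))
    if amplitude_threshold is None:
        amplitude_threshold = 5.0 * profile.noise_sd if profile.noise_sd > 0 \
            else 1e-6
    cp_pos, cp_amp, cp_ok = _find_half_peak(prof, 0, k_split, pitch,
                                            amplitude_threshold)
    ref_pos, ref_amp, ref_ok = _find_half_peak(prof, k_split, len(prof), pitch,
                                               amplitude_threshold)
    return PeakSet(cp_pos, ref_pos, cp_amp, ref_amp, cp_ok, ref_ok)


def tracking_state(peaks: PeakSet, calib: SdoctConfig, n: float = 1.376
                   ) -> TrackingState:
    """Fig.-2e-style quantities from a detected peak pair.

    e  = ref_peak - ref_peak0          (current reference extension)
    d  = (cp_peak - cp_peak0) - e      (corneal displacement toward objective)
    depth = (e + d) / n, clipped at 0  (coherence-gate depth in tissue)
    e* = (n^2 - 1) * d                 (optimal extension, defocus correction)
    error = e - e*
    """
    if calib is None:
        raise ConfigurationError("tracker calibration is required")
    valid = peaks.common_path_valid and peaks.reference_mirror_valid
    if not valid:
        return TrackingState(np.nan, np.nan, np.nan, np.nan, np.nan, False)
    e = peaks.reference_mirror_position_um - calib.ref_peak0_um
    d = (peaks.common_path_position_um - calib.cp_peak0_um) - e
    depth = max((e + d) / n, 0.0)
    e_opt = defocus_geometry(d, n).required_reference_extension_um
    return TrackingState(
        corneal_surface_position_um=calib.cornea_position0_um - d,
        imaging_depth_in_cornea_um=depth,
        optimal_reference_position_um=e_opt,
        actual_reference_position_um=e,
        error_um=e - e_opt,
        valid=True,
    )
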