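"""Instrument parameter containers and YAML run configuration.

Every dataclass here has defaults matching the bench instrument: an 850 nm
LED source of 30 nm bandwidth, 0.3 NA / 10x air objectives, a 1440 x 1440
CMOS camera covering a 1.25 mm field, a voice-coil reference stage
(2.2 um accuracy, 1 mm/s, 25 mm/s^2, 50 Hz command rate) and an SDOCT
rangefinder refreshing every 8.2 +/- 0.5 ms over a 2.7 mm axial window.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .errors import ConfigurationError, InvalidParameterError


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


@dataclass(frozen=True)
class SourceSpec:
    """Illumination source: center wavelength and FWHM bandwidth, in nm."""

    center_wavelength_nm: float = 850.0
    bandwidth_fwhm_nm: float = 30.0

    def __post_init__(self) -> None:
        _require(self.center_wavelength_nm > 0, "center wavelength must be > 0")
        _require(self.bandwidth_fwhm_nm > 0, "bandwidth must be > 0")
        _require(
            self.bandwidth_fwhm_nm < self.center_wavelength_nm,
            "bandwidth must be smaller than the center wavelength",
        )


@dataclass(frozen=True)
class ObjectiveSpec:
    """Microscope objective parameters."""

    numerical_aperture: float = 0.3
    magnification: float = 10.0
    working_distance_mm: float = 18.0
    depth_of_focus_halfwidth_um: float = 35.0

    def __post_init__(self) -> None:
        _require(0 < self.numerical_aperture < 1, "NA must be in (0, 1)")
        _require(self.depth_of_focus_halfwidth_um > 0, "depth of focus must be > 0")


@dataclass(frozen=True)
class MediumIndices:
    """Refractive indices of the media in the optical train.

    Air and cornea are the instrument's operating values; tear and aqueous
    default to the physiological 1.336 and the reference attenuator glass
    to a catalog 1.5.
    """

    air: float = 1.0
    tear: float = 1.336
    aqueous: float = 1.336
    cornea: float = 1.376
    reference_glass: float = 1.5

    def __post_init__(self) -> None:
        for name in ("air", "tear", "aqueous", "cornea", "reference_glass"):
            _require(getattr(self, name) >= 1.0, f"index {name!r} must be >= 1")

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class CameraSpec:
    """FFOCT camera geometry and timing."""

    frame_shape: tuple[int, int] = (1440, 1440)
    frame_exposure_ms: float = 1.75
    pair_time_ms: float = 3.5
    fast_rate_fps: float = 550.0
    ffoct_rate_fps: float = 275.0
    live_rate_fps: float = 10.0
    pixel_pitch_um: float = 1250.0 / 1440.0
    full_well_electrons: float = 2.0e6

    def __post_init__(self) -> None:
        _require(self.pair_time_ms >= 2 * self.frame_exposure_ms,
                 "pair time must cover two exposures")
        _require(self.pixel_pitch_um > 0, "pixel pitch must be > 0")


@dataclass(frozen=True)
class StageSpec:
    """Voice-coil reference-stage limits."""

    accuracy_um: float = 2.2
    max_velocity_mm_s: float = 1.0
    max_acceleration_mm_s2: float = 25.0
    command_rate_hz: float = 50.0
    settle_error_model: str = "uniform"  # or "gaussian"

    def __post_init__(self) -> None:
        for name in ("accuracy_um", "max_velocity_mm_s",
                     "max_acceleration_mm_s2", "command_rate_hz"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")


@dataclass(frozen=True)
class LoopTiming:
    """Tracker and simulation cadence of the closed loop."""

    tracker_period_ms: float = 8.2
    tracker_period_jitter_ms: float = 0.5
    simulation_step_ms: float = 1.0

    def __post_init__(self) -> None:
        _require(self.simulation_step_ms <= self.tracker_period_ms / 4,
                 "simulation step must be <= tracker_period / 4")


@dataclass(frozen=True)
class FlowParams:
    """Block-matching velocimetry parameters."""

    window_px: int = 16
    max_speed_mm_s: float = 2.0
    frame_rate_fps: float = 275.0
    pixel_pitch_um: float = 1250.0 / 1440.0
    correlation_threshold: float = 0.3
    frames_per_map: int = 8
    min_valid_votes: int = 4
    subpixel: bool = False
    stride: int = 1

    def __post_init__(self) -> None:
        _require(self.window_px >= 8, "window must be >= 8 px")
        _require(self.max_speed_mm_s > 0, "max_speed must be > 0")
        _require(self.frames_per_map >= 2, "frames_per_map must be >= 2")


@dataclass(frozen=True)
class SdoctConfig:
    """SDOCT rangefinder geometry and the tracker calibration.

    Positions are optical-path micrometres on a depth axis that increases
    downward (longer path) from the top of the SDOCT window.  The
    calibration records the common-path and reference-mirror peak
    positions with the coherence gate on the corneal surface and the
    reference arm at its home position.
    """

    axial_range_um: float = 2700.0
    n_pixels: int = 1024
    lateral_lines: int = 64
    precision_um: float = 3.9          # peak FWHM, sets the sub-pixel noise scale
    split_fraction: float = 0.5        # boundary between the two detection half-ranges
    cp_peak0_um: float = 675.0
    ref_peak0_um: float = 2025.0
    cp_amplitude: float = 1.0
    ref_amplitude: float = 1.0
    noise_sd: float = 0.02             # per-line additive intensity noise
    threshold_factor: float = 5.0      # validity threshold in units of noise SD
    cornea_position0_um: float = 0.0   # calibrated absolute surface position

    def __post_init__(self) -> None:
        _require(self.axial_range_um > 0 and self.n_pixels > 1, "bad axial geometry")
        _require(0 < self.split_fraction < 1, "split_fraction must be in (0,1)")

    @property
    def pixel_pitch_um(self) -> float:
        return self.axial_range_um / self.n_pixels

    @property
    def split_boundary_um(self) -> float:
        return self.axial_range_um * self.split_fraction


@dataclass(frozen=True)
class OpticalConfig:
    """Bundle of source, objective, media and camera parameters."""

    source: SourceSpec = field(default_factory=SourceSpec)
    objective: ObjectiveSpec = field(default_factory=ObjectiveSpec)
    media: MediumIndices = field(default_factory=MediumIndices)
    camera: CameraSpec = field(default_factory=CameraSpec)


_SECTIONS: dict[str, type] = {
    "source": SourceSpec,
    "objective": ObjectiveSpec,
    "media": MediumIndices,
    "camera": CameraSpec,
    "stage": StageSpec,
    "timing": LoopTiming,
    "flow": FlowParams,
    "sdoct": SdoctConfig,
}


@dataclass(frozen=True)
class RunConfig:
    """Validated, fully-defaulted run configuration for the CLI."""

    source: SourceSpec = field(default_factory=SourceSpec)
    objective: ObjectiveSpec = field(default_factory=ObjectiveSpec)
    media: MediumIndices = field(default_factory=MediumIndices)
    camera: CameraSpec = field(default_factory=CameraSpec)
    stage: StageSpec = field(default_factory=StageSpec)
    timing: LoopTiming = field(default_factory=LoopTiming)
    flow: FlowParams = field(default_factory=FlowParams)
    sdoct: SdoctConfig = field(default_factory=SdoctConfig)
    seed: int = 0
    output_dir: str = "."

    @property
    def optical(self) -> OpticalConfig:
        return OpticalConfig(self.source, self.objective, self.media, self.camera)


def load_config(path: str | None = None) -> RunConfig:
    """Load a YAML configuration, merging overrides onto defaults.

    Unknown sections or keys raise :class:`ConfigurationError` naming every
    offending key at once.  ``path=None`` (or an empty file) returns pure
    defaults.
    """
    overrides: dict[str, Any] = {}
    if path is not None:
        try:
            with open(path) as fh:
                overrides = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"malformed YAML in {path}: {exc}") from exc
        if not isinstance(overrides, dict):
            raise ConfigurationError(f"top level of {path} must be a mapping")

    errors: list[str] = []
    kwargs: dict[str, Any] = {}
    for section, value in overrides.items():
        if section in ("seed", "output_dir"):
            kwargs[section] = value
            continue
        cls = _SECTIONS.get(section)
        if cls is None:
            errors.append(f"unknown section {section!r}")
            continue
        if not isinstance(value, dict):
            errors.append(f"section {section!r} must be a mapping")
            continue
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = sorted(set(value) - valid)
        errors.extend(f"unknown key {section}.{k!r}" for k in bad)
        if not bad:
            # YAML gives lists; frame_shape needs a tuple
            clean = {k: tuple(v) if isinstance(v, list) else v
                     for k, v in value.items()}
            kwargs[section] = cls(**clean)
    if errors:
        raise ConfigurationError("; ".join(errors))
    return RunConfig(**kwargs)
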