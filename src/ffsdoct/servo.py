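"""Closed-loop simulation of the voice-coil reference-arm servo.

At each SDOCT tracker tick (every ~8.2 ms with jitter) a B-scan is
simulated, its peaks detected, and the tracking state computed; the
resulting optimal reference extension is the most recent target.  At each
command tick (50 Hz stage encoder limit) that target is commanded to a
kinematic stage model limited by the voice coil's velocity, acceleration
and settling accuracy.  The loop outputs the required / actual / error
series of the on-screen performance plots, with blinks handled by holding
the last command.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import LoopTiming, SdoctConfig, StageSpec
from .errors import InvalidParameterError
from .motion import MotionTrace
from .tracker import detect_peaks, simulate_bscan, tracking_state

__all__ = ["StageState", "LoopTrace", "ErrorSummary",
           "stage_step", "run_closed_loop", "summarize_error"]


@dataclass(frozen=True)
class StageState:
    position_um: float = 0.0
    velocity_um_s: float = 0.0
    settled: bool = False
    last_command_um: float = 0.0


@dataclass
class LoopTrace:
    """Required / actual reference positions and their difference over time."""

    times_s: np.ndarray
    required_um: np.ndarray
    actual_um: np.ndarray
    blink_mask: np.ndarray
    n_measurements: int = 0

    @property
    def error_um(self) -> np.ndarray:
        return self.actual_um - self.required_um


@dataclass(frozen=True)
class ErrorSummary:
    mean_abs_um: float
    sd_abs_um: float
    n: int


def _settle_error(spec: StageSpec, rng: np.random.Generator) -> float:
    if spec.settle_error_model == "gaussian":
        return float(rng.normal(0.0, spec.accuracy_um / 2.0))
    return float(rng.uniform(-spec.accuracy_um, spec.accuracy_um))


def stage_step(state: StageState, command_um: float, dt_s: float,
               spec: StageSpec, rng: np.random.Generator) -> StageState:
    """Advance the stage by dt toward a commanded position.

    Trapezoidal kinematics: velocity is slewed at the acceleration limit
    toward the deceleration-safe approach speed, capped at max velocity.
    Once the remaining distance is reachable within the positioning
    accuracy the stage settles at command + a random settle error
    (uniform in +/-accuracy by default), drawn once per new command.
    """
    if dt_s <= 0:
        raise InvalidParameterError("dt must be > 0")
    if state.settled and command_um == state.last_command_um:
        return state
    vmax = spec.max_velocity_mm_s * 1e3
    amax = spec.max_acceleration_mm_s2 * 1e3
    delta = command_um - state.position_um
    if abs(delta) <= spec.accuracy_um:
        return StageState(command_um + _settle_error(spec, rng), 0.0,
                          True, command_um)
    v_des = np.sign(delta) * min(vmax, np.sqrt(2.0 * amax * abs(delta)))
    dv = np.clip(v_des - state.velocity_um_s, -amax * dt_s, amax * dt_s)
    v = state.velocity_um_s + dv
    pos = state.position_um + v * dt_s
    # do not fly past the command within a step
    if (command_um - pos) * np.sign(delta) < 0:
        return StageState(command_um + _settle_error(spec, rng), 0.0,
                          True, command_um)
    return StageState(float(pos), float(v), False, command_um)


def run_closed_loop(motion: MotionTrace, stage: StageSpec, timing: LoopTiming,
                    tracker: SdoctConfig, n_index: float = 1.376,
                    seed: int = 0,
                    measurement_noise_halfwidth_um: float = 3.9 / 2.0
                    ) -> LoopTrace:
    """Simulate the full tracker -> servo loop over a motion trace.

    The required reference position at every simulation step is the ideal
    defocus-correction extension (n^2-1) * d(t) computed from the true
    motion; the actual position is the simulated stage; their difference
    is the positioning error of the performance plots.  During blink
    intervals no measurement is produced and the last command is held,
    yielding the characteristic error spikes.
    """
    if motion.duration_s < 5.0:
        raise InvalidParameterError("motion trace must cover at least 5 s")
    rng = np.random.default_rng(seed)
    dt = timing.simulation_step_ms * 1e-3
    n_steps = int(motion.duration_s / dt)
    times = np.arange(n_steps) * dt
    factor = n_index**2 - 1.0

    state = StageState()
    required = np.empty(n_steps)
    actual = np.empty(n_steps)
    blink = np.zeros(n_steps, dtype=bool)

    next_track = max(rng.normal(timing.tracker_period_ms,
                                timing.tracker_period_jitter_ms), dt * 1e3) * 1e-3
    cmd_period = 1.0 / stage.command_rate_hz
    next_cmd = cmd_period
    target = 0.0        # latest measured optimal extension
    command = 0.0
    n_meas = 0

    for i, t in enumerate(times):
        in_blink = motion.in_blink(t)
        if t >= next_track:
            next_track += max(rng.normal(timing.tracker_period_ms,
                                         timing.tracker_period_jitter_ms),
                              dt * 1e3) * 1e-3
            d_true = motion.position_at(t)
            # blink: drive the common-path peak out of the window
            d_sim = d_true if not in_blink else -(tracker.cp_peak0_um + 100.0)
            prof = simulate_bscan(d_sim, state.position_um, tracker, seed=rng)
            st = tracking_state(detect_peaks(prof), tracker, n_index)
            if st.valid:
                d_est = tracker.cornea_position0_um - st.corneal_surface_position_um
                if measurement_noise_halfwidth_um > 0:
                    d_est += rng.uniform(-measurement_noise_halfwidth_um,
                                         measurement_noise_halfwidth_um)
                target = factor * d_est
                n_meas += 1
        if t >= next_cmd:
            next_cmd += cmd_period
            command = target
        state = stage_step(state, command, dt, stage, rng)
        required[i] = factor * motion.position_at(t)
        actual[i] = state.position_um
        blink[i] = in_blink
    return LoopTrace(times, required, actual, blink, n_meas)


def summarize_error(trace: LoopTrace) -> ErrorSummary:
    """Mean and SD of |error| over non-blink samples, with count."""
    err = np.abs(trace.error_um[~trace.blink_mask])
    if len(err) < 10:
        raise InvalidParameterError("need at least 10 valid samples")
    return ErrorSummary(float(err.mean()), float(err.std()), int(len(err)))
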