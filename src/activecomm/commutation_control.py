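"""Closed-loop commutation control.

The controller watches a stream of head/tailbase poses and keeps a tethered
cable untwisted by driving a motorised slip-ring commutator. Heading is the
unit vector from tailbase to head. The magnitude of the frame-to-frame
heading change comes from the dot product of successive heading vectors and
its direction (CW vs CCW in image view) from the z component of their cross
product. Signed changes accumulate; once the accumulator magnitude reaches a
threshold (90 deg in open/rotating arenas, 225 deg on a linear track) the
commutator is commanded to rotate by the accumulated amount and the
accumulator resets, keeping long-run cable twist centred on zero.

On a linear track the commutator also translates: the track is divided into
``n_segments`` half-open bins and whenever the head crosses into a new
segment the stage is sent to that segment's centre.

A rate-limited kinematic stage simulator (constant speed, FIFO command
queue, limit-switch clamping at the track ends) stands in for the physical
motors, and :func:`run_closed_loop` replays a pose stream through
controller + stage, logging the cable twist

    twist(t) = animal's cumulative heading rotation(t) - commutator angle(t).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegeneratePoseError, OutOfArenaError, ParameterError
from .pose_io import ArenaSpec, PoseSample, PoseStream, gate_sample

logger = logging.getLogger(__name__)

#: tolerance absorbing float accumulation error in the threshold comparison,
#: so that e.g. twenty exact 4.5-deg steps trigger at exactly 90 deg.
THRESHOLD_TOL_DEG = 1e-9


@dataclass(frozen=True)
class ControllerConfig:
    """Parameters of the compensation algorithm and the stage kinematics.

    ``rotation_threshold_deg``: accumulated-heading trigger; presets are
    90 (rotating/open arenas) and 225 (linear track). ``stride``: a new
    heading estimate is consumed at most once every ``stride`` frames.
    ``compensation``: ``"accumulated"`` rotates by the full accumulated
    angle (default); ``"threshold"`` rotates by the threshold only, leaving
    the residual in the accumulator.
    """

    rotation_threshold_deg: float = 90.0
    conf_threshold: float = 0.9
    stride: int = 5
    n_segments: int = 8
    track_length_m: float = 1.2
    rotation_speed_dps: float = 100.0
    translation_speed_mps: float = 0.2
    compensation: str = "accumulated"
    hysteresis_m: float = 0.0
    gap_warning_s: float = 1.0

    def __post_init__(self):
        if not 0 < self.rotation_threshold_deg <= 360:
            raise ParameterError("rotation_threshold_deg must be in (0, 360]")
        if self.stride < 1:
            raise ParameterError("stride must be >= 1")
        if self.n_segments < 1:
            raise ParameterError("n_segments must be >= 1")
        if self.compensation not in ("accumulated", "threshold"):
            raise ParameterError(f"unknown compensation mode {self.compensation!r}")


@dataclass(frozen=True)
class HeadingState:
    """Controller memory between frames."""

    last_accepted_vector: Optional[np.ndarray] = None
    last_accepted_time_s: Optional[float] = None
    cumulative_deg: float = 0.0
    frames_since_estimate: int = 0
    current_segment: Optional[int] = None


@dataclass(frozen=True)
class MotorCommand:
    """A single command in the (emulated) wireless motor protocol."""

    kind: str = "none"              # rotate_by | translate_to | none
    rotate_deg: float = 0.0         # CW-positive, for rotate_by
    target_x_m: float = 0.0         # segment centre, for translate_to

    def to_wire(self) -> str:
        """ASCII line protocol: ``R <deg>`` / ``T <x_mm>``."""
        if self.kind == "rotate_by":
            return f"R {self.rotate_deg:.6f}"
        if self.kind == "translate_to":
            return f"T {self.target_x_m * 1000:.3f}"
        return ""


NONE_COMMAND = MotorCommand()


@dataclass(frozen=True)
class StageState:
    """Simulated slip-ring pose plus the FIFO queue of unfinished motions.

    Queue entries are ``("rotate", target_deg)`` / ``("translate", target_x)``
    absolute targets, resolved at enqueue time so rotate-by commands sum.
    """

    commutator_angle_deg: float = 0.0
    x_m: float = 0.6
    t_s: float = 0.0
    queue: tuple = ()

    @property
    def busy(self) -> bool:
        return bool(self.queue)

    def busy_until_s(self, config: ControllerConfig) -> float:
        """Time when all queued motions complete (current time if idle)."""
        t = self.t_s
        angle, x = self.commutator_angle_deg, self.x_m
        for kind, target in self.queue:
            if kind == "rotate":
                t += abs(target - angle) / config.rotation_speed_dps
                angle = target
            else:
                t += abs(target - x) / config.translation_speed_mps
                x = target
        return t


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def heading_vector(head_xy: np.ndarray, tail_xy: np.ndarray) -> np.ndarray:
    """Unit vector from tailbase to head; the animal's heading direction."""
    d = np.asarray(head_xy, dtype=float) - np.asarray(tail_xy, dtype=float)
    n = float(np.hypot(d[0], d[1]))
    if n < 1e-9:
        raise DegeneratePoseError("head and tailbase coincide")
    return d / n


def signed_delta_deg(v_prev: np.ndarray, v_curr: np.ndarray) -> float:
    """Signed heading change in degrees, in (-180, +180], CW-positive.

    Magnitude from the dot product (arccos of the clipped inner product),
    sign from the z component of the 2-D cross product. Exactly antiparallel
    vectors return +180 by convention.
    """
    v_prev = np.asarray(v_prev, dtype=float)
    v_curr = np.asarray(v_curr, dtype=float)
    for v in (v_prev, v_curr):
        if abs(np.hypot(v[0], v[1]) - 1.0) > 1e-6:
            raise ParameterError("signed_delta_deg expects unit vectors")
    dot = float(np.clip(v_prev @ v_curr, -1.0, 1.0))
    cross_z = v_prev[0] * v_curr[1] - v_prev[1] * v_curr[0]
    # atan2(|cross|, dot) equals arccos(dot) but stays well-conditioned for
    # nearly parallel vectors, where arccos loses ~half the mantissa
    mag = math.degrees(math.atan2(abs(cross_z), dot))
    if cross_z > 0:
        return mag
    if cross_z < 0:
        return -mag
    # collinear: either no change or an exact half turn (tie-break CW)
    return 180.0 if dot < 0 else 0.0


def cumulative_heading_deg(stream: PoseStream) -> np.ndarray:
    """Unwrapped cumulative heading rotation per frame, relative to frame 0.

    Uses every non-degenerate pose (no gating, stride 1); degenerate frames
    carry the previous value forward. This is the reference against which
    cable twist is measured.
    """
    out = np.zeros(len(stream))
    prev = None
    cum = 0.0
    for i in range(len(stream)):
        try:
            v = heading_vector(stream.head_xy[i], stream.tail_xy[i])
        except DegeneratePoseError:
            out[i] = cum
            continue
        if prev is not None:
            cum += signed_delta_deg(prev, v)
        prev = v
        out[i] = cum
    return out


# ---------------------------------------------------------------------------
# rotation compensation
# ---------------------------------------------------------------------------

def update(state: HeadingState, sample: PoseSample,
           config: ControllerConfig) -> tuple[HeadingState, MotorCommand]:
    """Advance the rotation controller by one frame.

    The sample is consumed only when at least ``stride`` frames have elapsed
    since the last accepted estimate, the confidence gate passes, and the
    pose is non-degenerate; otherwise the state simply advances (bad frames
    degrade to a skip, accumulation pauses — no extrapolation). When the
    accumulator magnitude reaches the threshold a rotate command is emitted
    and the accumulator resets.
    """
    fse = state.frames_since_estimate + 1
    skip = replace(state, frames_since_estimate=fse)
    if fse < config.stride:
        return skip, NONE_COMMAND
    if not gate_sample(sample, config.conf_threshold):
        return skip, NONE_COMMAND
    try:
        v = heading_vector(sample.head_xy, sample.tail_xy)
    except DegeneratePoseError:
        return skip, NONE_COMMAND

    if state.last_accepted_vector is None:
        new = replace(state, last_accepted_vector=v,
                      last_accepted_time_s=sample.timestamp_s,
                      frames_since_estimate=0)
        return new, NONE_COMMAND

    gap = sample.timestamp_s - (state.last_accepted_time_s or sample.timestamp_s)
    if gap > config.gap_warning_s:
        logger.warning(
            "gap of %.2f s between accepted pose estimates; heading deltas "
            "assume < 180 deg net rotation across the gap", gap)

    cum = state.cumulative_deg + signed_delta_deg(state.last_accepted_vector, v)
    command = NONE_COMMAND
    if abs(cum) >= config.rotation_threshold_deg - THRESHOLD_TOL_DEG:
        if config.compensation == "accumulated":
            command = MotorCommand(kind="rotate_by", rotate_deg=cum)
            cum = 0.0
        else:
            amount = math.copysign(config.rotation_threshold_deg, cum)
            command = MotorCommand(kind="rotate_by", rotate_deg=amount)
            cum -= amount
    new = replace(state, last_accepted_vector=v,
                  last_accepted_time_s=sample.timestamp_s,
                  cumulative_deg=cum, frames_since_estimate=0)
    return new, command


# ---------------------------------------------------------------------------
# translation compensation
# ---------------------------------------------------------------------------

def segment_index(head_x_px: float, arena: ArenaSpec, n_segments: int) -> int:
    """Half-open segment binning of a linear track; the far end clamps.

    Segment k covers [k*L/n, (k+1)*L/n); x == L maps to the last segment.
    Positions up to one pixel outside the track are clamped, beyond that is
    an error.
    """
    if arena.kind != "linear":
        raise ParameterError("segment_index requires a linear arena")
    x_m = head_x_px / arena.px_per_m
    tol = 1.0 / arena.px_per_m
    if x_m < -tol or x_m > arena.size_m + tol:
        raise OutOfArenaError(f"x = {x_m:.4f} m outside [0, {arena.size_m}] m")
    x_m = min(max(x_m, 0.0), arena.size_m)
    width = arena.size_m / n_segments
    # tiny bias so positions on a boundary land in the upper segment even
    # when x/width rounds just below an integer
    idx = int(math.floor(x_m / width + 1e-9))
    return min(idx, n_segments - 1)


def segment_center_m(segment: int, arena: ArenaSpec, n_segments: int) -> float:
    width = arena.size_m / n_segments
    return (segment + 0.5) * width


def translation_update(state: HeadingState, sample: PoseSample,
                       arena: ArenaSpec, config: ControllerConfig
                       ) -> tuple[HeadingState, MotorCommand]:
    """Emit a translate-to-segment-centre command when the animal changes segment.

    ``hysteresis_m`` (default 0) widens the current segment by that margin so
    jitter on a boundary does not chatter; with the default there is no
    hysteresis and every boundary crossing commands a move.
    """
    if not gate_sample(sample, config.conf_threshold):
        return state, NONE_COMMAND
    seg = segment_index(sample.head_xy[0], arena, config.n_segments)
    if state.current_segment is None:
        return replace(state, current_segment=seg), NONE_COMMAND
    if seg == state.current_segment:
        return state, NONE_COMMAND
    if config.hysteresis_m > 0:
        width = arena.size_m / config.n_segments
        lo = state.current_segment * width - config.hysteresis_m
        hi = (state.current_segment + 1) * width + config.hysteresis_m
        x_m = sample.head_xy[0] / arena.px_per_m
        if lo <= x_m < hi:
            return state, NONE_COMMAND
    target = segment_center_m(seg, arena, config.n_segments)
    return (replace(state, current_segment=seg),
            MotorCommand(kind="translate_to", target_x_m=target))


# ---------------------------------------------------------------------------
# stage simulator
# ---------------------------------------------------------------------------

def step_stage(stage: StageState, command: MotorCommand, dt_s: float,
               config: ControllerConfig) -> StageState:
    """Advance the rate-limited stage by ``dt_s``, enqueueing ``command``.

    Motions run at constant speed (no acceleration ramp); commands arriving
    while busy queue FIFO. Translation targets clamp to the track bounds —
    the limit-switch model.
    """
    if dt_s <= 0:
        raise ParameterError("dt_s must be positive")
    queue = list(stage.queue)
    if command.kind == "rotate_by":
        last_rot = next((t for k, t in reversed(queue) if k == "rotate"), None)
        start = last_rot if last_rot is not None else stage.commutator_angle_deg
        queue.append(("rotate", start + command.rotate_deg))
    elif command.kind == "translate_to":
        target = min(max(command.target_x_m, 0.0), config.track_length_m)
        queue.append(("translate", target))

    angle, x = stage.commutator_angle_deg, stage.x_m
    remaining = dt_s
    while queue and remaining > 0:
        kind, target = queue[0]
        if kind == "rotate":
            delta = target - angle
            speed = config.rotation_speed_dps
        else:
            delta = target - x
            speed = config.translation_speed_mps
        if not math.isfinite(speed):          # instantaneous-motor option
            need = 0.0
        else:
            need = abs(delta) / speed if speed > 0 else math.inf
        if need <= remaining:
            if kind == "rotate":
                angle = target
            else:
                x = target
            remaining -= need
            queue.pop(0)
        else:
            step = math.copysign(speed * remaining, delta)
            if kind == "rotate":
                angle += step
            else:
                x += step
            remaining = 0.0
    return StageState(commutator_angle_deg=angle, x_m=x,
                      t_s=stage.t_s + dt_s, queue=tuple(queue))


# ---------------------------------------------------------------------------
# closed loop
# ---------------------------------------------------------------------------

@dataclass
class RunLog:
    """Per-frame record of a closed-loop replay."""

    frame_index: np.ndarray
    timestamp_s: np.ndarray
    processed: np.ndarray            # controller consumed this frame's pose
    cumulative_deg: np.ndarray       # accumulator after the frame
    commutator_angle_deg: np.ndarray
    stage_x_m: np.ndarray
    true_heading_cum_deg: np.ndarray
    twist_deg: np.ndarray
    commands: list                   # (frame_index, MotorCommand)

    def rotation_commands(self) -> list[MotorCommand]:
        return [c for _, c in self.commands if c.kind == "rotate_by"]

    def translation_commands(self) -> list[MotorCommand]:
        return [c for _, c in self.commands if c.kind == "translate_to"]

    def to_jsonl(self, path: str | Path) -> None:
        cmd_by_frame: dict[int, list] = {}
        for f, c in self.commands:
            cmd_by_frame.setdefault(int(f), []).append(
                {"kind": c.kind, "rotate_deg": c.rotate_deg,
                 "target_x_m": c.target_x_m})
        with open(path, "w") as fh:
            for i in range(len(self.frame_index)):
                rec = {
                    "frame": int(self.frame_index[i]),
                    "t_s": round(float(self.timestamp_s[i]), 9),
                    "processed": bool(self.processed[i]),
                    "cumulative_deg": round(float(self.cumulative_deg[i]), 9),
                    "commutator_angle_deg": round(float(self.commutator_angle_deg[i]), 9),
                    "stage_x_m": round(float(self.stage_x_m[i]), 9),
                    "twist_deg": round(float(self.twist_deg[i]), 9),
                    "commands": cmd_by_frame.get(int(self.frame_index[i]), []),
                }
                fh.write(json.dumps(rec) + "\n")

    def commands_to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "frame": [int(f) for f, _ in self.commands],
            "kind": [c.kind for _, c in self.commands],
            "rotate_deg": [c.rotate_deg for _, c in self.commands],
            "target_x_m": [c.target_x_m for _, c in self.commands],
        }).to_csv(path, index=False, float_format="%.6f")

    def twist_to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "frame": self.frame_index,
            "t_s": self.timestamp_s,
            "mouse_heading_cum_deg": self.true_heading_cum_deg,
            "commutator_angle_deg": self.commutator_angle_deg,
            "twist_deg": self.twist_deg,
        }).to_csv(path, index=False, float_format="%.6f")


def run_closed_loop(stream: PoseStream, arena: ArenaSpec,
                    config: ControllerConfig,
                    initial_stage: Optional[StageState] = None) -> RunLog:
    """Replay a pose stream through controller and stage simulator.

    Deterministic: the same stream/arena/config always yields an identical
    log. Cable twist is the animal's cumulative heading (from the raw
    stream, ungated, stride 1) minus the simulated commutator angle.
    """
    n = len(stream)
    if n == 0:
        raise ParameterError("empty pose stream")
    state = HeadingState()
    stage = initial_stage or StageState(
        x_m=config.track_length_m / 2 if arena.kind == "linear" else 0.0)
    stage = replace(stage, t_s=float(stream.timestamp_s[0]))
    true_cum = cumulative_heading_deg(stream)

    processed = np.zeros(n, dtype=bool)
    cumulative = np.zeros(n)
    angles = np.zeros(n)
    xs = np.zeros(n)
    commands: list = []

    for i in range(n):
        sample = stream[i]
        before = state.frames_since_estimate
        state, rot_cmd = update(state, sample, config)
        processed[i] = state.frames_since_estimate == 0 and before + 1 >= config.stride
        if rot_cmd.kind != "none":
            commands.append((sample.frame_index, rot_cmd))
        trans_cmd = NONE_COMMAND
        if arena.kind == "linear":
            state, trans_cmd = translation_update(state, sample, arena, config)
            if trans_cmd.kind != "none":
                commands.append((sample.frame_index, trans_cmd))
        dt = (float(stream.timestamp_s[i + 1] - stream.timestamp_s[i])
              if i + 1 < n else 1.0 / arena.fps)
        if dt <= 0:
            dt = 1.0 / arena.fps
        stage = step_stage(stage, rot_cmd, dt * 0.5, config)
        stage = step_stage(stage, trans_cmd, dt * 0.5, config)
        cumulative[i] = state.cumulative_deg
        angles[i] = stage.commutator_angle_deg
        xs[i] = stage.x_m

    return RunLog(
        frame_index=stream.frame_index.copy(),
        timestamp_s=stream.timestamp_s.copy(),
        processed=processed,
        cumulative_deg=cumulative,
        commutator_angle_deg=angles,
        stage_x_m=xs,
        true_heading_cum_deg=true_cum,
        twist_deg=true_cum - angles,
        commands=commands,
    )
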