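"""Synthetic pose streams and dual-illumination movies with known ground truth.

Every downstream stage of the package — the commutation controller, the
tracking evaluator, the calcium preprocessing chain and the peri-event
statistics — is exercised against data generated here, where the true
unwrapped heading, the true channel labels, the true calcium transients and
the planted motion are all known by construction.

Trajectories: either a scripted pirouette (uniform turn rate, exact net
rotation of 360 * n_full_turns degrees — the high-rotation stress case) or a
smooth random walk steered to stay inside the arena. Movies: interleaved
blue (calcium + haemodynamic) and green (haemodynamic only) frames with
Gaussian-footprint cells, exponential-kernel transients, a shared slow
haemodynamic fluctuation, optional rigid integer shifts (applied
circularly) and rare gross outlier frames.

All randomness flows from the single integer ``seed`` passed to each call;
no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .conventions import heading_from_angle_deg
from .errors import ParameterError
from .pose_io import ArenaSpec, PoseStream

DEFAULT_BODY_LENGTH_PX = 60.0


@dataclass
class TrajectoryTruth:
    """Ground truth for a generated trajectory.

    ``heading_deg`` is the unwrapped (continuous) heading, CW-positive in
    image view; ``cumulative_deg`` is heading relative to the first frame.
    """

    position_m: np.ndarray      # (N, 2) tailbase position in metres
    heading_deg: np.ndarray     # (N,) unwrapped
    cumulative_deg: np.ndarray  # (N,) heading - heading[0]


@dataclass
class SyntheticMovieTruth:
    """Ground truth for a generated dual-channel movie."""

    labels: np.ndarray          # (T,) 'blue' | 'green' | 'outlier'
    cell_traces: np.ndarray     # (n_pairs, n_cells) transient amplitude (dF/F units)
    footprints: np.ndarray      # (n_cells, H, W) spatial footprints, peak 1
    hemo: np.ndarray            # (T,) fractional haemodynamic fluctuation
    shifts: np.ndarray          # (T, 2) planted integer (dy, dx) per frame
    mask: np.ndarray            # (H, W) boolean brain mask
    outlier_frames: np.ndarray  # indices of injected outliers
    fps_total: float

    def calcium_dff(self) -> np.ndarray:
        """Per-pixel true calcium dF/F, one frame per blue/green pair."""
        return np.tensordot(self.cell_traces, self.footprints, axes=(1, 0))

    def roi_truth_trace(self, roi_mask: np.ndarray) -> np.ndarray:
        """ROI-mean true calcium dF/F time course."""
        dff = self.calcium_dff()
        return dff[:, roi_mask].mean(axis=1)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def _arena_center_m(arena: ArenaSpec) -> np.ndarray:
    if arena.kind == "linear":
        return np.array([arena.size_m / 2, 0.05])
    return np.array([arena.size_m / 2, arena.size_m / 2])


def _inside(arena: ArenaSpec, p: np.ndarray, margin: float) -> bool:
    if arena.kind == "circular":
        c = _arena_center_m(arena)
        return np.hypot(*(p - c)) <= arena.size_m / 2 - margin
    if arena.kind == "linear":
        return margin <= p[0] <= arena.size_m - margin
    return bool(np.all(p >= margin) and np.all(p <= arena.size_m - margin))


def generate_trajectory(arena: ArenaSpec, duration_s: float,
                        mean_speed: float = 0.1, turn_rate_sd: float = 30.0,
                        n_full_turns: Optional[int] = None, seed: int = 0,
                        body_length_px: float = DEFAULT_BODY_LENGTH_PX,
                        clockwise: bool = True
                        ) -> tuple[PoseStream, TrajectoryTruth]:
    """Simulate a pose stream with exactly known heading ground truth.

    Pirouette mode (``n_full_turns`` given): the animal stays at the arena
    centre and turns at a uniform rate; the net cumulative rotation is
    exactly ``360 * n_full_turns`` degrees (CW if ``clockwise``). Random-walk
    mode: heading receives Gaussian increments of SD ``turn_rate_sd`` deg/s
    and the animal advances at ``mean_speed`` m/s, steered back inside the
    arena when a step would leave it. Confidences are 1 everywhere; use
    :func:`corrupt_poses` to degrade them.
    """
    if duration_s <= 0:
        raise ParameterError("duration_s must be positive")
    n = int(round(duration_s * arena.fps))
    if n < 2:
        raise ParameterError("duration too short for two frames")
    dt = 1.0 / arena.fps
    body_m = body_length_px / arena.px_per_m
    if mean_speed * dt > arena.size_m:
        raise ParameterError("mean_speed leaves the arena in a single frame")
    if arena.kind != "linear" and body_m >= arena.size_m / 2:
        raise ParameterError("body length does not fit the arena")

    rng = np.random.default_rng(seed)
    heading = np.zeros(n)
    pos = np.zeros((n, 2))

    if n_full_turns is not None:
        step = (1.0 if clockwise else -1.0) * 360.0 * n_full_turns / (n - 1)
        heading = step * np.arange(n)
        pos[:] = _arena_center_m(arena)
    elif arena.kind == "linear":
        # shuttle along the track; heading follows travel direction with wobble
        x = body_m
        direction = 1.0
        wobble = rng.normal(0.0, turn_rate_sd * dt, size=n)
        base = 0.0
        for i in range(n):
            pos[i] = (x, 0.05)
            heading[i] = base + wobble[i]
            x_next = x + direction * mean_speed * dt
            if x_next < body_m or x_next > arena.size_m - body_m:
                direction = -direction
                # a 170-deg (not 180) CW about-turn keeps the per-frame
                # heading change strictly below 180 even with wobble
                base += 170.0
                x_next = x + direction * mean_speed * dt
            x = x_next
    else:
        p = _arena_center_m(arena).copy()
        h = float(rng.uniform(-180, 180))
        increments = rng.normal(0.0, turn_rate_sd * dt, size=n)
        margin = body_m + 0.01
        for i in range(n):
            heading[i] = h
            pos[i] = p
            h = h + increments[i]
            step_v = heading_from_angle_deg(h) * mean_speed * dt
            tries = 0
            while not _inside(arena, p + step_v, margin):
                h += 15.0     # steer clockwise until the step fits
                step_v = heading_from_angle_deg(h) * mean_speed * dt
                tries += 1
                if tries > 24:
                    step_v = np.zeros(2)
                    break
            p = p + step_v

    tail_px = pos * arena.px_per_m
    head_px = tail_px + heading_from_angle_deg(heading) * body_length_px
    frames = np.arange(n, dtype=np.int64)
    stream = PoseStream(
        frame_index=frames,
        timestamp_s=frames * dt,
        head_xy=head_px,
        tail_xy=tail_px,
        head_conf=np.ones(n),
        tail_conf=np.ones(n),
    )
    truth = TrajectoryTruth(
        position_m=pos,
        heading_deg=heading,
        cumulative_deg=heading - heading[0],
    )
    return stream, truth


def corrupt_poses(stream: PoseStream, dropout_rate: float = 0.0,
                  jitter_sd_px: float = 0.0, seed: int = 0,
                  gate: float = 0.9) -> PoseStream:
    """Degrade a pose stream the way a real tracker does.

    A Bernoulli(``dropout_rate``) subset of frames gets confidence drawn
    uniformly below ``gate`` (so they fail the confidence gate); all other
    frames keep their confidences and receive isotropic Gaussian positional
    jitter of SD ``jitter_sd_px`` on both keypoints.
    """
    if not 0.0 <= dropout_rate < 1.0:
        raise ParameterError("dropout_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = stream.copy()
    n = len(out)
    dropped = rng.random(n) < dropout_rate
    low_conf = rng.uniform(0.0, gate, size=n)
    out.head_conf = np.where(dropped, low_conf, out.head_conf)
    out.tail_conf = np.where(dropped, low_conf, out.tail_conf)
    if jitter_sd_px > 0:
        jitter_h = rng.normal(0.0, jitter_sd_px, size=(n, 2))
        jitter_t = rng.normal(0.0, jitter_sd_px, size=(n, 2))
        keep = ~dropped
        out.head_xy[keep] += jitter_h[keep]
        out.tail_xy[keep] += jitter_t[keep]
    return out


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------

def _disk_mask(h: int, w: int, radius_frac: float = 0.42) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    r = radius_frac * min(h, w)
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


def generate_movie(shape: tuple[int, int, int], n_cells: int = 6,
                   transient_tau_s: float = 1.0, hemo_amp: float = 0.03,
                   outlier_frac: float = 0.0, max_shift_px: int = 0,
                   blue_mean: float = 200.0, green_mean: float = 80.0,
                   seed: int = 0, fps_total: float = 30.0,
                   noise_sd: float = 1.0, transient_rate_hz: float = 0.25,
                   transient_amp: float = 0.15
                   ) -> tuple["DualChannelMovie", SyntheticMovieTruth]:
    """Simulate an interleaved dual-illumination calcium movie.

    Even frames are blue (calcium-sensitive), odd frames green
    (reflectance). Blue frames read
    ``base_b * (1 + dff_ca) * (1 + hemo) + noise`` and green frames
    ``base_g * (1 + hemo) + noise``, so a ratiometric correction can remove
    the shared haemodynamic term exactly. Calcium dF/F is a sum of Gaussian
    cell footprints driven by Poisson events convolved with an exponential
    kernel of time constant ``transient_tau_s``. Outlier frames (LED
    dropouts / gross motion) are replaced by a uniform intensity far from
    both channel means. Rigid integer shifts up to ``max_shift_px`` are
    applied circularly per frame and recorded in the truth.
    """
    from .calcium_pipeline import DualChannelMovie  # avoid import cycle

    T, H, W = shape
    if T % 2 != 0:
        raise ParameterError("frame count T must be even (alternating channels)")
    if blue_mean == green_mean:
        raise ParameterError(
            "blue_mean must differ from green_mean (K-means separability)")
    rng = np.random.default_rng(seed)
    n_pairs = T // 2
    fps_channel = fps_total / 2.0

    mask = _disk_mask(H, W)
    # static spatial pattern gives the registration something to lock onto
    texture = 1.0 + 0.15 * rng.standard_normal((H, W))
    texture = np.clip(texture, 0.4, 1.6)
    base = np.where(mask, texture, 0.35 * texture)
    blue_base = blue_mean * base
    green_base = green_mean * base

    # cell footprints inside the mask
    yy, xx = np.mgrid[0:H, 0:W]
    footprints = np.zeros((n_cells, H, W))
    sigma = max(2.0, min(H, W) / 14.0)
    inside = np.argwhere(mask)
    centers = inside[rng.choice(len(inside), size=n_cells, replace=False)]
    for k, (cy, cx) in enumerate(centers):
        footprints[k] = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))
        footprints[k][~mask] = 0.0

    # transient trains: Poisson events * exponential decay kernel
    p_event = min(1.0, transient_rate_hz / fps_channel)
    events = rng.random((n_pairs, n_cells)) < p_event
    kernel_len = max(1, int(round(6 * transient_tau_s * fps_channel)))
    kernel = np.exp(-np.arange(kernel_len) / (transient_tau_s * fps_channel))
    traces = np.zeros((n_pairs, n_cells))
    for k in range(n_cells):
        traces[:, k] = np.convolve(events[:, k].astype(float), kernel)[:n_pairs]
    # soft saturation (indicator-dye nonlinearity): bounds the per-frame
    # fluorescence excursion even when several events stack
    traces = transient_amp * np.tanh(traces)

    # shared slow haemodynamic fluctuation, fractional
    t_full = np.arange(T) / fps_total
    slow = rng.standard_normal(T)
    win = max(3, int(fps_total))            # ~1 s smoothing -> <~0.5 Hz content
    slow = np.convolve(slow, np.ones(win) / win, mode="same")
    slow = slow / (np.std(slow) + 1e-12)
    hemo = hemo_amp * (0.7 * np.sin(2 * np.pi * 0.4 * t_full) + 0.5 * slow)

    dff = np.tensordot(traces, footprints, axes=(1, 0))   # (n_pairs, H, W)

    frames = np.zeros((T, H, W))
    labels = np.empty(T, dtype=object)
    for i in range(T):
        if i % 2 == 0:
            p = i // 2
            img = blue_base * (1.0 + dff[p]) * (1.0 + hemo[i])
            labels[i] = "blue"
        else:
            img = green_base * (1.0 + hemo[i])
            labels[i] = "green"
        frames[i] = img + noise_sd * rng.standard_normal((H, W))

    shifts = np.zeros((T, 2), dtype=int)
    if max_shift_px > 0:
        shifts = rng.integers(-max_shift_px, max_shift_px + 1, size=(T, 2))
        shifts[0] = 0          # the trial's first frame defines the reference FOV
        for i in range(T):
            frames[i] = np.roll(frames[i], tuple(shifts[i]), axis=(0, 1))

    n_out = int(round(outlier_frac * T))
    outlier_idx = (rng.choice(T, size=n_out, replace=False) if n_out
                   else np.empty(0, dtype=int))
    for i in outlier_idx:
        frames[i] = 3.0 * max(blue_mean, green_mean)   # far above both clusters
        labels[i] = "outlier"

    frames_u16 = np.clip(np.round(frames), 0, np.iinfo(np.uint16).max
                         ).astype(np.uint16)
    movie = DualChannelMovie(frames=frames_u16, fps_total=fps_total)
    truth = SyntheticMovieTruth(
        labels=np.array([str(l) for l in labels]),
        cell_traces=traces, footprints=footprints, hemo=hemo,
        shifts=shifts, mask=mask, outlier_frames=np.sort(outlier_idx),
        fps_total=fps_total,
    )
    return movie, truth
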