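"""Pose-stream data model, CSV readers/writers and confidence gating.

Two on-disk dialects are supported:

* the DeepLabCut-style CSV with a triple header (scorer / bodyparts /
  coords) and per-bodypart ``x, y, likelihood`` columns, and
* a plain long-format CSV with columns
  ``frame,x_head,y_head,conf_head,x_tail,y_tail,conf_tail``.

Coordinates are raw image pixels (x right, y down); nothing here converts
to metres — that happens only through :class:`ArenaSpec.px_per_m` at the
point of use. Trackers emit NaN coordinates on lost frames; those are kept
in the stream but demoted to confidence 0 so the gate removes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, PoseFormatError, StreamError

HEAD_ALIASES = ("head",)
TAIL_ALIASES = ("tailbase", "tail_base", "tail")

PLAIN_COLUMNS = ["frame", "x_head", "y_head", "conf_head",
                 "x_tail", "y_tail", "conf_tail"]


@dataclass(frozen=True)
class PoseSample:
    """One camera frame's head/tailbase estimate — the controller's only input."""

    frame_index: int
    timestamp_s: float
    head_xy: np.ndarray
    tail_xy: np.ndarray
    head_conf: float
    tail_conf: float


@dataclass(frozen=True)
class ArenaSpec:
    """Behavioural arena geometry and camera timing.

    ``size_m`` is the diameter (circular), track length (linear) or side
    (open field). ``px_per_m`` maps image pixels to metres. Overhead
    behaviour cameras in this setting run at roughly 6–10 frames per second.
    """

    kind: str
    size_m: float
    px_per_m: float
    fps: float

    def __post_init__(self):
        if self.kind not in ("circular", "linear", "open_field"):
            raise ParameterError(f"unknown arena kind {self.kind!r}")
        if self.size_m <= 0 or self.px_per_m <= 0:
            raise ParameterError("size_m and px_per_m must be positive")
        if not 0 < self.fps <= 1000:
            raise ParameterError(f"fps {self.fps} outside sane range")


@dataclass(frozen=True)
class AnnotationRecord:
    """Manually annotated ground-truth head/tailbase position for one frame."""

    frame_index: int
    true_head_xy: np.ndarray
    true_tail_xy: np.ndarray


@dataclass
class PoseStream:
    """Ordered per-frame pose estimates held as flat numpy arrays."""

    frame_index: np.ndarray
    timestamp_s: np.ndarray
    head_xy: np.ndarray
    tail_xy: np.ndarray
    head_conf: np.ndarray
    tail_conf: np.ndarray

    def __post_init__(self):
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self.timestamp_s = np.asarray(self.timestamp_s, dtype=float)
        self.head_xy = np.asarray(self.head_xy, dtype=float).reshape(-1, 2)
        self.tail_xy = np.asarray(self.tail_xy, dtype=float).reshape(-1, 2)
        self.head_conf = np.asarray(self.head_conf, dtype=float)
        self.tail_conf = np.asarray(self.tail_conf, dtype=float)
        n = len(self.frame_index)
        for arr in (self.timestamp_s, self.head_xy, self.tail_xy,
                    self.head_conf, self.tail_conf):
            if len(arr) != n:
                raise StreamError("field lengths disagree")
        if n > 1 and not np.all(np.diff(self.frame_index) > 0):
            raise StreamError("frame_index must be strictly increasing")
        # non-finite coordinates: keep the row, gate it out via confidence 0
        bad_head = ~np.isfinite(self.head_xy).all(axis=1)
        bad_tail = ~np.isfinite(self.tail_xy).all(axis=1)
        self.head_conf = np.where(bad_head, 0.0, self.head_conf)
        self.tail_conf = np.where(bad_tail, 0.0, self.tail_conf)
        self.head_xy = np.nan_to_num(self.head_xy)
        self.tail_xy = np.nan_to_num(self.tail_xy)
        self.head_conf = np.nan_to_num(np.clip(self.head_conf, 0.0, 1.0))
        self.tail_conf = np.nan_to_num(np.clip(self.tail_conf, 0.0, 1.0))

    def __len__(self) -> int:
        return len(self.frame_index)

    def __getitem__(self, i: int) -> PoseSample:
        return PoseSample(
            frame_index=int(self.frame_index[i]),
            timestamp_s=float(self.timestamp_s[i]),
            head_xy=self.head_xy[i].copy(),
            tail_xy=self.tail_xy[i].copy(),
            head_conf=float(self.head_conf[i]),
            tail_conf=float(self.tail_conf[i]),
        )

    def __iter__(self) -> Iterator[PoseSample]:
        for i in range(len(self)):
            yield self[i]

    def copy(self) -> "PoseStream":
        return PoseStream(
            self.frame_index.copy(), self.timestamp_s.copy(),
            self.head_xy.copy(), self.tail_xy.copy(),
            self.head_conf.copy(), self.tail_conf.copy(),
        )


def gate_sample(sample: PoseSample, conf_threshold: float) -> bool:
    """Confidence gate: accept only if *both* keypoints exceed the threshold.

    The comparison is strict (``conf > threshold``), i.e. accuracy must be
    *above* the threshold; the canonical operating point is 0.9.
    """
    if not 0.0 <= conf_threshold <= 1.0:
        raise ParameterError("conf_threshold must lie in [0, 1]")
    return bool(sample.head_conf > conf_threshold
                and sample.tail_conf > conf_threshold)


def gate_stream(stream: PoseStream, conf_threshold: float) -> np.ndarray:
    """Vectorised :func:`gate_sample`: boolean acceptance per frame."""
    if not 0.0 <= conf_threshold <= 1.0:
        raise ParameterError("conf_threshold must lie in [0, 1]")
    return (stream.head_conf > conf_threshold) & (stream.tail_conf > conf_threshold)


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def _find_bodypart(bodyparts: Sequence[str], aliases: Sequence[str],
                   role: str) -> str:
    for alias in aliases:
        if alias in bodyparts:
            return alias
    raise PoseFormatError(
        f"no {role} bodypart column found (looked for {list(aliases)}; "
        f"file has {sorted(set(bodyparts))})")


def read_pose_csv(path: str | Path, fps: float | None = None,
                  head_aliases: Sequence[str] = HEAD_ALIASES,
                  tail_aliases: Sequence[str] = TAIL_ALIASES) -> PoseStream:
    """Read a pose stream from either supported CSV dialect.

    ``fps`` converts frame indices to timestamps; without it, timestamps
    equal the frame index (i.e. a nominal 1 fps clock).
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.split(",")[0].strip().lower() == "scorer":
        return _read_dlc_csv(path, fps, head_aliases, tail_aliases)
    return _read_plain_csv(path, fps)


def _timestamps(frames: np.ndarray, fps: float | None) -> np.ndarray:
    return frames / fps if fps else frames.astype(float)


def _read_dlc_csv(path: Path, fps, head_aliases, tail_aliases) -> PoseStream:
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    bodyparts = [c[1] for c in df.columns]
    head = _find_bodypart(bodyparts, head_aliases, "head")
    tail = _find_bodypart(bodyparts, tail_aliases, "tailbase")
    scorer = df.columns[0][0]

    def col(part, coord):
        key = (scorer, part, coord)
        if key not in df.columns:
            raise PoseFormatError(f"missing column {part}/{coord}")
        return df[key].to_numpy(dtype=float)

    frames = df.index.to_numpy(dtype=np.int64)
    if len(frames) > 1 and not np.all(np.diff(frames) > 0):
        raise StreamError(f"{path}: non-monotone frame index")
    return PoseStream(
        frame_index=frames,
        timestamp_s=_timestamps(frames, fps),
        head_xy=np.column_stack([col(head, "x"), col(head, "y")]),
        tail_xy=np.column_stack([col(tail, "x"), col(tail, "y")]),
        head_conf=col(head, "likelihood"),
        tail_conf=col(tail, "likelihood"),
    )


def _read_plain_csv(path: Path, fps) -> PoseStream:
    df = pd.read_csv(path)
    missing = [c for c in PLAIN_COLUMNS if c not in df.columns]
    if missing:
        raise PoseFormatError(f"{path}: missing columns {missing}")
    frames = df["frame"].to_numpy(dtype=np.int64)
    if len(frames) > 1 and not np.all(np.diff(frames) > 0):
        raise StreamError(f"{path}: non-monotone frame index")
    return PoseStream(
        frame_index=frames,
        timestamp_s=_timestamps(frames, fps),
        head_xy=df[["x_head", "y_head"]].to_numpy(dtype=float),
        tail_xy=df[["x_tail", "y_tail"]].to_numpy(dtype=float),
        head_conf=df["conf_head"].to_numpy(dtype=float),
        tail_conf=df["conf_tail"].to_numpy(dtype=float),
    )


def write_pose_csv(stream: PoseStream, path: str | Path,
                   dialect: str = "dlc", scorer: str = "activecomm") -> None:
    """Write a pose stream as DLC-dialect (default) or plain long CSV."""
    path = Path(path)
    if dialect == "plain":
        df = pd.DataFrame({
            "frame": stream.frame_index,
            "x_head": stream.head_xy[:, 0], "y_head": stream.head_xy[:, 1],
            "conf_head": stream.head_conf,
            "x_tail": stream.tail_xy[:, 0], "y_tail": stream.tail_xy[:, 1],
            "conf_tail": stream.tail_conf,
        })
        df.to_csv(path, index=False, float_format="%.6f")
        return
    if dialect != "dlc":
        raise ParameterError(f"unknown dialect {dialect!r}")
    cols = pd.MultiIndex.from_tuples(
        [(scorer, part, coord)
         for part in ("head", "tailbase")
         for coord in ("x", "y", "likelihood")],
        names=["scorer", "bodyparts", "coords"])
    data = np.column_stack([
        stream.head_xy[:, 0], stream.head_xy[:, 1], stream.head_conf,
        stream.tail_xy[:, 0], stream.tail_xy[:, 1], stream.tail_conf,
    ])
    df = pd.DataFrame(data, index=stream.frame_index, columns=cols)
    df.to_csv(path, float_format="%.6f")


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read a manual-annotation CSV (frame,x_head,y_head,x_tail,y_tail)."""
    df = pd.read_csv(path)
    required = ["frame", "x_head", "y_head", "x_tail", "y_tail"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PoseFormatError(f"{path}: missing columns {missing}")
    return [
        AnnotationRecord(
            frame_index=int(r.frame),
            true_head_xy=np.array([r.x_head, r.y_head], dtype=float),
            true_tail_xy=np.array([r.x_tail, r.y_tail], dtype=float),
        )
        for r in df.itertuples()
    ]


def write_annotations(records: Sequence[AnnotationRecord],
                      path: str | Path) -> None:
    pd.DataFrame({
        "frame": [r.frame_index for r in records],
        "x_head": [r.true_head_xy[0] for r in records],
        "y_head": [r.true_head_xy[1] for r in records],
        "x_tail": [r.true_tail_xy[0] for r in records],
        "y_tail": [r.true_tail_xy[1] for r in records],
    }).to_csv(path, index=False, float_format="%.6f")
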