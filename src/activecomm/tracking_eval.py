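"""Evaluation of pose streams against manual annotations.

A prediction matches the annotation when it falls within an inclusive
radius (10 px is the canonical choice) of the hand-labelled point. Per
annotated frame the bookkeeping is: confident and within radius -> TP;
confident but outside the radius -> FP *and* FN (the reported point is
spurious and the true point went undetected); not confident (or missing)
-> FN only. Precision = TP/(TP+FP) and sensitivity = TP/(TP+FN) therefore
differ whenever wrong-but-confident and unconfident frames mix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import AlignmentError, ParameterError
from .pose_io import AnnotationRecord, PoseStream, gate_stream


@dataclass(frozen=True)
class EvalResult:
    """Radius-thresholded detection metrics for one bodypart."""

    precision: Optional[float]    # None when no confident predictions exist
    sensitivity: float
    n_tp: int
    n_fp: int
    n_fn: int
    radius_px: float

    def to_dict(self) -> dict:
        return {
            "precision": self.precision, "sensitivity": self.sensitivity,
            "n_tp": self.n_tp, "n_fp": self.n_fp, "n_fn": self.n_fn,
            "radius_px": self.radius_px,
        }


def match_prediction(pred_xy: np.ndarray, true_xy: np.ndarray,
                     radius_px: float) -> bool:
    """Inclusive radius test: Euclidean distance <= radius."""
    if radius_px <= 0:
        raise ParameterError("radius_px must be positive")
    d = np.asarray(pred_xy, dtype=float) - np.asarray(true_xy, dtype=float)
    return bool(math.hypot(d[0], d[1]) <= radius_px)


def precision_sensitivity(preds: PoseStream,
                          annotations: Sequence[AnnotationRecord],
                          radius_px: float = 10.0,
                          conf_threshold: float = 0.9,
                          bodypart: str = "head") -> EvalResult:
    """Precision and sensitivity on annotated frames.

    Every annotation frame must be present in ``preds``. ``bodypart``
    selects which keypoint is scored ("head" or "tailbase"); confidence is
    that keypoint's own likelihood (strict > threshold).
    """
    if bodypart not in ("head", "tailbase"):
        raise ParameterError(f"unknown bodypart {bodypart!r}")
    index = {int(f): i for i, f in enumerate(preds.frame_index)}
    xy = preds.head_xy if bodypart == "head" else preds.tail_xy
    conf = preds.head_conf if bodypart == "head" else preds.tail_conf
    tp = fp = fn = 0
    for ann in annotations:
        if ann.frame_index not in index:
            raise AlignmentError(
                f"annotation frame {ann.frame_index} absent from predictions")
        i = index[ann.frame_index]
        truth = ann.true_head_xy if bodypart == "head" else ann.true_tail_xy
        if conf[i] > conf_threshold:
            if match_prediction(xy[i], truth, radius_px):
                tp += 1
            else:
                fp += 1     # spurious detection ...
                fn += 1     # ... and the annotated point was missed
        else:
            fn += 1
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    return EvalResult(precision=precision, sensitivity=sensitivity,
                      n_tp=tp, n_fp=fp, n_fn=fn, radius_px=radius_px)


def fraction_below_accuracy(stream: PoseStream,
                            conf_threshold: float = 0.9) -> float:
    """Fraction of frames failing the confidence gate at the threshold."""
    if len(stream) == 0:
        raise ParameterError("empty pose stream")
    return float(np.mean(~gate_stream(stream, conf_threshold)))


def latency_summary(latencies_ms: Sequence[float]) -> tuple[float, float]:
    """Mean and sample SD of per-frame inference latencies (ms)."""
    arr = np.asarray(latencies_ms, dtype=float)
    if arr.size == 0:
        raise ParameterError("empty latency list")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd
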