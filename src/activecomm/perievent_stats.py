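"""Peri-event statistics around commutation epochs.

Does motor-driven compensation of the tether perturb the measured calcium
signal? To answer that, ROI-mean z-scored DF/F traces are averaged around
compensation events (a peri-event time histogram, PETH), and compared
against a bootstrap null built from the whole trial: windows of the same
length are drawn uniformly at random (with replacement), averaged in
groups matching the real event count, and the per-timepoint mean and SD of
1000 such surrogate PETHs define the null band. Timepoints are flagged only
when their empirical two-sided tail probability survives Bonferroni
correction across all tested timepoints (and ROIs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError

DEFAULT_WINDOW_S = (2.0, 10.0)   # pre, post — covers a 720 deg turn at ~100 deg/s


@dataclass(frozen=True)
class Epoch:
    """One compensation event: [start_frame, end_frame) at the DF/F frame rate."""

    start_frame: int
    end_frame: int
    direction: str = "CW"        # CW | CCW
    magnitude_deg: float = 0.0

    def __post_init__(self):
        if self.end_frame <= self.start_frame:
            raise ParameterError("epoch end must exceed start")
        if self.direction not in ("CW", "CCW"):
            raise ParameterError(f"bad direction {self.direction!r}")


@dataclass
class RoiTrace:
    """ROI-mean z-scored DF/F time series."""

    roi_name: str
    series: np.ndarray
    fps: float

    def __post_init__(self):
        self.series = np.asarray(self.series, dtype=float)
        if not np.all(np.isfinite(self.series)):
            raise ParameterError(f"ROI {self.roi_name}: non-finite samples")


@dataclass
class PethResult:
    """Event-aligned average with its bootstrap null and significance flags."""

    roi_name: str
    window_frames: np.ndarray    # offsets relative to event onset
    mean_trace: np.ndarray
    n_events: int
    null_mean: np.ndarray
    null_sd: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    alpha: float
    m_tests: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "offset_frames": self.window_frames,
            "mean": self.mean_trace,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "p_value": self.p_values,
            "significant": self.significant,
        })


def extract_roi_traces(dff, roi_masks: dict[str, np.ndarray],
                       fps: Optional[float] = None) -> list[RoiTrace]:
    """Average a DF/F stack over each named ROI mask.

    ``dff`` is a :class:`~activecomm.calcium_pipeline.DffMovie` or a plain
    (T, H, W) array (then ``fps`` is required). Empty ROIs raise, naming
    the offender.
    """
    data = getattr(dff, "data", dff)
    rate = getattr(dff, "fps_channel", None) or fps
    if rate is None:
        raise ParameterError("fps required when passing a bare array")
    traces = []
    for name, m in roi_masks.items():
        m = np.asarray(m, dtype=bool)
        if m.shape != data.shape[1:]:
            raise ParameterError(f"ROI {name!r}: mask shape {m.shape} does "
                                 f"not fit frames {data.shape[1:]}")
        if not m.any():
            raise ParameterError(f"ROI {name!r} is empty")
        traces.append(RoiTrace(name, data[:, m].mean(axis=1), rate))
    return traces


def _window_frames(window_s: tuple[float, float], fps: float) -> np.ndarray:
    pre = int(round(window_s[0] * fps))
    post = int(round(window_s[1] * fps))
    return np.arange(-pre, post + 1)


def peth(trace: RoiTrace, epochs: Sequence[Epoch],
         window_s: tuple[float, float] = DEFAULT_WINDOW_S
         ) -> tuple[np.ndarray, np.ndarray, int]:
    """Event-aligned average around epoch onsets.

    Returns ``(offsets_frames, mean_trace, n_events_used)``. Events whose
    window spills past the trial edges are dropped with a warning; zero
    usable events is an error.
    """
    offs = _window_frames(window_s, trace.fps)
    n = len(trace.series)
    rows = []
    for e in epochs:
        idx = e.start_frame + offs
        if idx[0] < 0 or idx[-1] >= n:
            warnings.warn(f"epoch at frame {e.start_frame} does not fit the "
                          "trial; dropped", stacklevel=2)
            continue
        rows.append(trace.series[idx])
    if not rows:
        raise ParameterError("no usable events for the PETH")
    stack = np.array(rows)
    return offs, stack.mean(axis=0), len(rows)


def bootstrap_null(trace: RoiTrace, window_len: int, n_events: int = 1,
                   n_boot: int = 1000, seed: int = 0,
                   exclude: Optional[Sequence[Epoch]] = None
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Surrogate PETH distribution from the whole trial.

    Draws ``n_boot`` groups of ``n_events`` windows of length
    ``window_len`` uniformly at random (with replacement) from the trial,
    averages each group, and returns per-timepoint ``(null_mean, null_sd,
    surrogates)`` where ``surrogates`` is the (n_boot, window_len) matrix of
    group means. ``exclude`` optionally removes start positions whose
    window would overlap the given epochs.
    """
    series = trace.series
    n = len(series)
    if n <= window_len:
        raise ParameterError("trial shorter than the PETH window")
    rng = np.random.default_rng(seed)
    valid = np.arange(n - window_len + 1)
    if exclude:
        bad = np.zeros(n, dtype=bool)
        for e in exclude:
            bad[max(0, e.start_frame - window_len + 1):e.end_frame] = True
        valid = valid[~bad[valid]]
        if len(valid) == 0:
            raise ParameterError("exclusion left no valid window positions")
    starts = rng.choice(valid, size=(n_boot, n_events), replace=True)
    windows = series[starts[..., None] + np.arange(window_len)]
    surrogates = windows.mean(axis=1)
    return surrogates.mean(axis=0), surrogates.std(axis=0), surrogates


def flag_significance(mean_trace: np.ndarray, surrogates: np.ndarray,
                      alpha: float = 0.05, m_tests: Optional[int] = None,
                      method: str = "empirical", sd_floor: float = 0.0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni-corrected per-timepoint significance against the null.

    ``method="empirical"``: two-sided bootstrap tail probability
    ``(1 + #{|surrogate - null_mean| >= |observed - null_mean|}) / (n_boot + 1)``
    compared with ``alpha / m_tests``. ``method="sd"`` uses the normal
    SD-threshold approximation instead. Returns ``(p_values, flags)``.
    """
    mean_trace = np.asarray(mean_trace, dtype=float)
    if m_tests is None:
        m_tests = len(mean_trace)
    if m_tests < 1:
        raise ParameterError("m_tests must be >= 1")
    null_mean = surrogates.mean(axis=0)
    dev = np.abs(mean_trace - null_mean)
    if method == "empirical":
        exceed = (np.abs(surrogates - null_mean) >= dev).sum(axis=0)
        p = (1.0 + exceed) / (surrogates.shape[0] + 1.0)
    elif method == "sd":
        from scipy import stats
        sd = np.maximum(surrogates.std(axis=0), max(sd_floor, 1e-12))
        p = 2.0 * stats.norm.sf(dev / sd)
    else:
        raise ParameterError(f"unknown method {method!r}")
    return p, p < alpha / m_tests


def run_peth(trace: RoiTrace, epochs: Sequence[Epoch],
             window_s: tuple[float, float] = DEFAULT_WINDOW_S,
             n_boot: int = 1000, seed: int = 0, alpha: float = 0.05,
             m_tests: Optional[int] = None, method: str = "empirical",
             exclude_events: bool = False) -> PethResult:
    """PETH + bootstrap null + Bonferroni flags for one ROI.

    ``m_tests`` defaults to the number of tested timepoints; when several
    ROIs are analysed together, pass ``n_rois * n_timepoints`` for the
    family-wise correction across the whole analysis.
    """
    offs, mean_trace, n_used = peth(trace, epochs, window_s)
    null_mean, null_sd, surr = bootstrap_null(
        trace, len(offs), n_events=n_used, n_boot=n_boot, seed=seed,
        exclude=epochs if exclude_events else None)
    p, flags = flag_significance(mean_trace, surr, alpha=alpha,
                                 m_tests=m_tests or len(offs), method=method)
    return PethResult(
        roi_name=trace.roi_name, window_frames=offs, mean_trace=mean_trace,
        n_events=n_used, null_mean=null_mean, null_sd=null_sd,
        p_values=p, significant=flags, alpha=alpha,
        m_tests=m_tests or len(offs))


# ---------------------------------------------------------------------------
# epochs I/O and RunLog bridge
# ---------------------------------------------------------------------------

def epochs_to_csv(epochs: Sequence[Epoch], path: str | Path) -> None:
    pd.DataFrame({
        "start_frame": [e.start_frame for e in epochs],
        "end_frame": [e.end_frame for e in epochs],
        "direction": [e.direction for e in epochs],
        "magnitude_deg": [e.magnitude_deg for e in epochs],
    }).to_csv(path, index=False, float_format="%.6f")


def epochs_from_csv(path: str | Path) -> list[Epoch]:
    df = pd.read_csv(path)
    return [Epoch(int(r.start_frame), int(r.end_frame), str(r.direction),
                  float(r.magnitude_deg)) for r in df.itertuples()]


def epochs_from_runlog(runlog, fps_behavior: float, fps_dff: float,
                       rotation_speed_dps: float = 100.0) -> list[Epoch]:
    """Turn a controller RunLog's rotation commands into imaging-frame epochs.

    Each rotate command becomes an epoch starting at the command's time and
    lasting |angle| / rotation speed, converted to DF/F frame indices.
    """
    epochs = []
    for frame, cmd in runlog.commands:
        if cmd.kind != "rotate_by":
            continue
        t0 = frame / fps_behavior
        dur = abs(cmd.rotate_deg) / rotation_speed_dps
        start = int(round(t0 * fps_dff))
        end = max(start + 1, int(round((t0 + dur) * fps_dff)))
        epochs.append(Epoch(start, end,
                            "CW" if cmd.rotate_deg >= 0 else "CCW",
                            abs(cmd.rotate_deg)))
    return epochs
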