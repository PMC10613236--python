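"""Movement-trace cleaning and movement-stereotypy statistics.

Traces follow the tracking-export CSV dialect: one row per camera frame
with ``bodypart, frame, x, y, likelihood``.  Cleaning applies, in order:
(1) linear interpolation across low-confidence points, (2) replacement
of outliers that deviate more than 3x the (unscaled) median absolute
deviation within a centered 5-frame window, and (3) a 3-frame
moving-average smooth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CAMERA_RATE_HZ = 60.0


@dataclass
class MovementTrace:
    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray
    bodypart: str = "right_forelimb"
    rate_hz: float = CAMERA_RATE_HZ

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.likelihood)):
            raise ValueError("x, y, likelihood must be equally long")
        if np.any((self.likelihood < 0) | (self.likelihood > 1)):
            raise ValueError("likelihood must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.x)

    @classmethod
    def from_table(cls, table: pd.DataFrame, bodypart: str | None = None) -> "MovementTrace":
        t = table
        if bodypart is not None:
            t = t[t["bodypart"] == bodypart]
        elif "bodypart" in t.columns:
            parts = t["bodypart"].unique()
            if len(parts) != 1:
                raise ValueError(f"multiple bodyparts present {list(parts)}; pick one")
            bodypart = str(parts[0])
        t = t.sort_values("frame") if "frame" in t.columns else t
        return cls(
            x=t["x"].to_numpy(),
            y=t["y"].to_numpy(),
            likelihood=t["likelihood"].to_numpy(),
            bodypart=bodypart or "right_forelimb",
        )


def _interpolate_low_confidence(values: np.ndarray, ok: np.ndarray) -> np.ndarray:
    """Replace not-``ok`` points by linear interpolation between the
    nearest flanking ok points; leading/trailing gaps take the nearest
    ok value."""
    if not ok.any():
        raise ValueError("no point with likelihood >= threshold to anchor interpolation")
    idx = np.arange(len(values))
    return np.interp(idx, idx[ok], values[ok])


def _replace_mad_outliers(values: np.ndarray, window: int = 5, k: float = 3.0) -> np.ndarray:
    """Replace points deviating > k*MAD within a centered window by the
    previous (already processed) value; an outlier at frame 0 takes the
    next non-outlier value."""
    n = len(values)
    half = window // 2
    med = np.empty(n)
    mad = np.empty(n)
    for i in range(n):
        w = values[max(0, i - half):min(n, i + half + 1)]
        m = np.median(w)
        med[i] = m
        mad[i] = np.median(np.abs(w - m))
    is_out = np.abs(values - med) > k * mad
    out = values.copy()
    first_good = np.flatnonzero(~is_out)
    for i in np.flatnonzero(is_out):
        if i == 0:
            if first_good.size == 0:
                continue  # everything flagged: leave untouched
            out[i] = values[first_good[0]]
        else:
            out[i] = out[i - 1]
    return out


def _moving_average(values: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average; edge windows shrink."""
    kernel = np.ones(window)
    sums = np.convolve(values, kernel, mode="same")
    counts = np.convolve(np.ones_like(values), kernel, mode="same")
    return sums / counts


def clean_movement_trace(
    trace: MovementTrace,
    likelihood_threshold: float = 0.95,
    mad_window: int = 5,
    mad_k: float = 3.0,
    smooth_window: int = 3,
) -> MovementTrace:
    """Confidence interpolation, MAD outlier replacement, then smoothing."""
    if len(trace) < mad_window:
        raise ValueError(f"need at least {mad_window} frames")
    ok = trace.likelihood >= likelihood_threshold
    x = _interpolate_low_confidence(trace.x, ok)
    y = _interpolate_low_confidence(trace.y, ok)
    x = _replace_mad_outliers(x, mad_window, mad_k)
    y = _replace_mad_outliers(y, mad_window, mad_k)
    x = _moving_average(x, smooth_window)
    y = _moving_average(y, smooth_window)
    return replace(trace, x=x, y=y, likelihood=np.ones_like(trace.likelihood))


def epoch_distance(trace: MovementTrace, frames: "range | np.ndarray") -> float:
    """Euclidean path length (pixels) over consecutive frames of an epoch."""
    idx = np.asarray(list(frames) if isinstance(frames, range) else frames, dtype=int)
    if idx.size < 2:
        logger.warning("epoch shorter than 2 frames; distance is 0")
        return 0.0
    dx = np.diff(trace.x[idx])
    dy = np.diff(trace.y[idx])
    return float(np.sum(np.sqrt(dx**2 + dy**2)))


def camera_frames_for_epoch(frames: range, frame_rate: float,
                            camera_rate: float = CAMERA_RATE_HZ) -> range:
    """Map an imaging-frame epoch to camera frames."""
    ratio = camera_rate / frame_rate
    return range(int(frames.start * ratio), int(frames.stop * ratio))


def movement_stereotypy(
    trajectories: "list[np.ndarray]",
) -> tuple[np.ndarray, float, int]:
    """Pairwise Pearson correlations of baseline-subtracted trajectories.

    Each trajectory is the per-trial epoch path with x and y concatenated
    (in this order) after subtracting the trial's first-frame position.
    Returns (all pairwise correlations, their median, number of excluded
    zero-variance pairs).
    """
    if len(trajectories) < 2:
        raise ValueError("need at least 2 trials")
    # frame-rate conversion can leave trials one camera frame apart;
    # crop to the common length before correlating
    n_min = min(len(xy) for xy in trajectories)
    flat = []
    for xy in trajectories:
        xy = np.asarray(xy, dtype=float)[:n_min]
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValueError("each trajectory must be (frames, 2)")
        rel = xy - xy[0]
        flat.append(np.concatenate([rel[:, 0], rel[:, 1]]))
    flat = np.asarray(flat)
    corrs = []
    excluded = 0
    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            a, b = flat[i], flat[j]
            if a.std() == 0 or b.std() == 0:
                excluded += 1
                continue
            corrs.append(float(np.corrcoef(a, b)[0, 1]))
    corrs = np.asarray(corrs)
    median = float(np.median(corrs)) if corrs.size else float("nan")
    if excluded:
        logger.warning("excluded %d zero-variance trajectory pairs", excluded)
    return corrs, median, excluded


def trial_trajectories(
    trace: MovementTrace,
    trials: pd.DataFrame,
    epoch_frames_per_trial: "list[range]",
    frame_rate: float,
) -> list[np.ndarray]:
    """Extract per-trial (frames, 2) camera-frame trajectories for an epoch."""
    out = []
    for frames in epoch_frames_per_trial:
        cam = camera_frames_for_epoch(frames, frame_rate, trace.rate_hz)
        sl = slice(cam.start, min(cam.stop, len(trace)))
        out.append(np.column_stack([trace.x[sl], trace.y[sl]]))
    return out


def read_tracking_csv(path: str, bodypart: str | None = None) -> MovementTrace:
    return MovementTrace.from_table(pd.read_csv(path), bodypart=bodypart)


def write_tracking_csv(trace: MovementTrace, path: str) -> None:
    pd.DataFrame(
        {
            "bodypart": trace.bodypart,
            "frame": np.arange(len(trace)),
            "x": trace.x,
            "y": trace.y,
            "likelihood": trace.likelihood,
        }
    ).to_csv(path, index=False)
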