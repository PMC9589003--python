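"""Raw keypoint sequence -> analysis segment.

The analysis unit is a face-toward, MidHip-centred, Gaussian-smoothed,
fixed-length (default 75 frames at 25 Hz, i.e. a 3-s window) segment of the
24 retained joints (48 x/y channels). Pipeline order is fixed:

    interpolate -> facing-select -> centre -> smooth -> standardise length

The smoothing filter is the 5-tap binomial kernel [1, 4, 6, 4, 1]/16 applied
as a forward window with no padding, so each pass shortens a series by 4
frames; length standardisation is a centre-crop, never a resampling, keeping
native frame timing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DataQualityError, FacingDetectionError, GaitWarning
from .io_keypoints import (
    BODY25_NAMES,
    MIDHIP,
    N_RETAINED,
    RETAINED_JOINTS,
    GaitSequence,
)

DEFAULT_KERNEL_WEIGHTS = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0
MIN_SEGMENT_FRAMES = 32  # 5-level dyadic decomposition feasibility


@dataclass
class SmoothingKernel:
    """Low-pass convolution kernel; the default is the binomial [1,4,6,4,1]/16."""

    weights: np.ndarray = field(default_factory=lambda: DEFAULT_KERNEL_WEIGHTS.copy())
    window: int = 5
    alignment: str = "forward"  # forward | centered; relabels output frames only

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != self.window:
            raise ValueError("window must equal the number of weights")
        if not math.isclose(self.weights.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("kernel weights must sum to 1")
        if self.alignment not in ("forward", "centered"):
            raise ValueError("alignment must be 'forward' or 'centered'")


@dataclass
class GaitSegment:
    """Centred, smoothed, fixed-length 24-joint segment (48 channels).

    ``data`` has shape (n_frames, 24, 2); ``joint_order`` lists the retained
    BODY25 indices (ascending, MidHip excluded). Channel order everywhere in
    the package is (joint ascending) x (x then y).
    """

    data: np.ndarray
    fps: float = 25.0
    participant_id: str = ""
    joint_order: tuple[int, ...] = RETAINED_JOINTS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1:] != (N_RETAINED, 2):
            raise ValueError(f"segment data must be (n, 24, 2), got {self.data.shape}")
        if self.data.shape[0] < MIN_SEGMENT_FRAMES:
            raise ValueError(
                f"segment has {self.data.shape[0]} frames; need >= {MIN_SEGMENT_FRAMES}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("segment data must be finite")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def joint_xy(self, body25_index: int) -> np.ndarray:
        """(n_frames, 2) trajectory of one retained joint, by BODY25 index."""
        return self.data[:, self.joint_order.index(body25_index), :]

    def channel_matrix(self) -> np.ndarray:
        """(48, n_frames) channel view in canonical order (per joint: x, then y)."""
        return self.data.transpose(1, 2, 0).reshape(2 * N_RETAINED, self.n_frames)

    @property
    def channel_names(self) -> list[str]:
        return [f"j{j:02d}_{ax}" for j in self.joint_order for ax in ("x", "y")]


@dataclass
class PreprocessConfig:
    fps: float = 25.0
    n_frames: int = 75
    filter_weights: np.ndarray = field(default_factory=lambda: DEFAULT_KERNEL_WEIGHTS.copy())
    filter_window: int = 5
    filter_alignment: str = "forward"
    min_conf: float = 0.1
    facing_window_s: float = 1.0
    facing_slope_min: float = 0.0

    def kernel(self) -> SmoothingKernel:
        return SmoothingKernel(self.filter_weights, self.filter_window,
                               self.filter_alignment)


# ---------------------------------------------------------------------------
# Steps
# ---------------------------------------------------------------------------

def interpolate_missing(seq: GaitSequence, min_conf: float = 0.1) -> GaitSequence:
    """Linearly interpolate low-confidence keypoints over time, per channel.

    Leading/trailing gaps take the nearest valid value; filled points get
    confidence ``min_conf``. A joint missing in more than half of the frames
    is a data-quality error.
    """
    if not 0 <= min_conf < 1:
        raise ValueError("min_conf must lie in [0, 1)")
    missing = seq.confidence < min_conf
    if not missing.any():
        return seq
    coords = seq.coords.copy()
    conf = seq.confidence.copy()
    n = seq.n_frames
    idx = np.arange(n)
    for j in range(coords.shape[1]):
        bad = missing[:, j]
        if not bad.any():
            continue
        if bad.mean() > 0.5:
            raise DataQualityError(
                f"joint {j} ({BODY25_NAMES[j]}): {bad.sum()}/{n} frames below "
                f"confidence {min_conf}")
        good = ~bad
        for ax in (0, 1):
            coords[bad, j, ax] = np.interp(idx[bad], idx[good], coords[good, j, ax])
        conf[bad, j] = min_conf
    return GaitSequence(coords, conf, fps=seq.fps, participant_id=seq.participant_id,
                        facing_labels=seq.facing_labels)


def detect_facing_segments(seq: GaitSequence, min_len: int = 75,
                           window_s: float = 1.0,
                           slope_min: float = 0.0) -> list[tuple[int, int]]:
    """Half-open [start, end) intervals where the walker faces the camera.

    Heuristic: the apparent torso length (Neck-MidHip distance, moving-average
    smoothed over ``window_s``) grows while the walker approaches, so frames
    with positive smoothed slope are face-toward. ``facing_labels`` metadata,
    when present on the sequence, overrides the heuristic. Intervals shorter
    than ``min_len`` frames are discarded.
    """
    if seq.n_frames < 2 * seq.fps:
        raise ValueError("sequence must be at least 2 s long")
    if seq.facing_labels is not None:
        mask = np.asarray([lab == "toward" for lab in seq.facing_labels])
    else:
        torso = np.linalg.norm(seq.coords[:, 1] - seq.coords[:, MIDHIP], axis=1)
        w = max(1, int(round(window_s * seq.fps)))
        kernel = np.ones(w) / w
        pad = np.pad(torso, (w // 2, w - 1 - w // 2), mode="edge")
        smooth = np.convolve(pad, kernel, mode="valid")
        # slope over a centred window-length baseline; a per-frame gradient is
        # far too noisy relative to the slow approach trend
        spad = np.pad(smooth, (w, w), mode="edge")
        slope = (spad[2 * w:] - spad[:-2 * w]) / (2 * w)
        mask = slope > slope_min
    intervals = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            if i - start >= min_len:
                intervals.append((start, i))
            start = None
    if start is not None and len(mask) - start >= min_len:
        intervals.append((start, len(mask)))
    if not intervals:
        raise FacingDetectionError(
            "no face-toward interval found; supply facing_labels metadata if the "
            "heuristic cannot apply")
    return intervals


def center_on_midhip(seq: GaitSequence) -> np.ndarray:
    """Subtract the MidHip coordinates per frame and drop the MidHip joint.

    Returns the (n_frames, 24, 2) array of the retained joints (ascending
    BODY25 order), which makes the rest of the pipeline translation-invariant.
    """
    if np.any(seq.confidence[:, MIDHIP] <= 0):
        raise DataQualityError("MidHip missing in some frames; interpolate first")
    centered = seq.coords - seq.coords[:, MIDHIP:MIDHIP + 1, :]
    return centered[:, list(RETAINED_JOINTS), :]


def gaussian_smooth(series: np.ndarray,
                    kernel: Optional[SmoothingKernel] = None) -> np.ndarray:
    """Forward-window binomial smoothing: Out[i] = sum_j w[j] * In[i+j].

    Operates along axis 0 of any array; output is shorter by ``window - 1``
    frames (no padding). The ``centered`` alignment produces identical values
    (the window is symmetric); it only relabels which input frame an output
    sample is attributed to, which the later centre-crop ignores.
    """
    kernel = kernel or SmoothingKernel()
    x = np.asarray(series, dtype=float)
    n = x.shape[0]
    w = kernel.window
    if n < w:
        raise ValueError(f"series of length {n} shorter than window {w}")
    out = np.zeros((n - w + 1,) + x.shape[1:])
    for j, wj in enumerate(kernel.weights):
        out += wj * x[j:n - w + 1 + j]
    return out


def standardize_length(data: np.ndarray, n_frames: int = 75, fps: float = 25.0,
                       participant_id: str = "") -> GaitSegment:
    """Centre-crop a centred+smoothed (n, 24, 2) array to exactly ``n_frames``.

    Warns when the estimated gait cycle length implies fewer than four full
    cycles in the window.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n < n_frames:
        raise ValueError(f"input of {n} frames shorter than target {n_frames}")
    off = (n - n_frames) // 2
    seg = GaitSegment(data[off:off + n_frames], fps=fps, participant_id=participant_id)
    cyc = estimate_cycle_length(seg)
    if np.isfinite(cyc) and 4 * cyc > n_frames:
        warnings.warn(
            f"window of {n_frames} frames holds fewer than 4 gait cycles "
            f"(estimated cycle {cyc:.1f} frames)", GaitWarning, stacklevel=2)
    return seg


def estimate_cycle_length(segment: GaitSegment) -> float:
    """Frames per gait cycle from the ankle-ankle horizontal distance.

    The series peaks twice per stride, so the cycle length is twice the lag of
    the first prominent positive autocorrelation peak (> 0.3). Returns NaN
    when no peak qualifies (e.g. constant channels).
    """
    d = np.abs(segment.joint_xy(11)[:, 0] - segment.joint_xy(14)[:, 0])
    d = d - d.mean()
    denom = float(d @ d)
    if denom <= 0:
        return math.nan
    n = len(d)
    ac = np.correlate(d, d, mode="full")[n - 1:] / denom
    for lag in range(2, n - 1):
        if ac[lag] > 0.3 and ac[lag] > ac[lag - 1] and ac[lag] >= ac[lag + 1]:
            return 2.0 * lag
    return math.nan


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def preprocess_sequence(seq: GaitSequence,
                        config: Optional[PreprocessConfig] = None) -> GaitSegment:
    """Run the full fixed-order pipeline on one raw sequence.

    The face-toward interval must be long enough that the smoothing loss of
    ``window - 1`` frames still leaves ``n_frames``; among qualifying
    intervals the longest (earliest on ties) is used.
    """
    config = config or PreprocessConfig()
    kernel = config.kernel()
    seq = interpolate_missing(seq, config.min_conf)
    need = config.n_frames + kernel.window - 1
    intervals = detect_facing_segments(seq, min_len=need,
                                       window_s=config.facing_window_s,
                                       slope_min=config.facing_slope_min)
    start, end = max(intervals, key=lambda iv: iv[1] - iv[0])
    sub = GaitSequence(seq.coords[start:end], seq.confidence[start:end],
                       fps=seq.fps, participant_id=seq.participant_id)
    centered = center_on_midhip(sub)
    smoothed = gaussian_smooth(centered, kernel)
    return standardize_length(smoothed, config.n_frames, fps=seq.fps,
                              participant_id=seq.participant_id)
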