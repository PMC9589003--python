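"""Time-domain gait features: 1,320 dimensions.

Ten summary statistics over four series families derived from a 48-channel
segment: the 48 raw channels, their 48 first-difference channels (the
inter-frame motion), 26 per-axis inter-joint distance channels (13 joint
pairs x {x, y}), and 10 inter-joint angle series. 48*10 + 48*10 + 26*10 +
10*10 = 1,320.

Statistic conventions (frozen here and in the docs): variance is the
population variance (divisor n); skewness m3/m2^1.5 and kurtosis m4/m2^2 - 3
are moment-based (excess), both defined as 0 for constant series; the
variation coefficient sqrt(var)/mean is 0 when |mean| < 1e-12; abs_energy is
the sum of squares. Angles are radians in [0, pi].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError
from .preprocess import GaitSegment

#: Angle indicators: (a, vertex b, c) BODY25 triples.
ANGLE_INDICATORS: dict[str, tuple[int, int, int]] = {
    "A0": (0, 1, 2), "A1": (0, 1, 5), "A2": (1, 2, 3), "A3": (1, 5, 6),
    "A4": (2, 3, 4), "A5": (5, 6, 7), "A6": (12, 9, 10), "A7": (9, 12, 13),
    "A8": (9, 10, 11), "A9": (12, 13, 14),
}

#: Distance indicators: joint pairs; each yields an |dx| and an |dy| channel.
DISTANCE_INDICATORS: dict[str, tuple[int, int]] = {
    "D1": (1, 0), "D2": (3, 2), "D3": (4, 2), "D4": (6, 5), "D5": (7, 5),
    "D6": (6, 3), "D7": (7, 4), "D8": (10, 9), "D9": (11, 9), "D10": (13, 12),
    "D11": (14, 12), "D12": (13, 10), "D13": (14, 11),
}

#: Canonical statistic order.
STAT_NAMES: tuple[str, ...] = (
    "max", "min", "mean", "median", "var", "rms", "skew", "kurt", "energy", "cv")

N_TIME_FEATURES = 1320
_EPS_MEAN = 1e-12


@dataclass
class SummaryStats:
    """The ten per-series statistics, in canonical order."""

    max: float
    min: float
    mean: float
    median: float
    var: float
    rms: float
    skew: float
    kurt: float
    energy: float
    cv: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in STAT_NAMES])


def _stats_matrix(X: np.ndarray) -> np.ndarray:
    """(rows, 10) statistics for each row of a (rows, n) matrix. Vectorised."""
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    if n < 2:
        raise ValueError("series must have length >= 2")
    mean = X.mean(axis=1)
    centered = X - mean[:, None]
    m2 = (centered ** 2).mean(axis=1)
    m3 = (centered ** 3).mean(axis=1)
    m4 = (centered ** 4).mean(axis=1)
    energy = (X ** 2).sum(axis=1)
    m2_safe = np.where(m2 > 0, m2, 1.0)
    mean_safe = np.where(np.abs(mean) < _EPS_MEAN, 1.0, mean)
    skew = np.where(m2 > 0, m3 / m2_safe ** 1.5, 0.0)
    kurt = np.where(m2 > 0, m4 / m2_safe ** 2 - 3.0, 0.0)
    cv = np.where(np.abs(mean) < _EPS_MEAN, 0.0, np.sqrt(m2) / mean_safe)
    return np.column_stack([
        X.max(axis=1), X.min(axis=1), mean, np.median(X, axis=1), m2,
        np.sqrt(energy / n), skew, kurt, energy, cv,
    ])


def summary_stats(x: Sequence[float]) -> SummaryStats:
    """Compute the ten statistics of one series."""
    row = _stats_matrix(np.asarray(x, dtype=float)[None, :])[0]
    return SummaryStats(*row)


def frame_difference(segment: GaitSegment) -> np.ndarray:
    """(48, n_frames - 1) first differences of the channel matrix."""
    if segment.n_frames < 2:
        raise ValueError("need at least 2 frames")
    return np.diff(segment.channel_matrix(), axis=1)


def angle_series(segment: GaitSegment, indicator: str) -> np.ndarray:
    """Per-frame angle (radians, [0, pi]) at the vertex of an indicator triple."""
    a, b, c = ANGLE_INDICATORS[indicator]
    u = segment.joint_xy(a) - segment.joint_xy(b)
    v = segment.joint_xy(c) - segment.joint_xy(b)
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    bad = (nu == 0) | (nv == 0)
    if bad.any():
        raise DegenerateGeometryError(
            f"indicator {indicator}: zero-length bone vector at frame "
            f"{int(np.argmax(bad))}")
    cos = np.clip((u * v).sum(axis=1) / (nu * nv), -1.0, 1.0)
    return np.arccos(cos)


def distance_series(segment: GaitSegment, indicator: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame transverse (|dx|) and longitudinal (|dy|) joint distances."""
    a, b = DISTANCE_INDICATORS[indicator]
    diff = np.abs(segment.joint_xy(a) - segment.joint_xy(b))
    return diff[:, 0], diff[:, 1]


def _series_blocks(segment: GaitSegment) -> list[tuple[str, np.ndarray]]:
    """All 132 named series: 48 raw, 48 diff, 26 distance, 10 angle."""
    chan_names = segment.channel_names
    raw = segment.channel_matrix()
    blocks = [(f"td_raw_{c}", raw[i]) for i, c in enumerate(chan_names)]
    diff = frame_difference(segment)
    blocks += [(f"td_diff_{c}", diff[i]) for i, c in enumerate(chan_names)]
    for ind in DISTANCE_INDICATORS:
        dx, dy = distance_series(segment, ind)
        blocks += [(f"td_dist_{ind}_x", dx), (f"td_dist_{ind}_y", dy)]
    for ind in ANGLE_INDICATORS:
        blocks.append((f"td_angle_{ind}", angle_series(segment, ind)))
    return blocks


def time_domain_features(segment: GaitSegment) -> pd.Series:
    """The 1,320 time-domain features as a named vector (canonical order)."""
    blocks = _series_blocks(segment)
    names = [f"{base}_{stat}" for base, _ in blocks for stat in STAT_NAMES]
    # raw/diff rows share length; distance/angle rows share segment length;
    # stack per equal-length group for vectorised statistics
    values = np.empty(len(blocks) * len(STAT_NAMES))
    series = [s for _, s in blocks]
    lengths = np.array([len(s) for s in series])
    for ln in np.unique(lengths):
        rows = np.nonzero(lengths == ln)[0]
        stats = _stats_matrix(np.stack([series[r] for r in rows]))
        for k, r in enumerate(rows):
            values[r * 10:(r + 1) * 10] = stats[k]
    out = pd.Series(values, index=names)
    assert len(out) == N_TIME_FEATURES
    return out
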