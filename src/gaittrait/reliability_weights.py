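"""Split-half reliability of model predictions and indicator-level weights.

Reliability: each participant's segment is split into the odd-position and
even-position frame halves (1-based parity, so 75 frames give 38 + 37);
features are recomputed independently on each half with the same code path
as full-length extraction, both halves are scored with the unmodified
full-segment model, and the reliability is the Pearson correlation between
the two prediction vectors across participants.

Weights: for a linear model, each selected feature's absolute standardised
coefficient is added to the aggregate of its source indicator (A0-A9
angles, D1-D13 distances, pooled raw/diff/wavelet channel groups);
indicators with no selected feature keep weight 0. The distances-vs-angles
contrast is a pooled-variance two-sample t-test on the 13 distance against
the 10 angle aggregates (df = 13 + 10 - 2 = 21 structurally).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GaitTraitError, GaitWarning
from .features_time import ANGLE_INDICATORS, DISTANCE_INDICATORS
from .modeling import TraitRegressor
from .pipeline import extract_features, feature_dictionary
from .preprocess import GaitSegment

MIN_SPLIT_FRAMES = 64  # both halves must support a 5-level decomposition
OTHER_GROUPS = ("raw", "diff", "wavelet")
ALL_INDICATORS = tuple(ANGLE_INDICATORS) + tuple(DISTANCE_INDICATORS) + OTHER_GROUPS


@dataclass
class ReliabilityReport:
    r_split: float
    n: int
    half_sizes: tuple[int, int]  # (n_odd_frames, n_even_frames)
    predictions_odd: pd.Series | None = None
    predictions_even: pd.Series | None = None


def split_half(segment: GaitSegment) -> tuple[GaitSegment, GaitSegment]:
    """Odd-position and even-position frame halves of one segment.

    Parity is 1-based: the odd half takes frames 1, 3, 5, ... (i.e. array
    positions 0, 2, ...). Each half is a valid GaitSegment sampled at half
    the frame rate; interleaving the halves back reproduces the original.
    """
    n = segment.n_frames
    if n < MIN_SPLIT_FRAMES:
        raise ValueError(f"need >= {MIN_SPLIT_FRAMES} frames to split, got {n}")
    odd = GaitSegment(segment.data[0::2], fps=segment.fps / 2,
                      participant_id=segment.participant_id)
    even = GaitSegment(segment.data[1::2], fps=segment.fps / 2,
                       participant_id=segment.participant_id)
    return odd, even


def split_half_reliability(model: TraitRegressor,
                           segments: Mapping[str, GaitSegment] | Sequence[GaitSegment],
                           ) -> ReliabilityReport:
    """Correlation between predictions from the odd and even frame halves."""
    if isinstance(segments, Mapping):
        items = list(segments.items())
    else:
        items = [(s.participant_id or f"sample{i:03d}", s)
                 for i, s in enumerate(segments)]
    rows_odd, rows_even, ids = [], [], []
    half_sizes = None
    for pid, seg in items:
        try:
            odd, even = split_half(seg)
            rows_odd.append(extract_features(odd))
            rows_even.append(extract_features(even))
        except (GaitTraitError, ValueError) as exc:
            warnings.warn(f"dropping participant {pid}: {exc}", GaitWarning,
                          stacklevel=2)
            continue
        ids.append(pid)
        half_sizes = (odd.n_frames, even.n_frames)
    if len(ids) < 3:
        raise GaitTraitError(f"only {len(ids)} participants survived the split")
    pred_odd = model.predict(pd.DataFrame(rows_odd, index=ids))
    pred_even = model.predict(pd.DataFrame(rows_even, index=ids))
    if np.std(pred_odd) == 0 or np.std(pred_even) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(pred_odd, pred_even)[0])
    return ReliabilityReport(r_split=r, n=len(ids), half_sizes=half_sizes,
                             predictions_odd=pd.Series(pred_odd, index=ids),
                             predictions_even=pd.Series(pred_even, index=ids))


def aggregate_weights(model: TraitRegressor, how: str = "sum") -> pd.DataFrame:
    """Indicator-level weight table from a fitted linear model.

    Each selected feature contributes |standardised coefficient| to its
    source indicator; ``how="mean"`` averages instead of summing. Returns a
    DataFrame with columns (indicator, group, weight) covering every
    indicator, unselected ones at 0.
    """
    if model.algorithm != "lr":
        raise GaitTraitError("indicator weights are defined only for algorithm='lr'")
    if how not in ("sum", "mean"):
        raise ValueError("how must be 'sum' or 'mean'")
    fdict = feature_dictionary()
    sums = {ind: 0.0 for ind in ALL_INDICATORS}
    counts = {ind: 0 for ind in ALL_INDICATORS}
    for name, coef in model.coef_.items():
        info = fdict.get(name)
        ind = info["indicator"] if info else "wavelet"
        sums[ind] += abs(float(coef))
        counts[ind] += 1
    weight = {ind: (sums[ind] / counts[ind] if how == "mean" and counts[ind]
                    else sums[ind]) for ind in ALL_INDICATORS}
    group = {**{a: "angle" for a in ANGLE_INDICATORS},
             **{d: "distance" for d in DISTANCE_INDICATORS},
             **{g: "other" for g in OTHER_GROUPS}}
    return pd.DataFrame({
        "indicator": list(ALL_INDICATORS),
        "group": [group[i] for i in ALL_INDICATORS],
        "weight": [weight[i] for i in ALL_INDICATORS],
    })


@dataclass
class GroupComparison:
    t: float
    df: int
    p: float
    mean_dist: float
    sd_dist: float
    mean_angle: float
    sd_angle: float


def compare_indicator_groups(weight_table: pd.DataFrame) -> GroupComparison:
    """Pooled-variance two-sample t-test: 13 distance vs 10 angle aggregates."""
    wt = weight_table.set_index("indicator")["weight"]
    dist = wt.loc[list(DISTANCE_INDICATORS)].to_numpy(dtype=float)
    ang = wt.loc[list(ANGLE_INDICATORS)].to_numpy(dtype=float)
    if dist.std(ddof=1) == 0 and ang.std(ddof=1) == 0:
        raise GaitTraitError("zero pooled variance: t statistic undefined")
    t, p = stats.ttest_ind(dist, ang, equal_var=True)
    df = len(dist) + len(ang) - 2
    return GroupComparison(t=float(t), df=df, p=float(p),
                           mean_dist=float(dist.mean()), sd_dist=float(dist.std(ddof=1)),
                           mean_angle=float(ang.mean()), sd_angle=float(ang.std(ddof=1)))
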