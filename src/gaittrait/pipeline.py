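"""End-to-end feature pipeline: sequences -> segments -> 2,472-d vectors.

`GaitFeatureExtractor` is a scikit-learn transformer over lists of
GaitSequence/GaitSegment objects, producing a participant x feature
DataFrame (1,320 time-domain + 1,152 frequency-domain columns).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import GaitTraitError, GaitWarning
from .features_freq import BAND_NAMES, BAND_STAT_NAMES, N_FREQ_FEATURES, freq_domain_features
from .features_time import (
    ANGLE_INDICATORS,
    DISTANCE_INDICATORS,
    N_TIME_FEATURES,
    STAT_NAMES,
    time_domain_features,
)
from .io_keypoints import GaitSequence, RETAINED_JOINTS
from .preprocess import GaitSegment, PreprocessConfig, preprocess_sequence

N_TOTAL_FEATURES = N_TIME_FEATURES + N_FREQ_FEATURES  # 2472


def extract_features(segment: GaitSegment) -> pd.Series:
    """The full 2,472-dimensional named feature vector of one segment."""
    return pd.concat([time_domain_features(segment), freq_domain_features(segment)])


def canonical_feature_names() -> list[str]:
    """The 2,472 feature names in canonical column order."""
    names = []
    chans = [f"j{j:02d}_{ax}" for j in RETAINED_JOINTS for ax in ("x", "y")]
    for fam in ("raw", "diff"):
        names += [f"td_{fam}_{c}_{s}" for c in chans for s in STAT_NAMES]
    names += [f"td_dist_{d}_{ax}_{s}" for d in DISTANCE_INDICATORS
              for ax in ("x", "y") for s in STAT_NAMES]
    names += [f"td_angle_{a}_{s}" for a in ANGLE_INDICATORS for s in STAT_NAMES]
    names += [f"fd_{c}_{b}_{s}" for c in chans for b in BAND_NAMES
              for s in BAND_STAT_NAMES]
    assert len(names) == N_TOTAL_FEATURES
    return names


def feature_dictionary() -> dict[str, dict[str, str]]:
    """Map feature name -> provenance: family, indicator, indicator group, statistic.

    Indicator ids are A0-A9 (angles), D1-D13 (distances) and the pooled
    channel groups "raw", "diff", "wavelet"; the group label is
    angle/distance/other, which is what the weight analysis aggregates over.
    """
    out = {}
    for name in canonical_feature_names():
        parts = name.split("_")
        if name.startswith("td_angle"):
            info = {"family": "angle", "indicator": parts[2], "group": "angle",
                    "stat": parts[3]}
        elif name.startswith("td_dist"):
            info = {"family": "distance", "indicator": parts[2], "group": "distance",
                    "stat": parts[4], "axis": parts[3]}
        elif name.startswith("td_raw") or name.startswith("td_diff"):
            info = {"family": parts[1], "indicator": parts[1], "group": "other",
                    "stat": parts[4], "channel": f"{parts[2]}_{parts[3]}"}
        else:  # fd_j00_x_D1_absmax
            info = {"family": "wavelet", "indicator": "wavelet", "group": "other",
                    "stat": parts[4], "channel": f"{parts[1]}_{parts[2]}",
                    "band": parts[3]}
        out[name] = info
    return out


class GaitFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transform gait sequences (or ready segments) into feature rows.

    Parameters
    ----------
    config : PreprocessConfig, optional
        Preprocessing settings applied when inputs are raw GaitSequence
        objects; GaitSegment inputs are featurised as-is.
    on_error : {"raise", "drop"}
        Whether a participant whose preprocessing/extraction fails aborts the
        run or is dropped with a warning.
    """

    def __init__(self, config: Optional[PreprocessConfig] = None,
                 on_error: str = "raise"):
        self.config = config
        self.on_error = on_error

    def fit(self, X: Sequence, y=None) -> "GaitFeatureExtractor":
        self.feature_names_out_ = canonical_feature_names()
        return self

    def transform(self, X: Iterable) -> pd.DataFrame:
        if self.on_error not in ("raise", "drop"):
            raise ValueError("on_error must be 'raise' or 'drop'")
        rows, index = [], []
        for i, item in enumerate(X):
            try:
                seg = item if isinstance(item, GaitSegment) else \
                    preprocess_sequence(item, self.config)
                rows.append(extract_features(seg))
                index.append(seg.participant_id or f"sample{i:03d}")
            except (GaitTraitError, ValueError) as exc:
                if self.on_error == "raise":
                    raise
                pid = getattr(item, "participant_id", f"sample{i:03d}")
                warnings.warn(f"dropping participant {pid}: {exc}", GaitWarning,
                              stacklevel=2)
        if not rows:
            raise GaitTraitError("no participant survived feature extraction")
        df = pd.DataFrame(rows, index=index)
        return df[canonical_feature_names()]

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(canonical_feature_names())


def extract_cohort_features(sequences: Iterable[GaitSequence],
                            config: Optional[PreprocessConfig] = None,
                            on_error: str = "raise") -> pd.DataFrame:
    """Functional wrapper: one feature row per participant."""
    return GaitFeatureExtractor(config=config, on_error=on_error).fit([]).transform(sequences)
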