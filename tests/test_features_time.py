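import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from gaittrait import GaitSegment, summary_stats, time_domain_features
from gaittrait.errors import DegenerateGeometryError
from gaittrait.features_time import (
    ANGLE_INDICATORS,
    DISTANCE_INDICATORS,
    STAT_NAMES,
    angle_series,
    distance_series,
    frame_difference,
)
from gaittrait.io_keypoints import RETAINED_JOINTS


def _segment_with(joint_positions: dict, n=40) -> GaitSegment:
    data = np.zeros((n, 24, 2))
    data[:, :, 0] = np.linspace(0, 1, 24)  # avoid coincident joints
    data[:, :, 1] = 1.0
    for j, xy in joint_positions.items():
        data[:, RETAINED_JOINTS.index(j), :] = xy
    return GaitSegment(data)


# ---------------------------------------------------------------------------
# component series
# ---------------------------------------------------------------------------

def test_frame_difference_values(random_segment):
    seg = random_segment(75)
    diff = frame_difference(seg)
    assert diff.shape == (48, 74)
    np.testing.assert_allclose(diff, np.diff(seg.channel_matrix(), axis=1))
    const = GaitSegment(np.ones((40, 24, 2)))
    assert np.all(frame_difference(const) == 0)


@pytest.mark.parametrize("a, c, expected", [
    ((0, 1), (1, 0), math.pi / 2),
    ((-1, 0), (1, 0), math.pi),
    ((1, 0), (2, 0), 0.0),
])
def test_angle_geometry(a, c, expected):
    seg = _segment_with({0: a, 1: (0, 0), 2: c})
    np.testing.assert_allclose(angle_series(seg, "A0"), expected, atol=1e-12)


def test_degenerate_angle_raises():
    seg = _segment_with({0: (0, 0), 1: (0, 0), 2: (1, 0)})
    with pytest.raises(DegenerateGeometryError, match="A0"):
        angle_series(seg, "A0")


def test_distance_series_axis_split_and_symmetry():
    seg = _segment_with({1: (3, 4), 0: (0, 0)})
    dx, dy = distance_series(seg, "D1")  # pair (1, 0)
    assert np.all(dx == 3) and np.all(dy == 4)
    seg2 = _segment_with({1: (0, 0), 0: (3, 4)})
    dx2, dy2 = distance_series(seg2, "D1")
    np.testing.assert_array_equal(dx, dx2)
    np.testing.assert_array_equal(dy, dy2)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def test_summary_stats_hand_values():
    s = summary_stats([1, 2, 3])
    assert s.energy == 14
    assert s.mean == 2
    assert s.var == pytest.approx(2 / 3)
    assert s.rms == pytest.approx(math.sqrt(14 / 3))
    assert s.skew == pytest.approx(0, abs=1e-12)

    c = summary_stats([5, 5, 5, 5])
    assert (c.var, c.skew, c.kurt, c.cv) == (0, 0, 0, 0)
    assert c.energy == 100


def test_summary_stats_rejects_singletons():
    with pytest.raises(ValueError):
        summary_stats([1.0])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(arrays(float, st.integers(2, 30),
              elements=st.floats(-1e4, 1e4, allow_nan=False, allow_infinity=False)))
def test_summary_stats_parity(x):
    s, m = summary_stats(x), summary_stats(-x)
    assert m.max == -s.min and m.min == -s.max
    assert m.mean == pytest.approx(-s.mean, rel=1e-9, abs=1e-12)
    assert m.median == pytest.approx(-s.median, rel=1e-9, abs=1e-12)
    assert m.skew == pytest.approx(-s.skew, rel=1e-6, abs=1e-9)
    assert m.var == pytest.approx(s.var, rel=1e-9, abs=1e-12)
    assert m.energy == pytest.approx(s.energy, rel=1e-12)


# ---------------------------------------------------------------------------
# full vector
# ---------------------------------------------------------------------------

def _naive_stats(xs):
    """Brute-force reference: plain Python, no shared code with the package."""
    n = len(xs)
    mean = sum(xs) / n
    m2 = sum((v - mean) ** 2 for v in xs) / n
    m3 = sum((v - mean) ** 3 for v in xs) / n
    m4 = sum((v - mean) ** 4 for v in xs) / n
    energy = sum(v * v for v in xs)
    return [
        max(xs), min(xs), mean, statistics.median(xs), m2,
        math.sqrt(energy / n),
        m3 / m2 ** 1.5 if m2 > 0 else 0.0,
        m4 / m2 ** 2 - 3 if m2 > 0 else 0.0,
        energy,
        math.sqrt(m2) / mean if abs(mean) >= 1e-12 else 0.0,
    ]


def _naive_time_features(seg):
    series = []
    for p, j in enumerate(seg.joint_order):
        for ax in (0, 1):
            series.append(list(seg.data[:, p, ax]))
    for p, j in enumerate(seg.joint_order):
        for ax in (0, 1):
            xs = seg.data[:, p, ax]
            series.append([xs[k + 1] - xs[k] for k in range(len(xs) - 1)])
    pos = {j: p for p, j in enumerate(seg.joint_order)}
    for a, b in DISTANCE_INDICATORS.values():
        for ax in (0, 1):
            series.append([abs(seg.data[k, pos[a], ax] - seg.data[k, pos[b], ax])
                           for k in range(seg.n_frames)])
    for a, b, c in ANGLE_INDICATORS.values():
        vals = []
        for k in range(seg.n_frames):
            ux, uy = seg.data[k, pos[a]] - seg.data[k, pos[b]]
            vx, vy = seg.data[k, pos[c]] - seg.data[k, pos[b]]
            cosv = (ux * vx + uy * vy) / (math.hypot(ux, uy) * math.hypot(vx, vy))
            vals.append(math.acos(max(-1.0, min(1.0, cosv))))
        series.append(vals)
    return [v for s in series for v in _naive_stats(s)]


def test_vector_matches_bruteforce_oracle(random_segment):
    seg = random_segment(40, seed=7)
    got = time_domain_features(seg)
    expected = _naive_time_features(seg)
    assert len(got) == 1320
    np.testing.assert_allclose(got.to_numpy(), expected, rtol=1e-9, atol=1e-9)


def test_vector_shape_names_and_ranges(default_walker_segment):
    f = time_domain_features(default_walker_segment)
    assert len(f) == 1320
    assert f.index.is_unique
    for a in ANGLE_INDICATORS:
        assert 0 <= f[f"td_angle_{a}_mean"] <= math.pi
        assert 0 <= f[f"td_angle_{a}_min"] <= f[f"td_angle_{a}_max"] <= math.pi
    for d in DISTANCE_INDICATORS:
        for stat in ("min", "max", "mean", "rms"):
            assert f[f"td_dist_{d}_x_{stat}"] >= 0


_MIRROR = {2: 5, 5: 2, 3: 6, 6: 3, 4: 7, 7: 4, 9: 12, 12: 9,
           10: 13, 13: 10, 11: 14, 14: 11, 15: 16, 16: 15, 17: 18, 18: 17,
           19: 22, 22: 19, 20: 23, 23: 20, 21: 24, 24: 21}
_ANGLE_PAIRS = [("A0", "A1"), ("A2", "A3"), ("A4", "A5"), ("A6", "A7"), ("A8", "A9")]
_DIST_PAIRS = [("D2", "D4"), ("D3", "D5"), ("D8", "D10"), ("D9", "D11")]


def test_mirror_symmetry(random_segment):
    seg = random_segment(40, seed=11)
    pos = {j: p for p, j in enumerate(RETAINED_JOINTS)}
    mirrored = np.empty_like(seg.data)
    for j in RETAINED_JOINTS:
        src = _MIRROR.get(j, j)
        mirrored[:, pos[j], 0] = -seg.data[:, pos[src], 0]
        mirrored[:, pos[j], 1] = seg.data[:, pos[src], 1]
    f = time_domain_features(seg)
    fm = time_domain_features(GaitSegment(mirrored))
    for left, right in _ANGLE_PAIRS:
        for stat in STAT_NAMES:
            assert fm[f"td_angle_{left}_{stat}"] == \
                pytest.approx(f[f"td_angle_{right}_{stat}"], rel=1e-9, abs=1e-12)
    for left, right in _DIST_PAIRS:
        for ax in ("x", "y"):
            for stat in STAT_NAMES:
                assert fm[f"td_dist_{left}_{ax}_{stat}"] == \
                    pytest.approx(f[f"td_dist_{right}_{ax}_{stat}"],
                                  rel=1e-9, abs=1e-12)
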