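"""BODY25 keypoint I/O: the OpenPose per-frame JSON dialect and a flat CSV table.

This module also owns the skeleton indexing (joint names, the MidHip
reference joint, the 24 joints retained after re-referencing) that every
downstream module relies on.

Conventions: image pixels, x rightward, y downward (the OpenPose convention);
0-based frame indexing; a frame with no detected person is encoded as 25
joints at (0, 0) with confidence 0 rather than being dropped, so that frame
timing stays intact for gait-cycle estimation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, GaitWarning

#: BODY25 joint names, indexed 0-24.
BODY25_NAMES: tuple[str, ...] = (
    "Nose", "Neck", "RShoulder", "RElbow", "RWrist",
    "LShoulder", "LElbow", "LWrist", "MidHip", "RHip",
    "RKnee", "RAnkle", "LHip", "LKnee", "LAnkle",
    "REye", "LEye", "REar", "LEar", "LBigToe",
    "LSmallToe", "LHeel", "RBigToe", "RSmallToe", "RHeel",
)

N_JOINTS = 25
MIDHIP = 8

#: Joints kept after MidHip re-referencing (all but the reference itself).
RETAINED_JOINTS: tuple[int, ...] = tuple(i for i in range(N_JOINTS) if i != MIDHIP)
N_RETAINED = len(RETAINED_JOINTS)  # 24
N_CHANNELS = 2 * N_RETAINED  # 48 (x and y per retained joint)

JOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(BODY25_NAMES)}


@dataclass(frozen=True)
class Joint:
    """A BODY25 joint: index 0-24 and its canonical name."""

    index: int
    name: str

    def __post_init__(self) -> None:
        if not 0 <= self.index < N_JOINTS:
            raise ValueError(f"joint index {self.index} outside 0-24")
        if BODY25_NAMES[self.index] != self.name:
            raise ValueError(f"joint {self.index} is {BODY25_NAMES[self.index]!r}, not {self.name!r}")


JOINTS: tuple[Joint, ...] = tuple(Joint(i, n) for i, n in enumerate(BODY25_NAMES))


@dataclass
class KeypointFrame:
    """One video frame: 25 (x, y) coordinates with per-joint confidence."""

    coords: np.ndarray  # (25, 2) pixels
    confidence: np.ndarray  # (25,) in [0, 1]
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.coords.shape != (N_JOINTS, 2):
            raise FormatError(f"coords must be (25, 2), got {self.coords.shape}")
        if self.confidence.shape != (N_JOINTS,):
            raise FormatError(f"confidence must be (25,), got {self.confidence.shape}")
        if np.any((self.confidence < 0) | (self.confidence > 1)):
            raise FormatError("confidences must lie in [0, 1]")


@dataclass
class GaitSequence:
    """An ordered 25-joint keypoint time series for one participant.

    Stored internally as dense arrays (``coords`` of shape (n, 25, 2),
    ``confidence`` of shape (n, 25)) for vectorised processing; the
    per-frame view is available through :meth:`frame` / :attr:`frames`.

    ``facing_labels``, when present, gives a per-frame label in
    {"toward", "away", "unknown"} and overrides heuristic facing detection.
    """

    coords: np.ndarray
    confidence: np.ndarray
    fps: float = 25.0
    participant_id: str = ""
    facing_labels: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (N_JOINTS, 2):
            raise FormatError(f"coords must be (n, 25, 2), got {self.coords.shape}")
        if self.confidence.shape != self.coords.shape[:2]:
            raise FormatError("confidence shape must match coords")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.facing_labels is not None:
            self.facing_labels = np.asarray(self.facing_labels, dtype=object)
            if self.facing_labels.shape != (self.n_frames,):
                raise FormatError("facing_labels must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> KeypointFrame:
        return KeypointFrame(self.coords[i], self.confidence[i], frame_index=i)

    @property
    def frames(self) -> Iterator[KeypointFrame]:
        return (self.frame(i) for i in range(self.n_frames))

    @classmethod
    def from_frames(cls, frames: Sequence[KeypointFrame], fps: float = 25.0,
                    participant_id: str = "", facing_labels=None) -> "GaitSequence":
        coords = np.stack([f.coords for f in frames])
        conf = np.stack([f.confidence for f in frames])
        return cls(coords, conf, fps=fps, participant_id=participant_id,
                   facing_labels=facing_labels)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


# ---------------------------------------------------------------------------
# OpenPose per-frame JSON dialect
# ---------------------------------------------------------------------------

def _parse_frame_json(path: Path) -> tuple[np.ndarray, np.ndarray]:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed JSON in {path.name}: {exc}") from exc
    people = doc.get("people", [])
    if not people:
        return np.zeros((N_JOINTS, 2)), np.zeros(N_JOINTS)
    if len(people) > 1:
        warnings.warn(f"{path.name}: {len(people)} people detected, using people[0]",
                      GaitWarning, stacklevel=3)
    kp = people[0].get("pose_keypoints_2d")
    if kp is None or len(kp) != 3 * N_JOINTS:
        n = 0 if kp is None else len(kp)
        raise FormatError(f"{path.name}: pose_keypoints_2d has {n} values, expected 75")
    arr = np.asarray(kp, dtype=float).reshape(N_JOINTS, 3)
    return arr[:, :2], arr[:, 2]


def read_openpose_dir(path: str | Path, participant_id: str, fps: float = 25.0) -> GaitSequence:
    """Read a directory of OpenPose per-frame JSON files into a GaitSequence.

    Files are taken in lexicographic order; frame_index equals file rank.
    Frames whose ``people`` array is empty become all-missing frames
    (all confidences 0).
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.suffix == ".json")
    if not files:
        raise FormatError(f"no .json frame files in {path}")
    coords = np.empty((len(files), N_JOINTS, 2))
    conf = np.empty((len(files), N_JOINTS))
    for i, f in enumerate(files):
        coords[i], conf[i] = _parse_frame_json(f)
    return GaitSequence(coords, conf, fps=fps, participant_id=participant_id)


def write_openpose_dir(seq: GaitSequence, path: str | Path, stem: str | None = None) -> list[Path]:
    """Write a sequence as per-frame OpenPose JSON files (one file per frame)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    stem = stem or (seq.participant_id or "frame")
    written = []
    for i in range(seq.n_frames):
        flat = np.column_stack([seq.coords[i], seq.confidence[i]]).reshape(-1)
        doc = {"version": 1.3,
               "people": [{"pose_keypoints_2d": [round(float(v), 6) for v in flat]}]}
        out = path / f"{stem}_{i:06d}_keypoints.json"
        with open(out, "w") as fh:
            json.dump(doc, fh)
        written.append(out)
    return written


# ---------------------------------------------------------------------------
# Consolidated CSV table
# ---------------------------------------------------------------------------

def _table_columns() -> list[str]:
    cols = ["frame"]
    for j in range(N_JOINTS):
        cols += [f"j{j:02d}_x", f"j{j:02d}_y", f"j{j:02d}_c"]
    return cols


def write_keypoint_table(seq: GaitSequence, path: str | Path) -> None:
    """Write a sequence as one CSV row per frame (columns frame, j00_x, ..., j24_c)."""
    n = seq.n_frames
    data = np.empty((n, 1 + 3 * N_JOINTS))
    data[:, 0] = np.arange(n)
    block = np.concatenate([seq.coords, seq.confidence[:, :, None]], axis=2)
    data[:, 1:] = block.reshape(n, 3 * N_JOINTS)
    df = pd.DataFrame(data, columns=_table_columns())
    df["frame"] = df["frame"].astype(int)
    df.to_csv(path, index=False, float_format="%.10g")


def read_keypoint_table(path: str | Path, participant_id: str = "",
                        fps: float = 25.0) -> GaitSequence:
    """Read the consolidated CSV format back into a GaitSequence."""
    df = pd.read_csv(path)
    expected = _table_columns()
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    arr = df[expected[1:]].to_numpy(dtype=float).reshape(len(df), N_JOINTS, 3)
    return GaitSequence(arr[:, :, :2], arr[:, :, 2], fps=fps,
                        participant_id=participant_id or str(Path(path).stem))
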