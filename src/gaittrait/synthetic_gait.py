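"""Synthetic 2D articulated walker with a planted linear trait.

The generator emulates the acquisition protocol the pipeline is built for:
a single walker filmed at 25 Hz for 2 minutes, walking toward the camera for
the first half of the bout and away for the second. Limb kinematics are a
minimal sinusoidal model — thigh and shank angles oscillate at the stride
frequency with the two legs in antiphase, arms antiphase to the ipsilateral
legs — projected onto the image plane with an isotropic scale that grows
while the walker approaches (a perspective proxy). Keypoint jitter is
i.i.d. Gaussian per joint per frame.

The planted trait is a linear function of the two kinematic *amplitudes*
(arm swing and stride) plus Gaussian noise, then affinely rescaled so the
cohort sample moments hit a target mean/SD. By construction the trait never
depends on image scale, so any feature pipeline that recovers it must read
body kinematics rather than apparent size.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import GaitWarning
from .io_keypoints import (
    N_JOINTS,
    GaitSequence,
    write_keypoint_table,
    write_openpose_dir,
)

# Body-frame template (units of hip-to-neck length, y downward, pelvis at origin)
_NECK_Y = -1.0
_TEMPLATE = {
    0: (0.0, -1.18),    # Nose
    1: (0.0, _NECK_Y),  # Neck
    2: (-0.22, -0.92),  # RShoulder
    5: (0.22, -0.92),   # LShoulder
    8: (0.0, 0.0),      # MidHip
    9: (-0.12, 0.03),   # RHip
    12: (0.12, 0.03),   # LHip
    15: (-0.05, -1.23), 16: (0.05, -1.23),  # eyes
    17: (-0.09, -1.20), 18: (0.09, -1.20),  # ears
}
_UPPER_ARM, _FOREARM = 0.42, 0.40
_THIGH, _SHANK = 0.48, 0.45
_ELBOW_BEND = 0.35      # constant elbow flexion, radians
_SHANK_RATIO = 0.7      # shank angle as a fraction of thigh angle
# inward whole-leg lean cancelling the hip x-offset, so the ankles oscillate
# about the midline and their separation peaks twice per gait cycle
_LEG_LEAN = float(np.arcsin(0.12 / (_THIGH + _SHANK)))
# foot points relative to the ankle (x mirrored for the right side)
_FOOT_OFFSETS = {"BigToe": (0.06, 0.10), "SmallToe": (0.09, 0.09), "Heel": (-0.03, 0.08)}
_MIN_CYCLES = 4
_SEGMENT_SECONDS = 3.0  # analysis window the >=4-cycle guidance refers to


@dataclass
class WalkerParams:
    """Kinematic parameters of one synthetic walker.

    Angular amplitudes are in radians, ``head_bob_amp`` and ``noise_sd`` in
    pixels, ``base_scale`` is the hip-to-neck length in pixels, and
    ``approach_rate`` the relative scale growth per second while the walker
    approaches the camera.
    """

    stride_freq: float = 1.0
    arm_swing_amp: float = 0.35
    stride_amp: float = 0.55
    head_bob_amp: float = 2.0
    base_scale: float = 200.0
    approach_rate: float = 0.01
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stride_freq <= 0:
            raise ValueError("stride_freq must be positive")
        if min(self.arm_swing_amp, self.stride_amp, self.head_bob_amp) < 0:
            raise ValueError("amplitudes must be nonnegative")
        if self.base_scale <= 0:
            raise ValueError("base_scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _limb_chain(root_xy, length1, angle1, length2, angle2):
    """Two-segment chain: returns (joint1, joint2) positions, angles from vertical-down."""
    j1x = root_xy[..., 0] + length1 * np.sin(angle1)
    j1y = root_xy[..., 1] + length1 * np.cos(angle1)
    j2x = j1x + length2 * np.sin(angle2)
    j2y = j1y + length2 * np.cos(angle2)
    return np.stack([j1x, j1y], -1), np.stack([j2x, j2y], -1)


def simulate_walker(params: WalkerParams, seconds: float = 120.0,
                    fps: float = 25.0) -> GaitSequence:
    """Simulate one walking bout and return it as a BODY25 GaitSequence.

    The bout has ``round(seconds * fps)`` frames; the walker approaches the
    camera during the first half (facing label "toward", image scale growing
    at ``approach_rate``) and recedes during the second ("away", shrinking).
    """
    n = int(round(seconds * fps))
    if n < 2:
        raise ValueError(f"bout of {n} frames is too short (need >= 2)")
    if params.stride_freq < _MIN_CYCLES / _SEGMENT_SECONDS:
        warnings.warn(
            f"stride_freq {params.stride_freq:.2f} Hz yields fewer than "
            f"{_MIN_CYCLES} gait cycles per {_SEGMENT_SECONDS:.0f}-s window",
            GaitWarning, stacklevel=2)
    rng = np.random.default_rng(params.seed)
    t = np.arange(n) / fps
    omega = 2 * np.pi * params.stride_freq
    phase = omega * t

    body = np.zeros((n, N_JOINTS, 2))
    for j, (x, y) in _TEMPLATE.items():
        body[:, j] = (x, y)

    # arms: antiphase to the ipsilateral leg (right leg phase 0, left leg pi)
    for shoulder, elbow, wrist, arm_phase in ((2, 3, 4, np.pi), (5, 6, 7, 0.0)):
        theta = params.arm_swing_amp * np.sin(phase + arm_phase)
        e, w = _limb_chain(body[:, shoulder], _UPPER_ARM, theta,
                           _FOREARM, theta + _ELBOW_BEND)
        body[:, elbow], body[:, wrist] = e, w
    # legs
    leg_joints = {"R": (9, 10, 11, 0.0), "L": (12, 13, 14, np.pi)}
    for side, (hip, knee, ankle, leg_phase) in leg_joints.items():
        lean = _LEG_LEAN if side == "R" else -_LEG_LEAN
        theta = params.stride_amp * np.sin(phase + leg_phase)
        k, a = _limb_chain(body[:, hip], _THIGH, theta + lean,
                           _SHANK, _SHANK_RATIO * theta + lean)
        body[:, knee], body[:, ankle] = k, a
    # feet ride on the ankles
    foot_map = {19: ("L", "BigToe"), 20: ("L", "SmallToe"), 21: ("L", "Heel"),
                22: ("R", "BigToe"), 23: ("R", "SmallToe"), 24: ("R", "Heel")}
    for j, (side, part) in foot_map.items():
        ox, oy = _FOOT_OFFSETS[part]
        if side == "R":
            ox = -ox
        ankle = leg_joints[side][2]
        body[:, j] = body[:, ankle] + (ox, oy)

    # approach/away scale profile, continuous at the turn
    half = seconds / 2.0
    scale = np.where(t < half,
                     1.0 + params.approach_rate * t,
                     1.0 + params.approach_rate * np.maximum(seconds - t, 0.0))
    scale = params.base_scale * scale

    coords = np.array([320.0, 240.0]) + body * scale[:, None, None]
    # vertical head bob at twice the stride frequency (one bob per step)
    head_joints = [0, 15, 16, 17, 18]
    coords[:, head_joints, 1] += (params.head_bob_amp * np.sin(2 * phase))[:, None]
    if params.noise_sd > 0:
        coords += rng.normal(0.0, params.noise_sd, size=coords.shape)
    conf = 0.3 + 0.7 * rng.random((n, N_JOINTS))

    labels = np.where(t < half, "toward", "away").astype(object)
    return GaitSequence(coords, conf, fps=fps, facing_labels=labels)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Cohort-level generator settings: sample size, trait model, acquisition.

    ``trait_coefficients`` is (intercept, beta_arm, beta_leg); the raw trait is
    ``b0 + b_arm * arm_swing_amp + b_leg * stride_amp + Normal(0, trait_noise_sd)``
    and is then affinely rescaled so the cohort sample mean/SD equal
    ``trait_mean`` / ``trait_sd``.
    """

    n_walkers: int = 150
    trait_coefficients: tuple[float, float, float] = (0.0, 10.0, 10.0)
    trait_noise_sd: float = 0.8
    trait_mean: float = 31.40
    trait_sd: float = 4.55
    bout_seconds: float = 120.0
    fps: float = 25.0
    seed: int = 0
    stride_freq_range: tuple[float, float] = (0.8, 1.2)
    arm_swing_range: tuple[float, float] = (0.15, 0.55)
    stride_amp_range: tuple[float, float] = (0.35, 0.75)
    head_bob_range: tuple[float, float] = (1.0, 4.0)
    base_scale_range: tuple[float, float] = (150.0, 250.0)
    approach_rate: float = 0.01
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.n_walkers < 2:
            raise ValueError("n_walkers must be >= 2")
        if self.trait_sd <= 0:
            raise ValueError("trait_sd must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")


@dataclass
class Cohort:
    """In-memory cohort: sequences, trait table and a full manifest."""

    sequences: list[GaitSequence]
    traits: pd.DataFrame  # participant_id, score, sex
    manifest: dict
    walker_params: list[WalkerParams] = field(default_factory=list)


def _uniform(rng: np.random.Generator, lo_hi: tuple[float, float]) -> float:
    lo, hi = lo_hi
    return lo + (hi - lo) * rng.random()


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full cohort in memory; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    b0, b_arm, b_leg = config.trait_coefficients
    params_list, eps, walker_rows = [], [], []
    for i in range(config.n_walkers):
        # fixed draw order: the trait depends only on the amplitude draws,
        # so rescaling the base_scale range cannot perturb it
        p = WalkerParams(
            stride_freq=_uniform(rng, config.stride_freq_range),
            arm_swing_amp=_uniform(rng, config.arm_swing_range),
            stride_amp=_uniform(rng, config.stride_amp_range),
            head_bob_amp=_uniform(rng, config.head_bob_range),
            base_scale=_uniform(rng, config.base_scale_range),
            approach_rate=config.approach_rate,
            noise_sd=config.noise_sd,
            seed=int(rng.integers(2 ** 31)),
        )
        params_list.append(p)
        eps.append(rng.normal(0.0, config.trait_noise_sd) if config.trait_noise_sd > 0 else 0.0)

    amps = np.array([(p.arm_swing_amp, p.stride_amp) for p in params_list])
    raw = b0 + b_arm * amps[:, 0] + b_leg * amps[:, 1] + np.asarray(eps)
    sd = raw.std(ddof=1)
    if sd > 0:
        scores = (raw - raw.mean()) / sd * config.trait_sd + config.trait_mean
    else:
        scores = np.full_like(raw, config.trait_mean)

    sequences = []
    for i, p in enumerate(params_list):
        pid = f"p{i:03d}"
        seq = simulate_walker(p, seconds=config.bout_seconds, fps=config.fps)
        seq.participant_id = pid
        sequences.append(seq)
        walker_rows.append({
            "participant_id": pid, "sex": "male" if i % 2 == 0 else "female",
            "score_raw": float(raw[i]), "score": float(scores[i]),
            **{k: (float(v) if isinstance(v, float) else v) for k, v in asdict(p).items()},
        })

    traits = pd.DataFrame({
        "participant_id": [r["participant_id"] for r in walker_rows],
        "score": [r["score"] for r in walker_rows],
        "sex": [r["sex"] for r in walker_rows],
    })
    manifest = {"config": asdict(config), "walkers": walker_rows}
    return Cohort(sequences, traits, manifest, walker_params=params_list)


def generate_cohort(config: CohortConfig, out: str | Path) -> Cohort:
    """Generate a cohort and write it to disk in both supported formats.

    Layout: ``<out>/json/<pid>/`` per-frame OpenPose JSON, ``<out>/csv/<pid>.csv``
    consolidated tables, plus ``traits.csv`` and ``manifest.json``.
    """
    out = Path(out)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    cohort = simulate_cohort(config)
    for seq in cohort.sequences:
        write_openpose_dir(seq, out / "json" / seq.participant_id)
        (out / "csv").mkdir(exist_ok=True)
        write_keypoint_table(seq, out / "csv" / f"{seq.participant_id}.csv")
    cohort.traits.to_csv(out / "traits.csv", index=False, float_format="%.10g")
    with open(out / "manifest.json", "w") as fh:
        json.dump(cohort.manifest, fh, sort_keys=True, indent=1)
    return cohort
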