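"""Flat, typed run configuration shared by the CLI commands.

A RunConfig is a flat key-value document (YAML on disk); unknown keys are
rejected, CLI flags override file values, and every artifact written by a
command embeds the config hash, the seed and the package version so equal
(hash, seed, version) triples identify bit-identical runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from . import __version__
from .preprocess import PreprocessConfig


@dataclass
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    # acquisition / preprocessing
    fps: float = 25.0
    n_frames: int = 75
    filter_window: int = 5
    filter_weights: list = field(default_factory=lambda: [1, 4, 6, 4, 1])
    filter_alignment: str = "forward"
    min_conf: float = 0.1
    facing_window_s: float = 1.0
    facing_slope_min: float = 0.0
    # wavelet
    wavelet_base: str = "haar"
    wavelet_levels: int = 5
    wavelet_padding: str = "symmetric"
    # modeling
    algorithm: str = "lr"
    max_features: int = 10
    tol: float = 1.0e-2
    cv_folds: int = 10
    scoring: str = "r"
    paper_mode: bool = False

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        doc = {}
        if path is not None:
            with open(path) as fh:
                doc = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        return {"config_hash": self.hash(), "seed": self.seed,
                "version": __version__}

    def preprocess_config(self) -> PreprocessConfig:
        import numpy as np
        w = np.asarray(self.filter_weights, dtype=float)
        return PreprocessConfig(
            fps=self.fps, n_frames=self.n_frames,
            filter_weights=w / w.sum(), filter_window=self.filter_window,
            filter_alignment=self.filter_alignment, min_conf=self.min_conf,
            facing_window_s=self.facing_window_s,
            facing_slope_min=self.facing_slope_min)

    def dump_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)
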