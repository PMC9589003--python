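"""Frequency-domain gait features: 1,152 dimensions.

Each of the 48 segment channels is decomposed with a 5-level orthonormal
Haar discrete wavelet transform into detail bands D1..D5 and the final
approximation A5 (so the per-band reconstructions sum back to the signal).
Four statistics per band — absolute maximum, mean, population variance and
absolute energy (sum of squared coefficients) — give 48 * 6 * 4 = 1,152
features.

Non-dyadic lengths (the default segment is 75 frames) use half-sample
symmetric boundary padding; on dyadic lengths the Haar analysis is pad-free
and exactly orthonormal (Parseval holds to machine precision).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt

from .preprocess import GaitSegment

WAVELET = "haar"
LEVELS = 5
PADDING_MODE = "symmetric"  # half-sample symmetric
BAND_NAMES: tuple[str, ...] = ("D1", "D2", "D3", "D4", "D5", "A5")
BAND_STAT_NAMES: tuple[str, ...] = ("absmax", "mean", "var", "energy")
N_FREQ_FEATURES = 1152


@dataclass
class WaveletBands:
    """Decomposition result: details D1..D5 (fine to coarse) and approximation A5."""

    details: list[np.ndarray]  # [D1, D2, D3, D4, D5]
    approx: np.ndarray  # A5
    n: int  # original series length
    level: int = LEVELS
    base: str = WAVELET
    padding_mode: str = PADDING_MODE

    @property
    def bands(self) -> dict[str, np.ndarray]:
        out = {f"D{i + 1}": d for i, d in enumerate(self.details)}
        out["A5" if self.level == 5 else f"A{self.level}"] = self.approx
        return out

    def _coeff_list(self) -> list[np.ndarray]:
        # pywt wavedec order: [A_L, D_L, ..., D_1]
        return [self.approx] + self.details[::-1]


def haar_dwt(x: np.ndarray, levels: int = LEVELS) -> WaveletBands:
    """Recursive orthonormal Haar analysis of one series."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("haar_dwt expects a 1-D series")
    if len(x) < 2 ** levels:
        raise ValueError(f"series of length {len(x)} too short for {levels} levels "
                         f"(need >= {2 ** levels})")
    coeffs = pywt.wavedec(x, WAVELET, mode=PADDING_MODE, level=levels)
    approx, details_coarse_to_fine = coeffs[0], coeffs[1:]
    return WaveletBands(details=details_coarse_to_fine[::-1], approx=approx,
                        n=len(x), level=levels)


def reconstruct_bands(bands: WaveletBands, n: int | None = None) -> dict[str, np.ndarray]:
    """Per-band inverse transforms; the six series sum to the original signal."""
    n = bands.n if n is None else n
    if n != bands.n:
        raise ValueError(f"inconsistent length: bands built from {bands.n}, asked {n}")
    full = bands._coeff_list()
    out: dict[str, np.ndarray] = {}
    for i, name in enumerate(("A5", "D5", "D4", "D3", "D2", "D1")):
        coeffs = [np.zeros_like(c) for c in full]
        coeffs[i] = full[i]
        rec = pywt.waverec(coeffs, WAVELET, mode=PADDING_MODE)
        out[name] = rec[:n]
    return {name: out[name] for name in BAND_NAMES}


def band_stats(bands: WaveletBands) -> np.ndarray:
    """24 values: (absmax, mean, population variance, energy) per band, D1..D5, A5."""
    vals = []
    for name in BAND_NAMES:
        c = bands.bands[name]
        vals += [np.abs(c).max(), c.mean(), c.var(), float(c @ c)]
    return np.asarray(vals)


def freq_domain_features(segment: GaitSegment) -> pd.Series:
    """The 1,152 frequency-domain features as a named vector."""
    chans = segment.channel_matrix()
    names, values = [], []
    for cname, x in zip(segment.channel_names, chans):
        stats = band_stats(haar_dwt(x, LEVELS))
        values.append(stats)
        names += [f"fd_{cname}_{band}_{stat}"
                  for band in BAND_NAMES for stat in BAND_STAT_NAMES]
    out = pd.Series(np.concatenate(values), index=names)
    assert len(out) == N_FREQ_FEATURES
    return out
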