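"""Reconstruction-quality metrics on 8-bit images.

MAE, MSE and PSNR (peak 255) between a reconstruction and its ground
truth. Both inputs are clipped to [0, 255] before comparison: the PSNR
formula presumes an 8-bit peak, and clipping keeps solver overshoot
from making scores incomparable across methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MetricReport", "mae", "mse", "psnr", "psnr_from_mse", "evaluate", "error_map"]

PEAK = 255.0


@dataclass(frozen=True)
class MetricReport:
    mae: float
    mse: float
    psnr: float
    n_pixels: int


def _clipped_pair(x: np.ndarray, x_star: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    x_star = np.asarray(x_star, dtype=float)
    if x.shape != x_star.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_star.shape}")
    return np.clip(x, 0.0, PEAK), np.clip(x_star, 0.0, PEAK)


def mae(x: np.ndarray, x_star: np.ndarray) -> float:
    """Mean absolute pixel error."""
    a, b = _clipped_pair(x, x_star)
    return float(np.mean(np.abs(a - b)))


def mse(x: np.ndarray, x_star: np.ndarray) -> float:
    """Mean squared pixel error."""
    a, b = _clipped_pair(x, x_star)
    return float(np.mean((a - b) ** 2))


def psnr_from_mse(mse_value: float) -> float:
    """PSNR in dB from an MSE on the 8-bit scale: 20 log10(255 / sqrt(MSE))."""
    if mse_value < 0:
        raise ValueError("mse must be >= 0")
    if mse_value == 0:
        return float("inf")
    return float(20.0 * np.log10(PEAK / np.sqrt(mse_value)))


def psnr(x: np.ndarray, x_star: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB (+inf for identical images)."""
    return psnr_from_mse(mse(x, x_star))


def evaluate(x: np.ndarray, x_star: np.ndarray) -> MetricReport:
    """All three metrics at once."""
    m = mse(x, x_star)
    return MetricReport(mae=mae(x, x_star), mse=m, psnr=psnr_from_mse(m),
                        n_pixels=int(np.asarray(x).size))


def error_map(x: np.ndarray, x_star: np.ndarray, brighten: float = 5.0) -> np.ndarray:
    """Brightened absolute-difference image, clipped to [0, 255]."""
    if brighten < 1:
        raise ValueError("brighten must be >= 1")
    a, b = _clipped_pair(x, x_star)
    return np.clip(np.abs(a - b) * brighten, 0.0, PEAK)
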