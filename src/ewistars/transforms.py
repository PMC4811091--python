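"""Sparsifying transforms: wavelet, exponential wavelet, random shift.

The discrete wavelet transform (DWT) sparsifies MR magnitude images;
the exponential wavelet transform (EWT) sharpens that sparsity by
iterating, k times, a global [0, 1] normalization of the coefficient
*magnitudes* followed by the pointwise map v -> (e^v - 1)/(e - 1),
with signs carried through unchanged. The map is increasing and
convex on [0, 1], so large coefficients are enhanced relative to
small ones while magnitude ranks are preserved. Signs must survive
the transform because the downstream shrinkage operator is the signed
soft-thresholding sgn(z)(|z| - min(b/2, |z|)): a sign-free domain
would make both the sgn and the annihilation region meaningless, and
thresholding toward 0 must mean thresholding toward a zero wavelet
coefficient. Exact inversion requires the per-iteration normalization
extrema, which are recorded in :class:`EWTState`.

The DWT uses periodic ("periodization") boundary extension so that
circular shifts of the image commute cleanly with the transform grid —
the random-shift (cycle-spinning) mechanism relies on this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt

__all__ = [
    "WaveletSpec",
    "CoefficientSet",
    "EWTState",
    "ShiftVector",
    "SUPPORTED_WAVELETS",
    "dwt_forward",
    "dwt_inverse",
    "normalize01",
    "denormalize01",
    "ewt_forward",
    "ewt_inverse",
    "ewt_scalar",
    "draw_shift",
    "circ_shift",
    "circ_unshift",
    "gini_index",
]

SUPPORTED_WAVELETS = ("db1", "db2", "db3", "bior2.2", "bior3.3", "bior4.4")

_E_MINUS_1 = np.e - 1.0


@dataclass(frozen=True)
class WaveletSpec:
    """Wavelet family/order and decomposition depth."""

    name: str = "bior4.4"
    levels: int = 5

    def __post_init__(self) -> None:
        if self.name not in SUPPORTED_WAVELETS:
            raise ValueError(
                f"unsupported wavelet {self.name!r}; choose from {SUPPORTED_WAVELETS}"
            )
        if self.levels < 1:
            raise ValueError("levels must be >= 1")

    def validate_for(self, shape: tuple[int, int]) -> None:
        max_levels = int(np.log2(min(shape))) - 2
        if self.levels > max_levels:
            raise ValueError(
                f"{self.levels} levels too deep for image {shape}; max {max_levels}"
            )


@dataclass
class CoefficientSet:
    """Multi-level 2-D wavelet coefficients in stacked-array form.

    ``array`` holds all bands in the standard stacked layout (same shape
    as the source image under periodization); ``slices`` is the layout
    descriptor needed to rebuild the per-band list. Flatten/unflatten
    round-trips exactly.
    """

    array: np.ndarray
    slices: list
    spec: WaveletSpec

    @property
    def bands(self) -> list:
        return pywt.array_to_coeffs(self.array, self.slices, output_format="wavedec2")

    def copy_with(self, array: np.ndarray) -> "CoefficientSet":
        return CoefficientSet(array, self.slices, self.spec)


@dataclass
class EWTState:
    """Exponential-wavelet coefficients plus inversion bookkeeping.

    ``norm_params`` holds the k (c_min, c_max) pairs recorded before
    each [0, 1] normalization, in application order; they are consumed
    in reverse by :func:`ewt_inverse`.
    """

    coeffs: CoefficientSet
    k: int
    norm_params: list[tuple[float, float]]
    spec: WaveletSpec


@dataclass(frozen=True)
class ShiftVector:
    """Circular shift amounts, reduced modulo the image dimensions."""

    s_row: int
    s_col: int


def dwt_forward(x: np.ndarray, spec: WaveletSpec) -> CoefficientSet:
    """Multi-level separable 2-D DWT with periodic boundary extension."""
    spec.validate_for(x.shape)
    with warnings.catch_warnings():
        # pywt warns when the depth exceeds the filter-length heuristic;
        # periodization keeps perfect reconstruction regardless
        warnings.filterwarnings("ignore", message=".*boundary effects.*")
        coeffs = pywt.wavedec2(x, spec.name, mode="periodization", level=spec.levels)
    array, slices = pywt.coeffs_to_array(coeffs)
    return CoefficientSet(array, slices, spec)


def dwt_inverse(c: CoefficientSet, spec: WaveletSpec | None = None) -> np.ndarray:
    """Exact inverse of :func:`dwt_forward` (up to floating-point error)."""
    spec = spec or c.spec
    if spec.name != c.spec.name or spec.levels != c.spec.levels:
        raise ValueError(f"layout mismatch: coefficients are {c.spec}, requested {spec}")
    return pywt.waverec2(c.bands, spec.name, mode="periodization")


def normalize01(c: CoefficientSet) -> tuple[CoefficientSet, tuple[float, float]]:
    """Affinely map all coefficients jointly onto [0, 1].

    Returns the normalized set and the recorded global (c_min, c_max).
    A constant input maps to all-zeros with the degenerate range
    replaced by 1 so the map stays invertible.
    """
    arr = c.array
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite coefficients")
    c_min, c_max = float(arr.min()), float(arr.max())
    span = c_max - c_min if c_max > c_min else 1.0
    return c.copy_with((arr - c_min) / span), (c_min, c_max)


def denormalize01(c: CoefficientSet, params: tuple[float, float]) -> CoefficientSet:
    """Invert :func:`normalize01` with the recorded extrema."""
    c_min, c_max = params
    span = c_max - c_min if c_max > c_min else 1.0
    return c.copy_with(c.array * span + c_min)


def _exp_map(v: np.ndarray) -> np.ndarray:
    # (e^v - 1)/(e - 1): fixes 0 and 1, convex increasing in between
    return np.expm1(v) / _E_MINUS_1


def _log_map(v: np.ndarray) -> np.ndarray:
    return np.log1p(_E_MINUS_1 * v)


def ewt_forward(x: np.ndarray, k: int, spec: WaveletSpec) -> EWTState:
    """Exponential wavelet transform with k exponentiation iterations.

    The wavelet decomposition is computed once; then k rounds of
    {normalize magnitudes into [0, 1] by the recorded global maximum,
    apply v -> (e^v - 1)/(e - 1) to the magnitudes, restore signs} act
    on the coefficients. The normalization is anchored at zero (the
    recorded pair is (0, c_max)) so that exactly the zero coefficients
    map to zero — any other anchor would make the sign of the
    smallest-magnitude coefficient irrecoverable on inversion. Output
    magnitudes lie in [0, 1].
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    c = dwt_forward(x, spec)
    arr = c.array
    params: list[tuple[float, float]] = []
    for _ in range(k):
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite coefficients")
        m = np.abs(arr)
        c_max = float(m.max())
        span = c_max if c_max > 0 else 1.0
        params.append((0.0, c_max))
        arr = np.sign(arr) * _exp_map(m / span)
    return EWTState(c.copy_with(arr), k, params, spec)


def ewt_inverse(state: EWTState) -> np.ndarray:
    """Invert :func:`ewt_forward` using the recorded normalizations.

    Magnitudes are clipped to [0, 1] before each log map: shrinkage
    only moves values toward 0 inside the valid range, so clipping
    only removes floating-point overshoot and is exact for thresholded
    coefficients.
    """
    if len(state.norm_params) != state.k:
        raise ValueError(
            f"need {state.k} normalization records, have {len(state.norm_params)}"
        )
    arr = state.coeffs.array
    for c_min, c_max in reversed(state.norm_params):
        span = c_max - c_min if c_max > c_min else 1.0
        m = np.clip(np.abs(arr), 0.0, 1.0)
        arr = np.sign(arr) * (_log_map(m) * span + c_min)
    return dwt_inverse(state.coeffs.copy_with(arr))


def ewt_scalar(value: float, norm_params: list[tuple[float, float]]) -> float:
    """Push a nonnegative magnitude through the normalize+exp chain.

    Maps a raw wavelet-coefficient magnitude into the exponential
    domain of a given :class:`EWTState`; used to express thresholds
    chosen on the raw coefficient scale in exponential-domain units, so
    the shrinkage dead zone is the same set of raw coefficients for
    every k.
    """
    v = float(value)
    for c_min, c_max in norm_params:
        span = c_max - c_min if c_max > c_min else 1.0
        v = float(_exp_map(np.clip((v - c_min) / span, 0.0, 1.0)))
    return v


def draw_shift(rng: np.random.Generator, shape: tuple[int, int]) -> ShiftVector:
    """Draw a uniform random circular shift for an image of this shape."""
    h, w = shape
    return ShiftVector(int(rng.integers(0, h)), int(rng.integers(0, w)))


def circ_shift(x: np.ndarray, s: ShiftVector) -> np.ndarray:
    """Circular (wrap-around) shift by (s_row, s_col)."""
    return np.roll(x, (s.s_row, s.s_col), axis=(0, 1))


def circ_unshift(x: np.ndarray, s: ShiftVector) -> np.ndarray:
    """Exact inverse of :func:`circ_shift`."""
    return np.roll(x, (-s.s_row, -s.s_col), axis=(0, 1))


def gini_index(values: np.ndarray) -> float:
    """Gini sparsity index of |values|: 0 = flat, ->1 = maximally sparse."""
    v = np.sort(np.abs(np.asarray(values, dtype=float)).ravel())
    n = v.size
    total = v.sum()
    if total == 0:
        return 0.0
    ranks = np.arange(1, n + 1)
    return float(1.0 - 2.0 * np.sum(v / total * (n - ranks + 0.5) / n))
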