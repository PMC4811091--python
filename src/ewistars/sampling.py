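"""Undersampled Fourier acquisition model.

An MRI scanner samples the image's 2-D Fourier transform (k-space); a
compressed-sensing acquisition keeps only a random subset of samples,
y = U x + e, where U composes the unitary 2-D DFT with a binary keep
mask and e is complex white Gaussian noise on the kept samples.

Masks are indexed DC-centered (`fftshift` convention); the operators
apply the shift at the boundary so that density schemes can be defined
radially from the k-space origin. With unitary FFT normalization,
U^H U is an orthogonal projector, so its largest eigenvalue is 1 and
step-size bounds in the solvers are scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SamplingMask",
    "KSpaceData",
    "make_mask",
    "forward_model",
    "apply_U",
    "apply_U_adjoint",
]

_SCHEMES = ("variable_density_random", "radial_lines", "uniform_random")


@dataclass(frozen=True)
class SamplingMask:
    """Boolean k-space inclusion pattern (DC-centered indexing)."""

    keep: np.ndarray
    acceleration: float
    scheme: str
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.keep.shape

    @property
    def kept_fraction(self) -> float:
        return float(self.keep.mean())


@dataclass(frozen=True)
class KSpaceData:
    """Measured k-space samples; exactly zero off-mask."""

    values: np.ndarray
    mask: SamplingMask
    noise_sigma: float
    seed: int


def _dc_index(shape: tuple[int, int]) -> tuple[int, int]:
    # DC lands at (H//2, W//2) after fftshift
    return shape[0] // 2, shape[1] // 2


def _radial_keep(shape: tuple[int, int], n_spokes: int) -> np.ndarray:
    h, w = shape
    cy, cx = _dc_index(shape)
    keep = np.zeros(shape, dtype=bool)
    radius = int(np.hypot(h, w) / 2) + 1
    t = np.arange(-radius, radius + 1)
    for j in range(n_spokes):
        theta = np.pi * j / n_spokes
        rows = np.rint(cy + t * np.sin(theta)).astype(int)
        cols = np.rint(cx + t * np.cos(theta)).astype(int)
        ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        keep[rows[ok], cols[ok]] = True
    return keep


def make_mask(shape: tuple[int, int], acceleration: float,
              scheme: str = "variable_density_random", seed: int = 0) -> SamplingMask:
    """Generate a k-space sampling mask with the given acceleration factor.

    The kept fraction is 1/acceleration up to the granularity of the
    scheme (exact count of rows or samples), and the DC sample is always
    kept. ``acceleration == 1`` is the fully sampled limit.

    Schemes
    -------
    variable_density_random
        Full phase-encode rows drawn without replacement with
        probability decaying from the k-space center as a Gaussian of
        width H/4 (standard CS-MRI practice), trimmed to the exact row
        count.
    radial_lines
        Pseudo-radial spokes through DC; the spoke count is grown until
        the target sample count is reached, then the mask is trimmed or
        topped up at random to the exact count.
    uniform_random
        Uniformly random samples at the exact count.
    """
    h, w = shape
    if acceleration < 1:
        raise ValueError("acceleration must be >= 1")
    if acceleration >= h:
        raise ValueError(f"acceleration {acceleration} >= number of rows {h}")
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {_SCHEMES}")
    if acceleration == 1:
        return SamplingMask(np.ones(shape, dtype=bool), 1.0, scheme, seed)

    rng = np.random.default_rng(seed)
    cy, cx = _dc_index(shape)

    if scheme == "variable_density_random":
        target_rows = max(1, int(round(h / acceleration)))
        d = np.arange(h) - cy
        weights = np.exp(-(d**2) / (2.0 * (h / 4.0) ** 2))
        rows = {cy}
        if target_rows > 1:
            pool = np.delete(np.arange(h), cy)
            p = weights[pool] / weights[pool].sum()
            rows.update(rng.choice(pool, size=target_rows - 1, replace=False, p=p))
        keep = np.zeros(shape, dtype=bool)
        keep[sorted(rows), :] = True
    else:
        target = max(1, int(round(h * w / acceleration)))
        if scheme == "uniform_random":
            keep = np.zeros(h * w, dtype=bool)
            flat_dc = cy * w + cx
            pool = np.delete(np.arange(h * w), flat_dc)
            keep[flat_dc] = True
            keep[rng.choice(pool, size=target - 1, replace=False)] = True
            keep = keep.reshape(shape)
        else:  # radial_lines
            n = 1
            keep = _radial_keep(shape, n)
            while keep.sum() < target and n < 4 * max(h, w):
                n += 1
                keep = _radial_keep(shape, n)
            count = int(keep.sum())
            flat = keep.ravel().copy()
            flat_dc = cy * w + cx
            if count > target:  # trim random kept samples, never DC
                kept_idx = np.flatnonzero(flat)
                kept_idx = kept_idx[kept_idx != flat_dc]
                flat[rng.choice(kept_idx, size=count - target, replace=False)] = False
            elif count < target:
                off_idx = np.flatnonzero(~flat)
                flat[rng.choice(off_idx, size=target - count, replace=False)] = True
            keep = flat.reshape(shape)

    keep = keep.copy()
    keep[cy, cx] = True
    return SamplingMask(keep, float(acceleration), scheme, seed)


def apply_U(x: np.ndarray, mask: SamplingMask) -> np.ndarray:
    """Masked unitary 2-D DFT: returns complex k-space (DC-centered)."""
    if x.shape != mask.shape:
        raise ValueError(f"shape mismatch: image {x.shape} vs mask {mask.shape}")
    X = np.fft.fftshift(np.fft.fft2(x, norm="ortho"))
    return np.where(mask.keep, X, 0.0 + 0.0j)


def apply_U_adjoint(y_values: np.ndarray, mask: SamplingMask) -> np.ndarray:
    """Adjoint of :func:`apply_U`: zero-fill then inverse unitary DFT.

    Returns a complex image-shaped array (real part is the zero-filled
    reconstruction of a real image).
    """
    if y_values.shape != mask.shape:
        raise ValueError(f"shape mismatch: data {y_values.shape} vs mask {mask.shape}")
    masked = np.where(mask.keep, y_values, 0.0 + 0.0j)
    return np.fft.ifft2(np.fft.ifftshift(masked), norm="ortho")


def forward_model(x: np.ndarray, mask: SamplingMask, noise_sigma: float = 0.0,
                  seed: int = 0) -> KSpaceData:
    """Simulate the acquisition y = U x + e.

    Complex circular Gaussian noise with standard deviation
    ``noise_sigma`` per real/imaginary component is added on kept
    samples only. Deterministic per seed.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    y = apply_U(x, mask)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        e = noise_sigma * (rng.standard_normal(mask.shape)
                           + 1j * rng.standard_normal(mask.shape))
        y = y + np.where(mask.keep, e, 0.0 + 0.0j)
    return KSpaceData(y, mask, float(noise_sigma), seed)
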