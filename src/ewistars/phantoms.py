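"""Synthetic tissue-like test images.

Clinical MR magnitude images are piecewise smooth (tissue compartments)
with superimposed gray-level texture. The generators here emulate both
regimes on power-of-two grids so that multi-level wavelet decompositions
are exact: a resampled Shepp-Logan head phantom (piecewise constant) and
a ``piecewise_texture`` phantom that overlays seeded band-limited noise
on elliptical tissue regions. All outputs are rescaled to the 8-bit
display range [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.data import shepp_logan_phantom
from skimage.transform import resize

__all__ = ["PhantomSpec", "make_phantom"]

_KINDS = ("shepp_logan", "piecewise_texture")


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a synthetic ground-truth image.

    Parameters
    ----------
    size : tuple of int
        (height, width); each must be a power of two >= 32 so that deep
        wavelet decompositions need no boundary bookkeeping.
    kind : str
        ``"shepp_logan"`` (piecewise constant head phantom) or
        ``"piecewise_texture"`` (elliptical tissue regions with seeded
        band-limited texture).
    texture_amplitude : float
        Peak-to-peak scale of the texture component, in gray levels.
        Ignored for the Shepp-Logan kind.
    seed : int
        Seed for the texture noise; the generator is a pure function of
        the full spec.
    """

    size: tuple[int, int] = (256, 256)
    kind: str = "piecewise_texture"
    texture_amplitude: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.size
        for n in (h, w):
            if n < 32 or (n & (n - 1)) != 0:
                raise ValueError(
                    f"phantom size must be powers of two >= 32, got {self.size}"
                )
        if self.kind not in _KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; choose from {_KINDS}")
        if self.texture_amplitude < 0:
            raise ValueError("texture_amplitude must be >= 0")


def _rescale_0_255(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return np.zeros_like(img, dtype=float)
    return (img - lo) * (255.0 / (hi - lo))


def _shepp_logan(size: tuple[int, int]) -> np.ndarray:
    base = shepp_logan_phantom()  # 400x400 in [0, 1]
    out = resize(base, size, order=1, anti_aliasing=True, mode="reflect")
    return _rescale_0_255(out)


# (center_y, center_x, semi_y, semi_x, angle_deg, gray) in unit coordinates
_ELLIPSES = (
    (0.50, 0.50, 0.42, 0.34, 0.0, 90.0),   # outer tissue
    (0.42, 0.50, 0.26, 0.20, 10.0, 150.0),  # inner compartment
    (0.62, 0.38, 0.10, 0.08, -20.0, 200.0),
    (0.62, 0.62, 0.10, 0.08, 20.0, 60.0),
    (0.35, 0.55, 0.05, 0.04, 0.0, 230.0),
)


def _piecewise_texture(spec: PhantomSpec) -> np.ndarray:
    h, w = spec.size
    yy, xx = np.meshgrid(np.linspace(0, 1, h), np.linspace(0, 1, w), indexing="ij")
    img = np.zeros((h, w))
    tissue = np.zeros((h, w), dtype=bool)
    for cy, cx, sy, sx, ang, gray in _ELLIPSES:
        t = np.deg2rad(ang)
        dy, dx = yy - cy, xx - cx
        ry = dy * np.cos(t) - dx * np.sin(t)
        rx = dy * np.sin(t) + dx * np.cos(t)
        inside = (ry / sy) ** 2 + (rx / sx) ** 2 <= 1.0
        img[inside] = gray
        tissue |= inside
    # partial-volume smoothing: tissue boundaries in MR magnitude images
    # are a few pixels wide, not step edges
    img = ndimage.gaussian_filter(img, sigma=min(h, w) / 96.0, mode="wrap")
    rng = np.random.default_rng(spec.seed)
    # coil-sensitivity (B1) inhomogeneity: a smooth multiplicative
    # modulation of +/-15%, present in essentially all clinical MR
    bias = ndimage.gaussian_filter(rng.standard_normal((h, w)),
                                   sigma=min(h, w) / 8.0, mode="wrap")
    peak = np.abs(bias).max()
    if peak > 0:
        img = img * (1.0 + 0.15 * bias / peak)
    if spec.texture_amplitude > 0:
        noise = rng.standard_normal((h, w))
        # band-limited: low-pass at a few-pixel correlation length
        noise = ndimage.gaussian_filter(noise, sigma=min(h, w) / 64.0, mode="wrap")
        peak = np.abs(noise).max()
        if peak > 0:
            noise *= spec.texture_amplitude / (2.0 * peak)
        img = img + noise * tissue
    return _rescale_0_255(img)


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Generate a deterministic synthetic ground-truth image in [0, 255].

    Returns a 2-D float array; identical specs (seed included) produce
    bit-identical images.
    """
    if spec.kind == "shepp_logan":
        return _shepp_logan(spec.size)
    return _piecewise_texture(spec)
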