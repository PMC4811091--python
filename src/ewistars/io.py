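"""Image and result I/O.

Images travel as 8-bit grayscale PNG or single slices of NIfTI-1
volumes, always presented to the rest of the toolkit as 2-D float
arrays in [0, 255]. Reconstruction runs (ground truth, mask, k-space
data, estimate, traces, configuration) persist in an HDF5 container.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import imageio.v3 as iio
import nibabel as nib
import numpy as np

__all__ = ["read_image", "write_image", "save_result", "load_result"]


def _rescale_0_255(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return np.zeros_like(img)
    return (img - lo) * (255.0 / (hi - lo))


def read_image(path: str | Path, format: str | None = None, slice_index: int | None = None) -> np.ndarray:
    """Read a grayscale image as a 2-D float array rescaled to [0, 255].

    ``format`` is ``"png"`` or ``"nifti"``; inferred from the suffix when
    omitted. Multi-channel inputs are collapsed by luminance average;
    3-D NIfTI volumes require an explicit ``slice_index`` (axial, last
    axis).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "nifti" if ".nii" in path.suffixes or path.suffix == ".nii" else "png"
    if format == "nifti":
        vol = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
        if vol.ndim == 3:
            if slice_index is None:
                raise ValueError("3-D NIfTI volume: a slice_index is required")
            vol = vol[:, :, slice_index]
        elif vol.ndim != 2:
            raise ValueError(f"unsupported NIfTI dimensionality {vol.ndim}")
        return _rescale_0_255(vol)
    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:  # RGB(A) -> luminance average over color channels
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    return _rescale_0_255(arr)


def write_image(image: np.ndarray, path: str | Path, format: str | None = None) -> None:
    """Write an image, clipping to [0, 255] and rounding to 8 bits.

    Lossless for content already on the 8-bit integer grid.
    """
    image = np.asarray(image, dtype=float)
    path = Path(path)
    if format is None:
        format = "nifti" if ".nii" in path.suffixes or path.suffix == ".nii" else "png"
    quantized = np.rint(np.clip(image, 0.0, 255.0))
    if format == "nifti":
        nib.save(nib.Nifti1Image(quantized.astype(np.uint8), affine=np.eye(4)), str(path))
    else:
        iio.imwrite(path, quantized.astype(np.uint8))


def save_result(path: str | Path, *, ground_truth=None, mask=None, y=None,
                estimate=None, trace=None, config: dict | None = None) -> None:
    """Persist a reconstruction run to an HDF5 container.

    Any of the arrays may be omitted; ``trace`` is a dict of named 1-D
    series and ``config`` is stored as a JSON attribute.
    """
    with h5py.File(path, "w") as f:
        for name, arr in (("ground_truth", ground_truth), ("mask", mask),
                          ("y", y), ("estimate", estimate)):
            if arr is not None:
                f.create_dataset(name, data=np.asarray(arr))
        if trace:
            g = f.create_group("trace")
            for name, series in trace.items():
                g.create_dataset(name, data=np.asarray(series, dtype=float))
        if config is not None:
            f.attrs["config"] = json.dumps(config)


def load_result(path: str | Path) -> dict:
    """Load a container written by :func:`save_result`."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        for name in ("ground_truth", "mask", "y", "estimate"):
            if name in f:
                out[name] = f[name][...]
        if "trace" in f:
            out["trace"] = {k: f["trace"][k][...] for k in f["trace"]}
        if "config" in f.attrs:
            out["config"] = json.loads(f.attrs["config"])
    return out
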