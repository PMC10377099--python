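"""Reading slices from PNG/TIFF/NIfTI/DICOM and writing 16-bit PNG output.

All readers return float arrays scaled to [0, 1]; integer inputs are divided
by their dtype maximum, float volumes are min-max rescaled per slice. Color
inputs come back as HxWx3 RGB.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_image", "read_nifti_slice", "read_dicom", "write_png16"]


def _rescale(arr: np.ndarray) -> np.ndarray:
    """Dtype-scaled conversion for file images (8/16-bit PNG/TIFF)."""
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(np.float64) / info.max
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def _minmax(arr: np.ndarray) -> np.ndarray:
    """Per-slice min-max rescale for scanner data, whose intensity units are
    arbitrary and rarely span the storage dtype."""
    arr = np.asarray(arr, dtype=np.float64)
    lo, hi = np.nanmin(arr), np.nanmax(arr)
    if hi > lo:
        arr = (arr - lo) / (hi - lo)
    else:
        arr = np.zeros_like(arr)
    return np.clip(arr, 0.0, 1.0)


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image to float [0, 1]; grayscale HxW or RGB HxWx3."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input image not found: {path}")
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.ndim == 3 and arr.shape[2] == 3 and np.ptp(arr, axis=2).max() == 0:
        arr = arr[..., 0]  # gray stored as RGB
    return _rescale(arr)


def read_nifti_slice(path, axis: int = 2, index: int | None = None) -> np.ndarray:
    """Extract one 2-D slice from a NIfTI volume along ``axis`` (middle by default)."""
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"NIfTI volume not found: {path}")
    vol = np.asanyarray(nib.load(str(path)).dataobj)
    if vol.ndim > 3:
        vol = vol[..., 0]
    if not 0 <= axis < 3:
        raise ValueError("axis must be 0, 1 or 2")
    if index is None:
        index = vol.shape[axis] // 2
    if not 0 <= index < vol.shape[axis]:
        raise ValueError(f"slice index {index} out of range for axis {axis}")
    return _minmax(np.take(vol, index, axis=axis))


def read_dicom(path) -> np.ndarray:
    """Read a single-frame DICOM image to float [0, 1]."""
    import pydicom

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"DICOM file not found: {path}")
    ds = pydicom.dcmread(str(path))
    return _minmax(ds.pixel_array)


def load_slice(path, axis: int = 2, index: int | None = None) -> np.ndarray:
    """Dispatch on file extension to the right reader."""
    p = Path(path)
    name = p.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return read_nifti_slice(p, axis=axis, index=index)
    if name.endswith((".dcm", ".dicom")):
        return read_dicom(p)
    return read_image(p)


def write_png16(path, img: np.ndarray) -> None:
    """Write a [0, 1] float image as PNG: 16-bit for grayscale, 8-bit for RGB
    (16-bit multichannel PNG is not supported by the Pillow backend)."""
    arr = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    if arr.ndim == 2:
        out = np.round(arr * 65535.0).astype(np.uint16)
    else:
        out = np.round(arr * 255.0).astype(np.uint8)
    iio.imwrite(Path(path), out)
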