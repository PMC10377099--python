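"""Programmatic preprocessing of structural/functional brain slices.

These operations replace the manual Analyze/GIMP workflow used to condition
MRI-like and PET-like slices before fusion: grayscale morphology to fine-tune
structural and functional detail, integer translation and sub-degree rotation
for rigid alignment, kernel sharpening, and luminance conversion for
pseudo-colored functional images.

Images are 2-D float arrays with values in [0, 1] (row-major, origin at the
top-left, y increasing downward). Every operation preserves shape and range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "StructuringElement",
    "as_image",
    "dilate",
    "erode",
    "shift",
    "rotate",
    "sharpen",
    "to_luminance",
    "DEFAULT_SHARPEN_KERNEL",
]

#: Unsharp kernel (sums to 1: a constant image is a fixed point).
DEFAULT_SHARPEN_KERNEL = np.array(
    [[0.0, -1.0, 0.0], [-1.0, 5.0, -1.0], [0.0, -1.0, 0.0]]
)


def as_image(arr, *, name: str = "image") -> np.ndarray:
    """Validate and coerce ``arr`` into a 2-D float64 image in [0, 1]."""
    img = np.asarray(arr, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"{name} must be a non-empty 2-D array, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError(f"{name} contains non-finite values")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError(f"{name} values must lie in [0, 1]")
    return img


def _default_mask() -> np.ndarray:
    return np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class StructuringElement:
    """Odd-sided square boolean neighborhood for grayscale morphology.

    The default 3x3 all-true element matches the usual "predefined
    neighborhood" of slice-preparation toolboxes.
    """

    mask: np.ndarray = field(default_factory=_default_mask)

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2 or mask.shape[0] != mask.shape[1]:
            raise ValueError("structuring element mask must be square")
        if mask.shape[0] % 2 == 0 or mask.shape[0] < 3:
            raise ValueError("structuring element side must be odd and >= 3")
        if not mask.any():
            raise ValueError("structuring element must have at least one true cell")
        c = mask.shape[0] // 2
        if not mask[c, c]:
            raise ValueError("structuring element center must be true")
        object.__setattr__(self, "mask", mask)

    @property
    def radius(self) -> int:
        return self.mask.shape[0] // 2


def dilate(img, se: StructuringElement | None = None) -> np.ndarray:
    """Grayscale dilation: per-pixel maximum over the structuring element.

    Out-of-frame neighbors are ignored (the running maximum simply has fewer
    contributors near the border).
    """
    img = as_image(img)
    se = se or StructuringElement()
    return ndimage.grey_dilation(
        img, footprint=se.mask, mode="constant", cval=-np.inf
    )


def erode(img, se: StructuringElement | None = None) -> np.ndarray:
    """Grayscale erosion: per-pixel minimum over the structuring element."""
    img = as_image(img)
    se = se or StructuringElement()
    return ndimage.grey_erosion(
        img, footprint=se.mask, mode="constant", cval=np.inf
    )


def shift(img, dx: int, dy: int) -> np.ndarray:
    """Translate by ``dx`` pixels rightward and ``dy`` pixels downward.

    Vacated regions are filled with 0; content shifted off-frame is dropped.
    """
    img = as_image(img)
    dx, dy = int(dx), int(dy)
    h, w = img.shape
    if abs(dx) >= w or abs(dy) >= h:
        raise ValueError(
            f"shift magnitude ({dx}, {dy}) must be smaller than image size ({w}, {h})"
        )
    out = np.zeros_like(img)
    src_r = slice(max(0, -dy), h - max(0, dy))
    src_c = slice(max(0, -dx), w - max(0, dx))
    dst_r = slice(max(0, dy), h - max(0, -dy))
    dst_c = slice(max(0, dx), w - max(0, -dx))
    out[dst_r, dst_c] = img[src_r, src_c]
    return out


def rotate(img, angle_deg: float) -> np.ndarray:
    """Rotate about the image center, counter-clockwise positive.

    Bilinear interpolation, output shape unchanged, out-of-frame fill 0.
    Zero angle is an exact identity.
    """
    img = as_image(img)
    if not np.isfinite(angle_deg):
        raise ValueError("rotation angle must be finite")
    if angle_deg % 360.0 == 0.0:
        return img.copy()
    out = ndimage.rotate(
        img, angle_deg, reshape=False, order=1, mode="constant", cval=0.0
    )
    return np.clip(out, 0.0, 1.0)


def sharpen(img, kernel=None) -> np.ndarray:
    """2-D correlation with a 3x3 kernel, reflect-padded, clipped to [0, 1]."""
    img = as_image(img)
    k = DEFAULT_SHARPEN_KERNEL if kernel is None else np.asarray(kernel, dtype=np.float64)
    if k.shape != (3, 3):
        raise ValueError(f"sharpening kernel must be 3x3, got {k.shape}")
    out = ndimage.correlate(img, k, mode="reflect")
    return np.clip(out, 0.0, 1.0)


def to_luminance(img) -> np.ndarray:
    """ITU-R BT.601 luminance of an RGB image: 0.299 R + 0.587 G + 0.114 B."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)) or arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("RGB values must be finite and in [0, 1]")
    lum = arr[..., 0] * 0.299 + arr[..., 1] * 0.587 + arr[..., 2] * 0.114
    return np.clip(lum, 0.0, 1.0)
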