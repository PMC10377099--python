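"""Synthetic structural/functional phantom pairs for offline testing.

Real evaluations of multimodal fusion use co-registered T1 MRI and FDG-PET
slice pairs, which cannot be redistributed. This module generates the same
*shape* of data from parametric geometry: a structural phantom (elliptical
"skull" ring plus quantized tissue texture and dark ventricles — sharp
boundaries, high spatial frequency, MRI-like) and a functional phantom
(smooth Gaussian "uptake" hotspots over the same brain geometry, rendered
through a hot black->red->yellow->white pseudo-color ramp, PET-like). The
functional image can be misaligned by a known integer shift and rotation and
degraded with seeded Gaussian noise, so registration and robustness tests
have ground truth.

Everything is driven by ``numpy.random.default_rng(seed)``; no global random
state is touched and identical specs give bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .preprocessing import rotate as _rotate
from .preprocessing import shift as _shift

__all__ = ["PhantomSpec", "make_phantom_pair", "make_batch", "hot_colormap"]


@dataclass(frozen=True)
class PhantomSpec:
    """Controls one phantom pair: geometry size, misalignment, degradation."""

    size: int = 128
    seed: int = 0
    shift_px: tuple[int, int] = (0, 0)
    rotation_deg: float = 0.0
    noise_sigma: float = 0.01
    n_hotspots: int = 3

    def __post_init__(self):
        if self.size < 32:
            raise ValueError("phantom size must be >= 32")
        if not (0.0 <= self.noise_sigma < 0.5):
            raise ValueError("noise_sigma must be in [0, 0.5)")
        if self.n_hotspots < 0:
            raise ValueError("n_hotspots must be >= 0")
        if abs(self.shift_px[0]) >= self.size or abs(self.shift_px[1]) >= self.size:
            raise ValueError("shift must be smaller than the phantom size")


def hot_colormap(v: np.ndarray) -> np.ndarray:
    """Black -> red -> yellow -> white ramp; v in [0,1] -> HxWx3 RGB."""
    v = np.clip(np.asarray(v, dtype=np.float64), 0.0, 1.0)
    return np.stack(
        [np.clip(3.0 * v, 0, 1), np.clip(3.0 * v - 1.0, 0, 1), np.clip(3.0 * v - 2.0, 0, 1)],
        axis=-1,
    )


def _brain_mask(size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    a, b = 0.42 * size, 0.34 * size  # head is taller than wide
    return ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0


def make_phantom_pair(spec: PhantomSpec = PhantomSpec()):
    """Build one (structural, functional, truth) triple.

    Returns the structural slice as an HxW float image in [0, 1], the
    functional slice as an HxWx3 pseudo-colored float image, and a ``truth``
    dict recording the misalignment actually applied to the functional image.
    At zero misalignment and zero noise the two modalities are nonzero on
    exactly the same elliptical support.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    yy, xx = np.mgrid[0:n, 0:n]
    cy = cx = (n - 1) / 2.0
    mask = _brain_mask(n)

    # --- structural: skull ring + quantized tissue + dark ventricles -------
    a, b = 0.42 * n, 0.34 * n
    r2 = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2
    skull = (r2 <= 1.0) & (r2 >= 0.82)
    texture = gaussian_filter(rng.standard_normal((n, n)), sigma=n / 32.0)
    levels = np.quantile(texture, [0.25, 0.5, 0.75])
    tissue = 0.30 + 0.12 * np.digitize(texture, levels)  # 4 sharp plateaus
    structural = np.where(mask, tissue, 0.0)
    for sx in (-1, 1):  # ventricle pair
        vr2 = ((yy - cy + 0.08 * n) / (0.16 * n)) ** 2 + (
            (xx - cx - sx * 0.09 * n) / (0.07 * n)
        ) ** 2
        structural[vr2 <= 1.0] = 0.12
    structural[skull] = 0.95
    structural = np.clip(np.where(mask, np.maximum(structural, 0.05), 0.0), 0.0, 1.0)

    # --- functional: smooth uptake over the same geometry ------------------
    uptake = np.full((n, n), 0.30)
    for _ in range(spec.n_hotspots):
        hy = cy + rng.uniform(-0.25, 0.25) * n
        hx = cx + rng.uniform(-0.20, 0.20) * n
        sig = rng.uniform(0.06, 0.12) * n
        amp = rng.uniform(0.35, 0.6)
        uptake += amp * np.exp(-((yy - hy) ** 2 + (xx - hx) ** 2) / (2 * sig**2))
    uptake = np.where(mask, np.clip(uptake, 0.05, 1.0), 0.0)

    dx, dy = int(spec.shift_px[0]), int(spec.shift_px[1])
    if (dx, dy) != (0, 0):
        uptake = _shift(uptake, dx, dy)
    if spec.rotation_deg != 0.0:
        uptake = _rotate(uptake, spec.rotation_deg)

    functional = hot_colormap(uptake)
    if spec.noise_sigma > 0:
        functional = functional + rng.normal(0.0, spec.noise_sigma, functional.shape)
        structural = structural + rng.normal(0.0, spec.noise_sigma, structural.shape)
        functional = np.clip(functional, 0.0, 1.0)
        structural = np.clip(structural, 0.0, 1.0)

    truth = {"shift_px": (dx, dy), "rotation_deg": float(spec.rotation_deg)}
    return structural, functional, truth


def make_batch(n: int, base_seed: int = 0, **overrides):
    """n phantom pairs with consecutive seeds base_seed .. base_seed + n - 1."""
    if n < 1:
        raise ValueError("need n >= 1")
    out = []
    for i in range(n):
        spec = PhantomSpec(seed=base_seed + i, **overrides)
        out.append(make_phantom_pair(spec))
    return out
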