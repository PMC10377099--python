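"""Fusion-quality metrics: SSIM, PSNR, MSE, and Shannon entropy.

Because no ground-truth fused image exists for multimodal fusion, quality is
scored per modality: the fused slice is compared against each source
(structural row, functional row), plus the entropy of the fused slice itself.
Higher SSIM/PSNR/entropy and lower MSE indicate a better fusion.

SSIM uses the canonical configuration: 11x11 Gaussian window with sigma 1.5,
K1=0.01, K2=0.03, dynamic range L=1 for [0, 1] images.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict

import numpy as np
from skimage.metrics import structural_similarity

from .preprocessing import as_image

__all__ = ["QualityReport", "mse", "psnr", "ssim", "entropy", "evaluate",
           "reports_to_csv", "reports_to_json"]


@dataclass(frozen=True)
class QualityReport:
    """Scores of a fused image against one reference source."""

    reference_id: str
    ssim: float
    psnr: float  # dB; inf when the images are identical
    mse: float
    entropy: float  # bits, of the fused image


def _pair(a, b):
    a, b = as_image(a, name="a"), as_image(b, name="b")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mse(a, b) -> float:
    """Mean squared per-pixel difference."""
    a, b = _pair(a, b)
    return float(np.mean((a - b) ** 2))


def psnr(a, b, max_val: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB: 10 log10(max_val^2 / MSE).

    Returns ``inf`` for identical images (zero error).
    """
    err = mse(a, b)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(max_val**2 / err))


def ssim(a, b, max_val: float = 1.0) -> float:
    """Mean structural similarity with the standard 11x11 Gaussian window."""
    a, b = _pair(a, b)
    if min(a.shape) < 11:
        raise ValueError(f"image sides must be >= 11 for the 11x11 window, got {a.shape}")
    return float(
        structural_similarity(
            a, b,
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
            data_range=max_val,
        )
    )


def entropy(img, bins: int = 256) -> float:
    """Shannon entropy (bits) of the intensity histogram over [0, 1].

    Empty bins contribute zero; a constant image has zero entropy and the
    maximum is log2(bins).
    """
    img = as_image(img)
    if bins < 2:
        raise ValueError("need at least 2 bins")
    counts, _ = np.histogram(img, bins=bins, range=(0.0, 1.0))
    p = counts[counts > 0] / img.size
    return float(-(p * np.log2(p)).sum())


def evaluate(fused, sources: dict[str, np.ndarray] | list) -> list[QualityReport]:
    """Score ``fused`` against each labeled source, one report per source."""
    if not isinstance(sources, dict):
        sources = {f"source_{i}": s for i, s in enumerate(sources)}
    fused = as_image(fused, name="fused")
    ent = entropy(fused)
    return [
        QualityReport(
            reference_id=label,
            ssim=ssim(fused, src),
            psnr=psnr(fused, src),
            mse=mse(fused, src),
            entropy=ent,
        )
        for label, src in sources.items()
    ]


def _fmt(v: float) -> str:
    return "inf" if np.isinf(v) else repr(float(v))


def reports_to_csv(reports: list[QualityReport], path) -> None:
    """Long-format CSV: one row per (metric, reference)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["metric", "reference_id", "value"])
        for r in reports:
            for metric in ("ssim", "psnr", "mse", "entropy"):
                w.writerow([metric, r.reference_id, _fmt(getattr(r, metric))])


def reports_to_json(reports: list[QualityReport], path) -> None:
    rows = []
    for r in reports:
        d = asdict(r)
        if np.isinf(d["psnr"]):
            d["psnr"] = "inf"
        rows.append(d)
    with open(path, "w") as fh:
        json.dump(rows, fh, indent=2)
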