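"""Deep-feature image fusion: activity maps -> softmax weight maps -> fused slice.

For each co-registered source image the backbone yields multi-channel feature
maps at the tapped convolution blocks. Per block, the channel-collapsed
activity maps of all sources are turned into convex per-pixel weights by a
softmax, the sources pass through the transposed-convolution enhancement
layer, and the block-level fused image is the weighted sum

    I_F = sum_z W_z * TransConv(I_z)                ("apply" operator)
    I_F = sum_z W_z * I_z * TransConv(I_z)          ("hadamard" operator)

The final image is the per-pixel maximum over the block-level fusions, i.e.
each pixel keeps the layer that assigns it the highest value.

Softmax is computed with the per-pixel maximum subtracted before
exponentiation; by shift invariance this is exact, not an approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import backbone as bb
from .preprocessing import as_image

__all__ = ["FusionConfig", "weight_maps", "fuse_layer", "fuse_max", "fuse_pair"]


@dataclass(frozen=True)
class FusionConfig:
    """All tunables of the fusion pipeline.

    ``tap_blocks`` selects which convolution blocks contribute a block-level
    fusion (shallow blocks carry the fine detail that drives fusion quality,
    hence the default {1}); ``activity_mode`` picks channel sum vs mean;
    ``eq7_operator`` selects the weighting operator above; ``enhance=False``
    bypasses the transposed-convolution layer entirely for ablation.
    """

    backbone: bb.BackboneSpec = field(default_factory=bb.BackboneSpec)
    transconv: bb.TransConvSpec = field(default_factory=bb.TransConvSpec)
    activity_mode: str = "mean"
    upsample_mode: str = "bilinear"
    eq7_operator: str = "apply"
    enhance: bool = True

    def __post_init__(self):
        if self.activity_mode not in ("sum", "mean"):
            raise ValueError("activity_mode must be 'sum' or 'mean'")
        if self.upsample_mode not in ("bilinear", "nearest"):
            raise ValueError("upsample_mode must be 'bilinear' or 'nearest'")
        if self.eq7_operator not in ("apply", "hadamard"):
            raise ValueError("eq7_operator must be 'apply' or 'hadamard'")

    @property
    def tap_blocks(self) -> tuple[int, ...]:
        return self.backbone.tap_blocks

    def with_tap_blocks(self, blocks) -> "FusionConfig":
        spec = bb.BackboneSpec(
            variant=self.backbone.variant,
            weights_source=self.backbone.weights_source,
            seed=self.backbone.seed,
            tap_blocks=tuple(blocks),
        )
        return FusionConfig(
            backbone=spec,
            transconv=self.transconv,
            activity_mode=self.activity_mode,
            upsample_mode=self.upsample_mode,
            eq7_operator=self.eq7_operator,
            enhance=self.enhance,
        )

    def to_dict(self) -> dict:
        return {
            "backbone": self.backbone.to_dict(),
            "transconv": self.transconv.to_dict(),
            "activity_mode": self.activity_mode,
            "upsample_mode": self.upsample_mode,
            "eq7_operator": self.eq7_operator,
            "enhance": self.enhance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FusionConfig":
        return cls(
            backbone=bb.BackboneSpec.from_dict(d.get("backbone", {})),
            transconv=bb.TransConvSpec.from_dict(d.get("transconv", {})),
            activity_mode=d.get("activity_mode", "mean"),
            upsample_mode=d.get("upsample_mode", "bilinear"),
            eq7_operator=d.get("eq7_operator", "apply"),
            enhance=bool(d.get("enhance", True)),
        )


def weight_maps(activities: list[np.ndarray]) -> list[np.ndarray]:
    """Per-pixel softmax over per-source activity maps.

    W_z = exp(a_z) / sum_j exp(a_j). Outputs match the input order, lie in
    [0, 1], and sum to 1 at every pixel.
    """
    if len(activities) < 2:
        raise ValueError("need at least two sources to compute weight maps")
    acts = [np.asarray(a, dtype=np.float64) for a in activities]
    shape = acts[0].shape
    if any(a.shape != shape for a in acts):
        raise ValueError("all activity maps must share one shape")
    stack = np.stack(acts)  # (Z, H, W)
    stack = stack - stack.max(axis=0, keepdims=True)  # exact: softmax shift invariance
    e = np.exp(stack)
    w = e / e.sum(axis=0, keepdims=True)
    return [w[z] for z in range(len(acts))]


def fuse_layer(sources, weights, cfg: FusionConfig | None = None) -> np.ndarray:
    """Fuse sources at one block with the given per-source weight maps.

    Weight maps supplied at block resolution are upsampled to the source
    shape first. Result is clipped to [0, 1] (non-identity enhancement
    kernels can push values out of range).
    """
    cfg = cfg or FusionConfig()
    if len(sources) != len(weights):
        raise ValueError(
            f"{len(sources)} sources but {len(weights)} weight maps"
        )
    srcs = [as_image(s) for s in sources]
    shape = srcs[0].shape
    if any(s.shape != shape for s in srcs):
        raise ValueError("all sources must share one shape")
    ws = []
    for w in weights:
        w = np.asarray(w, dtype=np.float64)
        if w.shape != shape:
            w = bb.upsample_to(w, *shape, mode=cfg.upsample_mode)
        ws.append(w)
    out = np.zeros(shape)
    for s, w in zip(srcs, ws):
        enhanced = bb.transposed_conv(s, cfg.transconv) if cfg.enhance else s
        if cfg.eq7_operator == "hadamard":
            out += w * s * enhanced
        else:
            out += w * enhanced
    return np.clip(out, 0.0, 1.0)


def fuse_max(layer_images) -> np.ndarray:
    """Max-selection reconstruction: per-pixel maximum over block-level fusions."""
    imgs = [as_image(i) for i in layer_images]
    if not imgs:
        raise ValueError("need at least one layer image")
    if any(i.shape != imgs[0].shape for i in imgs):
        raise ValueError("all layer images must share one shape")
    return np.maximum.reduce(imgs)


def fuse_pair(structural, functional, cfg: FusionConfig | None = None) -> np.ndarray:
    """End-to-end fusion of two (or more, via ``fuse_sources``) registered slices."""
    return fuse_sources([structural, functional], cfg)


def fuse_sources(sources, cfg: FusionConfig | None = None) -> np.ndarray:
    """Full pipeline over n >= 2 registered grayscale sources.

    Per source: backbone features at each tap block -> activity map ->
    upsample to image resolution. Per block: softmax weight maps -> enhanced
    weighted fusion. Finally max-selection over blocks. Deterministic for
    fixture weights.
    """
    cfg = cfg or FusionConfig()
    srcs = [as_image(s) for s in sources]
    if len(srcs) < 2:
        raise ValueError("need at least two sources")
    shape = srcs[0].shape
    if any(s.shape != shape for s in srcs):
        raise ValueError("all sources must share one shape")

    per_source_taps = [bb.extract_features(s, cfg.backbone) for s in srcs]
    layer_fusions = []
    for tap_idx, block in enumerate(cfg.tap_blocks):
        acts = [
            bb.upsample_to(
                bb.activity_map(taps[tap_idx], cfg.activity_mode),
                *shape,
                mode=cfg.upsample_mode,
            )
            for taps in per_source_taps
        ]
        ws = weight_maps(acts)
        layer_fusions.append(fuse_layer(srcs, ws, cfg))
    return fuse_max(layer_fusions)
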