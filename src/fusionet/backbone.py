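"""Fixed-weight VGG-style feature extraction and transposed-convolution layers.

The fusion algebra only needs the deep-feature *activity* of each source
image, not a trained classifier, so the backbone here is the plain VGG
convolutional trunk — 3x3 convolutions with ReLU, 2x2 max pooling between the
five convolution blocks — evaluated with numpy (im2col + matmul). Weights come
from a seeded He-normal initializer (``weights_source="fixture"``) so the
whole pipeline is deterministic and runs offline; loading ImageNet-trained
weights requires torchvision and is rejected with an explicit error when that
stack is absent.

A feature tap at block ``b`` is the ReLU output of the block's last
convolution, taken before that block's pooling step, so block 1 is at full
resolution and block ``b`` has spatial side ``ceil(side / 2**(b-1))``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Literal

import numpy as np
from skimage.transform import resize

from .preprocessing import as_image

__all__ = [
    "VGG_BLOCKS",
    "BackboneSpec",
    "TransConvSpec",
    "FeatureStack",
    "extract_features",
    "activity_map",
    "transposed_conv",
    "transconv_kernel",
    "upsample_to",
    "parameter_count",
]

#: Convolution-layer channel widths per block for each VGG variant.
VGG_BLOCKS: dict[str, tuple[tuple[int, ...], ...]] = {
    "vgg11": ((64,), (128,), (256, 256), (512, 512), (512, 512)),
    "vgg16": ((64, 64), (128, 128), (256, 256, 256), (512, 512, 512), (512, 512, 512)),
    "vgg19": (
        (64, 64),
        (128, 128),
        (256, 256, 256, 256),
        (512, 512, 512, 512),
        (512, 512, 512, 512),
    ),
}


@dataclass(frozen=True)
class BackboneSpec:
    """Which VGG trunk to evaluate, with which weights, tapped where."""

    variant: str = "vgg19"
    weights_source: str = "fixture"
    seed: int = 0
    tap_blocks: tuple[int, ...] = (1,)

    def __post_init__(self):
        if self.variant not in VGG_BLOCKS:
            raise ValueError(
                f"unknown variant {self.variant!r}; choose from {sorted(VGG_BLOCKS)}"
            )
        if self.weights_source not in ("fixture", "pretrained"):
            raise ValueError("weights_source must be 'fixture' or 'pretrained'")
        taps = tuple(sorted(set(int(b) for b in self.tap_blocks)))
        if not taps or any(b < 1 or b > 5 for b in taps):
            raise ValueError("tap_blocks must be a non-empty subset of {1..5}")
        object.__setattr__(self, "tap_blocks", taps)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "weights_source": self.weights_source,
            "seed": self.seed,
            "tap_blocks": list(self.tap_blocks),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BackboneSpec":
        return cls(
            variant=d.get("variant", "vgg19"),
            weights_source=d.get("weights_source", "fixture"),
            seed=int(d.get("seed", 0)),
            tap_blocks=tuple(d.get("tap_blocks", (1,))),
        )


@dataclass(frozen=True)
class TransConvSpec:
    """Transposed-convolution enhancement layer: kernel K, stride S, padding P.

    The default K=3, S=1, P=1 preserves spatial shape; ``init="identity"``
    makes the layer an exact no-op, giving a strict baseline against which the
    enhancement can be ablated.
    """

    K: int = 3
    S: int = 1
    P: int = 1
    init: Literal["identity", "smoothing", "random"] = "identity"
    seed: int = 0

    def __post_init__(self):
        if self.K < 1 or self.S < 1 or self.P < 0:
            raise ValueError("require K >= 1, S >= 1, P >= 0")
        if self.init not in ("identity", "smoothing", "random"):
            raise ValueError("init must be identity, smoothing, or random")
        if self.init == "identity" and self.K % 2 == 0:
            raise ValueError("identity init needs an odd kernel side")

    def output_shape(self, h: int, w: int) -> tuple[int, int]:
        ho = (h - 1) * self.S - 2 * self.P + self.K
        wo = (w - 1) * self.S - 2 * self.P + self.K
        if ho < 1 or wo < 1:
            raise ValueError(
                f"spec K={self.K},S={self.S},P={self.P} gives non-positive "
                f"output size for {h}x{w} input"
            )
        return ho, wo

    def to_dict(self) -> dict:
        return {"K": self.K, "S": self.S, "P": self.P, "init": self.init, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "TransConvSpec":
        return cls(
            K=int(d.get("K", 3)),
            S=int(d.get("S", 1)),
            P=int(d.get("P", 1)),
            init=d.get("init", "identity"),
            seed=int(d.get("seed", 0)),
        )


@dataclass(frozen=True)
class FeatureStack:
    """Multi-channel ReLU feature maps tapped at one convolution block."""

    layer_id: int
    maps: np.ndarray  # (channels, H, W), all values >= 0

    @property
    def channels(self) -> int:
        return self.maps.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.maps.shape[1], self.maps.shape[2]


# --------------------------------------------------------------------------
# weights


@lru_cache(maxsize=4)
def fixture_weights(variant: str, seed: int) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Seeded He-normal conv weights (biases zero) for the given trunk.

    Returns, per block, a list of ``(W, b)`` with ``W`` of shape
    (out_ch, in_ch, 3, 3). Fully deterministic for a given seed; memoized,
    so callers must not mutate the returned arrays.
    """
    rng = np.random.default_rng(seed)
    weights = []
    in_ch = 3
    for block in VGG_BLOCKS[variant]:
        layers = []
        for out_ch in block:
            fan_in = in_ch * 9
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, 3, 3))
            layers.append((w.astype(np.float32), np.zeros(out_ch, dtype=np.float32)))
            in_ch = out_ch
        weights.append(layers)
    return weights


def _load_weights(spec: BackboneSpec):
    if spec.weights_source == "fixture":
        return fixture_weights(spec.variant, spec.seed)
    raise RuntimeError(
        "weights_source='pretrained' loads ImageNet VGG weights through "
        "torchvision, which is not installed; use weights_source='fixture'"
    )


def parameter_count(variant: str, up_to_block: int) -> int:
    """Trainable-parameter count of the conv trunk tapped through ``up_to_block``."""
    if variant not in VGG_BLOCKS:
        raise ValueError(f"unknown variant {variant!r}")
    n, in_ch = 0, 3
    for block in VGG_BLOCKS[variant][:up_to_block]:
        for out_ch in block:
            n += out_ch * in_ch * 9 + out_ch
            in_ch = out_ch
    return n


# --------------------------------------------------------------------------
# forward pass


def _conv3x3_relu(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Zero-padded 3x3 convolution + ReLU via im2col matmul. x: (C, H, W)."""
    c, h, wid = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    cols = cols.transpose(1, 2, 0, 3, 4).reshape(h * wid, c * 9)
    out = cols @ w.reshape(w.shape[0], -1).T + b
    out = out.T.reshape(w.shape[0], h, wid)
    return np.maximum(out, 0.0)


def _maxpool2(x: np.ndarray) -> np.ndarray:
    """2x2 stride-2 max pooling with ceil semantics (edge windows may be partial)."""
    c, h, w = x.shape
    ph, pw = (-h) % 2, (-w) % 2
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, ph), (0, pw)), constant_values=-np.inf)
    h2, w2 = x.shape[1] // 2, x.shape[2] // 2
    return x.reshape(c, h2, 2, w2, 2).max(axis=(2, 4))


#: ImageNet channel statistics, applied only with pretrained weights.
_IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
_IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


def extract_features(img, spec: BackboneSpec) -> list[FeatureStack]:
    """Run the trunk on a grayscale image; return one FeatureStack per tap block.

    The single-channel input is replicated to 3 channels before the first
    convolution. Deterministic: repeated calls are bit-identical for a fixed
    spec.
    """
    img = as_image(img)
    weights = _load_weights(spec)
    x = np.repeat(img.astype(np.float32)[None], 3, axis=0)
    if spec.weights_source == "pretrained":  # pragma: no cover - needs torchvision
        x = (x - _IMAGENET_MEAN[:, None, None]) / _IMAGENET_STD[:, None, None]
    taps: list[FeatureStack] = []
    for block_idx, layers in enumerate(weights, start=1):
        for w, b in layers:
            x = _conv3x3_relu(x, w, b)
        if block_idx in spec.tap_blocks:
            taps.append(FeatureStack(layer_id=block_idx, maps=x.copy()))
        if block_idx == max(spec.tap_blocks):
            break
        x = _maxpool2(x)
    return taps


def activity_map(fs: FeatureStack, mode: str = "mean") -> np.ndarray:
    """Collapse a feature stack to a per-pixel activity level.

    ``mode="sum"`` sums over channels; ``mode="mean"`` divides by the channel
    count, keeping activity scales comparable across blocks of different width.
    """
    if mode not in ("sum", "mean"):
        raise ValueError("mode must be 'sum' or 'mean'")
    out = fs.maps.sum(axis=0, dtype=np.float64)
    if mode == "mean":
        out /= fs.channels
    return out


# --------------------------------------------------------------------------
# transposed convolution


def transconv_kernel(spec: TransConvSpec) -> np.ndarray:
    """Materialize the enhancement kernel for a spec."""
    if spec.init == "identity":
        k = np.zeros((spec.K, spec.K))
        k[spec.K // 2, spec.K // 2] = 1.0
        return k
    if spec.init == "smoothing":
        return np.full((spec.K, spec.K), 1.0 / (spec.K * spec.K))
    rng = np.random.default_rng(spec.seed)
    return rng.normal(0.0, 1.0 / spec.K, size=(spec.K, spec.K))


def transposed_conv(img, spec: TransConvSpec = TransConvSpec(), kernel=None) -> np.ndarray:
    """Transposed convolution: scatter each input value through the kernel.

    Input value at (h, w) contributes ``x[h, w] * kernel[i, j]`` to output
    position (h*S - P + i, w*S - P + j); contributions outside the output
    frame are dropped. For the default K=3, S=1, P=1 the output shape equals
    the input shape, and the identity kernel returns the input exactly.
    """
    img = as_image(img)
    h, w = img.shape
    ho, wo = spec.output_shape(h, w)
    k = transconv_kernel(spec) if kernel is None else np.asarray(kernel, dtype=np.float64)
    if k.shape != (spec.K, spec.K):
        raise ValueError(f"kernel shape {k.shape} does not match spec K={spec.K}")
    if spec.init == "identity" and kernel is None and spec.S == 1 and 2 * spec.P == spec.K - 1:
        return img.copy()
    # full scatter grid, then crop P from each side
    full = np.zeros(((h - 1) * spec.S + spec.K, (w - 1) * spec.S + spec.K))
    for i in range(spec.K):
        for j in range(spec.K):
            full[i : i + (h - 1) * spec.S + 1 : spec.S,
                 j : j + (w - 1) * spec.S + 1 : spec.S] += img * k[i, j]
    return full[spec.P : spec.P + ho, spec.P : spec.P + wo]


def upsample_to(arr, target_h: int, target_w: int, mode: str = "bilinear") -> np.ndarray:
    """Resample an activity or weight map up to ``(target_h, target_w)``.

    Needed because pooling shrinks deep-block maps below image resolution.
    Bilinear stays within the input value range; nearest replicates values.
    """
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D map")
    if target_h < arr.shape[0] or target_w < arr.shape[1]:
        raise ValueError(
            f"target {target_h}x{target_w} smaller than source {arr.shape}"
        )
    if (target_h, target_w) == arr.shape:
        return arr.copy()
    if mode == "bilinear":
        order = 1
    elif mode == "nearest":
        order = 0
    else:
        raise ValueError("mode must be 'bilinear' or 'nearest'")
    return resize(
        arr, (target_h, target_w), order=order, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
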