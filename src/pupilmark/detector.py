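"""Multiscale heatmap-regression CNN (the landmark detector).

The network is a decoder-only fully convolutional model in two subparts:
S1, four convolutional blocks applied with *shared weights* to all three
Gaussian-pyramid levels of the input (so the parameter count is independent
of the number of scales), and S2, which maps the element-wise average of
the resampled S1 feature maps to one heatmap per landmark.  The total
spatial stride of S1 fixes the heatmap stride (default 4: a 240x360 input
yields 60x90 maps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, avg_pool2, bilinear_resize, conv2d
from .heatmaps import HeatmapStack, gaussian_pyramid

__all__ = ["BlockSpec", "DetectorConfig", "DetectorModel", "build_detector", "detect",
           "small_config"]


@dataclass(frozen=True)
class BlockSpec:
    """One convolutional block: same-padded conv (+ReLU) and optional 2x pool."""

    channels: int
    kernel: int
    pool: bool = False
    kind: str = "conv"


def _default_s1() -> tuple[BlockSpec, ...]:
    return (
        BlockSpec(16, 5),
        BlockSpec(32, 5, pool=True),
        BlockSpec(64, 3),
        BlockSpec(64, 3, pool=True),
    )


def _default_s2() -> tuple[BlockSpec, ...]:
    return (BlockSpec(128, 9), BlockSpec(128, 9), BlockSpec(17, 1))


@dataclass(frozen=True)
class DetectorConfig:
    """Architecture description.

    S1 must have exactly four blocks; the last S2 block is a linear head
    with ``n_landmarks`` channels; no fully-connected layers exist anywhere
    (the network is an FCN), and S1 weights are shared across scales.
    """

    s1_blocks: tuple[BlockSpec, ...] = field(default_factory=_default_s1)
    s2_blocks: tuple[BlockSpec, ...] = field(default_factory=_default_s2)
    input_channels: int = 1
    n_landmarks: int = 17
    n_scales: int = 3
    per_scale_weights: bool = False

    @property
    def stride(self) -> int:
        return 2 ** sum(1 for b in self.s1_blocks if b.pool) * 2 ** sum(
            1 for b in self.s2_blocks if b.pool
        )


def small_config(n_landmarks: int = 17) -> DetectorConfig:
    """A narrow, stride-2 configuration for desk-scale training runs.

    The finer stride keeps hard-argmax quantization well below the 10%
    interpupillary PCK threshold on small frames (64x96 and similar).
    """
    return DetectorConfig(
        s1_blocks=(
            BlockSpec(8, 5),
            BlockSpec(8, 5, pool=True),
            BlockSpec(16, 3),
            BlockSpec(16, 3),
        ),
        s2_blocks=(BlockSpec(32, 5), BlockSpec(n_landmarks, 1)),
        n_landmarks=n_landmarks,
    )


class DetectorModel:
    """Weights + forward pass; S1 weights are reused for every scale."""

    def __init__(self, config: DetectorConfig, seed: int = 0):
        _validate(config)
        self.config = config
        rng = np.random.default_rng(seed)
        self.s1_weights: list[tuple[Tensor, Tensor]] = []
        self.s2_weights: list[tuple[Tensor, Tensor]] = []
        cin = config.input_channels
        for blk in config.s1_blocks:
            self.s1_weights.append(_init_conv(rng, cin, blk))
            cin = blk.channels
        for i, blk in enumerate(config.s2_blocks):
            last = i == len(config.s2_blocks) - 1
            self.s2_weights.append(_init_conv(rng, cin, blk, head=last))
            cin = blk.channels

    def parameters(self) -> list[Tensor]:
        out = []
        for w, b in self.s1_weights + self.s2_weights:
            out += [w, b]
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def _run_s1(self, x: Tensor) -> Tensor:
        for (w, b), blk in zip(self.s1_weights, self.config.s1_blocks):
            x = conv2d(x, w, b, padding="same").relu()
            if blk.pool:
                x = avg_pool2(x)
        return x

    def forward(self, levels: list[Tensor]) -> Tensor:
        """S1 on each pyramid level, resample to the finest S1 output size,
        average, then S2.  Returns (N, n_landmarks, H/stride, W/stride)."""
        feats = [self._run_s1(lv) for lv in levels]
        target = feats[0].data.shape[2:]
        acc = feats[0]
        for f in feats[1:]:
            acc = acc + (f if f.data.shape[2:] == target else bilinear_resize(f, target))
        x = acc * (1.0 / len(feats))
        for i, ((w, b), blk) in enumerate(zip(self.s2_weights, self.config.s2_blocks)):
            x = conv2d(x, w, b, padding="same")
            if i < len(self.s2_weights) - 1:
                x = x.relu()
            if blk.pool:
                x = avg_pool2(x)
        return x

    def forward_images(self, images: np.ndarray, requires_grad: bool = False) -> Tensor:
        """Pyramid + forward for a batch of (N, H, W) grayscale images."""
        images = np.asarray(images, dtype=np.float32)
        n = images.shape[0]
        levels: list[list[np.ndarray]] = [[] for _ in range(self.config.n_scales)]
        for i in range(n):
            for s, lv in enumerate(gaussian_pyramid(images[i], self.config.n_scales)):
                levels[s].append(lv)
        tensors = [
            Tensor(np.stack(lvl)[:, None].astype(np.float32)) for lvl in levels
        ]
        return self.forward(tensors)


def _init_conv(rng: np.random.Generator, cin: int, blk: BlockSpec, head: bool = False):
    fan_in = cin * blk.kernel * blk.kernel
    std = 1e-3 if head else np.sqrt(2.0 / fan_in)
    w = Tensor(
        rng.normal(0.0, std, (blk.channels, cin, blk.kernel, blk.kernel)).astype(np.float32),
        requires_grad=True,
    )
    b = Tensor(np.zeros(blk.channels, dtype=np.float32), requires_grad=True)
    return w, b


def _validate(cfg: DetectorConfig) -> None:
    if len(cfg.s1_blocks) != 4:
        raise ValueError("S1 must consist of exactly four convolutional blocks")
    for blk in cfg.s1_blocks + cfg.s2_blocks:
        if blk.kind != "conv":
            raise ValueError(
                f"block kind {blk.kind!r} not allowed: the detector is fully "
                "convolutional (no dense/fully-connected layers)"
            )
        if blk.kernel % 2 == 0:
            raise ValueError("kernel sizes must be odd (same-padded convolutions)")
    if cfg.s2_blocks[-1].channels != cfg.n_landmarks:
        raise ValueError("the final S2 head must have n_landmarks channels")
    if cfg.per_scale_weights:
        raise ValueError(
            "per-scale S1 weights are not supported: all scales share one set "
            "of S1 parameters by design"
        )


def build_detector(config: DetectorConfig | None = None, seed: int = 0) -> DetectorModel:
    """Construct a detector; rejects configurations violating the design
    invariants (per-scale weights, dense layers, wrong head width)."""
    return DetectorModel(config or DetectorConfig(), seed=seed)


def detect(model: DetectorModel, image: np.ndarray) -> HeatmapStack:
    """Run the detector on one grayscale image -> HeatmapStack."""
    out = model.forward_images(np.asarray(image, dtype=float)[None])
    stride = image.shape[0] / out.data.shape[2]
    return HeatmapStack(out.data[0].astype(float), stride=stride)
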