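"""Heatmap construction, Gaussian pyramid and coordinate decoding.

Heatmaps live on a grid whose cells subsample the image by ``stride``:
image pixel u maps to heatmap coordinate ``(u - (stride-1)/2) / stride``
(pixel-center aligned), so cell ``c`` represents image pixel
``c*stride + (stride-1)/2``.  Ground-truth maps place a fixed 3x3 binomial
kernel (center value 1) at the rounded scaled coordinate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .schema import DEFAULT_SCHEMA, LandmarkSet17

__all__ = [
    "HeatmapStack",
    "GT_KERNEL",
    "gt_heatmap",
    "gaussian_pyramid",
    "argmax_decode",
    "soft_argmax",
    "image_to_grid",
    "grid_to_image",
    "save_stack",
    "load_stack",
]

#: 3x3 binomial kernel, outer([1,2,1],[1,2,1])/4, normalized to center 1.
GT_KERNEL = np.outer([1.0, 2.0, 1.0], [1.0, 2.0, 1.0]) / 4.0


@dataclass
class HeatmapStack:
    """Per-landmark unary maps on a common grid."""

    maps: np.ndarray  # (17, H, W), values >= 0 for ground truth / priors
    stride: float = 4.0

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 3:
            raise ValueError("maps must be (n_landmarks, H, W)")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.maps.shape[1:]

    def copy(self) -> "HeatmapStack":
        return HeatmapStack(self.maps.copy(), self.stride)


def image_to_grid(coords_uv: np.ndarray, stride: float) -> np.ndarray:
    """Image-pixel (u, v) -> heatmap-grid coordinates (pixel-center aligned)."""
    return (np.asarray(coords_uv, dtype=float) - (stride - 1.0) / 2.0) / stride


def grid_to_image(coords_uv: np.ndarray, stride: float) -> np.ndarray:
    """Inverse of :func:`image_to_grid`."""
    return np.asarray(coords_uv, dtype=float) * stride + (stride - 1.0) / 2.0


def gt_heatmap(
    landmarks: LandmarkSet17,
    grid_shape: tuple[int, int],
    stride: float = 4.0,
) -> HeatmapStack:
    """Ground-truth heatmaps: a 3x3 binomial patch per visible landmark.

    Landmarks within 1 cell of the border get a cropped kernel (center cell
    still 1); invisible landmarks yield all-zero maps.
    """
    h, w = grid_shape
    maps = np.zeros((17, h, w))
    grid_uv = image_to_grid(landmarks.coords, stride)
    for k in range(17):
        if not landmarks.visibility[k]:
            continue
        c = int(round(grid_uv[k, 0]))
        r = int(round(grid_uv[k, 1]))
        if not (0 <= c < w and 0 <= r < h):
            raise ValueError(
                f"landmark {k} maps outside the {h}x{w} grid at ({r}, {c})"
            )
        r0, r1 = max(r - 1, 0), min(r + 2, h)
        c0, c1 = max(c - 1, 0), min(c + 2, w)
        maps[k, r0:r1, c0:c1] = GT_KERNEL[r0 - r + 1 : r1 - r + 1, c0 - c + 1 : c1 - c + 1]
    return HeatmapStack(maps, stride)


def gaussian_pyramid(image: np.ndarray, n_levels: int = 3, min_size: int = 8) -> list[np.ndarray]:
    """Smoothed-then-decimated pyramid at relative scales 1, 1/2, 1/4.

    Level l is built by Gaussian blur (sigma=1, reflect boundary) followed by
    2x decimation of level l-1.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    need = min_size * 2 ** (n_levels - 1)
    if h < need or w < need:
        raise ValueError(
            f"image {h}x{w} too small for a {n_levels}-level pyramid; "
            f"minimum is {need}x{need}"
        )
    levels = [image]
    for _ in range(n_levels - 1):
        blurred = ndimage.gaussian_filter(levels[-1], sigma=1.0, mode="reflect")
        levels.append(blurred[::2, ::2])
    return levels


def argmax_decode(stack: HeatmapStack) -> LandmarkSet17:
    """Per-landmark argmax in heatmap-grid units (ties: smallest row-major
    index); all-zero maps are flagged not-visible."""
    n, h, w = stack.maps.shape
    coords = np.zeros((n, 2))
    vis = np.ones(n, dtype=bool)
    flat = stack.maps.reshape(n, -1)
    idx = flat.argmax(axis=1)  # argmax returns the first (row-major) maximum
    coords[:, 0] = idx % w
    coords[:, 1] = idx // w
    vis &= ~np.all(flat == 0.0, axis=1)
    return LandmarkSet17(coords, vis)


def soft_argmax(hm: np.ndarray, temperature: float = 1.0) -> tuple[float, float]:
    """Expectation of the coordinate grid under the softmax-normalized map."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    hm = np.asarray(hm, dtype=float)
    z = (hm - hm.max()) / temperature
    e = np.exp(z)
    p = e / e.sum()
    h, w = hm.shape
    u = float((p.sum(axis=0) * np.arange(w)).sum())
    v = float((p.sum(axis=1) * np.arange(h)).sum())
    return (u, v)


def save_stack(path, stack: HeatmapStack, schema=DEFAULT_SCHEMA) -> None:
    """Serialize a stack as a compressed array plus a JSON sidecar."""
    path = Path(path)
    np.savez_compressed(path, maps=stack.maps)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"stride": stack.stride, "landmarks": list(schema.landmark_ids)})
    )


def load_stack(path) -> HeatmapStack:
    path = Path(path)
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    sidecar = path.with_suffix(path.suffix + ".json")
    stride = 4.0
    if sidecar.exists():
        stride = float(json.loads(sidecar.read_text())["stride"])
    return HeatmapStack(data["maps"], stride)
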