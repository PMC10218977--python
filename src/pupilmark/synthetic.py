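"""Parametric synthetic faces: images, landmarks, heatmap fixtures, augmentation.

The generator renders schematic grayscale faces (head ellipse, brow and eye
strokes, dark pupils, nose and mouth strokes) whose stroke geometry is tied
to a posed, jittered 17-landmark canonical shape.  It exists to give every
downstream stage -- prior learning, spatial filtering, detector training and
evaluation -- a fully annotated population with controlled pose statistics;
it makes no attempt at photorealism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import transform as sktf

from .heatmaps import HeatmapStack, image_to_grid
from .schema import DEFAULT_SCHEMA, AnnotatedImage, LandmarkSchema, LandmarkSet17

__all__ = [
    "CANONICAL_SHAPE",
    "FaceShapeParams",
    "AugmentConfig",
    "PopulationConfig",
    "sample_face",
    "sample_dataset",
    "synth_heatmaps",
    "inject_outlier",
    "augment",
    "draw_augment_params",
]

#: Mean 17-landmark shape on the unit face (u, v in [0, 1], v grows downward),
#: ordered as schema.LANDMARK_IDS.  Interpupillary distance is 0.40 units.
CANONICAL_SHAPE = np.array(
    [
        [0.30, 0.40],  # LPc
        [0.70, 0.40],  # RPc
        [0.50, 0.62],  # NT
        [0.34, 0.78],  # LMe
        [0.66, 0.78],  # RMe
        [0.16, 0.30],  # LBo
        [0.28, 0.24],  # LBm
        [0.40, 0.28],  # LBi
        [0.60, 0.28],  # RBi
        [0.72, 0.24],  # RBm
        [0.84, 0.30],  # RBo
        [0.20, 0.41],  # LEo
        [0.27, 0.36],  # LEt
        [0.40, 0.41],  # LEi
        [0.60, 0.41],  # REi
        [0.73, 0.36],  # REt
        [0.80, 0.41],  # REo
    ]
)

#: Fraction of the frame spanned by the unit face under the identity pose.
FACE_SPAN = 0.80


@dataclass
class FaceShapeParams:
    """Shape/pose parameters for one synthetic face."""

    canonical_shape: np.ndarray = field(default_factory=lambda: CANONICAL_SHAPE.copy())
    jitter: float = 0.02          # per-landmark isotropic sd, unit-face fraction
    rotation_deg: float = 0.0
    scale: float = 1.0
    translation: tuple[float, float] = (0.0, 0.0)  # pixels (u, v)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


@dataclass
class AugmentConfig:
    """Affine augmentation distribution (uniform over the stated ranges)."""

    scale_range: tuple[float, float] = (1.05, 1.5)
    translate_frac_range: tuple[float, float] = (0.0, 0.10)
    rotation_range_deg: tuple[float, float] = (-20.0, 20.0)
    hflip_prob: float = 0.5

    def __post_init__(self) -> None:
        for lo, hi in (self.scale_range, self.translate_frac_range, self.rotation_range_deg):
            if hi < lo:
                raise ValueError("augmentation ranges must be well-ordered")
        if not 0.0 <= self.hflip_prob <= 1.0:
            raise ValueError("hflip_prob must lie in [0, 1]")


@dataclass
class PopulationConfig:
    """Pose statistics of a sampled synthetic population."""

    rotation_sd_deg: float = 0.0
    rotation_range_deg: tuple[float, float] = (-15.0, 15.0)
    scale_range: tuple[float, float] = (0.85, 1.15)
    translate_frac: float = 0.05
    jitter: float = 0.02


def _base_affine(frame_shape: tuple[int, int]) -> np.ndarray:
    """Unit-face -> pixel affine placing the face over FACE_SPAN of the frame."""
    h, w = frame_shape
    cu, cv = (w - 1) / 2.0, (h - 1) / 2.0
    m = np.eye(3)
    m[0, 0] = FACE_SPAN * (w - 1)
    m[1, 1] = FACE_SPAN * (h - 1)
    m[0, 2] = cu - 0.5 * m[0, 0]
    m[1, 2] = cv - 0.5 * m[1, 1]
    return m


def _pose_affine(frame_shape: tuple[int, int], rotation_deg: float, scale: float,
                 translation: tuple[float, float]) -> np.ndarray:
    """Rotation+scale about the frame center followed by translation."""
    h, w = frame_shape
    cu, cv = (w - 1) / 2.0, (h - 1) / 2.0
    th = np.deg2rad(rotation_deg)
    r = np.array(
        [
            [np.cos(th), -np.sin(th), 0.0],
            [np.sin(th), np.cos(th), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    s = np.diag([scale, scale, 1.0])
    to_c = np.eye(3)
    to_c[:2, 2] = (-cu, -cv)
    from_c = np.eye(3)
    from_c[:2, 2] = (cu + translation[0], cv + translation[1])
    return from_c @ r @ s @ to_c


def _apply_affine(m: np.ndarray, uv: np.ndarray) -> np.ndarray:
    uv1 = np.column_stack([uv, np.ones(len(uv))])
    return (uv1 @ m.T)[:, :2]


def _soft_stroke(canvas, uu, vv, p0, p1, width, darkness):
    """Darken an antialiased line segment from p0 to p1 (u, v pixels)."""
    d = np.asarray(p1, float) - np.asarray(p0, float)
    l2 = float(d @ d)
    pu, pv = uu - p0[0], vv - p0[1]
    if l2 < 1e-12:
        dist = np.hypot(pu, pv)
    else:
        t = np.clip((pu * d[0] + pv * d[1]) / l2, 0.0, 1.0)
        dist = np.hypot(pu - t * d[0], pv - t * d[1])
    alpha = np.clip(1.0 - (dist - width), 0.0, 1.0)
    canvas -= darkness * alpha * canvas
    np.clip(canvas, 0.0, 1.0, out=canvas)


def _soft_disk(canvas, uu, vv, center, radius, value):
    dist = np.hypot(uu - center[0], vv - center[1])
    alpha = np.clip(1.0 - (dist - radius), 0.0, 1.0)
    canvas *= 1.0 - alpha
    canvas += alpha * value


def _polyline(canvas, uu, vv, pts, width, darkness):
    for a, b in zip(pts[:-1], pts[1:]):
        _soft_stroke(canvas, uu, vv, a, b, width, darkness)


def _render(frame_shape: tuple[int, int], lm: np.ndarray, pose_m: np.ndarray,
            base_m: np.ndarray, schema: LandmarkSchema) -> np.ndarray:
    h, w = frame_shape
    uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    canvas = np.full((h, w), 0.55)
    idx = schema.index
    m = pose_m @ base_m
    px = float(w) / 120.0  # stroke widths relative to a 120-px-wide frame

    # head: ellipse outline through canonical boundary, posed
    t = np.linspace(0.0, 2 * np.pi, 48)
    head = np.column_stack([0.5 + 0.47 * np.cos(t), 0.52 + 0.55 * np.sin(t)])
    head_px = _apply_affine(m, head)
    # fill the head a bit brighter than background using the ellipse interior
    inner = np.column_stack([0.5 + 0.47 * 0.98 * np.cos(t), 0.52 + 0.55 * 0.98 * np.sin(t)])
    c_head = _apply_affine(m, np.array([[0.5, 0.52]]))[0]
    rad = np.linalg.norm(_apply_affine(m, inner) - c_head, axis=1).mean()
    _soft_disk(canvas, uu, vv, c_head, rad, 0.82)
    _polyline(canvas, uu, vv, head_px, 1.2 * px, 0.55)

    # brows
    _polyline(canvas, uu, vv, lm[[idx("LBo"), idx("LBm"), idx("LBi")]], 1.3 * px, 0.75)
    _polyline(canvas, uu, vv, lm[[idx("RBi"), idx("RBm"), idx("RBo")]], 1.3 * px, 0.75)

    # eyes: upper lid through the three eye points, lower lid corner-to-corner
    for eo, et, ei in (("LEo", "LEt", "LEi"), ("REo", "REt", "REi")):
        pts = lm[[idx(eo), idx(et), idx(ei)]]
        _polyline(canvas, uu, vv, pts, 1.0 * px, 0.7)
        _soft_stroke(canvas, uu, vv, lm[idx(eo)], lm[idx(ei)], 0.8 * px, 0.45)
    # pupils: dark disks with a bright glint at the exact landmark
    for p in ("LPc", "RPc"):
        _soft_disk(canvas, uu, vv, lm[idx(p)], 2.2 * px, 0.05)
        _soft_disk(canvas, uu, vv, lm[idx(p)], 0.8 * px, 0.95)

    # nose: bridge from between-the-eyes down to NT plus a nostril bar
    bridge_top = 0.5 * (lm[idx("LEi")] + lm[idx("REi")])
    nt = lm[idx("NT")]
    _soft_stroke(canvas, uu, vv, bridge_top, nt, 0.9 * px, 0.4)
    wing = _apply_affine(m, np.array([[0.045, 0.0]]))[0] - _apply_affine(m, np.array([[0.0, 0.0]]))[0]
    _soft_stroke(canvas, uu, vv, nt - wing, nt + wing, 1.1 * px, 0.65)

    # mouth: bowed polyline between the extremities
    lme, rme = lm[idx("LMe")], lm[idx("RMe")]
    drop = _apply_affine(m, np.array([[0.0, 0.035]]))[0] - _apply_affine(m, np.array([[0.0, 0.0]]))[0]
    mid = 0.5 * (lme + rme) + drop
    _polyline(canvas, uu, vv, np.array([lme, mid, rme]), 1.2 * px, 0.7)
    return canvas


def sample_face(
    params: FaceShapeParams,
    frame_shape: tuple[int, int] = (64, 96),
    rng: np.random.Generator | None = None,
    schema: LandmarkSchema = DEFAULT_SCHEMA,
    max_retries: int = 20,
    source_id: str = "synthetic",
) -> AnnotatedImage:
    """Render one synthetic face; deterministic for a given seed.

    The landmark list is the posed, jittered canonical shape.  Jitter draws
    that push any landmark outside the frame are rejected and resampled up to
    ``max_retries`` times, after which an error names the pose.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    h, w = frame_shape
    base_m = _base_affine(frame_shape)
    pose_m = _pose_affine(frame_shape, params.rotation_deg, params.scale, params.translation)
    m = pose_m @ base_m
    for _ in range(max_retries):
        shape = params.canonical_shape + (
            rng.normal(0.0, params.jitter, (17, 2)) if params.jitter > 0 else 0.0
        )
        lm = _apply_affine(m, shape)
        if (lm[:, 0].min() >= 1 and lm[:, 0].max() <= w - 2
                and lm[:, 1].min() >= 1 and lm[:, 1].max() <= h - 2):
            break
    else:
        raise ValueError(
            f"pose (rot={params.rotation_deg}, scale={params.scale}, "
            f"t={params.translation}) pushes landmarks outside the {h}x{w} frame"
        )
    pixels = _render(frame_shape, lm, pose_m, base_m, schema)
    return AnnotatedImage(pixels, LandmarkSet17(lm), source_id=source_id)


def sample_dataset(
    n: int,
    frame_shape: tuple[int, int] = (64, 96),
    seed: int = 0,
    cfg: PopulationConfig | None = None,
    schema: LandmarkSchema = DEFAULT_SCHEMA,
) -> list[AnnotatedImage]:
    """Sample a population of synthetic faces with uniform pose variation."""
    cfg = cfg or PopulationConfig()
    rng = np.random.default_rng(seed)
    h, w = frame_shape
    out = []
    for k in range(n):
        params = FaceShapeParams(
            jitter=cfg.jitter,
            rotation_deg=float(rng.uniform(*cfg.rotation_range_deg)),
            scale=float(rng.uniform(*cfg.scale_range)),
            translation=(
                float(rng.uniform(-cfg.translate_frac, cfg.translate_frac) * w),
                float(rng.uniform(-cfg.translate_frac, cfg.translate_frac) * h),
            ),
        )
        out.append(sample_face(params, frame_shape, rng=rng, schema=schema,
                               source_id=f"synthetic-{k:05d}"))
    return out


def synth_heatmaps(
    landmarks: LandmarkSet17,
    grid_shape: tuple[int, int],
    stride: float = 4.0,
    peak: float = 1.0,
    sigma: float = 1.5,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> HeatmapStack:
    """Idealized detector output: one Gaussian blob per landmark.

    Each map carries a blob of height ``peak`` at the landmark's scaled grid
    coordinate plus optional i.i.d. Gaussian noise, clipped at zero.
    """
    h, w = grid_shape
    grid_uv = image_to_grid(landmarks.coords, stride)
    if np.any((grid_uv < -0.5) | (grid_uv > [w - 0.5, h - 0.5])):
        raise ValueError("landmarks map outside the heatmap grid")
    cc, rr = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    maps = np.zeros((17, h, w))
    for k in range(17):
        u, v = grid_uv[k]
        maps[k] = peak * np.exp(-((cc - u) ** 2 + (rr - v) ** 2) / (2.0 * sigma**2))
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        maps += rng.normal(0.0, noise_sd, maps.shape)
    np.clip(maps, 0.0, None, out=maps)
    return HeatmapStack(maps, stride)


def inject_outlier(
    hm: np.ndarray, offset_px: tuple[int, int], sigma: float = 1.5
) -> np.ndarray:
    """Add an equal-intensity false-positive stain ``offset_px`` cells away.

    The stain is a Gaussian blob added at argmax+offset and rescaled so the
    cell at its center exactly equals the map's absolute maximum, giving two
    exactly-tied global maxima (for offsets much larger than ``sigma``).
    A zero offset therefore leaves the map unchanged.
    """
    hm = np.asarray(hm, dtype=float)
    h, w = hm.shape
    r0, c0 = np.unravel_index(int(hm.argmax()), hm.shape)
    dc, dr = int(offset_px[0]), int(offset_px[1])
    rs, cs = r0 + dr, c0 + dc
    if not (0 <= rs < h and 0 <= cs < w):
        raise ValueError(f"stain position ({rs}, {cs}) outside the {h}x{w} grid")
    m = hm[r0, c0]
    cc, rr = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    d2 = (cc - cs) ** 2 + (rr - rs) ** 2
    blob = np.exp(-d2 / (2.0 * sigma**2))
    blob[d2 > (4.0 * sigma) ** 2] = 0.0  # finite support: keep the original peak untouched
    scale = m - hm[rs, cs]
    return hm + scale * blob


def draw_augment_params(cfg: AugmentConfig, rng: np.random.Generator):
    """Draw one augmentation parameter set: uniform scale/translation
    magnitudes/rotation on the configured ranges, random translation signs,
    Bernoulli flip.  Returns (scale, (tu_frac, tv_frac), rotation_deg, flip)."""
    scale = float(rng.uniform(*cfg.scale_range))
    t_lo, t_hi = cfg.translate_frac_range
    tu = float(rng.uniform(t_lo, t_hi)) * (1.0 if rng.random() < 0.5 else -1.0)
    tv = float(rng.uniform(t_lo, t_hi)) * (1.0 if rng.random() < 0.5 else -1.0)
    rot = float(rng.uniform(*cfg.rotation_range_deg))
    do_flip = bool(rng.random() < cfg.hflip_prob)
    return scale, (tu, tv), rot, do_flip


def augment(
    img: AnnotatedImage,
    cfg: AugmentConfig,
    rng: np.random.Generator,
    schema: LandmarkSchema = DEFAULT_SCHEMA,
) -> AnnotatedImage:
    """One random affine (scale, translation, rotation) + optional h-flip.

    Pixels are warped bilinearly; landmark coordinates are transformed
    analytically with the same matrix (never resampled).  Landmarks leaving
    the frame are marked not-visible.  A horizontal flip additionally
    permutes landmark ids by the schema's flip_map.
    """
    h, w = img.pixels.shape
    scale, (tfu, tfv), rot, do_flip = draw_augment_params(cfg, rng)
    tu, tv = tfu * w, tfv * h
    m = _pose_affine((h, w), rot, scale, (tu, tv))
    coords = _apply_affine(m, img.landmarks.coords)
    tform = sktf.AffineTransform(matrix=np.linalg.inv(m))
    pixels = sktf.warp(img.pixels, tform, order=1, mode="edge", preserve_range=True)

    if do_flip:
        pixels = pixels[:, ::-1].copy()
        coords = coords.copy()
        coords[:, 0] = (w - 1) - coords[:, 0]
        perm = schema.flip_permutation
        coords = coords[perm]
        vis = img.landmarks.visibility[perm].copy()
    else:
        vis = img.landmarks.visibility.copy()

    inside = (
        (coords[:, 0] >= 0) & (coords[:, 0] <= w - 1)
        & (coords[:, 1] >= 0) & (coords[:, 1] <= h - 1)
    )
    vis &= inside
    safe = coords.copy()
    safe[~vis] = np.clip(safe[~vis], 0, [w - 1, h - 1])
    return AnnotatedImage(pixels, LandmarkSet17(safe, vis), source_id=img.source_id)
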