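"""17-landmark facial schema and conversion from 68-point annotations.

The package works on a reduced set of 17 named landmarks focused on the
pupil region: the two pupil centers, the nose tip, the two mouth
extremities, and 12 points on the eyebrows and eye contours.  Coordinates
are 0-based ``(u, v) = (column, row)`` pairs with pixel centers at integer
positions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LandmarkSchema",
    "LandmarkSet17",
    "AnnotatedImage",
    "DEFAULT_SCHEMA",
    "IBUG_INDEX_TABLE",
    "derive_17",
]

#: Landmark identifiers in canonical order.  The five "well defined" points
#: come first, then the brow triplets, then the eye-contour triplets.
LANDMARK_IDS = (
    "LPc",  # left pupil center
    "RPc",  # right pupil center
    "NT",   # nose tip
    "LMe",  # left mouth extremity
    "RMe",  # right mouth extremity
    "LBo",  # left brow outer end
    "LBm",  # left brow mid
    "LBi",  # left brow inner end
    "RBi",  # right brow inner end
    "RBm",  # right brow mid
    "RBo",  # right brow outer end
    "LEo",  # left eye outer corner
    "LEt",  # left eye upper-lid mid point
    "LEi",  # left eye inner corner
    "REi",  # right eye inner corner
    "REt",  # right eye upper-lid mid point
    "REo",  # right eye outer corner
)

LANDMARK_NAMES = {
    "LPc": "left_pupil_center",
    "RPc": "right_pupil_center",
    "NT": "nose_tip",
    "LMe": "left_mouth_extremity",
    "RMe": "right_mouth_extremity",
    "LBo": "left_brow_outer",
    "LBm": "left_brow_mid",
    "LBi": "left_brow_inner",
    "RBi": "right_brow_inner",
    "RBm": "right_brow_mid",
    "RBo": "right_brow_outer",
    "LEo": "left_eye_outer_corner",
    "LEt": "left_eye_upper_mid",
    "LEi": "left_eye_inner_corner",
    "REi": "right_eye_inner_corner",
    "REt": "right_eye_upper_mid",
    "REo": "right_eye_outer_corner",
}

_FLIP_PAIRS = (
    ("LPc", "RPc"),
    ("LMe", "RMe"),
    ("LBo", "RBo"),
    ("LBm", "RBm"),
    ("LBi", "RBi"),
    ("LEo", "REo"),
    ("LEt", "REt"),
    ("LEi", "REi"),
)

#: iBUG-68 source indices (0-based) for each schema landmark.  Pupil centers
#: are centroids of the six eye-contour points; everything else is a single
#: point pick.  This table approximates the manual enhancement of standard
#: 68-point annotations with pupil/nose/mouth points; it is configurable.
IBUG_INDEX_TABLE: dict[str, tuple[int, ...]] = {
    "LPc": (36, 37, 38, 39, 40, 41),
    "RPc": (42, 43, 44, 45, 46, 47),
    "NT": (30,),
    "LMe": (48,),
    "RMe": (54,),
    "LBo": (17,),
    "LBm": (19,),
    "LBi": (21,),
    "RBi": (22,),
    "RBm": (24,),
    "RBo": (26,),
    "LEo": (36,),
    "LEt": (37,),
    "LEi": (39,),
    "REi": (42,),
    "REt": (44,),
    "REo": (45,),
}

_EYE_BROW_GROUP = frozenset(
    ("LBo", "LBm", "LBi", "RBi", "RBm", "RBo",
     "LEo", "LEt", "LEi", "REi", "REt", "REo", "LPc", "RPc")
)


@dataclass(frozen=True)
class LandmarkSchema:
    """Named landmark set with mirroring and central-landmark designation.

    Parameters
    ----------
    landmark_ids : ordered identifiers (length 17).
    names : human-readable label per id.
    flip_map : involutive id -> id mapping under horizontal mirroring.
    global_set : ids of the fixed "central landmarks" N_g used by the
        spatial model's global neighborhood.
    """

    landmark_ids: tuple[str, ...] = LANDMARK_IDS
    names: dict[str, str] = field(default_factory=lambda: dict(LANDMARK_NAMES))
    flip_map: dict[str, str] = field(default_factory=lambda: _build_flip_map())
    global_set: frozenset[str] = frozenset(("LPc", "RPc", "NT", "LMe", "RMe"))

    def __post_init__(self) -> None:
        if len(self.landmark_ids) != 17:
            raise ValueError(f"schema needs exactly 17 ids, got {len(self.landmark_ids)}")
        ids = set(self.landmark_ids)
        for a, b in self.flip_map.items():
            if self.flip_map.get(b) != a:
                raise ValueError(f"flip_map is not involutive at {a!r}<->{b!r}")
            if a not in ids or b not in ids:
                raise ValueError(f"flip_map references unknown id {a!r} or {b!r}")
        if not set(self.global_set) <= ids:
            raise ValueError("global_set must be a subset of landmark_ids")
        n_eye_brow = sum(1 for i in self.landmark_ids if i in _EYE_BROW_GROUP)
        if n_eye_brow < 12:
            raise ValueError("schema must keep >=12 eyebrow/eye landmarks")

    def index(self, lid: str) -> int:
        return self.landmark_ids.index(lid)

    @property
    def flip_permutation(self) -> np.ndarray:
        """Index permutation implementing flip_map on coordinate arrays."""
        return np.array(
            [self.landmark_ids.index(self.flip_map.get(i, i)) for i in self.landmark_ids]
        )

    def hash(self) -> str:
        """Stable hash used to pair checkpoints with prior banks."""
        payload = json.dumps(
            {
                "ids": list(self.landmark_ids),
                "flip": sorted(self.flip_map.items()),
                "global": sorted(self.global_set),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _build_flip_map() -> dict[str, str]:
    fm: dict[str, str] = {}
    for a, b in _FLIP_PAIRS:
        fm[a] = b
        fm[b] = a
    fm["NT"] = "NT"
    return fm


DEFAULT_SCHEMA = LandmarkSchema()


@dataclass
class LandmarkSet17:
    """17 landmark coordinates (u, v) in image-pixel units plus visibility."""

    coords: np.ndarray  # (17, 2) float, columns (u, v)
    visibility: np.ndarray = None  # (17,) bool

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (17, 2):
            raise ValueError(f"coords must be (17, 2), got {self.coords.shape}")
        if self.visibility is None:
            self.visibility = np.ones(17, dtype=bool)
        self.visibility = np.asarray(self.visibility, dtype=bool)
        if self.visibility.shape != (17,):
            raise ValueError("visibility must have shape (17,)")
        if not np.all(np.isfinite(self.coords[self.visibility])):
            raise ValueError("visible landmark coordinates must be finite")

    def interpupillary_distance(self, schema: LandmarkSchema = DEFAULT_SCHEMA) -> float:
        il, ir = schema.index("LPc"), schema.index("RPc")
        return float(np.linalg.norm(self.coords[il] - self.coords[ir]))

    def copy(self) -> "LandmarkSet17":
        return LandmarkSet17(self.coords.copy(), self.visibility.copy())


@dataclass
class AnnotatedImage:
    """A grayscale image with its 17-landmark annotation."""

    pixels: np.ndarray  # (H, W) float
    landmarks: LandmarkSet17
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale grid")
        h, w = self.pixels.shape
        vis = self.landmarks.visibility
        c = self.landmarks.coords
        inside = (c[:, 0] >= 0) & (c[:, 0] <= w - 1) & (c[:, 1] >= 0) & (c[:, 1] <= h - 1)
        if not np.all(inside[vis]):
            raise ValueError("all visible landmarks must lie inside the pixel grid")


def derive_17(
    points68: np.ndarray,
    schema: LandmarkSchema = DEFAULT_SCHEMA,
    index_table: dict[str, tuple[int, ...]] | None = None,
) -> LandmarkSet17:
    """Reduce an iBUG 68-point annotation to the 17-landmark schema.

    Pupil centers are the centroids of the six eye-contour points; the nose
    tip and mouth extremities come from their iBUG indices; the 12 brow/eye
    points are fixed index picks.  Centroids and index picks commute with
    affine maps, so the reduction is affine-equivariant.
    """
    pts = np.asarray(points68, dtype=float)
    if pts.shape != (68, 2):
        raise ValueError(f"expected 68 points of shape (68, 2), got {pts.shape}")
    table = IBUG_INDEX_TABLE if index_table is None else index_table
    coords = np.empty((17, 2))
    for k, lid in enumerate(schema.landmark_ids):
        idx = table[lid]
        coords[k] = pts[list(idx)].mean(axis=0)
    return LandmarkSet17(coords)
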