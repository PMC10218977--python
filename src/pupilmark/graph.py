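"""Per-landmark neighborhood graphs for the spatial model.

Each landmark i gets a star graph over N_u(i) = N_i(r) ∪ N_g: the radius-r
local neighborhood on the mean shape plus a fixed set of global "central"
landmarks.  Cliques are restricted to the bivertex pairs (i, j), j ∈ N_u(i);
there are no neighbor-neighbor edges.  Distances are measured on the mean
shape normalized by interpupillary distance, so the default radius is a
fraction of that distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schema import DEFAULT_SCHEMA, LandmarkSchema

__all__ = ["NeighborhoodGraph", "local_neighborhood", "build_graph", "default_graph"]

DEFAULT_RADIUS = 0.25  # in units of interpupillary distance


@dataclass(frozen=True)
class NeighborhoodGraph:
    ids: tuple[str, ...]
    radius: float
    local_sets: dict
    global_set: frozenset
    union_sets: dict
    edges: tuple  # directed (i, j) pairs, deterministically sorted

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, i: str) -> frozenset:
        return self.union_sets[i]


def local_neighborhood(coords: np.ndarray, i: int, r: float) -> set[int]:
    """Indices within Euclidean distance r of point i (excluding i itself)."""
    if r <= 0:
        raise ValueError("radius must be > 0")
    coords = np.asarray(coords, dtype=float)
    d = np.linalg.norm(coords - coords[i], axis=1)
    return {int(k) for k in np.nonzero(d <= r)[0] if k != i}


def build_graph(
    ids,
    mean_shape: np.ndarray,
    r: float,
    global_set,
) -> NeighborhoodGraph:
    """Assemble union neighborhoods and the directed edge list.

    ``mean_shape`` coordinates are used as given (normalize beforehand if the
    radius is in normalized units).  Raises if some landmark ends up with an
    empty neighborhood.
    """
    ids = tuple(ids)
    coords = np.asarray(mean_shape, dtype=float)
    if coords.shape[0] != len(ids):
        raise ValueError("mean_shape and ids disagree in length")
    global_set = frozenset(global_set)
    if not global_set <= set(ids):
        raise ValueError("global_set must be a subset of ids")
    pos = {lid: k for k, lid in enumerate(ids)}
    local_sets = {}
    union_sets = {}
    edges = []
    for lid in ids:
        loc = frozenset(ids[k] for k in local_neighborhood(coords, pos[lid], r))
        union = (loc | global_set) - {lid}
        if not union:
            raise ValueError(
                f"landmark {lid!r} has an empty neighborhood; increase the radius r"
            )
        local_sets[lid] = loc
        union_sets[lid] = union
        edges += [(lid, j) for j in sorted(union)]
    return NeighborhoodGraph(
        ids=ids,
        radius=float(r),
        local_sets=local_sets,
        global_set=global_set,
        union_sets=union_sets,
        edges=tuple(sorted(edges)),
    )


def default_graph(
    schema: LandmarkSchema = DEFAULT_SCHEMA,
    mean_shape: np.ndarray | None = None,
    r: float = DEFAULT_RADIUS,
    global_set=None,
) -> NeighborhoodGraph:
    """Graph on the canonical mean shape with interpupillary normalization."""
    from .synthetic import CANONICAL_SHAPE

    shape = CANONICAL_SHAPE if mean_shape is None else np.asarray(mean_shape, dtype=float)
    ipd = np.linalg.norm(shape[schema.index("LPc")] - shape[schema.index("RPc")])
    if ipd <= 0:
        raise ValueError("mean shape has zero interpupillary distance")
    return build_graph(
        schema.landmark_ids,
        shape / ipd,
        r,
        schema.global_set if global_set is None else global_set,
    )
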