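"""MRF-like spatial-consistency filter over per-landmark star graphs.

For every landmark i the filter combines, in log-space, the Softplus-lifted
unary map with one message per neighbor j ∈ N_u(i).  A message is the
full-range correlation of the Softplus-lifted neighbor map with the
Softplus-lifted conditional-prior kernel p_{i|j} (pooled 2x down to heatmap
resolution), plus a per-edge background bias and a stabilizer ε, passed
through a logarithm:

    p̂_i = exp( ln Softplus(p_i + ε)
               + Σ_j ln[ Softplus(p_{i|j}) ⊛ Softplus(p_j) + b_{j→i} + ε ] )

The kernel is anchored so that its center cell sits on the candidate
position (the translate-to-center convention of the prior learning); prior
values outside the stored grid equal the kernel's own floor value.  All
edges are convolved in a single batched call grouped by edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, prior_message
from .graph import NeighborhoodGraph
from .heatmaps import HeatmapStack
from .priors import PriorBank

__all__ = [
    "SpatialModelParams",
    "EdgeSet",
    "build_edge_set",
    "filter_heatmaps",
    "filter_log_tensor",
    "filter_oracle",
]

ORACLE_MAX_CELLS = 16


def _np_softplus(x, beta: float = 1.0):
    return np.logaddexp(0.0, beta * np.asarray(x, dtype=float)) / beta


@dataclass
class SpatialModelParams:
    """Stabilizer, Softplus sharpness and per-edge background bias.

    ``bias`` is the raw per-edge parameter (learnable during joint
    training); it is passed through Softplus before use so the log argument
    stays strictly positive.
    """

    eps: float = 1e-6
    softplus_beta: float = 10.0
    bias_init: float = 1e-3

    def __post_init__(self) -> None:
        if self.eps <= 0 or self.softplus_beta <= 0:
            raise ValueError("eps and softplus_beta must be > 0")


@dataclass
class EdgeSet:
    """Precomputed per-edge kernels/pads/biases for the batched filter."""

    edges: tuple                 # directed (i, j) in deterministic order
    target_idx: np.ndarray       # index of i per edge
    source_idx: np.ndarray       # index of j per edge
    kernels: np.ndarray          # (E, H, W) Softplus-lifted pooled priors
    pad_vals: np.ndarray         # (E,) Softplus-lifted per-kernel floor
    anchor: tuple[int, int]
    bias: Tensor                 # (E,) raw biases (Softplus-ed before use)


def _pool2(grid: np.ndarray) -> np.ndarray:
    """Mean-pool a (2H, 2W) prior grid down to (H, W)."""
    h2, w2 = grid.shape
    return grid.reshape(h2 // 2, 2, w2 // 2, 2).mean(axis=(1, 3))


def build_edge_set(
    bank: PriorBank,
    graph: NeighborhoodGraph,
    params: SpatialModelParams,
    heatmap_shape: tuple[int, int],
    trainable_bias: bool = False,
) -> EdgeSet:
    """Pool each prior to heatmap resolution and Softplus-lift it."""
    h, w = heatmap_shape
    if bank.grid_shape != (2 * h, 2 * w):
        raise ValueError(
            f"prior bank grids {bank.grid_shape} do not match twice the "
            f"heatmap shape {heatmap_shape}"
        )
    pos = {lid: k for k, lid in enumerate(graph.ids)}
    kernels = []
    pads = []
    for e in graph.edges:
        if e not in bank:
            raise ValueError(f"prior bank has no entry for edge {e}")
        pooled = _pool2(bank[e].grid)
        kernels.append(_np_softplus(pooled, params.softplus_beta))
        pads.append(_np_softplus(pooled.min(), params.softplus_beta))
    bias = Tensor(
        np.full(len(graph.edges), params.bias_init, dtype=float),
        requires_grad=trainable_bias,
    )
    return EdgeSet(
        edges=graph.edges,
        target_idx=np.array([pos[i] for i, _ in graph.edges]),
        source_idx=np.array([pos[j] for _, j in graph.edges]),
        kernels=np.stack(kernels),
        pad_vals=np.asarray(pads),
        anchor=(h // 2, w // 2),
        bias=bias,
    )


def filter_log_tensor(hm: Tensor, edge_set: EdgeSet, params: SpatialModelParams) -> Tensor:
    """ln p̂ for a batch: hm is (N, L, H, W); differentiable in hm and bias."""
    n, n_lm, h, w = hm.data.shape
    beta = params.softplus_beta
    sp_all = hm.softplus(beta)                       # Softplus(p_j)
    me = (hm + params.eps).softplus(beta).log()      # ln Softplus(p_i + ε)

    e = len(edge_set.edges)
    src = sp_all[:, edge_set.source_idx]             # (N, E, H, W)
    flat = src.reshape(n * e, h, w)
    kern = np.tile(edge_set.kernels, (n, 1, 1))
    pads = np.tile(edge_set.pad_vals, n)
    conv = prior_message(flat, kern, pads, edge_set.anchor).reshape(n, e, h, w)
    bias_sp = edge_set.bias.softplus(beta)           # keeps log argument > 0
    arg = conv + bias_sp.reshape(1, e, 1, 1) + params.eps
    if np.any(arg.data <= 0.0):
        raise ArithmeticError(
            "non-positive log argument in the spatial filter; the Softplus "
            "bias floor should make this impossible"
        )
    msg = arg.log()                                  # (N, E, H, W)
    return me + _sum_by_target(msg, edge_set.target_idx, n_lm)


def _sum_by_target(msg: Tensor, target_idx: np.ndarray, n_lm: int) -> Tensor:
    """Sum per-edge messages into their target landmark slot."""
    m = np.zeros((n_lm, len(target_idx)))
    m[target_idx, np.arange(len(target_idx))] = 1.0
    out = Tensor(
        np.einsum("le,nehw->nlhw", m, msg.data, optimize=True),
        msg.requires_grad,
        (msg,),
    )
    out._backward = lambda g: msg._accum(np.einsum("le,nlhw->nehw", m, g, optimize=True))
    return out


def filter_heatmaps(
    hm: HeatmapStack,
    bank: PriorBank,
    graph: NeighborhoodGraph,
    params: SpatialModelParams | None = None,
    edge_set: EdgeSet | None = None,
) -> HeatmapStack:
    """Run the spatial filter on one heatmap stack; returns p̂ (all > 0)."""
    params = params or SpatialModelParams()
    if np.any(hm.maps < 0):
        raise ValueError("filter_heatmaps expects non-negative unary maps")
    if edge_set is None:
        edge_set = build_edge_set(bank, graph, params, hm.grid_shape)
    log_phat = filter_log_tensor(Tensor(hm.maps[None]), edge_set, params)
    phat = np.exp(log_phat.data[0])
    if not np.all(np.isfinite(phat)) or np.any(phat <= 0):
        raise ArithmeticError("spatial filter produced non-finite or non-positive output")
    return HeatmapStack(phat, hm.stride)


def filter_oracle(
    hm: HeatmapStack,
    bank: PriorBank,
    graph: NeighborhoodGraph,
    params: SpatialModelParams | None = None,
) -> HeatmapStack:
    """Reference evaluation of the filter by explicit nested loops.

    Numerically identical contract to :func:`filter_heatmaps`, written
    without convolution primitives or batching; refuses grids larger than
    16x16 to guard against accidental use on real-size inputs.
    """
    import math

    params = params or SpatialModelParams()
    n_lm, h, w = hm.maps.shape
    if h > ORACLE_MAX_CELLS or w > ORACLE_MAX_CELLS:
        raise ValueError(f"oracle refuses grids larger than {ORACLE_MAX_CELLS} cells")
    beta = params.softplus_beta

    def sp(x):
        return math.log1p(math.exp(beta * x)) / beta if beta * x < 30 else x

    pos = {lid: k for k, lid in enumerate(graph.ids)}
    a0, b0 = h // 2, w // 2
    bias_eff = sp(params.bias_init)
    out = np.zeros_like(hm.maps)
    for lid in graph.ids:
        i = pos[lid]
        log_total = np.empty((h, w))
        for r in range(h):
            for c in range(w):
                log_total[r, c] = math.log(sp(hm.maps[i, r, c] + params.eps))
        for j_lid in sorted(graph.union_sets[lid]):
            j = pos[j_lid]
            grid2 = bank[(lid, j_lid)].grid
            pooled = np.empty((h, w))
            for rr in range(h):
                for cc in range(w):
                    pooled[rr, cc] = (
                        grid2[2 * rr, 2 * cc] + grid2[2 * rr + 1, 2 * cc]
                        + grid2[2 * rr, 2 * cc + 1] + grid2[2 * rr + 1, 2 * cc + 1]
                    ) / 4.0
            floor = sp(pooled.min())
            for r in range(h):
                for c in range(w):
                    conv = 0.0
                    for rr in range(h):
                        for cc in range(w):
                            kr, kc = a0 + r - rr, b0 + c - cc
                            kval = sp(pooled[kr, kc]) if 0 <= kr < h and 0 <= kc < w else floor
                            conv += kval * sp(hm.maps[j, rr, cc])
                    log_total[r, c] += math.log(conv + bias_eff + params.eps)
        for r in range(h):
            for c in range(w):
                out[i, r, c] = math.exp(log_total[r, c])
    return HeatmapStack(out, hm.stride)
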