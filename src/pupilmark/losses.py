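"""Adaptive Wing loss and the heterogeneous combined training loss.

The Adaptive Wing (AWing) loss compares two heatmap pixel values y (ground
truth, in [0, 1]) and ŷ.  It is nonlinear below a threshold θ and linear
above it, with the exponent α − y adapting the curvature to the pixel's
foreground/background status:

    AWing(y, ŷ) = ω ln(1 + (|y−ŷ|/ε)^(α−y))        if |y−ŷ| < θ
                  A |y−ŷ| − C                       otherwise

with A and C fixed by requiring continuity and a continuous first
derivative at |y−ŷ| = θ:

    A = ω (α−y) (θ/ε)^(α−y−1) / ( ε (1 + (θ/ε)^(α−y)) )
    C = θ A − ω ln(1 + (θ/ε)^(α−y))

The combined loss mixes the mean AWing over heatmap pixels with the squared
L2 error of the spatial model's coordinates, weighted by β (default 0.1);
coordinates are in heatmap-pixel units and invisible landmarks are masked
out of both terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor

__all__ = [
    "AWingParams",
    "CombinedLossConfig",
    "awing",
    "awing_heatmap",
    "combined_loss",
    "awing_tensor",
    "masked_combined_loss_tensor",
]


@dataclass(frozen=True)
class AWingParams:
    alpha: float = 2.1
    omega: float = 14.0
    epsilon: float = 1.0
    theta: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha <= 1:
            raise ValueError("alpha must exceed 1 so alpha - y > 1 for y in [0, 1]")
        if min(self.omega, self.epsilon, self.theta) <= 0:
            raise ValueError("omega, epsilon and theta must be > 0")


@dataclass(frozen=True)
class CombinedLossConfig:
    beta: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")


def _linear_coeffs(y: np.ndarray, p: AWingParams) -> tuple[np.ndarray, np.ndarray]:
    """A and C of the linear branch, as functions of the GT pixel value."""
    e = p.alpha - y
    te = p.theta / p.epsilon
    a = p.omega * e * te ** (e - 1.0) / (p.epsilon * (1.0 + te**e))
    c = p.theta * a - p.omega * np.log1p(te**e)
    return a, c


def awing(y, yhat, params: AWingParams | None = None) -> np.ndarray:
    """Elementwise AWing loss between GT values y (in [0, 1]) and ŷ."""
    p = params or AWingParams()
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    d = np.abs(y - yhat)
    a, c = _linear_coeffs(y, p)
    nonlinear = p.omega * np.log1p((d / p.epsilon) ** (p.alpha - y))
    linear = a * d - c
    out = np.where(d < p.theta, nonlinear, linear)
    return out if out.shape else float(out)


def awing_heatmap(hm1, hm2, params: AWingParams | None = None) -> float:
    """Mean of the pixelwise AWing loss over two same-shape heatmaps."""
    hm1 = np.asarray(hm1, dtype=float)
    hm2 = np.asarray(hm2, dtype=float)
    if hm1.shape != hm2.shape:
        raise ValueError(f"heatmap shapes differ: {hm1.shape} vs {hm2.shape}")
    return float(np.mean(awing(hm1, hm2, params)))


def combined_loss(
    hm_gt,
    hm_ld,
    x_gt,
    x_sm,
    cfg: CombinedLossConfig | None = None,
    awing_params: AWingParams | None = None,
    visibility=None,
) -> float:
    """(1−β)·AWing(hm, hm_ld) + β·|x − x_sm|², averaged over visible landmarks.

    ``hm_gt``/``hm_ld`` are (L, H, W) stacks; ``x_gt``/``x_sm`` are (L, 2)
    coordinates in heatmap-pixel units.
    """
    cfg = cfg or CombinedLossConfig()
    hm_gt = np.asarray(hm_gt, dtype=float)
    hm_ld = np.asarray(hm_ld, dtype=float)
    x_gt = np.asarray(x_gt, dtype=float)
    x_sm = np.asarray(x_sm, dtype=float)
    n_lm = hm_gt.shape[0]
    vis = np.ones(n_lm, dtype=bool) if visibility is None else np.asarray(visibility, bool)
    if not vis.any():
        return 0.0
    total = 0.0
    for k in np.nonzero(vis)[0]:
        aw = awing_heatmap(hm_gt[k], hm_ld[k], awing_params)
        sq = float(np.sum((x_gt[k] - x_sm[k]) ** 2))
        total += (1.0 - cfg.beta) * aw + cfg.beta * sq
    return total / int(vis.sum())


# -- differentiable versions used by the training loop -------------------

def awing_tensor(y: np.ndarray, yhat: Tensor, params: AWingParams | None = None) -> Tensor:
    """AWing loss elementwise on a Tensor prediction (y is constant)."""
    p = params or AWingParams()
    y = np.asarray(y, dtype=yhat.data.dtype)
    expo = p.alpha - y
    a, c = _linear_coeffs(y, p)
    d = (yhat - y).abs()
    nonlinear = ((d * (1.0 / p.epsilon)).pow_const(expo) + 1.0).log() * p.omega
    linear = d * a - c
    mask = (d.data < p.theta).astype(yhat.data.dtype)
    return nonlinear * mask + linear * (1.0 - mask)


def masked_combined_loss_tensor(
    hm_gt: np.ndarray,
    hm_ld: Tensor,
    x_gt: np.ndarray,
    x_sm_u: Tensor | None,
    x_sm_v: Tensor | None,
    visibility: np.ndarray,
    cfg: CombinedLossConfig | None = None,
    awing_params: AWingParams | None = None,
) -> Tensor:
    """Batch loss: (N, L, H, W) heatmaps, (N, L) visibility, (N, L, 2) coords.

    When the spatial-model coordinates are None (detector-only training) the
    coordinate term is dropped, which is the β = 0 limit.
    """
    cfg = cfg or CombinedLossConfig()
    n, n_lm = visibility.shape
    vis = visibility.astype(hm_ld.data.dtype)
    n_vis = max(vis.sum(), 1.0)

    aw = awing_tensor(hm_gt, hm_ld, awing_params)          # (N, L, H, W)
    aw_per_lm = aw.mean(axis=(2, 3))                        # (N, L)
    aw_term = (aw_per_lm * vis).sum() * (1.0 / n_vis)

    if x_sm_u is None or cfg.beta == 0.0:
        return aw_term
    du = x_sm_u - x_gt[..., 0]
    dv = x_sm_v - x_gt[..., 1]
    sq = du * du + dv * dv                                  # (N, L)
    coord_term = (sq * vis).sum() * (1.0 / n_vis)
    return aw_term * (1.0 - cfg.beta) + coord_term * cfg.beta
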