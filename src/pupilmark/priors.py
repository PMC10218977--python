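"""Pairwise conditional priors p_{i|j} learned by translate-to-center + GMM.

For every directed edge (i, j) of the neighborhood graph, the position of
landmark i is translated by the amount that would bring landmark j to the
frame center; the resulting point cloud over the training population is fit
with a full-covariance Gaussian mixture whose order is chosen by AIC/BIC,
then rasterized onto a grid at twice the heatmap resolution whose center
cell is the conditioning landmark's position.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import multivariate_normal
from sklearn.mixture import GaussianMixture

from .graph import NeighborhoodGraph
from .heatmaps import image_to_grid
from .schema import DEFAULT_SCHEMA, LandmarkSet17

__all__ = [
    "ConditionalPrior",
    "PriorBank",
    "PriorConfig",
    "center_translate",
    "fit_pair_gmm",
    "rasterize_prior",
    "learn_priors",
    "save_bank",
    "load_bank",
]


def frame_center(frame_shape: tuple[int, int]) -> np.ndarray:
    """(u, v) center of an (H, W) frame under the 0-based convention."""
    h, w = frame_shape
    return np.array([(w - 1) / 2.0, (h - 1) / 2.0])


def center_translate(x_i, x_condi, frame_shape: tuple[int, int]) -> np.ndarray:
    """Translate x_i by the shift that would move x_condi to the frame center."""
    t = frame_center(frame_shape) - np.asarray(x_condi, dtype=float)
    return np.asarray(x_i, dtype=float) + t


@dataclass
class ConditionalPrior:
    """Rasterized conditional density plus its mixture parameters."""

    pair: tuple[str, str]  # (i, conditioning j)
    weights: np.ndarray
    means: np.ndarray       # (order, 2) in grid (u, v) units
    covariances: np.ndarray  # (order, 2, 2)
    order: int
    grid: np.ndarray         # (2*H_hm, 2*W_hm) density, floored at eps_raster


@dataclass
class PriorBank:
    """All conditional priors required by a neighborhood graph."""

    priors: dict
    grid_shape: tuple[int, int]
    schema_hash: str = ""

    def __getitem__(self, pair) -> ConditionalPrior:
        return self.priors[tuple(pair)]

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self.priors

    def __len__(self) -> int:
        return len(self.priors)


@dataclass
class PriorConfig:
    order_range: tuple[int, int] = (1, 12)
    n_init: int = 3
    seed: int = 0
    eps_raster: float = 1e-9
    reg_covar: float = 1e-6
    max_missing_frac: float = 0.2


def fit_pair_gmm(
    samples: np.ndarray,
    order_range: tuple[int, int] = (1, 12),
    seed: int = 0,
    n_init: int = 3,
    reg_covar: float = 1e-6,
) -> tuple[GaussianMixture, int]:
    """Fit full-covariance GMMs over a range of orders and select one.

    For every candidate order the mixture is fit with fixed-seed k-means
    initialization, best of ``n_init`` restarts by likelihood.  The selected
    order is the integer mean of the AIC-minimizing and BIC-minimizing
    orders, with half-way ties resolved toward the smaller order.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("samples must be an (n, 2) array of offsets")
    k_lo, k_hi = order_range
    if x.shape[0] < 10 * k_hi:
        raise ValueError(
            f"need at least {10 * k_hi} samples for order_range up to {k_hi}, "
            f"got {x.shape[0]}"
        )
    cov = np.cov(x.T)
    if np.linalg.matrix_rank(cov, tol=1e-10) < 2:
        warnings.warn(
            "rank-deficient offset samples; increasing covariance regularization",
            stacklevel=2,
        )
        reg_covar = max(reg_covar, 1e-4)
    fits: dict[int, GaussianMixture] = {}
    aic = {}
    bic = {}
    for k in range(k_lo, k_hi + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            init_params="kmeans",
            reg_covar=reg_covar,
            random_state=seed,
        )
        gm.fit(x)
        fits[k] = gm
        aic[k] = gm.aic(x)
        bic[k] = gm.bic(x)
    k_aic = min(aic, key=aic.get)
    k_bic = min(bic, key=bic.get)
    selected = (k_aic + k_bic) // 2
    selected = max(k_lo, min(k_hi, selected))
    return fits[selected], selected


def rasterize_prior(
    gmm,
    grid_shape: tuple[int, int],
    eps_raster: float = 1e-9,
) -> np.ndarray:
    """Evaluate the mixture density at every cell center of an (H, W) grid.

    Accepts a fitted GaussianMixture or a (weights, means, covariances)
    triple; means/covariances are in grid (u, v) units.  The result is
    floored at ``eps_raster`` so downstream logs never see exact zeros.
    """
    if hasattr(gmm, "weights_"):
        weights, means, covs = gmm.weights_, gmm.means_, gmm.covariances_
    else:
        weights, means, covs = gmm
    h, w = grid_shape
    uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    pts = np.column_stack([uu.ravel(), vv.ravel()])
    dens = np.zeros(h * w)
    for wk, mk, ck in zip(weights, means, covs):
        dens += wk * multivariate_normal(mean=mk, cov=ck).pdf(pts)
    return np.maximum(dens.reshape(h, w), eps_raster)


def translated_offsets(
    annotations,
    pair: tuple[int, int],
    heatmap_shape: tuple[int, int],
    stride: float = 4.0,
) -> np.ndarray:
    """Translate-to-center sample list for one directed pair of landmark
    indices (i, j), in prior-grid units (twice the heatmap resolution)."""
    i, j = pair
    h_hm, w_hm = heatmap_shape
    stride2 = stride / 2.0
    center = frame_center((2 * h_hm, 2 * w_hm))
    out = []
    for ann in annotations:
        coords = ann.coords if isinstance(ann, LandmarkSet17) else np.asarray(ann, float)
        g = image_to_grid(coords, stride2)
        out.append(g[i] + (center - g[j]))
    return np.asarray(out)


def learn_priors(
    annotations,
    graph: NeighborhoodGraph,
    heatmap_shape: tuple[int, int],
    stride: float = 4.0,
    cfg: PriorConfig | None = None,
    schema=DEFAULT_SCHEMA,
) -> PriorBank:
    """Learn the full prior bank from an annotated population.

    ``annotations`` is a sequence of LandmarkSet17 (or (17, 2) arrays).
    Coordinates are scaled to the prior grid at twice the heatmap
    resolution; for each directed edge the translated offsets are collected,
    a GMM fit and rasterized.  Pairs missing on more than the configured
    fraction of images raise an error naming the pair.
    """
    cfg = cfg or PriorConfig()
    h_hm, w_hm = heatmap_shape
    grid_shape = (2 * h_hm, 2 * w_hm)
    stride2 = stride / 2.0
    center = frame_center(grid_shape)
    pos = {lid: k for k, lid in enumerate(graph.ids)}

    coords = []
    vis = []
    for ann in annotations:
        if isinstance(ann, LandmarkSet17):
            coords.append(image_to_grid(ann.coords, stride2))
            vis.append(ann.visibility)
        else:
            coords.append(image_to_grid(np.asarray(ann, dtype=float), stride2))
            vis.append(np.ones(len(coords[-1]), dtype=bool))
    coords = np.asarray(coords)  # (n_img, n_lm, 2) in 2x-grid units
    vis = np.asarray(vis)
    n_img = len(coords)

    priors: dict[tuple[str, str], ConditionalPrior] = {}
    for i, j in graph.edges:
        ii, jj = pos[i], pos[j]
        ok = vis[:, ii] & vis[:, jj]
        if (n_img - ok.sum()) > cfg.max_missing_frac * n_img:
            raise ValueError(
                f"pair ({i}, {j}) is missing on more than "
                f"{cfg.max_missing_frac:.0%} of images"
            )
        samples = coords[ok, ii] + (center - coords[ok, jj])
        gm, order = fit_pair_gmm(
            samples,
            order_range=cfg.order_range,
            seed=cfg.seed,
            n_init=cfg.n_init,
            reg_covar=cfg.reg_covar,
        )
        grid = rasterize_prior(gm, grid_shape, eps_raster=cfg.eps_raster)
        priors[(i, j)] = ConditionalPrior(
            pair=(i, j),
            weights=gm.weights_.copy(),
            means=gm.means_.copy(),
            covariances=gm.covariances_.copy(),
            order=order,
            grid=grid,
        )
    return PriorBank(priors=priors, grid_shape=grid_shape, schema_hash=schema.hash())


def save_bank(path, bank: PriorBank) -> None:
    """One compressed array container plus a JSON index."""
    path = Path(path)
    arrays = {}
    index = {"grid_shape": list(bank.grid_shape), "schema_hash": bank.schema_hash,
             "pairs": []}
    for n, ((i, j), pr) in enumerate(sorted(bank.priors.items())):
        arrays[f"grid_{n}"] = pr.grid
        arrays[f"weights_{n}"] = pr.weights
        arrays[f"means_{n}"] = pr.means
        arrays[f"covs_{n}"] = pr.covariances
        index["pairs"].append({"i": i, "j": j, "order": pr.order, "slot": n})
    np.savez_compressed(path, **arrays)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(index))


def load_bank(path) -> PriorBank:
    path = Path(path)
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    index = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    priors = {}
    for ent in index["pairs"]:
        n = ent["slot"]
        pair = (ent["i"], ent["j"])
        priors[pair] = ConditionalPrior(
            pair=pair,
            weights=data[f"weights_{n}"],
            means=data[f"means_{n}"],
            covariances=data[f"covs_{n}"],
            order=int(ent["order"]),
            grid=data[f"grid_{n}"],
        )
    return PriorBank(
        priors=priors,
        grid_shape=tuple(index["grid_shape"]),
        schema_hash=index["schema_hash"],
    )
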