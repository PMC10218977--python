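"""Interpupillary-normalized evaluation metrics: PCKp, NME, CED.

All statistics normalize by the per-frame interpupillary distance
r_t = ||x_LPc - x_RPc|| of the ground truth.  PCKp counts a prediction as
correct when its Euclidean error is at most 10% of r_t (boundary included);
NME is reported in percent.  The "best-90%" figure is the error bound
covering the best 90% of per-landmark predictions, i.e. the 90th percentile
of the pooled normalized error distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .schema import DEFAULT_SCHEMA, LandmarkSchema, LandmarkSet17

__all__ = ["EvalResult", "pckp", "nme_stats"]


@dataclass
class EvalResult:
    pckp: dict                 # landmark id -> percentage in [0, 100]
    nme_per_frame: np.ndarray  # per-frame mean normalized error, percent
    median_nme: float          # percent
    nme_best90: float          # percent; 90th percentile of landmark errors
    ced: np.ndarray            # sorted per-landmark normalized errors, percent


def _as_arrays(sets, schema: LandmarkSchema):
    coords = np.stack(
        [s.coords if isinstance(s, LandmarkSet17) else np.asarray(s, float) for s in sets]
    )
    vis = np.stack(
        [
            s.visibility if isinstance(s, LandmarkSet17) else np.ones(coords.shape[1], bool)
            for s in sets
        ]
    )
    return coords, vis


def _pupil_distances(gt_coords, gt_vis, schema):
    il, ir = schema.index("LPc"), schema.index("RPc")
    r = np.linalg.norm(gt_coords[:, il] - gt_coords[:, ir], axis=1)
    ok = (r > 0) & gt_vis[:, il] & gt_vis[:, ir]
    if not ok.all():
        warnings.warn(
            f"excluding {int((~ok).sum())} frame(s) with zero or undefined "
            "interpupillary distance",
            stacklevel=3,
        )
    return r, ok


def pckp(preds, gts, frac: float = 0.1, schema: LandmarkSchema = DEFAULT_SCHEMA) -> dict:
    """Percentage of correct keypoints at ``frac`` of interpupillary distance.

    For landmark i: 100/N · #{t : ||x*_it − x_it|| ≤ frac·r_t} over frames
    where the landmark is visible in the ground truth.
    """
    p, _ = _as_arrays(preds, schema)
    g, gvis = _as_arrays(gts, schema)
    if len(p) == 0:
        raise ValueError("need at least one frame")
    r, ok = _pupil_distances(g, gvis, schema)
    out = {}
    err = np.linalg.norm(p - g, axis=2)  # (N, L)
    for k, lid in enumerate(schema.landmark_ids):
        use = ok & gvis[:, k]
        n = int(use.sum())
        if n == 0:
            out[lid] = float("nan")
            continue
        out[lid] = 100.0 * float((err[use, k] <= frac * r[use]).sum()) / n
    return out


def nme_stats(preds, gts, schema: LandmarkSchema = DEFAULT_SCHEMA) -> EvalResult:
    """Normalized-mean-error statistics and the cumulative error distribution.

    Per-frame NME is the mean over visible landmarks of the normalized
    point error, in percent; ``median_nme`` is its median over frames;
    ``nme_best90`` the 90th percentile of the pooled per-landmark errors.
    """
    p, _ = _as_arrays(preds, schema)
    g, gvis = _as_arrays(gts, schema)
    if len(p) == 0:
        raise ValueError("need at least one frame")
    r, ok = _pupil_distances(g, gvis, schema)
    err = 100.0 * np.linalg.norm(p - g, axis=2) / np.where(r > 0, r, np.nan)[:, None]
    err = np.where(gvis, err, np.nan)
    err = err[ok]
    per_frame = np.nanmean(err, axis=1)
    pooled = err[~np.isnan(err)]
    ced = np.sort(pooled)
    return EvalResult(
        pckp=pckp(preds, gts, schema=schema),
        nme_per_frame=per_frame,
        median_nme=float(np.median(per_frame)),
        nme_best90=float(np.percentile(pooled, 90.0)),
        ced=ced,
    )
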