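"""Joint training of the landmark detector and the spatial model.

Per batch: augment -> Gaussian pyramid -> detector forward -> (joint mode:
spatial filter -> soft-argmax) -> combined loss -> Adam step.  The spatial
model contributes through the coordinate term of the loss, produced by a
temperature-controlled soft-argmax over ln p̂ during training (hard argmax
at inference, which has no useful gradient).  The learning-rate schedule,
batch size, optimizer moments and early stopping follow the reference
protocol: base rate 1e-4, reduced to 1e-5 at epoch 25 and 1e-6 at epoch 40,
batch 16, Adam (0.9, 0.999), stop after 10 epochs without training-loss
improvement.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ._autodiff import Adam, Tensor
from .detector import BlockSpec, DetectorConfig, DetectorModel, build_detector
from .graph import NeighborhoodGraph, default_graph
from .heatmaps import HeatmapStack, grid_to_image, gt_heatmap, image_to_grid
from .losses import AWingParams, CombinedLossConfig, masked_combined_loss_tensor
from .metrics import EvalResult, nme_stats
from .priors import PriorBank
from .schema import DEFAULT_SCHEMA, AnnotatedImage, LandmarkSet17
from .spatial import EdgeSet, SpatialModelParams, build_edge_set, filter_log_tensor
from .synthetic import AugmentConfig, augment

logger = logging.getLogger("pupilmark")

__all__ = ["TrainingConfig", "TrainedModel", "train", "evaluate",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainingConfig:
    """Hyperparameters of a training run.

    ``mode`` is "detector" (heatmap loss only) or "joint" (adds the spatial
    model's coordinate term; requires a prior bank).
    """

    lr: float = 1e-4
    lr_milestones: tuple = ((25, 1e-5), (40, 1e-6))
    batch_size: int = 16
    max_epochs: int = 120
    early_stop_patience: int = 10
    early_stop_tol: float = 1e-6
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    seed: int = 0
    mode: str = "detector"
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)
    loss: CombinedLossConfig = field(default_factory=CombinedLossConfig)
    awing: AWingParams = field(default_factory=AWingParams)
    spatial: SpatialModelParams = field(default_factory=SpatialModelParams)
    soft_argmax_temperature: float = 0.1
    coord_warmup_epochs: int = 5
    detector: DetectorConfig = field(default_factory=DetectorConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("detector", "joint"):
            raise ValueError("mode must be 'detector' or 'joint'")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")
        epochs = [m[0] for m in self.lr_milestones]
        if epochs != sorted(epochs):
            raise ValueError("lr milestone epochs must be increasing")

    def lr_at(self, epoch: int) -> float:
        """Learning rate for a 1-based epoch number."""
        lr = self.lr
        for ep, rate in self.lr_milestones:
            if epoch >= ep:
                lr = rate
        return lr


@dataclass
class TrainedModel:
    model: DetectorModel
    config: TrainingConfig
    history: list
    edge_set: EdgeSet | None = None
    graph: NeighborhoodGraph | None = None
    schema_hash: str = ""


def _soft_argmax_batch(logmaps: Tensor, temperature: float) -> tuple[Tensor, Tensor]:
    """Soft-argmax over (N, L, H, W) log-space maps -> (u, v) Tensors (N, L)."""
    n, n_lm, h, w = logmaps.data.shape
    cmax = logmaps.data.max(axis=(2, 3), keepdims=True)  # constant shift
    z = (logmaps - cmax) * (1.0 / temperature)
    e = z.exp()
    s = e.sum(axis=(2, 3), keepdims=True)
    p = e / s
    ugrid = np.arange(w, dtype=logmaps.data.dtype)[None, None, None, :]
    vgrid = np.arange(h, dtype=logmaps.data.dtype)[None, None, :, None]
    u = (p * ugrid).sum(axis=(2, 3))
    v = (p * vgrid).sum(axis=(2, 3))
    return u, v


def train(
    cfg: TrainingConfig,
    data: list[AnnotatedImage],
    priors: PriorBank | None = None,
    graph: NeighborhoodGraph | None = None,
    schema=DEFAULT_SCHEMA,
) -> TrainedModel:
    """Run the training loop on an annotated dataset.

    Joint mode requires ``priors``; the per-edge background biases are then
    trained together with the CNN weights.  Fully seeded: two runs with the
    same config and data produce identical histories.
    """
    if cfg.mode == "joint" and priors is None:
        raise ValueError("joint training requires a prior bank")
    if not data:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(cfg.seed)
    model = build_detector(cfg.detector, seed=cfg.seed)
    h_img, w_img = data[0].pixels.shape
    stride = cfg.detector.stride
    hm_shape = (h_img // stride, w_img // stride)

    edge_set = None
    if cfg.mode == "joint":
        graph = graph or default_graph(schema)
        if priors.schema_hash and priors.schema_hash != schema.hash():
            raise ValueError("prior bank was learned under a different schema")
        edge_set = build_edge_set(priors, graph, cfg.spatial, hm_shape, trainable_bias=True)

    params = model.parameters() + ([edge_set.bias] if edge_set is not None else [])
    opt = Adam(params, lr=cfg.lr, beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)

    history = []
    best = np.inf
    stall = 0
    n = len(data)
    for epoch in range(1, cfg.max_epochs + 1):
        opt.lr = cfg.lr_at(epoch)
        order = rng.permutation(n)
        losses = []
        for b0 in range(0, n, cfg.batch_size):
            batch_ids = order[b0 : b0 + cfg.batch_size]
            batch = [data[k] for k in batch_ids]
            if cfg.augment is not None:
                batch = [augment(im, cfg.augment, rng, schema) for im in batch]
            warmup = cfg.mode == "joint" and epoch <= cfg.coord_warmup_epochs
            loss = _step(model, edge_set, batch, cfg, hm_shape, stride, opt,
                         coord_warmup=warmup)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch starting at index "
                    f"{b0} (source ids {[im.source_id for im in batch]})"
                )
            losses.append(loss)
        mean_loss = float(np.mean(losses))
        history.append({"epoch": epoch, "lr": opt.lr, "loss": mean_loss})
        logger.info("epoch %d: lr=%.1e loss=%.6f", epoch, opt.lr, mean_loss)
        if best - mean_loss > cfg.early_stop_tol:
            best = mean_loss
            stall = 0
        else:
            stall += 1
            if stall >= cfg.early_stop_patience:
                logger.info("early stop after %d stalled epochs", stall)
                break
    return TrainedModel(
        model=model,
        config=cfg,
        history=history,
        edge_set=edge_set,
        graph=graph,
        schema_hash=schema.hash(),
    )


def _step(model, edge_set, batch, cfg, hm_shape, stride, opt,
          coord_warmup: bool = False) -> float:
    """One optimizer step; returns the full combined-loss value.

    During the coordinate warm-up epochs of a joint run, only the heatmap
    term is optimized (soft-argmax over an untrained, nearly flat field
    yields uninformative coordinates whose gradients deform the maps); the
    reported loss is always the full objective.
    """
    images = np.stack([im.pixels for im in batch])
    gt_maps = np.stack(
        [gt_heatmap(im.landmarks, hm_shape, stride).maps for im in batch]
    ).astype(np.float32)
    vis = np.stack([im.landmarks.visibility for im in batch])
    x_gt = np.stack([image_to_grid(im.landmarks.coords, stride) for im in batch])

    out = model.forward_images(images)
    if edge_set is not None:
        log_phat = filter_log_tensor(out, edge_set, cfg.spatial)
        u, v = _soft_argmax_batch(log_phat, cfg.soft_argmax_temperature)
    else:
        u = v = None
    loss = masked_combined_loss_tensor(
        gt_maps, out, x_gt, u, v, vis, cfg.loss, cfg.awing
    )
    if coord_warmup:
        opt_loss = masked_combined_loss_tensor(
            gt_maps, out, x_gt, None, None, vis, cfg.loss, cfg.awing
        )
    else:
        opt_loss = loss
    opt.zero_grad()
    opt_loss.backward()
    opt.step()
    return float(loss.data)


def evaluate(
    trained: TrainedModel,
    data: list[AnnotatedImage],
    use_filter: bool | None = None,
    schema=DEFAULT_SCHEMA,
    corrupt=None,
) -> EvalResult:
    """Detect (+ optionally filter), hard-argmax decode, rescale, score.

    ``corrupt`` is an optional callable applied to each raw HeatmapStack
    before filtering/decoding (used for robustness experiments).
    """
    if not data:
        raise ValueError("empty evaluation dataset")
    if use_filter is None:
        use_filter = trained.edge_set is not None
    if use_filter and trained.edge_set is None:
        raise ValueError("model has no spatial model attached")
    preds, gts = predict_landmarks(trained, data, use_filter=use_filter, corrupt=corrupt)
    return nme_stats(preds, gts, schema=schema)


def predict_landmarks(trained: TrainedModel, data, use_filter=False, corrupt=None):
    from .heatmaps import argmax_decode

    stride = trained.config.detector.stride
    preds, gts = [], []
    for im in data:
        out = trained.model.forward_images(im.pixels[None])
        maps = out.data[0].astype(float)
        stack = HeatmapStack(maps, stride)
        if corrupt is not None:
            stack = corrupt(stack)
        if use_filter:
            clipped = HeatmapStack(np.clip(stack.maps, 0.0, None), stride)
            log_phat = filter_log_tensor(
                Tensor(clipped.maps[None]), trained.edge_set, trained.config.spatial
            )
            stack = HeatmapStack(np.exp(log_phat.data[0]), stride)
        dec = argmax_decode(stack)
        coords = grid_to_image(dec.coords, stride)
        preds.append(LandmarkSet17(coords, dec.visibility))
        gts.append(im.landmarks)
    return preds, gts


def save_checkpoint(path, trained: TrainedModel) -> None:
    path = Path(path)
    arrays = {}
    for k, p in enumerate(trained.model.parameters()):
        arrays[f"param_{k}"] = p.data
    if trained.edge_set is not None:
        arrays["edge_bias"] = trained.edge_set.bias.data
    np.savez_compressed(path, **arrays)
    meta = {
        "schema_hash": trained.schema_hash,
        "history": trained.history,
        "detector": _config_to_dict(trained.config.detector),
        "mode": trained.config.mode,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, default=float))


def load_checkpoint(path, cfg: TrainingConfig | None = None) -> TrainedModel:
    path = Path(path)
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    det_cfg = _config_from_dict(meta["detector"])
    cfg = replace(cfg or TrainingConfig(), detector=det_cfg, mode=meta["mode"])
    model = build_detector(det_cfg, seed=0)
    for k, p in enumerate(model.parameters()):
        p.data = data[f"param_{k}"]
    return TrainedModel(
        model=model,
        config=cfg,
        history=meta["history"],
        schema_hash=meta["schema_hash"],
    )


def _config_to_dict(cfg: DetectorConfig) -> dict:
    return {
        "s1": [[b.channels, b.kernel, b.pool] for b in cfg.s1_blocks],
        "s2": [[b.channels, b.kernel, b.pool] for b in cfg.s2_blocks],
        "input_channels": cfg.input_channels,
        "n_landmarks": cfg.n_landmarks,
        "n_scales": cfg.n_scales,
    }


def _config_from_dict(d: dict) -> DetectorConfig:
    return DetectorConfig(
        s1_blocks=tuple(BlockSpec(c, k, p) for c, k, p in d["s1"]),
        s2_blocks=tuple(BlockSpec(c, k, p) for c, k, p in d["s2"]),
        input_channels=d["input_channels"],
        n_landmarks=d["n_landmarks"],
        n_scales=d["n_scales"],
    )
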