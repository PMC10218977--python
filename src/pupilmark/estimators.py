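"""Scikit-learn-style estimator interfaces.

Three estimators cover the pipeline: :class:`PairwisePriorModel` learns the
conditional-prior bank from annotations (fit), :class:`SpatialHeatmapFilter`
applies the MRF-like consistency filter to heatmap stacks (transform), and
:class:`HeatmapLandmarkDetector` trains the CNN -- optionally jointly with
the spatial model -- and predicts landmark coordinates (fit/predict).  All
follow the get_params/set_params contract and expose fitted state through
trailing-underscore attributes, so they compose with sklearn pipelines and
model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .detector import DetectorConfig, small_config
from .graph import DEFAULT_RADIUS, default_graph
from .heatmaps import HeatmapStack
from .priors import PriorConfig, learn_priors
from .schema import DEFAULT_SCHEMA, AnnotatedImage, LandmarkSet17
from .spatial import SpatialModelParams, build_edge_set, filter_log_tensor
from .synthetic import AugmentConfig
from .training import TrainingConfig, predict_landmarks, train
from ._autodiff import Tensor

__all__ = ["PairwisePriorModel", "SpatialHeatmapFilter", "HeatmapLandmarkDetector"]


def _to_landmark_sets(y) -> list[LandmarkSet17]:
    out = []
    for item in y:
        out.append(item if isinstance(item, LandmarkSet17) else LandmarkSet17(item))
    return out


class PairwisePriorModel(BaseEstimator):
    """Learn the pairwise conditional-prior bank from landmark annotations.

    Parameters
    ----------
    radius : local-neighborhood radius in interpupillary-distance units.
    heatmap_shape : (H, W) of the heatmaps the filter will run on; priors
        are stored at twice this resolution.
    stride : image-to-heatmap stride.
    order_range : candidate GMM orders for AIC/BIC selection.
    random_state : seed for the GMM fits.
    """

    def __init__(self, radius=DEFAULT_RADIUS, heatmap_shape=(16, 24), stride=4.0,
                 order_range=(1, 12), eps_raster=1e-9, random_state=0):
        self.radius = radius
        self.heatmap_shape = heatmap_shape
        self.stride = stride
        self.order_range = order_range
        self.eps_raster = eps_raster
        self.random_state = random_state

    def fit(self, X, y=None):
        """X: sequence of LandmarkSet17 or (17, 2) coordinate arrays."""
        sets = _to_landmark_sets(X)
        mean_shape = np.mean([s.coords for s in sets], axis=0)
        self.graph_ = default_graph(DEFAULT_SCHEMA, mean_shape, r=self.radius)
        cfg = PriorConfig(
            order_range=tuple(self.order_range),
            seed=self.random_state,
            eps_raster=self.eps_raster,
        )
        self.bank_ = learn_priors(sets, self.graph_, tuple(self.heatmap_shape),
                                  stride=self.stride, cfg=cfg)
        self.orders_ = {e: self.bank_[e].order for e in self.graph_.edges}
        return self


class SpatialHeatmapFilter(TransformerMixin, BaseEstimator):
    """Apply the MRF-like spatial-consistency filter to heatmap stacks."""

    def __init__(self, prior_model=None, eps=1e-6, softplus_beta=1.0, bias_init=1e-3):
        self.prior_model = prior_model
        self.eps = eps
        self.softplus_beta = softplus_beta
        self.bias_init = bias_init

    def fit(self, X=None, y=None):
        if self.prior_model is None or not hasattr(self.prior_model, "bank_"):
            raise ValueError("prior_model must be a fitted PairwisePriorModel")
        self.params_ = SpatialModelParams(
            eps=self.eps, softplus_beta=self.softplus_beta, bias_init=self.bias_init
        )
        shape = tuple(self.prior_model.heatmap_shape)
        self.edge_set_ = build_edge_set(
            self.prior_model.bank_, self.prior_model.graph_, self.params_, shape
        )
        return self

    def transform(self, X):
        """X: (n, 17, H, W) array or sequence of HeatmapStack -> p̂ array."""
        if not hasattr(self, "edge_set_"):
            self.fit()
        maps = np.stack(
            [x.maps if isinstance(x, HeatmapStack) else np.asarray(x, float) for x in X]
        )
        log_phat = filter_log_tensor(Tensor(maps), self.edge_set_, self.params_)
        return np.exp(log_phat.data)


class HeatmapLandmarkDetector(BaseEstimator):
    """Multiscale heatmap-regression CNN, optionally joint with the spatial model.

    Parameters mirror :class:`~pupilmark.training.TrainingConfig`; ``config``
    may be "default", "small" or a DetectorConfig.  ``prior_model`` (a fitted
    PairwisePriorModel) switches training to joint mode.
    """

    def __init__(self, config="small", prior_model=None, lr=1e-3, epochs=10,
                 batch_size=16, beta=0.1, augment=True, seed=0,
                 soft_argmax_temperature=0.1, early_stop_patience=10):
        self.config = config
        self.prior_model = prior_model
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.beta = beta
        self.augment = augment
        self.seed = seed
        self.soft_argmax_temperature = soft_argmax_temperature
        self.early_stop_patience = early_stop_patience

    def _training_config(self) -> TrainingConfig:
        from .losses import CombinedLossConfig

        if isinstance(self.config, DetectorConfig):
            det = self.config
        elif self.config == "small":
            det = small_config()
        else:
            det = DetectorConfig()
        return TrainingConfig(
            lr=self.lr,
            lr_milestones=(),
            batch_size=self.batch_size,
            max_epochs=self.epochs,
            early_stop_patience=self.early_stop_patience,
            seed=self.seed,
            mode="joint" if self.prior_model is not None else "detector",
            augment=AugmentConfig() if self.augment else None,
            loss=CombinedLossConfig(beta=self.beta),
            soft_argmax_temperature=self.soft_argmax_temperature,
            detector=det,
        )

    def fit(self, X, y):
        """X: (n, H, W) images; y: (n, 17, 2) coordinates or LandmarkSet17."""
        sets = _to_landmark_sets(y)
        data = [
            AnnotatedImage(np.asarray(img, float), lm, source_id=str(k))
            for k, (img, lm) in enumerate(zip(X, sets))
        ]
        cfg = self._training_config()
        priors = graph = None
        if self.prior_model is not None:
            priors = self.prior_model.bank_
            graph = self.prior_model.graph_
        self.trained_ = train(cfg, data, priors=priors, graph=graph)
        self.history_ = self.trained_.history
        return self

    def predict(self, X):
        """Predicted landmark coordinates (n, 17, 2) in image pixels."""
        data = [
            AnnotatedImage(
                np.asarray(img, float),
                LandmarkSet17(np.full((17, 2), 1.0)),  # placeholder annotation
                source_id=str(k),
            )
            for k, img in enumerate(X)
        ]
        use_filter = self.trained_.edge_set is not None
        preds, _ = predict_landmarks(self.trained_, data, use_filter=use_filter)
        return np.stack([p.coords for p in preds])

    def score(self, X, y):
        """Mean PCKp over landmarks (fraction of correct keypoints)."""
        from .metrics import pckp

        preds = self.predict(X)
        gts = _to_landmark_sets(y)
        table = pckp([LandmarkSet17(p) for p in preds], gts)
        vals = [v for v in table.values() if np.isfinite(v)]
        return float(np.mean(vals)) / 100.0
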