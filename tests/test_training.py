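"""Training loop: determinism, schedule, gradient flow, evaluation errors."""

import numpy as np
import pytest

from pupilmark.detector import BlockSpec, DetectorConfig
from pupilmark.estimators import (
    HeatmapLandmarkDetector,
    PairwisePriorModel,
    SpatialHeatmapFilter,
)
from pupilmark.priors import PriorConfig, learn_priors
from pupilmark.graph import default_graph
from pupilmark.spatial import build_edge_set, filter_log_tensor
from pupilmark.synthetic import sample_dataset
from pupilmark.training import (
    TrainingConfig,
    load_checkpoint,
    save_checkpoint,
    train,
)

TINY_DET = DetectorConfig(
    s1_blocks=(
        BlockSpec(4, 3),
        BlockSpec(4, 3, pool=True),
        BlockSpec(8, 3),
        BlockSpec(8, 3, pool=True),
    ),
    s2_blocks=(BlockSpec(8, 3), BlockSpec(17, 1)),
)


def tiny_cfg(**kw):
    defaults = dict(
        lr=1e-3,
        lr_milestones=(),
        batch_size=4,
        max_epochs=1,
        mode="detector",
        detector=TINY_DET,
        seed=0,
    )
    defaults.update(kw)
    return TrainingConfig(**defaults)


@pytest.fixture(scope="module")
def tiny_data():
    return sample_dataset(8, (32, 48), seed=2)


@pytest.fixture(scope="module")
def tiny_bank(tiny_data):
    graph = default_graph()
    cfg = PriorConfig(order_range=(1, 1), n_init=1)
    extra = sample_dataset(40, (32, 48), seed=3)
    bank = learn_priors(
        [im.landmarks for im in extra], graph, (8, 12), stride=4.0, cfg=cfg
    )
    return bank, graph


class TestTrainLoop:
    def test_one_epoch_deterministic(self, tiny_data):
        r1 = train(tiny_cfg(), tiny_data)
        r2 = train(tiny_cfg(), tiny_data)
        assert r1.history == r2.history
        for a, b in zip(r1.model.parameters(), r2.model.parameters()):
            assert np.array_equal(a.data, b.data)

    def test_lr_schedule_milestones(self, tiny_data):
        cfg = tiny_cfg(
            max_epochs=3,
            lr=1e-4,
            lr_milestones=((2, 1e-5), (3, 1e-6)),
            augment=None,
            early_stop_patience=10,
        )
        r = train(cfg, tiny_data)
        assert [h["lr"] for h in r.history] == [1e-4, 1e-5, 1e-6]

    def test_paper_schedule_values(self):
        cfg = TrainingConfig()
        assert cfg.lr_at(24) == 1e-4
        assert cfg.lr_at(25) == 1e-5
        assert cfg.lr_at(40) == 1e-6
        assert cfg.batch_size == 16 and cfg.max_epochs == 120
        assert cfg.early_stop_patience == 10

    def test_joint_mode_requires_priors(self, tiny_data):
        with pytest.raises(ValueError, match="prior"):
            train(tiny_cfg(mode="joint"), tiny_data)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train(tiny_cfg(), [])

    def test_evaluate_empty_dataset_rejected(self, tiny_data):
        from pupilmark.training import evaluate

        r = train(tiny_cfg(), tiny_data)
        with pytest.raises(ValueError, match="empty"):
            evaluate(r, [], use_filter=False)

    def test_evaluate_refuses_filter_without_spatial_model(self, tiny_data):
        from pupilmark.training import evaluate

        r = train(tiny_cfg(), tiny_data)
        with pytest.raises(ValueError, match="spatial"):
            evaluate(r, tiny_data, use_filter=True)

    def test_joint_gradient_reaches_first_s1_block(self, tiny_data, tiny_bank):
        """After one joint step the first S1 conv weights have moved."""
        bank, graph = tiny_bank
        cfg = tiny_cfg(mode="joint", max_epochs=1, augment=None)
        r = train(cfg, tiny_data[:4], priors=bank, graph=graph)
        trained_w = r.model.s1_weights[0][0].data
        from pupilmark.detector import build_detector

        init_w = build_detector(cfg.detector, seed=cfg.seed).s1_weights[0][0].data
        assert np.abs(trained_w - init_w).max() > 0

    def test_early_stopping_on_stalled_loss(self, tiny_data):
        cfg = tiny_cfg(lr=0.0, max_epochs=30, early_stop_patience=2, augment=None)
        r = train(cfg, tiny_data)
        # zero learning rate: loss never improves after the first epoch
        assert len(r.history) <= 3


class TestCheckpoints:
    def test_roundtrip(self, tiny_data, tmp_path):
        r = train(tiny_cfg(), tiny_data)
        save_checkpoint(tmp_path / "ck.npz", r)
        back = load_checkpoint(tmp_path / "ck.npz")
        for a, b in zip(r.model.parameters(), back.model.parameters()):
            assert np.allclose(a.data, b.data)
        assert back.schema_hash == r.schema_hash


class TestEstimators:
    def test_sklearn_params_roundtrip(self):
        est = HeatmapLandmarkDetector(lr=5e-4, epochs=2)
        params = est.get_params()
        assert params["lr"] == 5e-4
        est.set_params(epochs=3)
        assert est.epochs == 3

    def test_fit_predict_shapes(self, tiny_data):
        X = [im.pixels for im in tiny_data]
        y = [im.landmarks for im in tiny_data]
        est = HeatmapLandmarkDetector(
            config=TINY_DET, epochs=1, batch_size=4, augment=False, seed=0
        )
        est.fit(X, y)
        pred = est.predict(X[:3])
        assert pred.shape == (3, 17, 2)
        assert 0.0 <= est.score(X[:3], y[:3]) <= 1.0

    def test_prior_model_and_filter_transform(self, tiny_data, tiny_bank):
        X = [im.landmarks for im in sample_dataset(40, (32, 48), seed=4)]
        pm = PairwisePriorModel(heatmap_shape=(8, 12), order_range=(1, 1))
        pm.fit(X)
        assert len(pm.bank_) == pm.graph_.n_edges
        filt = SpatialHeatmapFilter(prior_model=pm).fit()
        maps = np.random.default_rng(0).random((2, 17, 8, 12))
        out = filt.transform(maps)
        assert out.shape == maps.shape
        assert np.all(out > 0)


def test_filter_tensor_batch_matches_single(tiny_bank, rng):
    """Batched filtering equals per-stack filtering."""
    from pupilmark._autodiff import Tensor
    from pupilmark.spatial import SpatialModelParams

    bank, graph = tiny_bank
    params = SpatialModelParams()
    es = build_edge_set(bank, graph, params, (8, 12))
    maps = rng.random((3, 17, 8, 12))
    batch = filter_log_tensor(Tensor(maps), es, params).data
    for k in range(3):
        single = filter_log_tensor(Tensor(maps[k][None]), es, params).data[0]
        assert np.allclose(single, batch[k], atol=1e-9)
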