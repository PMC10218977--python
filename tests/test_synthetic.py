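"""Synthetic face generator, heatmap fixtures and augmentation transforms."""

import numpy as np
import pytest
from scipy import stats

from pupilmark.heatmaps import image_to_grid
from pupilmark.schema import DEFAULT_SCHEMA, LandmarkSet17
from pupilmark.synthetic import (
    CANONICAL_SHAPE,
    AugmentConfig,
    FaceShapeParams,
    _base_affine,
    _pose_affine,
    augment,
    draw_augment_params,
    inject_outlier,
    sample_dataset,
    sample_face,
    synth_heatmaps,
)

FRAME = (64, 96)


class TestSampleFace:
    def test_identity_pose_zero_jitter_gives_scaled_canonical(self):
        im = sample_face(FaceShapeParams(jitter=0.0), FRAME)
        m = _base_affine(FRAME)
        expected = np.column_stack([CANONICAL_SHAPE, np.ones(17)]) @ m.T
        assert np.allclose(im.landmarks.coords, expected[:, :2], atol=1e-9)

    def test_same_seed_is_deterministic(self):
        a = sample_face(FaceShapeParams(seed=7), FRAME)
        b = sample_face(FaceShapeParams(seed=7), FRAME)
        assert np.array_equal(a.pixels, b.pixels)
        assert np.array_equal(a.landmarks.coords, b.landmarks.coords)

    def test_rotation_matches_independent_affine(self):
        base = sample_face(FaceShapeParams(jitter=0.0), FRAME)
        rot = sample_face(FaceShapeParams(jitter=0.0, rotation_deg=20.0), FRAME)
        m = _pose_affine(FRAME, 20.0, 1.0, (0.0, 0.0))
        expected = np.column_stack([base.landmarks.coords, np.ones(17)]) @ m.T
        assert np.allclose(rot.landmarks.coords, expected[:, :2], atol=1e-9)

    def test_impossible_pose_raises(self):
        with pytest.raises(ValueError, match="outside"):
            sample_face(FaceShapeParams(jitter=0.0, translation=(500.0, 0.0)), FRAME)

    def test_dataset_landmarks_inside_frame(self):
        data = sample_dataset(10, FRAME, seed=3)
        for im in data:
            c = im.landmarks.coords
            assert c[:, 0].min() >= 0 and c[:, 0].max() <= FRAME[1] - 1
            assert c[:, 1].min() >= 0 and c[:, 1].max() <= FRAME[0] - 1


class TestSynthHeatmaps:
    def test_noiseless_argmax_at_rounded_scaled_coordinate(self):
        im = sample_face(FaceShapeParams(jitter=0.0), FRAME)
        hm = synth_heatmaps(im.landmarks, (16, 24), stride=4.0)
        grid = image_to_grid(im.landmarks.coords, 4.0)
        for k in range(17):
            r, c = np.unravel_index(hm.maps[k].argmax(), hm.maps[k].shape)
            # the argmax cell is a nearest grid cell to the scaled coordinate
            assert abs(c - grid[k, 0]) <= 0.5 + 1e-9
            assert abs(r - grid[k, 1]) <= 0.5 + 1e-9

    def test_zero_peak_gives_zero_maps(self):
        im = sample_face(FaceShapeParams(jitter=0.0), FRAME)
        hm = synth_heatmaps(im.landmarks, (16, 24), peak=0.0)
        assert np.all(hm.maps == 0.0)


class TestInjectOutlier:
    def _clean_map(self):
        # off-center pose so no landmark sits exactly between two cells
        im = sample_face(
            FaceShapeParams(jitter=0.0, translation=(1.3, 0.7)), FRAME
        )
        return synth_heatmaps(im.landmarks, (16, 24)).maps[2]  # nose tip

    def test_offset_8_gives_two_equal_global_maxima(self):
        hm = self._clean_map()
        out = inject_outlier(hm, (8, 0))
        mx = out.max()
        ties = np.isclose(out, mx, rtol=0, atol=1e-12)
        assert ties.sum() == 2

    def test_zero_offset_leaves_map_unchanged(self):
        hm = self._clean_map()
        assert np.allclose(inject_outlier(hm, (0, 0)), hm)

    def test_out_of_bounds_stain_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            inject_outlier(self._clean_map(), (200, 0))


class TestAugment:
    def test_degenerate_config_is_identity(self, rng):
        im = sample_face(FaceShapeParams(seed=1), FRAME)
        cfg = AugmentConfig((1, 1), (0, 0), (0, 0), 0.0)
        out = augment(im, cfg, rng)
        assert np.allclose(out.landmarks.coords, im.landmarks.coords, atol=1e-9)
        assert np.allclose(out.pixels, im.pixels, atol=1e-6)

    def test_forced_flip_swaps_and_mirrors_pupils(self, rng):
        im = sample_face(FaceShapeParams(jitter=0.0), FRAME)
        cfg = AugmentConfig((1, 1), (0, 0), (0, 0), 1.0)
        out = augment(im, cfg, rng)
        w = FRAME[1]
        il, ir = DEFAULT_SCHEMA.index("LPc"), DEFAULT_SCHEMA.index("RPc")
        assert np.allclose(
            out.landmarks.coords[il, 0], (w - 1) - im.landmarks.coords[ir, 0]
        )
        assert np.allclose(
            out.landmarks.coords[ir, 0], (w - 1) - im.landmarks.coords[il, 0]
        )

    def test_landmark_roundtrip_through_inverse_affine(self, rng):
        im = sample_face(FaceShapeParams(seed=2), FRAME)
        cfg = AugmentConfig((1.05, 1.5), (0.0, 0.1), (-20, 20), 0.0)
        state = rng.bit_generator.state
        out = augment(im, cfg, rng)
        # replay the same draws to recover the transform
        rng2 = np.random.default_rng()
        rng2.bit_generator.state = state
        scale, (tfu, tfv), rot, _ = draw_augment_params(cfg, rng2)
        m = _pose_affine(FRAME, rot, scale, (tfu * FRAME[1], tfv * FRAME[0]))
        back = np.column_stack(
            [out.landmarks.coords, np.ones(17)]
        ) @ np.linalg.inv(m).T
        vis = out.landmarks.visibility
        assert np.abs(back[vis, :2] - im.landmarks.coords[vis]).max() < 0.5

    def test_parameter_histograms_uniform(self):
        """Drawn augmentation parameters are uniform on the configured ranges."""
        cfg = AugmentConfig()
        rng = np.random.default_rng(0)
        n = 10_000
        draws = [draw_augment_params(cfg, rng) for _ in range(n)]
        scales = [d[0] for d in draws]
        trans = [abs(d[1][0]) for d in draws]
        rots = [d[2] for d in draws]
        flips = sum(d[3] for d in draws)
        for vals, (lo, hi) in [
            (scales, cfg.scale_range),
            (trans, cfg.translate_frac_range),
            (rots, cfg.rotation_range_deg),
        ]:
            p = stats.kstest(vals, stats.uniform(lo, hi - lo).cdf).pvalue
            assert p > 0.01
        assert abs(flips / n - cfg.hflip_prob) < 0.02

    def test_out_of_frame_landmarks_marked_invisible(self):
        im = sample_face(FaceShapeParams(jitter=0.0), FRAME)
        cfg = AugmentConfig((3.0, 3.0), (0, 0), (0, 0), 0.0)  # strong zoom
        out = augment(im, cfg, np.random.default_rng(0))
        assert not out.landmarks.visibility.all()


class TestConfigValidation:
    def test_bad_ranges_rejected(self):
        with pytest.raises(ValueError):
            AugmentConfig(scale_range=(1.5, 1.0))
        with pytest.raises(ValueError):
            AugmentConfig(hflip_prob=1.5)
        with pytest.raises(ValueError):
            FaceShapeParams(scale=0.0)
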