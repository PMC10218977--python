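"""Translate-to-center offsets, GMM order selection and prior rasterization."""

import numpy as np
import pytest

from pupilmark.graph import default_graph
from pupilmark.priors import (
    PriorConfig,
    center_translate,
    fit_pair_gmm,
    learn_priors,
    load_bank,
    rasterize_prior,
    save_bank,
)
from pupilmark.schema import LandmarkSet17
from pupilmark.synthetic import sample_dataset


class TestCenterTranslate:
    def test_conditional_at_center_is_identity(self):
        x = center_translate((10.0, 20.0), (89.5, 59.5), (120, 180))
        assert np.allclose(x, (10.0, 20.0))

    def test_corner_conditional_shift(self):
        """Frame 120x180: center (89.5, 59.5) added when x_condi=(0,0)."""
        x = center_translate((3.0, 4.0), (0.0, 0.0), (120, 180))
        assert np.allclose(x, (92.5, 63.5))

    def test_roundtrip_to_1e12(self, rng):
        xi = rng.uniform(0, 100, 2)
        xc = rng.uniform(0, 100, 2)
        moved = center_translate(xi, xc, (64, 96))
        from pupilmark.priors import frame_center

        t = frame_center((64, 96)) - xc
        back = moved - t
        assert np.abs(back - xi).max() < 1e-12


class TestFitPairGmm:
    def test_single_gaussian_selects_order_one(self, rng):
        samples = rng.normal([5.0, -2.0], 1.0, (600, 2))
        gm, order = fit_pair_gmm(samples, order_range=(1, 5), seed=0)
        assert order == 1
        se = 1.0 / np.sqrt(600)
        assert np.abs(gm.means_[0] - [5.0, -2.0]).max() < 3 * se * 3

    def test_three_separated_components_select_order_three(self, rng):
        means = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        samples = np.vstack(
            [rng.normal(m, 1.0, (400, 2)) for m in means]
        )
        gm, order = fit_pair_gmm(samples, order_range=(1, 6), seed=0)
        assert order == 3

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="samples"):
            fit_pair_gmm(rng.normal(0, 1, (30, 2)), order_range=(1, 5))

    def test_degenerate_samples_warn(self, rng):
        x = np.column_stack([rng.normal(0, 1, 200), np.zeros(200)])
        with pytest.warns(UserWarning, match="rank"):
            fit_pair_gmm(x, order_range=(1, 2), seed=0)

    def test_reproducible_under_fixed_seed(self, rng):
        samples = rng.normal(0, 1, (300, 2)) + np.array([3.0, 3.0])
        g1, o1 = fit_pair_gmm(samples, order_range=(1, 4), seed=7)
        g2, o2 = fit_pair_gmm(samples, order_range=(1, 4), seed=7)
        assert o1 == o2
        assert np.allclose(g1.means_, g2.means_)


class TestRasterize:
    def test_symmetric_gaussian_is_rotation_symmetric(self):
        grid = rasterize_prior(
            ([1.0], np.array([[11.5, 7.5]]), np.array([[[4.0, 0], [0, 4.0]]])),
            (16, 24),
        )
        assert np.allclose(grid, grid[::-1, ::-1], atol=1e-9)

    def test_mass_within_two_percent(self):
        grid = rasterize_prior(
            ([1.0], np.array([[24.0, 16.0]]), np.array([[[6.0, 1.0], [1.0, 5.0]]])),
            (32, 48),
        )
        assert grid.sum() == pytest.approx(1.0, rel=0.02)

    def test_mixture_linearity(self):
        m1 = (np.array([1.0]), np.array([[10.0, 8.0]]), np.array([[[3.0, 0], [0, 3.0]]]))
        m2 = (np.array([1.0]), np.array([[30.0, 20.0]]), np.array([[[2.0, 0], [0, 4.0]]]))
        mix = (
            np.array([0.3, 0.7]),
            np.vstack([m1[1], m2[1]]),
            np.stack([m1[2][0], m2[2][0]]),
        )
        g1 = rasterize_prior(m1, (32, 48), eps_raster=0.0)
        g2 = rasterize_prior(m2, (32, 48), eps_raster=0.0)
        gm = rasterize_prior(mix, (32, 48), eps_raster=0.0)
        assert np.allclose(gm, 0.3 * g1 + 0.7 * g2, atol=1e-12)

    def test_floor_applied(self):
        grid = rasterize_prior(
            ([1.0], np.array([[5.0, 5.0]]), np.array([[[0.5, 0], [0, 0.5]]])),
            (32, 48),
            eps_raster=1e-9,
        )
        assert grid.min() == pytest.approx(1e-9)


class TestLearnPriors:
    @pytest.fixture(scope="class")
    def small_bank(self):
        data = sample_dataset(60, (64, 96), seed=5)
        graph = default_graph()
        cfg = PriorConfig(order_range=(1, 2), n_init=1)
        bank = learn_priors(
            [im.landmarks for im in data], graph, (16, 24), stride=4.0, cfg=cfg
        )
        return bank, graph, data

    def test_bank_covers_every_edge(self, small_bank):
        bank, graph, _ = small_bank
        assert len(bank) == graph.n_edges
        assert all(e in bank for e in graph.edges)

    def test_two_image_hand_translation(self):
        """Translated sample lists match a by-hand computation."""
        from pupilmark.priors import translated_offsets

        coords_a = np.zeros((17, 2))
        coords_a[0] = [20.0, 12.0]   # landmark i
        coords_a[1] = [40.0, 28.0]   # landmark j
        coords_b = coords_a + [8.0, -4.0]
        got = translated_offsets([coords_a, coords_b], (0, 1), (16, 24), stride=4.0)
        # stride/2 = 2: grid coord = (x - 0.5) / 2; center of 32x48 = (23.5, 15.5)
        ga_i, ga_j = (coords_a[0] - 0.5) / 2, (coords_a[1] - 0.5) / 2
        expected_a = ga_i + (np.array([23.5, 15.5]) - ga_j)
        assert np.allclose(got[0], expected_a, atol=1e-12)
        # a rigid shift of the whole frame leaves the offsets unchanged
        assert np.allclose(got[1], got[0], atol=1e-12)

    def test_translation_invariance_of_learned_priors(self):
        data = sample_dataset(40, (64, 96), seed=9)
        graph = default_graph()
        cfg = PriorConfig(order_range=(1, 1), n_init=1)
        sets = [im.landmarks for im in data]
        shifted = [LandmarkSet17(s.coords + [7.0, -4.0]) for s in sets]
        b1 = learn_priors(sets, graph, (16, 24), cfg=cfg)
        b2 = learn_priors(shifted, graph, (16, 24), cfg=cfg)
        for e in graph.edges:
            assert np.allclose(b1[e].grid, b2[e].grid, atol=1e-12)

    def test_mouth_prior_mode_below_left_of_center(self, small_bank):
        """p_{LMe|NT}: the left mouth extremity sits below-left of a centered
        nose tip."""
        bank, _, _ = small_bank
        grid = bank[("LMe", "NT")].grid
        h2, w2 = grid.shape
        r, c = np.unravel_index(grid.argmax(), grid.shape)
        assert r > (h2 - 1) / 2  # below center (v grows downward)
        assert c < (w2 - 1) / 2  # left of center

    def test_missing_landmarks_error_names_pair(self):
        data = sample_dataset(30, (64, 96), seed=11)
        graph = default_graph()
        sets = []
        for im in data:
            vis = im.landmarks.visibility.copy()
            vis[2] = False  # NT missing everywhere
            sets.append(LandmarkSet17(im.landmarks.coords, vis))
        with pytest.raises(ValueError, match="NT"):
            learn_priors(sets, graph, (16, 24), cfg=PriorConfig(order_range=(1, 1)))

    def test_bank_serialization_roundtrip(self, small_bank, tmp_path):
        bank, graph, _ = small_bank
        save_bank(tmp_path / "bank.npz", bank)
        back = load_bank(tmp_path / "bank.npz")
        assert len(back) == len(bank)
        e = graph.edges[0]
        assert np.allclose(back[e].grid, bank[e].grid)
        assert back[e].order == bank[e].order
        assert back.schema_hash == bank.schema_hash
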