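"""FID / FHD / PPL metric tests against independent oracles."""

import numpy as np
import pytest
import scipy.linalg

from ki67gan import embedders, metrics, synthdata as sd


def frechet_oracle(a, b):
    """Alternative formula: trace term via sqrt(S_a)^T S_b sqrt(S_a)."""
    sa_half = scipy.linalg.sqrtm(a.sigma).real
    mid = scipy.linalg.sqrtm(sa_half @ b.sigma @ sa_half).real
    d = a.mu - b.mu
    return float(d @ d + np.trace(a.sigma) + np.trace(b.sigma)
                 - 2 * np.trace(mid))


def stats1d(mu, var):
    return metrics.GaussianStats(np.array([mu]), np.array([[var]]), 10)


class TestFitGaussian:
    def test_identical_rows_give_zero_covariance(self):
        st = metrics.fit_gaussian(np.array([[1.0, 2.0], [1.0, 2.0]]))
        np.testing.assert_array_equal(st.sigma, np.zeros((2, 2)))

    def test_hand_computed_case(self):
        st = metrics.fit_gaussian(np.array([[0.0, 0.0], [2.0, 2.0]]))
        np.testing.assert_array_equal(st.mu, [1.0, 1.0])
        np.testing.assert_array_equal(st.sigma, [[2.0, 2.0], [2.0, 2.0]])

    def test_recovers_known_gaussian(self):
        rng = np.random.default_rng(0)
        mu = np.array([1.0, -2.0, 0.5])
        a = rng.standard_normal((3, 3))
        sigma = a @ a.T + np.eye(3)
        draws = rng.multivariate_normal(mu, sigma, size=10_000)
        st = metrics.fit_gaussian(draws)
        se_mu = np.sqrt(np.diag(sigma) / 10_000)
        assert np.all(np.abs(st.mu - mu) < 3 * se_mu)
        assert np.all(np.abs(st.sigma - sigma) < 0.15)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            metrics.fit_gaussian(np.array([[1.0, 2.0]]))


class TestFrechet:
    def test_identity(self):
        st = stats1d(0.0, 1.0)
        assert metrics.frechet(st, st) == 0.0

    def test_one_dimensional_closed_forms(self):
        assert metrics.frechet(stats1d(0, 1), stats1d(3, 1)) == pytest.approx(9.0)
        assert metrics.frechet(stats1d(0, 1), stats1d(0, 4)) == pytest.approx(1.0)

    def test_agrees_with_alternative_formula(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = metrics.fit_gaussian(rng.standard_normal((30, 4)))
            b = metrics.fit_gaussian(rng.standard_normal((30, 4)) * 1.5 + 0.3)
            assert metrics.frechet(a, b) == pytest.approx(
                frechet_oracle(a, b), abs=1e-6)

    def test_commuting_covariances_closed_form(self):
        rng = np.random.default_rng(4)
        la = rng.uniform(0.5, 2.0, 4)
        lb = rng.uniform(0.5, 2.0, 4)
        mu_a, mu_b = rng.standard_normal(4), rng.standard_normal(4)
        a = metrics.GaussianStats(mu_a, np.diag(la), 10)
        b = metrics.GaussianStats(mu_b, np.diag(lb), 10)
        closed = np.sum((np.sqrt(la) - np.sqrt(lb)) ** 2) + \
            np.sum((mu_a - mu_b) ** 2)
        assert metrics.frechet(a, b) == pytest.approx(closed, abs=1e-10)

    def test_symmetric_and_nonnegative(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            a = metrics.fit_gaussian(rng.standard_normal((20, 3)))
            b = metrics.fit_gaussian(rng.standard_normal((20, 3)) + 1)
            ab, ba = metrics.frechet(a, b), metrics.frechet(b, a)
            assert ab >= 0
            assert ab == pytest.approx(ba, abs=1e-8)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            metrics.frechet(stats1d(0, 1),
                            metrics.fit_gaussian(np.eye(3)))


@pytest.fixture(scope="module")
def colour_sets():
    rng = np.random.default_rng(7)
    def block(colour, n=40):
        imgs = np.empty((n, 32, 32, 3), dtype=np.uint8)
        imgs[:] = colour
        return (imgs.astype(np.int16) +
                rng.integers(-8, 9, imgs.shape)).clip(0, 255).astype(np.uint8)
    return block((200, 40, 40)), block((40, 40, 200))


class TestFID:
    def test_identical_sets_are_zero(self, colour_sets):
        red, _ = colour_sets
        assert metrics.fid(red, red.copy()) < 1e-6

    def test_disjoint_populations_exceed_split_halves(self, colour_sets):
        red, blue = colour_sets
        cross = metrics.fid(red, blue)
        within = metrics.fid(red[:20], red[20:])
        assert cross > within

    def test_order_invariance(self, colour_sets):
        red, blue = colour_sets
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(red))
        assert metrics.fid(red, blue) == pytest.approx(
            metrics.fid(red[perm], blue), abs=1e-9)

    def test_mixing_real_images_decreases_distance(self, colour_sets):
        red, blue = colour_sets
        vals = []
        for frac in (0.0, 0.5, 1.0):
            k = int(frac * len(blue))
            mixed = np.concatenate([red[:k], blue[k:]])
            vals.append(metrics.fid(red, mixed))
        assert vals[0] > vals[1] > vals[2]

    def test_too_few_images_rejected(self, colour_sets):
        red, blue = colour_sets
        with pytest.raises(ValueError):
            metrics.fid(red[:1], blue)


class TestHistologicalEmbedder:
    def test_too_few_rows_refused(self):
        images = np.zeros((30, 64, 64, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match=">= 50"):
            metrics.train_histological_embedder((images, np.linspace(0, 1, 30)))

    def test_embedding_dimension_matches_declaration(self, hist_embedder,
                                                     small_pairs):
        feats = hist_embedder.embed(np.stack(
            [p.he_image for p in small_pairs[:4]]))
        assert feats.shape == (4, hist_embedder.d)

    def test_heldout_prediction_tracks_truth(self, hist_embedder):
        # held-out pairs from the same (imbalanced) label distribution the
        # embedder was trained on
        held_out = sd.make_dataset(120, size=64, seed=22)
        images = np.stack([p.he_image for p in held_out])
        truth = np.array([p.true_index for p in held_out])
        mae = np.abs(hist_embedder.predict(images) - truth).mean()
        assert mae < 0.1

    def test_seeded_training_reproducible(self):
        pairs = sd.make_dataset(60, size=64, seed=42)
        data = (np.stack([p.he_image for p in pairs]),
                np.array([p.true_index for p in pairs]))
        e1 = metrics.train_histological_embedder(data, seed=1, epochs=2)
        e2 = metrics.train_histological_embedder(data, seed=1, epochs=2)
        assert e1.weights_blob() == e2.weights_blob()


class TestFHD:
    def test_self_distance_rounds_to_zero(self, hist_embedder, small_pairs):
        images = np.stack([p.he_image for p in small_pairs])
        assert round(metrics.fhd(images, images.copy(), hist_embedder), 2) == 0.0

    def test_separates_low_from_high_index_sets(self, hist_embedder):
        rng = np.random.default_rng(9)
        low1 = np.stack([sd.render_patch_pair(0.05, 64, rng).he_image
                         for _ in range(30)])
        low2 = np.stack([sd.render_patch_pair(0.05, 64, rng).he_image
                         for _ in range(30)])
        high = np.stack([sd.render_patch_pair(0.45, 64, rng).he_image
                         for _ in range(30)])
        assert metrics.fhd(low1, high, hist_embedder) > \
            metrics.fhd(low1, low2, hist_embedder)

    def test_requires_histological_embedder(self, small_pairs):
        images = np.stack([p.he_image for p in small_pairs[:4]])
        with pytest.raises(ValueError, match="histological"):
            metrics.fhd(images, images,
                        embedders.RandomFeatureEmbedder(kind="visual"))


class _IdentityEmbedder:
    def embed(self, x):
        return np.asarray(x, dtype=np.float64)


class _VectorGen:
    class spec:
        z_dim = 6


class TestPPL:
    def test_linear_generator_closed_form(self):
        # identity map + identity synthesis: PPL == E||z1 - z2||^2, any eps
        vals = []
        for eps in (1e-2, 1e-4):
            cfg = metrics.PPLConfig(epsilon=eps, n_pairs=64,
                                    space="intermediate-latent",
                                    label_value=0.3)
            vals.append(metrics.ppl(
                _VectorGen(), cfg, np.random.default_rng(1),
                embedder=_IdentityEmbedder(),
                synth_fn=lambda w: w, map_fn=lambda z, c: z))
        assert vals[0] == pytest.approx(vals[1], rel=1e-3)
        # single pair: exactly ||e1 - e2||^2
        rng = np.random.default_rng(2)
        cfg = metrics.PPLConfig(epsilon=1e-3, n_pairs=1,
                                space="intermediate-latent", label_value=0.0)
        z1 = rng.standard_normal((1, 6)); z2 = rng.standard_normal((1, 6))
        t = rng.uniform(0, 1, 1)
        val = metrics.ppl(_VectorGen(), cfg, np.random.default_rng(2),
                          embedder=_IdentityEmbedder(),
                          synth_fn=lambda w: w, map_fn=lambda z, c: z)
        expected = float(np.sum((z1 - z2) ** 2))
        assert val == pytest.approx(expected, rel=1e-3)

    def test_constant_generator_is_zero(self):
        cfg = metrics.PPLConfig(epsilon=1e-3, n_pairs=16, label_value=0.2)
        val = metrics.ppl(_VectorGen(), cfg, np.random.default_rng(3),
                          embedder=_IdentityEmbedder(),
                          synth_fn=lambda w: np.zeros((len(w), 4)),
                          map_fn=lambda z, c: z)
        assert val == 0.0

    def test_seeded_determinism(self):
        cfg = metrics.PPLConfig(epsilon=1e-3, n_pairs=16, label_value=0.2)
        kw = dict(embedder=_IdentityEmbedder(), synth_fn=lambda w: w,
                  map_fn=lambda z, c: z)
        assert metrics.ppl(_VectorGen(), cfg, np.random.default_rng(4), **kw) \
            == metrics.ppl(_VectorGen(), cfg, np.random.default_rng(4), **kw)

    def test_invalid_epsilon_rejected(self):
        with pytest.raises(ValueError):
            metrics.PPLConfig(epsilon=0.0).validate()
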