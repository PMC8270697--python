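"""Metric arithmetic against closed forms, and the classifier harness."""

import numpy as np
import pytest

from virtstain import evaluation as ev
from virtstain import synthetic
from virtstain.types import ImageTile

RNG = np.random.default_rng(7)


def _tiles(n, size=2, seed=0):
    rng = np.random.default_rng(seed)
    return [ImageTile(rng.uniform(0, 1, size=(size, size, 3)), "stained")
            for _ in range(n)]


class TestEmbed:
    def test_flatten_is_pixel_vectors(self):
        tiles = _tiles(3)
        fs = ev.embed(tiles, "flatten")
        for i, t in enumerate(tiles):
            assert np.array_equal(fs.features[i], t.data.ravel())

    def test_deterministic(self):
        tiles = _tiles(4, seed=1)
        a = ev.embed(tiles, "pool2")
        b = ev.embed(tiles, "pool2")
        assert np.array_equal(a.features, b.features)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ev.embed([], "flatten")

    def test_gaussian_fixture_moments_match_closed_form(self):
        rng = np.random.default_rng(0)
        mu_true, sd_true = 0.3, 0.05
        tiles = [ImageTile(np.clip(rng.normal(mu_true, sd_true, (4, 4, 3)), 0, 1),
                           "stained") for _ in range(600)]
        fs = ev.embed(tiles, "mean_color")
        assert np.allclose(fs.mu, mu_true, atol=5 * sd_true / np.sqrt(600 * 16))
        # variance of a per-tile channel mean over the 16 iid pixels of a channel
        assert np.allclose(np.diag(fs.sigma), sd_true ** 2 / 16, rtol=0.3)


class TestFID:
    def test_zero_on_identical(self):
        fs = ev.embed(_tiles(10, seed=3), "flatten")
        assert ev.fid(fs, fs) == pytest.approx(0.0, abs=1e-8)

    def test_pure_mean_shift_equals_squared_norm(self):
        f = RNG.normal(size=(50, 4))
        delta = np.array([0.5, -1.0, 0.25, 2.0])
        a = ev.FeatureSet(f, "synthetic")
        b = ev.FeatureSet(f + delta, "synthetic")
        assert ev.fid(a, b) == pytest.approx(np.sum(delta ** 2), abs=1e-8)

    def test_1d_gaussian_closed_form(self):
        x = RNG.normal(0.0, 1.0, size=(400, 1))
        y = RNG.normal(2.0, 3.0, size=(400, 1))
        a, b = ev.FeatureSet(x, "g1"), ev.FeatureSet(y, "g2")
        mu1, mu2 = a.mu[0], b.mu[0]
        s1, s2 = np.sqrt(a.sigma[0, 0]), np.sqrt(b.sigma[0, 0])
        expected = (mu1 - mu2) ** 2 + (s1 - s2) ** 2
        assert ev.fid(a, b) == pytest.approx(expected, abs=1e-6)

    def test_symmetry_and_mean_shift_monotonicity(self):
        f = RNG.normal(size=(60, 3))
        a = ev.FeatureSet(f, "s")
        prev = -1.0
        for scale in (0.0, 0.5, 1.0, 2.0):
            b = ev.FeatureSet(f + scale, "s")
            d = ev.fid(a, b)
            assert d == pytest.approx(ev.fid(b, a), abs=1e-8)
            assert d >= prev
            prev = d

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            ev.fid(ev.FeatureSet(np.zeros((3, 2)), "a"),
                   ev.FeatureSet(np.zeros((3, 3)), "b"))


class TestInceptionScore:
    def test_uniform_rows_give_one(self):
        p = ev.ProbSet(np.full((10, 4), 0.25))
        assert ev.inception_score(p) == pytest.approx(1.0)

    def test_one_hot_cover_gives_k(self):
        K = 5
        p = ev.ProbSet(np.eye(K))
        assert ev.inception_score(p, splits=1) == pytest.approx(K)

    def test_matches_loop_oracle_and_bounds(self):
        raw = RNG.uniform(0.01, 1.0, size=(12, 4))
        raw /= raw.sum(axis=1, keepdims=True)
        p = ev.ProbSet(raw)
        got = ev.inception_score(p, splits=1)
        marginal = raw.mean(axis=0)
        kl = 0.0
        for row in raw:
            kl += sum(pi * (np.log(pi) - np.log(q)) for pi, q in zip(row, marginal))
        expected = np.exp(kl / len(raw))
        assert got == pytest.approx(expected, abs=1e-6)
        assert 1.0 <= got <= 4.0

    def test_row_order_invariance(self):
        raw = RNG.uniform(0.01, 1.0, size=(9, 3))
        raw /= raw.sum(axis=1, keepdims=True)
        a = ev.inception_score(ev.ProbSet(raw))
        b = ev.inception_score(ev.ProbSet(raw[::-1]))
        assert a == pytest.approx(b)

    def test_invalid_probs_rejected(self):
        with pytest.raises(ValueError):
            ev.ProbSet(np.zeros((3, 4)))


class TestModeScore:
    def test_uniform_match_gives_one(self):
        p = ev.ProbSet(np.full((8, 4), 0.25))
        assert ev.mode_score(p, p) == pytest.approx(1.0)

    def test_reduces_to_is_under_matched_marginals(self):
        raw = RNG.uniform(0.01, 1.0, size=(10, 4))
        raw /= raw.sum(axis=1, keepdims=True)
        p_fake = ev.ProbSet(raw)
        # real set with the same marginal: the fake rows permuted
        p_real = ev.ProbSet(raw[::-1].copy())
        assert ev.mode_score(p_fake, p_real) == pytest.approx(
            ev.inception_score(p_fake, 1), abs=1e-9)

    def test_matches_direct_kl_computation(self):
        rf = RNG.uniform(0.01, 1.0, size=(8, 3))
        rf /= rf.sum(axis=1, keepdims=True)
        rr = RNG.uniform(0.01, 1.0, size=(6, 3))
        rr /= rr.sum(axis=1, keepdims=True)
        got = ev.mode_score(ev.ProbSet(rf), ev.ProbSet(rr))
        mstar = rr.mean(axis=0)
        mbar = rf.mean(axis=0)
        kl = np.mean([(row * (np.log(row) - np.log(mstar))).sum() for row in rf])
        kl2 = (mbar * (np.log(mbar) - np.log(mstar))).sum()
        assert got == pytest.approx(np.exp(kl - kl2), abs=1e-6)


def _class_fixture(n_per_class, n_classes=4, size=16, seed=0, noise=0.02):
    rng = np.random.default_rng(seed)
    tiles, labels = [], []
    count = 0
    while min((labels.count(k) for k in range(n_classes)), default=0) < n_per_class:
        geom = synthetic.generate_geometry(size, size, 8.0, n_classes,
                                           int(rng.integers(2 ** 31)))
        params = synthetic.RenderParams(noise_sd=noise,
                                        noise_seed=int(rng.integers(2 ** 31)))
        tiles.append(synthetic.render_stained(geom, params))
        labels.append(geom.tumor_class)
        count += 1
        if count > 50 * n_per_class * n_classes:
            raise RuntimeError("fixture generation stalled")
    return tiles, np.array(labels)


class TestClassifierHarness:
    def test_two_class_separable_fixture_perfect_train_accuracy(self):
        rng = np.random.default_rng(0)
        tiles, labels = [], []
        for i in range(40):
            color = (0.9, 0.1, 0.1) if i % 2 else (0.1, 0.1, 0.9)
            arr = np.clip(np.full((16, 16, 3), color)
                          + rng.normal(0, 0.02, (16, 16, 3)), 0, 1)
            tiles.append(ImageTile(arr, "stained"))
            labels.append(i % 2)
        clf = ev.TileClassifier(epochs=20, random_state=0).fit(tiles, labels)
        assert clf.score(tiles, labels) == 1.0

    def test_seeded_rerun_reproduces_accuracy(self):
        tiles, labels = _class_fixture(6, seed=3)
        a = ev.TileClassifier(epochs=10, random_state=1).fit(tiles, labels)
        b = ev.TileClassifier(epochs=10, random_state=1).fit(tiles, labels)
        assert a.score(tiles, labels) == b.score(tiles, labels)
        assert np.array_equal(a.predict(tiles), b.predict(tiles))

    def test_beats_nearest_centroid_oracle(self):
        tiles, labels = _class_fixture(8, seed=5)
        clf = ev.TileClassifier(epochs=40, random_state=0).fit(tiles, labels)
        X = np.stack([t.data.mean(axis=(0, 1)) for t in tiles])
        centroids = np.stack([X[labels == k].mean(axis=0) for k in range(4)])
        pred = np.argmin(((X[:, None, :] - centroids[None]) ** 2).sum(-1), axis=1)
        centroid_acc = np.mean(pred == labels)
        assert clf.score(tiles, labels) >= centroid_acc - 1e-9

    def test_single_class_rejected(self):
        tiles, _ = _class_fixture(2, n_classes=1, seed=1)
        with pytest.raises(ValueError):
            ev.TileClassifier(epochs=1).fit(tiles, [0] * len(tiles))


class TestVisualSimulation:
    def test_identity_passthrough_equals_real_accuracy(self):
        tiles, labels = _class_fixture(6, seed=9)
        clf = ev.TileClassifier(epochs=30, random_state=0).fit(tiles, labels)
        acc_real = clf.score(tiles, labels)
        acc_vis = ev.visual_simulation_accuracy(clf, tiles, labels)
        assert acc_vis == pytest.approx(acc_real)

    def test_empty_and_mismatch_rejected(self):
        tiles, labels = _class_fixture(2, seed=2)
        clf = ev.TileClassifier(epochs=2, random_state=0).fit(tiles, labels)
        with pytest.raises(ValueError):
            ev.visual_simulation_accuracy(clf, [], [])
        with pytest.raises(ValueError):
            ev.visual_simulation_accuracy(clf, tiles, labels[:-1])
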