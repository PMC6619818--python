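"""Kernel learning, split search, tree growth, boosting, self-training."""

import itertools

import numpy as np
import pytest

from clawtrack.imaging_io import SilhouetteMask
from clawtrack.kernel_boost import (
    ConvKernel,
    TrainingConfig,
    _grid_laplacian,
    _windows,
    find_best_split,
    fit_classifier,
    grow_tree,
    learn_kernel,
    load_classifier,
    predict_confidence,
    save_classifier,
    self_train,
)
from conftest import texture_patches


def _random_patches(n, rng):
    return rng.normal(0.5, 0.2, size=(n, 41, 41)).astype(np.float32)


def _mean_kernel(size, anchor):
    """Kernel whose response is the mean of its window (handy for oracles)."""
    return ConvKernel(np.full((size, size), 1.0 / size**2), anchor)


class TestLearnKernel:
    def test_satisfies_normal_equations(self):
        rng = np.random.default_rng(0)
        patches = _random_patches(300, rng)
        w = rng.uniform(0.5, 2.0, 300)
        r = rng.normal(0, 1, 300)
        for size, anchor, lam in [(4, (0, 0), 100.0), (9, (10, 15), 500.0), (19, (22, 3), 1000.0)]:
            k = learn_kernel(patches, w, r, size, anchor, lam)
            A = _windows(patches, size, anchor).astype(np.float64)
            G = (A * w[:, None]).T @ A + lam * _grid_laplacian(size)
            b = (A * w[:, None]).T @ r
            resid = G @ k.weights.ravel() - b
            assert np.linalg.norm(resid) < 1e-6 * (np.linalg.norm(G) * np.linalg.norm(k.weights) + np.linalg.norm(b))

    def test_lambda_zero_matches_dense_least_squares(self):
        rng = np.random.default_rng(1)
        size = 5
        n = 80  # > size**2 independent rows
        patches = _random_patches(n, rng)
        w = rng.uniform(0.5, 2.0, n)
        r = rng.normal(0, 1, n)
        k = learn_kernel(patches, w, r, size, (7, 7), 0.0)
        A = _windows(patches, size, (7, 7)).astype(np.float64)
        sw = np.sqrt(w)
        oracle, *_ = np.linalg.lstsq(A * sw[:, None], r * sw, rcond=None)
        np.testing.assert_allclose(k.weights.ravel(), oracle, rtol=1e-6, atol=1e-8)

    def test_huge_lambda_forces_constant_kernel(self):
        rng = np.random.default_rng(2)
        patches = _random_patches(200, rng)
        w = np.ones(200)
        r = rng.normal(0, 1, 200)
        k = learn_kernel(patches, w, r, 8, (5, 5), 1e9)
        spread = np.ptp(k.weights) / (np.abs(k.weights).max() + 1e-30)
        assert spread < 1e-4

    def test_zero_residuals_give_zero_kernel(self):
        rng = np.random.default_rng(3)
        patches = _random_patches(50, rng)
        k = learn_kernel(patches, np.ones(50), np.zeros(50), 6, (0, 0), 500.0)
        np.testing.assert_allclose(k.weights, 0.0, atol=1e-10)


def _patches_with_responses(values):
    """Constant patches: every mean kernel's response equals the value."""
    n = len(values)
    patches = np.zeros((n, 41, 41), dtype=np.float32)
    for i, v in enumerate(values):
        patches[i] = v
    return patches


class TestFindBestSplit:
    def test_perfectly_separable_node(self):
        patches = _patches_with_responses([1, 2, 9, 10])
        r = np.array([-1.0, -1.0, 1.0, 1.0])
        dec = find_best_split(patches, np.ones(4), r, [_mean_kernel(4, (0, 0))])
        assert 2 < dec.tau < 9
        assert dec.eta_left == pytest.approx(-1.0)
        assert dec.eta_right == pytest.approx(1.0)
        assert dec.cost == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(4)
        patches = _random_patches(50, rng)
        w = rng.uniform(0.2, 3.0, 50)
        r = rng.normal(0, 1, 50)
        cands = [
            ConvKernel(rng.normal(0, 1, (s, s)), (int(a), int(b)))
            for s, a, b in zip([4, 7, 11], [0, 5, 20], [3, 9, 12])
        ]
        dec = find_best_split(patches, w, r, cands)

        best = np.inf
        for kern in cands:
            resp = _windows(patches, kern.size, kern.anchor) @ kern.weights.ravel().astype(np.float32)
            for tau in np.sort(resp)[:-1] + np.diff(np.sort(resp)) / 2:
                left = resp < tau
                if not left.any() or left.all():
                    continue
                eta_l = np.sum(w[left] * r[left]) / np.sum(w[left])
                eta_r = np.sum(w[~left] * r[~left]) / np.sum(w[~left])
                c = np.sum(w[left] * (eta_l - r[left]) ** 2) + np.sum(
                    w[~left] * (eta_r - r[~left]) ** 2
                )
                best = min(best, c)
        assert dec.cost == pytest.approx(best, rel=1e-9)

    def test_cost_homogeneous_in_weights(self):
        rng = np.random.default_rng(5)
        patches = _random_patches(30, rng)
        w = rng.uniform(0.5, 2.0, 30)
        r = rng.normal(0, 1, 30)
        cands = [ConvKernel(rng.normal(0, 1, (5, 5)), (3, 3))]
        d1 = find_best_split(patches, w, r, cands)
        d2 = find_best_split(patches, 2 * w, r, cands)
        assert d2.tau == pytest.approx(d1.tau)
        assert d2.cost == pytest.approx(2 * d1.cost, rel=1e-9)


class TestGrowTree:
    def test_depth_cap(self):
        rng = np.random.default_rng(6)
        patches = _random_patches(300, rng)
        r = rng.choice([-1.0, 1.0], 300)
        idx = rng.permutation(300)
        tree = grow_tree(patches, np.ones(300), r, idx[:100], idx[100:],
                         np.random.default_rng(0), max_depth=5, n_candidates=5,
                         min_node_size=5)
        assert tree.depth() <= 5

    def test_separable_data_gives_pure_sides(self):
        # responses split perfectly at depth 1: every leaf on a side carries
        # that side's residual, so the tree predicts +/-1 exactly
        vals = np.concatenate([np.linspace(0, 0.2, 40), np.linspace(0.8, 1.0, 40)])
        patches = _patches_with_responses(vals)
        r = np.concatenate([-np.ones(40), np.ones(40)])
        idx = np.arange(80)
        tree = grow_tree(patches, np.ones(80), r, idx, idx,
                         np.random.default_rng(1), max_depth=5, n_candidates=30,
                         min_node_size=5, max_fit_samples=None)
        pred = tree.predict_patches(patches)
        np.testing.assert_allclose(pred, r, atol=1e-9)

    def test_deep_tree_beats_stump_on_textures(self):
        train = texture_patches(80, np.random.default_rng(7))
        kw = dict(n_candidates=15, min_node_size=10, max_fit_samples=None)
        idx = np.random.default_rng(2).permutation(len(train))
        t1, t2 = idx[:60], idx[60:]
        deep = grow_tree(train.patches, train.weights, train.residuals, t1, t2,
                         np.random.default_rng(3), max_depth=5, **kw)
        stump = grow_tree(train.patches, train.weights, train.residuals, t1, t2,
                          np.random.default_rng(3), max_depth=1, **kw)
        y = train.residuals
        sse_deep = np.sum((deep.predict_patches(train.patches) - y) ** 2)
        sse_stump = np.sum((stump.predict_patches(train.patches) - y) ** 2)
        assert sse_deep < sse_stump


class TestBoosting:
    def test_separable_toy_reaches_zero_training_error(self):
        rng = np.random.default_rng(8)
        n = 60
        patches = np.full((2 * n, 41, 41), 0.5, dtype=np.float32)
        patches[:n, 15:26, 15:26] = 0.9  # bright centres -> +1
        patches[n:, 15:26, 15:26] = 0.1  # dark centres -> -1
        patches += rng.normal(0, 0.02, patches.shape).astype(np.float32)
        from clawtrack.training_harvest import TrainingPatchSet

        labels = np.concatenate([np.ones(n, np.int8), -np.ones(n, np.int8)])
        train = TrainingPatchSet(patches, labels, np.ones(2 * n), labels.astype(float))
        clf = fit_classifier(train, n_rounds=20, t1_size=40, n_candidates=10,
                             min_node_size=10, rng=np.random.default_rng(0))
        scores = clf.decision_scores(patches)
        assert np.all(np.sign(scores) == labels)

    def test_loss_log_monotone_non_increasing(self):
        train = texture_patches(60, np.random.default_rng(9))
        clf = fit_classifier(train, n_rounds=15, t1_size=40, n_candidates=8,
                             min_node_size=10, rng=np.random.default_rng(1))
        log = np.asarray(clf.training_log)
        assert np.all(np.diff(log) <= 1e-9)

    def test_zero_shrinkage_gives_zero_scores(self):
        train = texture_patches(30, np.random.default_rng(10))
        clf = fit_classifier(train, n_rounds=3, gamma=0.0, t1_size=20,
                             n_candidates=5, min_node_size=10,
                             rng=np.random.default_rng(2))
        assert np.allclose(clf.decision_scores(train.patches), 0.0)

    def test_serialization_roundtrip(self, tmp_path):
        train = texture_patches(30, np.random.default_rng(11))
        clf = fit_classifier(train, n_rounds=4, t1_size=20, n_candidates=5,
                             min_node_size=10, rng=np.random.default_rng(3))
        path = tmp_path / "clf.npz"
        save_classifier(clf, path)
        clf2 = load_classifier(path)
        np.testing.assert_allclose(
            clf.decision_scores(train.patches), clf2.decision_scores(train.patches)
        )


class TestPrediction:
    def test_empty_mask_gives_all_zero_map(self):
        train = texture_patches(20, np.random.default_rng(12))
        clf = fit_classifier(train, n_rounds=2, t1_size=15, n_candidates=4,
                             min_node_size=8, rng=np.random.default_rng(4))
        frame = np.random.default_rng(0).integers(0, 255, (64, 64)).astype(np.uint8)
        conf = predict_confidence(clf, frame, SilhouetteMask(np.zeros((64, 64), bool), 0))
        assert not conf.values.any()

    def test_values_within_unit_interval(self):
        train = texture_patches(20, np.random.default_rng(13))
        clf = fit_classifier(train, n_rounds=3, t1_size=15, n_candidates=4,
                             min_node_size=8, rng=np.random.default_rng(5))
        frame = np.random.default_rng(1).integers(0, 255, (64, 64)).astype(np.uint8)
        mask = np.zeros((64, 64), bool)
        mask[10:50, 10:50] = True
        conf = predict_confidence(clf, frame, SilhouetteMask(mask, 0))
        vals = conf.values[mask]
        assert np.all((vals >= 0) & (vals <= 1))
        assert np.all(conf.values[~mask] == 0)


@pytest.fixture(scope="module")
def tiny_setup(walker_small):
    import clawtrack as ct
    from clawtrack.training_harvest import sample_training_frames

    params, stack, truth = walker_small
    bg = ct.estimate_background(
        stack, "loaded", background=np.full(stack.shape, 200.0)
    )
    ids = sample_training_frames(stack, 20)
    masks = [
        ct.extract_silhouette(stack.frames[i], bg, "auto", frame_index=i)
        for i in ids
    ]
    cfg = TrainingConfig(
        n_pos=400, n_neg=400, t1_size=200, n_rounds=5, n_candidates=8,
        max_fit_samples=300, seed=0,
    )
    return stack, masks, cfg


class TestSelfTrain:

    def test_single_round_equals_plain_fit(self, tiny_setup):
        import clawtrack as ct
        from clawtrack.training_harvest import extract_patches, harvest_confident_pixels
        from clawtrack.training_harvest import LabeledPixelPool

        stack, masks, cfg = tiny_setup
        clf, _ = self_train(stack, masks, rounds=1, config=cfg,
                            rng=np.random.default_rng(42))
        # replay the identical sequence of RNG-consuming steps by hand
        rng = np.random.default_rng(42)
        pool = LabeledPixelPool()
        for m in masks:
            pool.extend(harvest_confident_pixels(m, stack.frames[m.frame_index], rng=rng))
        train = extract_patches(pool, stack, cfg.n_pos, cfg.n_neg, rng=rng)
        ref = fit_classifier(train, n_rounds=cfg.n_rounds, t1_size=cfg.t1_size,
                             n_candidates=cfg.n_candidates,
                             min_node_size=cfg.min_node_size,
                             max_fit_samples=cfg.max_fit_samples, rng=rng)
        assert clf.training_log == ref.training_log

    def test_pools_grow_monotonically(self, tiny_setup):
        stack, masks, cfg = tiny_setup
        clf, pool_sizes = self_train(stack, masks, rounds=2, config=cfg,
                                     rng=np.random.default_rng(7))
        assert len(pool_sizes) >= 1
        for (p0, n0), (p1, n1) in zip(pool_sizes, pool_sizes[1:]):
            assert p1 >= p0 and n1 >= n0
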