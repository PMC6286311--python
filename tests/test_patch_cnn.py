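"""Patch classifier: architecture arithmetic, forward-pass oracle,
training behavior, hard-example mining and probability-map rendering."""

import numpy as np
import pytest

from lilack import _nn
from lilack.colony_sim import (
    LABEL_DIFF,
    LABEL_UNDIFF,
    ImageFrame,
    PatchSet,
    extract_patches,
)
from lilack.patch_cnn import (
    CnnArch,
    PatchCNNClassifier,
    TrainHyper,
    build_model,
    false_differentiated_count,
    mine_hard_examples,
    predict_map,
    train_round,
    train_with_mining,
)


def _texture_patches(n_per_class: int, seed: int, p: int = 70) -> PatchSet:
    """Two separable texture classes: fine high-contrast noise (class 0)
    vs coarse low-contrast noise (class 1)."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    imgs, labels = [], []
    for _ in range(n_per_class):
        imgs.append(1000 + 400 * rng.standard_normal((p, p)))
        labels.append(LABEL_UNDIFF)
    for _ in range(n_per_class):
        coarse = ndimage.gaussian_filter(rng.standard_normal((p, p)), 4.0)
        imgs.append(1200 + 150 * coarse / max(coarse.std(), 1e-9))
        labels.append(LABEL_DIFF)
    return PatchSet(np.stack(imgs), np.asarray(labels),
                    np.zeros((2 * n_per_class, 2), dtype=int), p)


class TestArchitecture:
    def test_size_chain_70_to_10(self):
        """Valid convolutions with pool stride = pool kernel walk
        70 -> 66 -> 22 -> 20 -> 10; the head sees 10*10*32 = 3200 units."""
        arch = CnnArch()
        assert arch.size_chain() == [70, 66, 22, 20, 10]
        assert arch.fc_inputs() == 3200

    def test_forward_probabilities_normalized(self):
        clf = build_model(seed=0)
        rng = np.random.default_rng(1)
        probs = clf.predict_proba(rng.normal(size=(5, 70, 70)))
        assert probs.shape == (5, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all() and (probs <= 1).all()

    def test_same_seed_same_initial_weights(self):
        a, b = build_model(seed=42), build_model(seed=42)
        for k in a.weights_:
            assert np.array_equal(a.weights_[k], b.weights_[k])
        c = build_model(seed=43)
        assert not np.array_equal(a.weights_["W1"], c.weights_["W1"])

    def test_nonstandard_input_size_rejected_unless_overridden(self):
        with pytest.raises(ValueError, match="input_px"):
            PatchCNNClassifier(input_px=64).initialize()
        clf = PatchCNNClassifier(input_px=64, allow_input_px_override=True)
        clf.initialize()
        assert clf.arch_.size_chain()[0] == 64


class TestForwardOracle:
    """A 1-filter, 1-layer reduction of the forward pass must match a
    direct brute-force convolution + max + softmax computation."""

    def test_conv_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 9, 9, 1)).astype(np.float32)
        w = rng.normal(size=(3, 3, 1, 1)).astype(np.float32)
        y, _ = _nn.conv_forward(x, w, np.zeros(1, dtype=np.float32))
        brute = np.zeros((2, 7, 7, 1))
        for n in range(2):
            for i in range(7):
                for j in range(7):
                    brute[n, i, j, 0] = (x[n, i : i + 3, j : j + 3, 0] * w[:, :, 0, 0]).sum()
        assert np.allclose(y, brute, atol=1e-6)

    def test_pool_and_softmax_match_bruteforce(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, 6, 6, 1)).astype(np.float32)
        y, _ = _nn.maxpool_forward(x, 3)
        brute = np.zeros((1, 2, 2, 1))
        for i in range(2):
            for j in range(2):
                brute[0, i, j, 0] = x[0, 3 * i : 3 * i + 3, 3 * j : 3 * j + 3, 0].max()
        assert np.allclose(y, brute, atol=1e-6)
        logits = rng.normal(size=(4, 2))
        p = _nn.softmax(logits)
        brute_p = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        assert np.allclose(p, brute_p, atol=1e-6)

    def test_conv_gradients_match_finite_differences(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(2, 6, 6, 2)).astype(np.float64)
        w = rng.normal(size=(3, 3, 2, 2)).astype(np.float64)
        b = rng.normal(size=2)
        y, cache = _nn.conv_forward(x, w, b)
        g = rng.normal(size=y.shape)
        dx, dw, db = _nn.conv_backward(g, cache)
        eps = 1e-6
        for idx in [(0, 0, 0, 0), (2, 1, 1, 1), (1, 2, 0, 1)]:
            wp = w.copy(); wp[idx] += eps
            wm = w.copy(); wm[idx] -= eps
            num = ((_nn.conv_forward(x, wp, b)[0] - _nn.conv_forward(x, wm, b)[0]) * g).sum() / (2 * eps)
            assert np.isclose(dw[idx], num, rtol=1e-4)
        for idx in [(0, 1, 1, 0), (1, 4, 3, 1)]:
            xp = x.copy(); xp[idx] += eps
            xm = x.copy(); xm[idx] -= eps
            num = ((_nn.conv_forward(xp, w, b)[0] - _nn.conv_forward(xm, w, b)[0]) * g).sum() / (2 * eps)
            assert np.isclose(dx[idx], num, rtol=1e-4)


class TestTraining:
    def test_separable_textures_high_heldout_accuracy(self):
        train = _texture_patches(200, seed=0)
        test = _texture_patches(60, seed=99)
        clf = PatchCNNClassifier(epochs=3, seed=1).fit(train.images, train.labels)
        acc = (clf.predict(test.images) == test.labels).mean()
        assert acc > 0.95
        # per-epoch loss is logged and decreases over the round
        assert clf.loss_history_[-1] < clf.loss_history_[0]

    def test_permuted_labels_give_chance_accuracy(self):
        train = _texture_patches(100, seed=3)
        rng = np.random.default_rng(0)
        y_perm = rng.permutation(train.labels)
        clf = PatchCNNClassifier(epochs=3, seed=1).fit(train.images, y_perm)
        test = _texture_patches(100, seed=4)
        acc = (clf.predict(test.images) == test.labels).mean()
        assert abs(acc - 0.5) < 0.2  # binomial noise around chance

    def test_duplicated_patches_remain_numerically_stable(self):
        train = _texture_patches(40, seed=5)
        dup = train.concat(train)
        clf = PatchCNNClassifier(epochs=2, seed=1).fit(dup.images, dup.labels)
        assert np.isfinite(clf.loss_history_).all()

    def test_single_class_rejected(self):
        train = _texture_patches(10, seed=6)
        only = train.labels == LABEL_UNDIFF
        with pytest.raises(ValueError, match="both classes"):
            PatchCNNClassifier(epochs=1, seed=0).fit(
                train.images[only], train.labels[only]
            )

    def test_fit_is_deterministic_under_seed(self):
        train = _texture_patches(30, seed=7)
        a = PatchCNNClassifier(epochs=2, seed=9).fit(train.images, train.labels)
        b = PatchCNNClassifier(epochs=2, seed=9).fit(train.images, train.labels)
        for k in a.weights_:
            assert np.array_equal(a.weights_[k], b.weights_[k])

    def test_sklearn_param_interface(self):
        clf = PatchCNNClassifier()
        params = clf.get_params()
        assert params["epochs"] == 10 and params["batch_size"] == 32
        clf.set_params(epochs=2)
        assert clf.epochs == 2


class TestMining:
    def test_perfect_model_mines_nothing(self, small_field, tiny_clf):
        phase, _, mask, _ = small_field
        mined = mine_hard_examples(tiny_clf, [(phase, mask)])
        grid = extract_patches(phase, mask, policy="grid_nonoverlap")
        n_undiff = int((grid.labels == LABEL_UNDIFF).sum())
        # the trained model misses at most a handful of training patches
        assert len(mined) <= 0.1 * n_undiff

    def test_always_differentiated_model_mines_all_undifferentiated(self, small_field):
        phase, _, mask, _ = small_field

        class AlwaysDiff:
            input_px = 70

            def predict(self, X):
                return np.full(len(X), LABEL_DIFF)

        mined = mine_hard_examples(AlwaysDiff(), [(phase, mask)])
        grid = extract_patches(phase, mask, policy="grid_nonoverlap")
        assert len(mined) == int((grid.labels == LABEL_UNDIFF).sum())
        assert (mined.labels == LABEL_UNDIFF).all()

    def test_round2_does_not_increase_false_differentiated_rate(
        self, small_field, small_field_holdout, fast_hyper
    ):
        """Paired comparison of the mining schedule on held-out frames."""
        phase, _, mask, _ = small_field
        ph_h, _, mask_h, _ = small_field_holdout
        pset = extract_patches(phase, mask, policy="random",
                               n_random=fast_hyper.n_patches,
                               seed=fast_hyper.seed)
        clf = PatchCNNClassifier(epochs=fast_hyper.epochs, seed=fast_hyper.seed)
        clf.fit(pset.images, pset.labels)
        fd_round1 = false_differentiated_count(clf, [(ph_h, mask_h)])
        mined = mine_hard_examples(clf, [(phase, mask)])
        if len(mined):
            pset = pset.concat(mined)
        clf.set_params(warm_start=True)
        clf.fit(pset.images, pset.labels)
        fd_round2 = false_differentiated_count(clf, [(ph_h, mask_h)])
        assert fd_round2 <= fd_round1

    def test_train_with_mining_completes_and_logs_rounds(self, tiny_clf):
        assert len(tiny_clf.training_log_["rounds"]) == 2
        assert "n_mined" in tiny_clf.training_log_

    def test_train_with_mining_deterministic(self, small_field, fast_hyper):
        phase, _, mask, _ = small_field
        again = train_with_mining([(phase, mask)], fast_hyper)
        ref = train_with_mining([(phase, mask)], fast_hyper)
        for k in ref.weights_:
            assert np.array_equal(again.weights_[k], ref.weights_[k])


class TestPredictMap:
    def test_map_range_and_geometry(self, tiny_clf, small_field_holdout):
        phase, _, _, _ = small_field_holdout
        pm = predict_map(tiny_clf, phase, stride_px=70)
        assert pm.probs.shape == phase.shape
        assert pm.probs.min() >= 0 and pm.probs.max() <= 1

    def test_map_piecewise_constant_on_grid_blocks(self, tiny_clf, small_field_holdout):
        phase, _, _, _ = small_field_holdout
        pm = predict_map(tiny_clf, phase, stride_px=70)
        # each full 70x70 block carries a single value
        block = pm.probs[:70, :70]
        assert np.ptp(block) == 0
        # margins replicate the nearest covered block
        h, w = phase.shape
        assert np.allclose(pm.probs[h - 1, :], pm.probs[(h // 70) * 70 - 1, :])

    def test_good_model_scores_undifferentiated_texture_low(
        self, tiny_clf, small_field_holdout
    ):
        phase, _, mask, _ = small_field_holdout
        pm = predict_map(tiny_clf, phase, stride_px=70)
        grid = extract_patches(phase, mask, policy="grid_nonoverlap")
        undiff = grid.origins[grid.labels == LABEL_UNDIFF]
        vals = np.array([pm.probs[r + 35, c + 35] for r, c in undiff])
        assert (vals < 0.5).mean() > 0.9

    def test_rejects_fluorescence_frames(self, tiny_clf, small_field):
        _, fluor, _, _ = small_field
        with pytest.raises(ValueError, match="phase"):
            predict_map(tiny_clf, fluor)

    def test_frame_smaller_than_patch_rejected(self, tiny_clf):
        small = ImageFrame(np.zeros((50, 50)), "phase", 1.0)
        with pytest.raises(ValueError, match="smaller"):
            predict_map(tiny_clf, small)


class TestPersistence:
    def test_save_load_roundtrip(self, tiny_clf, tmp_path):
        tiny_clf.save(tmp_path / "model")
        loaded = PatchCNNClassifier.load(tmp_path / "model")
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 70, 70))
        assert np.allclose(tiny_clf.predict_proba(x), loaded.predict_proba(x))
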