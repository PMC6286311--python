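"""Patch classifier for differentiated-region detection in phase-contrast frames.

A small convolutional network classifies 70x70-pixel crops as
differentiated vs undifferentiated: two valid convolutions (32 filters of
5x5 then 3x3, ReLU), max pooling (3x3 then 2x2, stride = kernel) and a
fully connected layer to two softmax logits trained with cross entropy.
Deployment is label-free: only the phase channel is ever classified; the
fluorescence channel exists solely to construct training labels.

Training follows a two-round hard-example-mining schedule: train on
randomly cropped patches, collect the undifferentiated patches the model
misclassifies as differentiated, add them to the training set and train
again.  The second-round model is the deployed classifier.

``PatchCNNClassifier`` follows scikit-learn estimator conventions
(``fit``/``predict``/``predict_proba``, ``get_params``/``set_params``,
fitted attributes with trailing underscores) and composes with sklearn
model-selection utilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import _nn
from .colony_sim import (
    LABEL_DIFF,
    LABEL_UNDIFF,
    ImageFrame,
    LabelMask,
    PatchSet,
    extract_patches,
)


@dataclass(frozen=True)
class CnnArch:
    """The fixed layer chain of the patch classifier."""

    input_px: int = 70
    conv1_filters: int = 32
    conv1_kernel: int = 5
    pool1_kernel: int = 3
    conv2_filters: int = 32
    conv2_kernel: int = 3
    pool2_kernel: int = 2
    n_classes: int = 2

    def size_chain(self) -> list[int]:
        """Spatial side length after each layer: input, conv1, pool1, conv2, pool2."""
        s = self.input_px
        chain = [s]
        s = s - (self.conv1_kernel - 1)
        chain.append(s)
        s = s // self.pool1_kernel
        chain.append(s)
        s = s - (self.conv2_kernel - 1)
        chain.append(s)
        s = s // self.pool2_kernel
        chain.append(s)
        if chain[-1] < 1:
            raise ValueError(f"input {self.input_px} px is too small for the chain")
        return chain

    def fc_inputs(self) -> int:
        return self.size_chain()[-1] ** 2 * self.conv2_filters


@dataclass(frozen=True)
class TrainHyper:
    """Training hyper-parameters (optimizer choice, schedule, sampling)."""

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 10
    class_balance: str = "balanced"  # "balanced" | "none"
    n_patches: int = 320  # random patches per training frame (split over classes)
    purity_threshold: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("learning rate, batch size and epochs must be positive")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.class_balance not in ("balanced", "none"):
            raise ValueError(f"unknown class_balance {self.class_balance!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class ProbabilityMap:
    """Per-pixel probability of the differentiated class, in [0, 1]."""

    probs: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2:
            raise ValueError("probs must be 2-D")
        if self.probs.size and (self.probs.min() < 0 or self.probs.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")


class PatchCNNClassifier(ClassifierMixin, BaseEstimator):
    """Two-conv-layer patch CNN with softmax cross-entropy training.

    Parameters mirror :class:`TrainHyper`; the architecture is fixed to
    the 70->66->22->20->10 chain unless ``input_px`` is overridden
    together with ``allow_input_px_override=True``.
    """

    def __init__(self, input_px: int = 70, optimizer: str = "adam",
                 learning_rate: float = 1e-3, batch_size: int = 32,
                 epochs: int = 10, class_balance: str = "balanced",
                 warm_start: bool = False, seed: int = 0,
                 allow_input_px_override: bool = False):
        self.input_px = input_px
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.class_balance = class_balance
        self.warm_start = warm_start
        self.seed = seed
        self.allow_input_px_override = allow_input_px_override

    # -- construction -------------------------------------------------------

    def _arch(self) -> CnnArch:
        if self.input_px != 70 and not self.allow_input_px_override:
            raise ValueError(
                "input_px is fixed at 70; pass allow_input_px_override=True to change it"
            )
        return CnnArch(input_px=self.input_px)

    def initialize(self) -> "PatchCNNClassifier":
        """Draw fresh He-normal weights from ``seed`` (untrained model)."""
        arch = self._arch()
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 0xC0]))

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

        k1, f1 = arch.conv1_kernel, arch.conv1_filters
        k2, f2 = arch.conv2_kernel, arch.conv2_filters
        self.weights_ = {
            "W1": he((k1, k1, 1, f1), k1 * k1),
            "b1": np.zeros(f1, dtype=np.float32),
            "W2": he((k2, k2, f1, f2), k2 * k2 * f1),
            "b2": np.zeros(f2, dtype=np.float32),
            "W3": he((arch.fc_inputs(), arch.n_classes), arch.fc_inputs()),
            "b3": np.zeros(arch.n_classes, dtype=np.float32),
        }
        self.arch_ = arch
        self.classes_ = np.array([LABEL_UNDIFF, LABEL_DIFF])
        self.loss_history_ = []
        self.training_log_ = {"rounds": []}
        return self

    # -- forward / backward -------------------------------------------------

    @staticmethod
    def _standardize(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        mu = x.mean(axis=(1, 2), keepdims=True)
        sd = x.std(axis=(1, 2), keepdims=True)
        return (x - mu) / np.maximum(sd, 1e-6)

    def _forward(self, xb: np.ndarray, want_cache: bool = False):
        w = self.weights_
        x = xb[..., None]  # NHWC with C=1
        z1, c1 = _nn.conv_forward(x, w["W1"], w["b1"])
        a1, m1 = _nn.relu_forward(z1)
        p1, cp1 = _nn.maxpool_forward(a1, self.arch_.pool1_kernel)
        z2, c2 = _nn.conv_forward(p1, w["W2"], w["b2"])
        a2, m2 = _nn.relu_forward(z2)
        p2, cp2 = _nn.maxpool_forward(a2, self.arch_.pool2_kernel)
        flat = p2.reshape(len(xb), -1)
        logits = flat @ w["W3"] + w["b3"]
        if not want_cache:
            return logits, None
        return logits, (c1, m1, cp1, c2, m2, cp2, flat, p2.shape)

    def _backward(self, dlogits: np.ndarray, cache):
        c1, m1, cp1, c2, m2, cp2, flat, p2_shape = cache
        w = self.weights_
        grads = {
            "W3": flat.T @ dlogits,
            "b3": dlogits.sum(axis=0),
        }
        dflat = dlogits @ w["W3"].T
        dp2 = dflat.reshape(p2_shape)
        da2 = _nn.maxpool_backward(dp2, cp2)
        dz2 = _nn.relu_backward(da2, m2)
        dp1, grads["W2"], grads["b2"] = _nn.conv_backward(dz2, c2)
        da1 = _nn.maxpool_backward(dp1, cp1)
        dz1 = _nn.relu_backward(da1, m1)
        _, grads["W1"], grads["b1"] = _nn.conv_backward(dz1, c1, need_dx=False)
        return grads

    # -- sklearn API --------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PatchCNNClassifier":
        """Train one round of the schedule on (n, p, p) patches.

        With ``warm_start=True`` a fitted model continues from its current
        weights (used for the hard-example round); otherwise weights are
        re-initialized from ``seed``.
        """
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 3 or X.shape[1] != self.input_px or X.shape[2] != self.input_px:
            raise ValueError(f"X must be (n, {self.input_px}, {self.input_px})")
        present = np.unique(y)
        if not np.isin(present, [LABEL_UNDIFF, LABEL_DIFF]).all():
            raise ValueError("labels must be 0 (undifferentiated) or 1 (differentiated)")
        if len(present) < 2:
            raise ValueError("training patches must contain both classes")

        if not (self.warm_start and hasattr(self, "weights_")):
            self.initialize()
        round_idx = len(self.training_log_["rounds"])
        rng = np.random.default_rng(
            np.random.SeedSequence([int(self.seed), 0x5F, round_idx])
        )

        xs = self._standardize(X)
        n = len(xs)
        if self.class_balance == "balanced":
            counts = np.bincount(y, minlength=2).astype(np.float64)
            cw = n / (2.0 * np.maximum(counts, 1))
        else:
            cw = np.ones(2)
        sw_all = cw[y].astype(np.float32)

        opt_cls = _nn.Adam if self.optimizer == "adam" else _nn.MomentumSGD
        opt = opt_cls(self.weights_, lr=self.learning_rate)

        losses = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            wtot = 0.0
            for start in range(0, n, self.batch_size):
                sel = order[start : start + self.batch_size]
                logits, cache = self._forward(xs[sel], want_cache=True)
                loss, dlogits = _nn.softmax_xent(logits, y[sel], sw_all[sel])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged (non-finite loss) in round {round_idx}, "
                        f"batch starting at {start}; lower the learning rate"
                    )
                grads = self._backward(dlogits.astype(np.float32), cache)
                opt.step(grads)
                bw = float(sw_all[sel].sum())
                epoch_loss += loss * bw
                wtot += bw
            losses.append(epoch_loss / wtot)
        self.loss_history_.extend(losses)
        self.training_log_["rounds"].append(
            {"n_patches": int(n), "epoch_loss": [float(v) for v in losses]}
        )
        self.n_features_in_ = self.input_px * self.input_px
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "weights_")
        xs = self._standardize(np.asarray(X))
        out = []
        for start in range(0, len(xs), 256):
            logits, _ = self._forward(xs[start : start + 256])
            out.append(_nn.softmax(logits.astype(np.float64)))
        return np.concatenate(out) if out else np.zeros((0, 2))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write weights (npz) plus a JSON sidecar with arch and hypers."""
        check_is_fitted(self, "weights_")
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.weights_)
        sidecar = {
            "arch": self.arch_.__dict__,
            "params": self.get_params(),
            "loss_history": [float(v) for v in self.loss_history_],
            "training_log": self.training_log_,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PatchCNNClassifier":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        clf = cls(**sidecar["params"])
        clf.arch_ = CnnArch(**sidecar["arch"])
        with np.load(path.with_suffix(".npz")) as z:
            clf.weights_ = {k: z[k] for k in z.files}
        clf.classes_ = np.array([LABEL_UNDIFF, LABEL_DIFF])
        clf.loss_history_ = sidecar["loss_history"]
        clf.training_log_ = sidecar["training_log"]
        clf.n_features_in_ = clf.input_px * clf.input_px
        return clf


# ---------------------------------------------------------------------------
# procedure-level API


def build_model(arch: CnnArch | None = None, seed: int = 0) -> PatchCNNClassifier:
    """Untrained classifier with seeded initial weights."""
    arch = arch or CnnArch()
    clf = PatchCNNClassifier(
        input_px=arch.input_px, seed=seed,
        allow_input_px_override=arch.input_px != 70,
    )
    return clf.initialize()


def train_round(model: PatchCNNClassifier, patches: PatchSet,
                hyper: TrainHyper | None = None) -> PatchCNNClassifier:
    """One training round; the model's ``training_log_`` records it."""
    if hyper is not None:
        hyper.validate()
        model.set_params(
            optimizer=hyper.optimizer, learning_rate=hyper.learning_rate,
            batch_size=hyper.batch_size, epochs=hyper.epochs,
            class_balance=hyper.class_balance,
        )
    return model.fit(patches.images, patches.labels)


def mine_hard_examples(model: PatchCNNClassifier,
                       frames_masks: list[tuple[ImageFrame, LabelMask]],
                       patch_px: int = 70,
                       purity_threshold: float = 0.8) -> PatchSet:
    """Undifferentiated patches the model misclassifies as differentiated.

    Tiles each frame with the non-overlap grid, keeps the patches whose
    ground truth is undifferentiated and whose current prediction is
    differentiated.  An empty set is a legal result (a perfect model).
    """
    hard_images, hard_origins = [], []
    for frame, mask in frames_masks:
        pset = extract_patches(frame, mask, patch_px, policy="grid_nonoverlap",
                               purity_threshold=purity_threshold)
        undiff = pset.labels == LABEL_UNDIFF
        if not undiff.any():
            continue
        pred = model.predict(pset.images[undiff])
        wrong = pred == LABEL_DIFF
        if wrong.any():
            hard_images.append(pset.images[undiff][wrong])
            hard_origins.append(pset.origins[undiff][wrong])
    if not hard_images:
        return PatchSet(
            np.zeros((0, patch_px, patch_px)), np.zeros(0, dtype=np.int64),
            np.zeros((0, 2), dtype=np.int64), patch_px,
        )
    images = np.concatenate(hard_images)
    return PatchSet(
        images, np.full(len(images), LABEL_UNDIFF, dtype=np.int64),
        np.concatenate(hard_origins), patch_px,
    )


def train_with_mining(frames_masks: list[tuple[ImageFrame, LabelMask]],
                      hyper: TrainHyper) -> PatchCNNClassifier:
    """Full two-round schedule; returns the round-2 (deployed) classifier."""
    hyper.validate()
    psets = [
        extract_patches(
            frame, mask, policy="random", n_random=hyper.n_patches,
            purity_threshold=hyper.purity_threshold, seed=hyper.seed + i,
        )
        for i, (frame, mask) in enumerate(frames_masks)
    ]
    patches = psets[0]
    for p in psets[1:]:
        patches = patches.concat(p)

    clf = PatchCNNClassifier(
        optimizer=hyper.optimizer, learning_rate=hyper.learning_rate,
        batch_size=hyper.batch_size, epochs=hyper.epochs,
        class_balance=hyper.class_balance, seed=hyper.seed,
    )
    clf.fit(patches.images, patches.labels)

    mined = mine_hard_examples(clf, frames_masks,
                               purity_threshold=hyper.purity_threshold)
    clf.training_log_["n_mined"] = int(len(mined))
    if len(mined):
        patches = patches.concat(mined)
    clf.set_params(warm_start=True)
    clf.fit(patches.images, patches.labels)
    clf.set_params(warm_start=False)
    return clf


def predict_map(model: PatchCNNClassifier, phase: ImageFrame,
                stride_px: int = 70) -> ProbabilityMap:
    """Slide 70x70 windows over a phase frame and paint each window's
    differentiated-class probability onto the pixels it covers.

    Overlapping windows (stride < 70) average; uncovered right/bottom
    margins replicate the nearest covered value.
    """
    if phase.channel != "phase":
        raise ValueError("the deployed classifier consumes phase-contrast frames only")
    p = model.input_px
    h, w = phase.shape
    if h < p or w < p:
        raise ValueError("frame smaller than one patch")
    if stride_px <= 0:
        raise ValueError("stride must be positive")
    rows = np.arange(0, h - p + 1, stride_px)
    cols = np.arange(0, w - p + 1, stride_px)
    windows = np.stack(
        [phase.pixels[r : r + p, c : c + p] for r in rows for c in cols]
    )
    probs = model.predict_proba(windows)[:, 1].reshape(len(rows), len(cols))

    acc = np.zeros((h, w))
    cnt = np.zeros((h, w))
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            acc[r : r + p, c : c + p] += probs[i, j]
            cnt[r : r + p, c : c + p] += 1
    covered_h = rows[-1] + p
    covered_w = cols[-1] + p
    out = np.zeros((h, w))
    out[:covered_h, :covered_w] = acc[:covered_h, :covered_w] / cnt[:covered_h, :covered_w]
    # margin fill: nearest covered pixel
    out[covered_h:, :covered_w] = out[covered_h - 1, :covered_w]
    out[:, covered_w:] = out[:, covered_w - 1][:, None]
    return ProbabilityMap(out, phase.pixel_size_um)


def false_differentiated_count(model: PatchCNNClassifier,
                               frames_masks: list[tuple[ImageFrame, LabelMask]],
                               purity_threshold: float = 0.8) -> int:
    """Count of undifferentiated grid patches currently predicted differentiated."""
    return len(mine_hard_examples(model, frames_masks,
                                  purity_threshold=purity_threshold))
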