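"""Pluggable segmentation backends for the cross-validation harness.

The harness treats the segmenter as an interface: anything with
``fit(images, masks)`` and ``predict(images)`` over lists of 3D arrays,
optionally with an epoch-wise ``partial_fit`` for models that train
iteratively. Three bindings are provided:

``QuantileThresholdSegmenter``
    Deterministic, training-free in the gradient sense: fit learns the mean
    lesion fraction of the training masks and predicts the corresponding
    top intensity quantile of each input volume. On FLAIR-like data where
    the lesion is the brightest structure this is a surprisingly strong
    desk-scale baseline, and it is the harness default.

``SGDLogisticSegmenter``
    A small trainable voxel classifier (logistic regression on intensity
    and local-mean features) optimized with minibatch SGD, Nesterov
    momentum 0.99 and learning rate 0.01 by default — the optimizer
    settings of the full-scale training schedule — so the harness can
    exercise genuine per-epoch validation traces.

``ExternalNNUNetSegmenter``
    Adapter stub for an installed nnU-Net v2. It shells out to the
    ``nnUNetv2_train`` executable and parses per-epoch pseudo-Dice from the
    training progress log; it raises a clear error with an install hint
    when the backend is absent. The full framework is deliberately not
    re-implemented here.
"""

from __future__ import annotations

import re
import shutil
import subprocess

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .exceptions import SegmenterUnavailableError

__all__ = [
    "QuantileThresholdSegmenter",
    "SGDLogisticSegmenter",
    "ExternalNNUNetSegmenter",
    "parse_nnunet_progress_log",
    "SEGMENTERS",
    "make_segmenter",
]


def _as_arrays(images) -> list[np.ndarray]:
    return [np.asarray(getattr(img, "data", img), dtype=float) for img in images]


def _as_masks(masks) -> list[np.ndarray]:
    return [np.asarray(getattr(m, "data", m)).astype(bool) for m in masks]


class QuantileThresholdSegmenter(BaseEstimator):
    """Predict lesion = voxels above a fitted intensity quantile.

    ``fit`` estimates the mean lesion fraction f of the training masks and
    sets ``quantile_ = 1 - f`` (unless a quantile is forced at
    construction). ``predict`` thresholds each volume at its own
    ``quantile_`` intensity quantile, so the predicted lesion fraction
    matches the training prevalence per case.
    """

    def __init__(self, quantile: float | None = None):
        self.quantile = quantile

    def fit(self, images, masks):
        masks = _as_masks(masks)
        if len(masks) == 0:
            raise ValueError("no training cases")
        fractions = [m.sum() / m.size for m in masks]
        self.lesion_fraction_ = float(np.mean(fractions))
        self.quantile_ = (
            float(self.quantile) if self.quantile is not None else 1.0 - self.lesion_fraction_
        )
        return self

    def predict(self, images) -> list[np.ndarray]:
        check_is_fitted(self, "quantile_")
        out = []
        for img in _as_arrays(images):
            thr = np.quantile(img, self.quantile_)
            out.append((img > thr).astype(np.uint8))
        return out


class SGDLogisticSegmenter(BaseEstimator):
    """Logistic voxel classifier trained by minibatch SGD with Nesterov momentum.

    Features per voxel: intensity and a 3x3x3 local mean. Each
    ``partial_fit`` call is one epoch: it iterates the training cases in
    seeded minibatches of ``batch_size`` cases, drawing a class-balanced
    voxel sample per case. Deterministic given ``random_state``.
    """

    def __init__(
        self,
        learning_rate: float = 0.01,
        momentum: float = 0.99,
        nesterov: bool = True,
        batch_size: int = 4,
        voxels_per_case: int = 2000,
        random_state: int = 0,
    ):
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.nesterov = nesterov
        self.batch_size = batch_size
        self.voxels_per_case = voxels_per_case
        self.random_state = random_state

    @staticmethod
    def _features(img: np.ndarray) -> np.ndarray:
        local = ndimage.uniform_filter(img, size=3, mode="nearest")
        return np.stack([img.ravel(), local.ravel()], axis=1)

    def _sample_case(self, rng, img, mask):
        feats = self._features(img)
        labels = mask.ravel()
        pos = np.flatnonzero(labels)
        neg = np.flatnonzero(~labels)
        n = self.voxels_per_case // 2
        take_pos = rng.choice(pos, size=min(n, pos.size), replace=pos.size < n) if pos.size else np.empty(0, int)
        take_neg = rng.choice(neg, size=n, replace=neg.size < n)
        idx = np.concatenate([take_pos, take_neg])
        return feats[idx], labels[idx].astype(float)

    def partial_fit(self, images, masks, classes=None):
        images, masks = _as_arrays(images), _as_masks(masks)
        if not hasattr(self, "coef_"):
            self.coef_ = np.zeros(3)  # [w_intensity, w_local, bias]
            self._velocity = np.zeros(3)
            self.n_epochs_ = 0
        rng = np.random.default_rng((int(self.random_state), self.n_epochs_))
        order = rng.permutation(len(images))
        for start in range(0, len(order), self.batch_size):
            batch = order[start : start + self.batch_size]
            X_parts, y_parts = [], []
            for i in batch:
                Xi, yi = self._sample_case(rng, images[i], masks[i])
                X_parts.append(Xi)
                y_parts.append(yi)
            X = np.concatenate(X_parts)
            y = np.concatenate(y_parts)
            Xb = np.hstack([X, np.ones((X.shape[0], 1))])
            w = self.coef_ + self.momentum * self._velocity if self.nesterov else self.coef_
            p = 1.0 / (1.0 + np.exp(-np.clip(Xb @ w, -50, 50)))
            grad = Xb.T @ (p - y) / y.size
            self._velocity = self.momentum * self._velocity - self.learning_rate * grad
            self.coef_ = self.coef_ + self._velocity
        self.n_epochs_ += 1
        return self

    def fit(self, images, masks, epochs: int = 10):
        for attr in ("coef_", "_velocity", "n_epochs_"):
            if hasattr(self, attr):
                delattr(self, attr)
        for _ in range(epochs):
            self.partial_fit(images, masks)
        return self

    def predict(self, images) -> list[np.ndarray]:
        check_is_fitted(self, "coef_")
        out = []
        for img in _as_arrays(images):
            Xb = np.hstack([self._features(img), np.ones((img.size, 1))])
            score = Xb @ self.coef_
            out.append((score > 0).astype(np.uint8).reshape(img.shape))
        return out


_PSEUDO_DICE_LINE = re.compile(r"Pseudo dice", re.IGNORECASE)
_NP_WRAPPER = re.compile(r"np\.float\d+\(([^)]*)\)")


def parse_nnunet_progress_log(text: str) -> np.ndarray:
    """Extract the per-epoch pseudo-Dice trace from an nnU-Net progress log.

    Each epoch's log contains a line like ``Pseudo dice [0.42, 0.5]`` (one
    value per foreground class, possibly wrapped as ``np.float32(...)``);
    the per-epoch value is the mean over classes. Returns one value per
    matching line, in order.
    """
    values = []
    for line in text.splitlines():
        if not _PSEUDO_DICE_LINE.search(line):
            continue
        bracket = re.search(r"\[(.*?)\]", line)
        if bracket is None:
            continue
        body = _NP_WRAPPER.sub(r"\1", bracket.group(1))  # unwrap np.float32(x)
        nums = []
        for tok in body.split(","):
            try:
                nums.append(float(tok.strip()))
            except ValueError:
                continue
        if nums:
            values.append(float(np.mean(nums)))
    return np.asarray(values, dtype=float)


class ExternalNNUNetSegmenter(BaseEstimator):
    """Adapter around an installed nnU-Net v2 (not re-implemented here).

    ``fit`` launches ``nnUNetv2_train`` for a prepared dataset/fold and
    stores the per-epoch pseudo-Dice trace parsed from the progress log.
    Raises :class:`SegmenterUnavailableError` when the executable is absent.
    """

    def __init__(self, dataset_id: int | None = None, configuration: str = "3d_fullres",
                 command: str = "nnUNetv2_train"):
        self.dataset_id = dataset_id
        self.configuration = configuration
        self.command = command

    def available(self) -> bool:
        return shutil.which(self.command) is not None

    def _require(self) -> None:
        if not self.available():
            raise SegmenterUnavailableError(
                f"{self.command!r} not found on PATH; install the external backend "
                "(pip install nnunetv2) and prepare its dataset layout to use this adapter"
            )

    def fit(self, images=None, masks=None, fold: int = 0):
        self._require()
        if self.dataset_id is None:
            raise ValueError("dataset_id is required to launch external training")
        proc = subprocess.run(
            [self.command, str(self.dataset_id), self.configuration, str(fold)],
            capture_output=True, text=True, check=True,
        )
        self.trace_ = parse_nnunet_progress_log(proc.stdout + proc.stderr)
        return self

    def predict(self, images):
        self._require()
        raise NotImplementedError(
            "external prediction is delegated to nnUNetv2_predict on exported NIfTI files"
        )


SEGMENTERS = {
    "quantile_threshold": QuantileThresholdSegmenter,
    "sgd_logistic": SGDLogisticSegmenter,
    "nnunet": ExternalNNUNetSegmenter,
}


def make_segmenter(name: str, train_cfg=None, random_state: int = 0):
    """Instantiate a registered segmenter, wiring TrainConfig fields where relevant."""
    if name not in SEGMENTERS:
        raise ValueError(f"unknown segmenter {name!r}; available: {sorted(SEGMENTERS)}")
    if name == "sgd_logistic":
        kwargs = {"random_state": random_state}
        if train_cfg is not None:
            kwargs.update(
                learning_rate=train_cfg.learning_rate,
                momentum=train_cfg.momentum,
                nesterov=train_cfg.nesterov,
                batch_size=train_cfg.batch_size,
            )
        return SGDLogisticSegmenter(**kwargs)
    return SEGMENTERS[name]()
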