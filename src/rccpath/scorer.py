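"""Patch scoring: dataset split, scorer contract, imbalance remedies.

The scorer is a behavioral contract — ``score(patches)`` returns class
probabilities and ``embed(patches)`` a fixed-dimension feature vector from
the penultimate representation.  The bundled reference implementation is a
small multilayer perceptron over downsampled, channel-standardized pixels,
trainable on one CPU in seconds; its hidden layer (default width 512) plays
the role of the penultimate embedding.  Heavier convolutional backbones can
be plugged in by registering another implementation under a backbone name —
the downstream pipeline only ever talks to the contract.

Class imbalance is addressed two ways, mirroring common practice:
minority-class augmentation (random vertical flip, rotation in [-25, +25]
degrees, additive Gaussian pixel noise, each applied with probability 0.5)
and inverse-class-frequency sampling weights.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import rotate as _rotate, resize as _resize
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import LabelBinarizer

from .tiling import Patch

__all__ = [
    "ScorerConfig", "PatchScorer", "ReferenceScorer",
    "split_dataset", "train_scorer", "extract_embeddings",
    "augment_minority", "weighted_sample_weights",
]


@dataclass
class ScorerConfig:
    """Training configuration for a patch scorer.

    Defaults mirror a fine-tuned deep-backbone setup (224-pixel inputs,
    batch 128, learning rate 1e-5); the reference MLP backbone is far
    smaller, so fixtures typically override ``resize`` and
    ``learning_rate`` with lighter values.
    """

    backbone: str = "reference"
    resize: int = 224
    batch_size: int = 128
    learning_rate: float = 1e-5
    patience: int = 5
    max_epochs: int = 40
    n_output_classes: int = 2
    embed_dim: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_output_classes < 2:
            raise ValueError("need at least 2 output classes")


def split_dataset(manifest: pd.DataFrame, fractions=(0.70, 0.15, 0.15),
                  seed: int = 0) -> dict[str, set[str]]:
    """Slide-level stratified train/val/test split.

    The split happens on slides (all patches of a slide land in one fold) so
    overlapping patches can never leak across folds.  Within each class,
    fold sizes follow the largest-remainder rounding of the requested
    fractions.  Requires ``slide_id`` and ``label`` columns and at least 3
    slides per class.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    folds: dict[str, set[str]] = {"train": set(), "val": set(), "test": set()}
    slides = manifest[["slide_id", "label"]].drop_duplicates()
    for label, group in slides.groupby("label", sort=True):
        ids = sorted(group["slide_id"])
        if len(ids) < 3:
            raise ValueError(f"class {label!r} has fewer than 3 slides")
        rng.shuffle(ids)
        n = len(ids)
        quotas = [f * n for f in fractions]
        counts = [int(q) for q in quotas]
        remainders = [q - c for q, c in zip(quotas, counts)]
        for _ in range(n - sum(counts)):
            i = int(np.argmax(remainders))
            counts[i] += 1
            remainders[i] = -1.0
        # every fold gets at least one slide per class
        for i in range(3):
            if counts[i] == 0:
                j = int(np.argmax(counts))
                counts[j] -= 1
                counts[i] += 1
        start = 0
        for name, c in zip(("train", "val", "test"), counts):
            folds[name].update(ids[start:start + c])
            start += c
    return folds


class PatchScorer:
    """Contract: probability scores and penultimate-layer embeddings."""

    classes_: list
    embed_dim: int
    epochs_run: int
    val_accuracy_trace: list

    def score(self, patches) -> np.ndarray:  # (n, n_classes) probabilities
        raise NotImplementedError

    def embed(self, patches) -> np.ndarray:  # (n, embed_dim)
        raise NotImplementedError


def _patch_array(patches) -> np.ndarray:
    imgs = [p.image if isinstance(p, Patch) else np.asarray(p) for p in patches]
    return np.stack(imgs).astype(np.float64)


class ReferenceScorer(PatchScorer):
    """MLP over downsampled pixels; hidden activations are the embedding.

    Patches are block-averaged to ``resize`` x ``resize``, standardized per
    channel with training-set statistics, flattened and fed to a single
    hidden layer of width ``embed_dim`` with ReLU, then a softmax output.
    Trained epoch-wise with early stopping on validation accuracy; the best
    validation state is restored at the end.
    """

    def __init__(self, config: ScorerConfig):
        self.config = config
        self.embed_dim = config.embed_dim
        self.classes_ = []
        self.epochs_run = 0
        self.val_accuracy_trace: list[float] = []
        self._mean = None
        self._std = None
        self._mlp: MLPClassifier | None = None
        self._trained = False

    # -- feature plumbing ------------------------------------------------
    def _features(self, patches) -> np.ndarray:
        X = _patch_array(patches)
        r = self.config.resize
        t = X.shape[1]
        if t != r:
            if t % r == 0:  # exact block mean, vectorized
                f = t // r
                X = X.reshape(len(X), r, f, r, f, 3).mean(axis=(2, 4))
            else:
                X = np.stack([
                    _resize(img, (r, r, 3), anti_aliasing=True,
                            preserve_range=True)
                    for img in X
                ])
        if self._mean is not None:
            X = (X - self._mean) / self._std
        return X.reshape(len(X), -1)

    # -- training --------------------------------------------------------
    def fit(self, train_patches, train_labels, val_patches, val_labels) -> "ReferenceScorer":
        cfg = self.config
        labels = np.asarray(train_labels)
        self.classes_ = sorted(set(labels))
        if len(self.classes_) < 2:
            raise ValueError("training data contains a single class")
        raw = _patch_array(train_patches)
        self._mean = raw.mean(axis=(0, 1, 2))
        self._std = raw.std(axis=(0, 1, 2)) + 1e-8
        Xtr = self._features(train_patches)
        Xva = self._features(val_patches)
        yva = np.asarray(val_labels)

        self._mlp = MLPClassifier(
            hidden_layer_sizes=(cfg.embed_dim,),
            solver="sgd", learning_rate_init=cfg.learning_rate,
            batch_size=min(cfg.batch_size, len(Xtr)),
            momentum=0.9, alpha=1e-4, max_iter=1,
            random_state=cfg.seed, warm_start=False,
        )
        rng = np.random.default_rng(cfg.seed)
        best_state, best_acc, since_best = None, -np.inf, 0
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(Xtr))
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                self._mlp.batch_size = len(idx)
                self._mlp.partial_fit(Xtr[idx], labels[idx], classes=self.classes_)
            acc = float(np.mean(self._mlp.predict(Xva) == yva))
            self.val_accuracy_trace.append(acc)
            self.epochs_run = epoch + 1
            if acc > best_acc + 1e-12:
                best_acc, since_best = acc, 0
                best_state = (copy.deepcopy(self._mlp.coefs_),
                              copy.deepcopy(self._mlp.intercepts_))
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
        if best_state is not None:
            self._mlp.coefs_, self._mlp.intercepts_ = best_state
        self._trained = True
        return self

    # -- persistence -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Checkpoint: weights as .npz plus a JSON config sidecar."""
        if not self._trained:
            raise RuntimeError("scorer is not trained")
        path = Path(path)
        arrays = {"mean": self._mean, "std": self._std}
        for k, (c, i) in enumerate(zip(self._mlp.coefs_, self._mlp.intercepts_)):
            arrays[f"coef_{k}"] = c
            arrays[f"intercept_{k}"] = i
        np.savez(path, **arrays)
        sidecar = {"config": dataclasses.asdict(self.config),
                   "classes": list(self.classes_),
                   "epochs_run": self.epochs_run,
                   "val_accuracy_trace": self.val_accuracy_trace,
                   "n_layers": len(self._mlp.coefs_)}
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceScorer":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        self = cls(ScorerConfig(**sidecar["config"]))
        self.classes_ = sidecar["classes"]
        self.epochs_run = sidecar["epochs_run"]
        self.val_accuracy_trace = sidecar["val_accuracy_trace"]
        data = np.load(path if path.suffix == ".npz" else f"{path}.npz")
        self._mean, self._std = data["mean"], data["std"]
        n = sidecar["n_layers"]
        mlp = MLPClassifier(hidden_layer_sizes=(self.config.embed_dim,))
        mlp.coefs_ = [data[f"coef_{k}"] for k in range(n)]
        mlp.intercepts_ = [data[f"intercept_{k}"] for k in range(n)]
        mlp.classes_ = np.asarray(self.classes_)
        mlp.n_layers_ = n + 1
        mlp.n_outputs_ = len(mlp.intercepts_[-1])
        mlp.out_activation_ = "logistic" if mlp.n_outputs_ == 1 else "softmax"
        mlp._label_binarizer = LabelBinarizer().fit(self.classes_)
        self._mlp = mlp
        self._trained = True
        return self

    # -- contract --------------------------------------------------------
    def score(self, patches) -> np.ndarray:
        if not self._trained:
            raise RuntimeError("scorer is not trained")
        return self._mlp.predict_proba(self._features(patches))

    def embed(self, patches) -> np.ndarray:
        if not self._trained:
            raise RuntimeError("scorer is not trained")
        X = self._features(patches)
        hidden = np.maximum(X @ self._mlp.coefs_[0] + self._mlp.intercepts_[0], 0.0)
        return hidden


_BACKBONES = {"reference": ReferenceScorer}


def train_scorer(train_patches, val_patches, config: ScorerConfig) -> PatchScorer:
    """Train the configured backbone on labeled patches.

    Patch labels are read from ``Patch.label``; both folds must be labeled
    and the training fold must contain at least two classes.
    """
    if config.backbone not in _BACKBONES:
        raise ValueError(
            f"unknown backbone {config.backbone!r}; available: {sorted(_BACKBONES)}"
        )
    ytr = [p.label for p in train_patches]
    yva = [p.label for p in val_patches]
    if any(l is None for l in ytr + yva):
        raise ValueError("all patches must carry labels")
    scorer = _BACKBONES[config.backbone](config)
    return scorer.fit(train_patches, ytr, val_patches, yva)


def extract_embeddings(scorer: PatchScorer, patches) -> np.ndarray:
    """Embedding matrix, one row per patch, from the trained scorer."""
    E = scorer.embed(patches)
    if not np.isfinite(E).all():
        raise ValueError("non-finite values in embeddings")
    return E


def _augment_one(img: np.ndarray, rng: np.random.Generator,
                 noise_sigma: float = 10.0,
                 force_flip: bool | None = None) -> np.ndarray:
    out = img.astype(np.float64)
    flip = rng.random() < 0.5 if force_flip is None else force_flip
    if flip:
        out = out[::-1]  # vertical flip
    if rng.random() < 0.5:
        angle = rng.uniform(-25.0, 25.0)
        out = _rotate(out, angle, mode="reflect", preserve_range=True)
    if rng.random() < 0.5:
        out = out + rng.normal(0.0, noise_sigma, size=out.shape)
    return np.clip(out, 0, 255).astype(np.uint8)


def augment_minority(patches: list[Patch], target_count: int,
                     seed: int = 0) -> list[Patch]:
    """Grow a minority class to ``target_count`` by randomized augmentation.

    Source patches are sampled with replacement; each sampled image gets a
    random vertical flip, a rotation in [-25, +25] degrees (reflect-filled
    corners) and additive Gaussian noise (sigma 10 intensity units, clipped
    to [0, 255]), each independently with probability 0.5.
    """
    if not patches:
        raise ValueError("cannot augment an empty patch list")
    if target_count < len(patches):
        raise ValueError("target_count must be >= the current count")
    rng = np.random.default_rng(seed)
    out = list(patches)
    for i in range(target_count - len(patches)):
        src = patches[int(rng.integers(len(patches)))]
        img = _augment_one(src.image, rng)
        out.append(Patch(src.slide_id, src.row, src.col, src.x, src.y,
                         img, src.label))
    return out


def weighted_sample_weights(labels) -> np.ndarray:
    """Per-sample weights proportional to inverse class frequency.

    Normalized to sum to 1; weighted sampling then draws each class with
    equal expected frequency.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("need at least one sample")
    _, inverse, counts = np.unique(labels, return_inverse=True, return_counts=True)
    w = 1.0 / counts[inverse]
    return w / w.sum()
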