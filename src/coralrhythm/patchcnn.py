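"""Patch-level convolutional classifier for the four colony statuses.

Architecture (configurable via :class:`CnnSpec`; defaults below): three
conv blocks of two 3x3 ReLU convolutions each, channel widths
(32,32)/(64,64)/(128,128), with 2x2 max pooling after the second convolution
of every block and dropout 0.25 per block; then a dense ReLU layer of 512,
dropout 0.5, and a dense softmax output over the four classes (background +
three activity statuses).  With "same" conv padding a 30x30 input shrinks
30 -> 15 -> 7 -> 3 through the pools, so the flattened feature is
3*3*c_last.  Training uses Adam (lr 1e-4, beta1 0.9, beta2 0.999),
categorical cross-entropy, batch 256, with flip/shift augmentation.

Evaluation reports the confusion matrix (targets on rows), overall accuracy,
per-class producer's accuracy (PA = recall = diag/row sum) and user's
accuracy (UA = precision = diag/column sum), and macro one-vs-rest AUC from
the softmax scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from ._nn import Adam, Conv3x3, Dense, Dropout, Flatten, MaxPool2, SequentialNet
from .annotation import LabeledPatchSet, augment
from .fixtures import CLASS_IDS

__all__ = ["CnnSpec", "TrainConfig", "EvalReport", "PatchClassifier",
           "build_model", "train", "evaluate", "cross_validate", "holdout_split"]

CLASS_ORDER = tuple(sorted(CLASS_IDS, key=CLASS_IDS.get))  # id -> name
N_CLASSES = len(CLASS_ORDER)


@dataclass(frozen=True)
class CnnSpec:
    """Layer plan of the patch network; the default is the full-width model."""

    conv_blocks: tuple[tuple[int, int], ...] = ((32, 32), (64, 64), (128, 128))
    block_dropout: float = 0.25
    dense_units: int = 512
    dense_dropout: float = 0.5
    input_size: int = 30
    n_classes: int = N_CLASSES

    def validate(self) -> None:
        if self.n_classes != N_CLASSES:
            raise ValueError(f"classifier is defined over {N_CLASSES} classes")
        if self.input_size < 2 ** len(self.conv_blocks):
            raise ValueError("input too small for the pooling depth")

    @classmethod
    def reduced(cls) -> "CnnSpec":
        """A narrow variant for CPU-budget experiments; same topology."""
        return cls(conv_blocks=((8, 8), (16, 16)), dense_units=64)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 256
    epochs: int = 100
    augment: bool = True
    flips: bool = True
    shift_frac: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


class PatchClassifier:
    """A built (possibly trained) patch network plus its metadata."""

    def __init__(self, spec: CnnSpec, seed: int):
        spec.validate()
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        layers = []
        c_in = 3
        for c1, c2 in spec.conv_blocks:
            layers += [Conv3x3(c_in, c1, rng), Conv3x3(c1, c2, rng), MaxPool2(),
                       Dropout(spec.block_dropout, rng)]
            c_in = c2
        side = spec.input_size
        for _ in spec.conv_blocks:
            side //= 2
        layers += [Flatten(), Dense(side * side * c_in, spec.dense_units, rng),
                   Dropout(spec.dense_dropout, rng),
                   Dense(spec.dense_units, spec.n_classes, rng, relu=False)]
        self.net = SequentialNet(layers, rng)
        self.loss_history: list[float] = []

    # -- inference ---------------------------------------------------------

    @staticmethod
    def _prep(patches: np.ndarray) -> np.ndarray:
        x = np.asarray(patches, dtype=np.float32)
        if x.max() > 1.5:  # uint8 input
            x = x / 255.0
        return x

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        """Softmax class probabilities, shape (N, 4); rows sum to 1."""
        return self.net.predict_proba(self._prep(patches))

    def predict(self, patches: np.ndarray) -> np.ndarray:
        return self.predict_proba(patches).argmax(axis=1)

    # -- persistence -------------------------------------------------------

    def save(self, stem) -> None:
        """Write ``<stem>.npz`` weights and a ``<stem>.json`` metadata sidecar."""
        stem = str(stem)
        np.savez(stem + ".npz", *self.net.get_weights())
        meta = {"spec": asdict(self.spec), "seed": self.seed,
                "class_order": list(CLASS_ORDER), "loss_history": self.loss_history}
        with open(stem + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, stem) -> "PatchClassifier":
        stem = str(stem)
        with open(stem + ".json") as fh:
            meta = json.load(fh)
        spec_d = meta["spec"]
        spec_d["conv_blocks"] = tuple(tuple(b) for b in spec_d["conv_blocks"])
        model = cls(CnnSpec(**spec_d), meta["seed"])
        with np.load(stem + ".npz") as data:
            model.net.set_weights([data[k] for k in data.files])
        model.loss_history = list(meta.get("loss_history", []))
        return model


def build_model(spec: CnnSpec | None = None, seed: int = 0) -> PatchClassifier:
    return PatchClassifier(spec or CnnSpec(), seed)


def train(model: PatchClassifier, patchset: LabeledPatchSet, cfg: TrainConfig) -> list[float]:
    """Train in place; returns the per-epoch mean loss history (len = epochs)."""
    cfg.validate()
    present = np.unique(patchset.labels)
    if len(present) < 2:
        warnings.warn("training set contains fewer than 2 classes; model will be degenerate")
    missing = [CLASS_ORDER[c] for c in range(N_CLASSES) if c not in present]
    if missing:
        warnings.warn(f"classes absent from training data: {missing}")

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(cfg.learning_rate, cfg.beta1, cfg.beta2)
    y_all = patchset.labels
    for _ in range(cfg.epochs):
        if cfg.augment:
            stream = augment(patchset, flips=cfg.flips, shift_frac=cfg.shift_frac, seed=rng)
            xs, ys = zip(*stream)
            x_all = model._prep(np.stack(xs))
            y_ep = np.asarray(ys)
        else:
            x_all = model._prep(patchset.patches)
            y_ep = y_all
        order = rng.permutation(len(x_all))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            sel = order[i : i + cfg.batch_size]
            losses.append(model.net.train_batch(x_all[sel], y_ep[sel], opt))
        model.loss_history.append(float(np.mean(losses)))
    return model.loss_history


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Confusion-matrix report; rows are targets, columns predictions."""

    confusion: np.ndarray
    accuracy: float
    pa: dict[str, float]  # producer's accuracy (recall), fractions
    ua: dict[str, float]  # user's accuracy (precision), fractions
    auc: float | None

    @classmethod
    def from_scores(cls, y_true: np.ndarray, probs: np.ndarray) -> "EvalReport":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(probs).argmax(axis=1)
        k = probs.shape[1]
        conf = np.zeros((k, k), dtype=int)
        np.add.at(conf, (y_true, y_pred), 1)
        acc = float(np.trace(conf)) / max(1, conf.sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            pa_v = np.diag(conf) / conf.sum(axis=1)
            ua_v = np.diag(conf) / conf.sum(axis=0)
        pa = {CLASS_ORDER[i]: float(pa_v[i]) for i in range(k) if conf.sum(axis=1)[i] > 0}
        ua = {CLASS_ORDER[i]: float(ua_v[i]) for i in range(k) if conf.sum(axis=0)[i] > 0}
        present = np.unique(y_true)
        auc = None
        if len(present) >= 2:
            try:
                if len(present) == probs.shape[1]:
                    auc = float(roc_auc_score(y_true, probs, multi_class="ovr", average="macro"))
                else:  # restrict to classes with support
                    sub = probs[:, present]
                    sub = sub / sub.sum(axis=1, keepdims=True)
                    remap = {c: i for i, c in enumerate(present)}
                    y_r = np.array([remap[c] for c in y_true])
                    auc = float(roc_auc_score(y_r, sub if len(present) > 2 else sub[:, 1],
                                              multi_class="ovr", average="macro"))
            except ValueError:
                auc = None
        return cls(conf, acc, pa, ua, auc)

    def summary(self) -> str:
        lines = ["class            PA        UA"]
        for name in CLASS_ORDER:
            pa = self.pa.get(name)
            ua = self.ua.get(name)
            fmt = lambda v: f"{100*v:6.2f}%" if v is not None and np.isfinite(v) else "    --"
            lines.append(f"{name:<15}{fmt(pa):>9}{fmt(ua):>10}")
        lines.append(f"accuracy {100*self.accuracy:.2f}%"
                     + (f"   macro AUC {self.auc:.4f}" if self.auc is not None else ""))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"confusion": self.confusion.tolist(), "accuracy": self.accuracy,
                "pa": self.pa, "ua": self.ua, "auc": self.auc}


def evaluate(model: PatchClassifier, patchset: LabeledPatchSet) -> EvalReport:
    probs = model.predict_proba(patchset.patches)
    return EvalReport.from_scores(patchset.labels, probs)


def holdout_split(patchset: LabeledPatchSet, test_frac: float = 0.30, seed: int = 0):
    """Stratified random 70/30-style split; returns (train_set, test_set)."""
    idx = np.arange(len(patchset))
    tr, te = train_test_split(idx, test_size=test_frac, random_state=seed,
                              stratify=patchset.labels)
    return patchset.subset(tr), patchset.subset(te)


def cross_validate(
    patchset: LabeledPatchSet,
    cfg: TrainConfig,
    k: int = 10,
    stratified: bool = True,
    seed: int = 0,
    spec: CnnSpec | None = None,
) -> dict:
    """k-fold cross-validation; each fold trains a fresh model.

    Folds are stratified (class proportions preserved within one sample) and
    shuffled.  Returns per-fold reports plus the mean accuracy and mean AUC —
    the averaged single-validation performances.
    """
    counts = np.bincount(patchset.labels, minlength=N_CLASSES)
    low = [CLASS_ORDER[i] for i in range(N_CLASSES) if 0 < counts[i] < k]
    if low:
        raise ValueError(f"classes with fewer than k={k} samples: {low}")
    if not stratified:
        from sklearn.model_selection import KFold

        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.arange(len(patchset)))
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.arange(len(patchset)), patchset.labels)

    reports: list[EvalReport] = []
    for fold, (tr, va) in enumerate(splits):
        model = build_model(spec, seed=seed + fold)
        train(model, patchset.subset(tr), cfg)
        reports.append(evaluate(model, patchset.subset(va)))
    aucs = [r.auc for r in reports if r.auc is not None]
    return {
        "fold_reports": reports,
        "mean_accuracy": float(np.mean([r.accuracy for r in reports])),
        "mean_auc": float(np.mean(aucs)) if aucs else None,
    }
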