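"""Binary ASD / non-ASD scanpath-image classifier.

The model is a small convolutional network: 4 convolutional layers, each
followed by 2x2 max pooling, then 2 fully connected layers with dropout
and a sigmoid output.  Evaluation uses k-fold cross-validation in two
split modes:

* ``image_wise`` -- folds over images, the optimistic setting in which a
  participant's images can appear on both sides of a fold;
* ``participant_wise`` -- folds over participants (class-stratified), so
  no participant's images (or augmented variants of them) ever leak from
  test into train.  This is the clinically honest estimate of how the
  classifier generalises to unseen children.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc, roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigError, DataError
from .io import CohortManifest
from .nn import (
    Adam,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    MaxPool2x2,
    ReLU,
    SGD,
    SequentialNet,
    bce_loss,
)
from .render import ScanpathImage

IMAGE_WISE = "image_wise"
PARTICIPANT_WISE = "participant_wise"


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    The layer-type counts (4 conv, 4 pool, 2 dense) are fixed by the
    design; filter widths, dense width, dropout rates, optimizer and
    learning rate are free and exposed here.  ``input_dims`` is
    (height, width, channels) and must be divisible by 2^4 spatially so
    the four poolings come out even.
    """

    conv_filters: tuple[int, ...] = (32, 32, 64, 64)
    kernel: int = 3
    dense_width: int = 512
    dropout_conv: float = 0.25
    dropout_dense: float = 0.5
    input_dims: tuple[int, int, int] = (256, 256, 1)
    epochs: int = 3
    folds: int = 3
    validation_fraction: float = 0.2
    batch_size: int = 32
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    lr_decay: float = 1.0  # multiplicative decay applied after each epoch
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 4:
            raise ConfigError("the architecture uses exactly 4 conv/pool blocks")
        if self.epochs < 1 or self.folds < 1:
            raise ConfigError("epochs and folds must be >= 1")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ConfigError("validation_fraction must be in [0, 1)")
        h, w, _ = self.input_dims
        if h % 16 or w % 16 or h <= 0 or w <= 0:
            raise ConfigError(
                f"input dims {h}x{w} must be positive and divisible by 16 "
                "(four 2x2 poolings)"
            )
        if self.optimizer not in ("adam", "sgd"):
            raise ConfigError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class FoldResult:
    """Metrics of one cross-validation fold."""

    fold: int
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    accuracy: float
    recall: float
    precision: float
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    n_test: int = 0


@dataclass
class EvaluationReport:
    """Per-fold ROC curves and summary metrics (mean +/- SD across folds)."""

    folds: list[FoldResult]
    split_mode: str

    def _stat(self, name: str) -> tuple[float, float]:
        vals = np.array([getattr(f, name) for f in self.folds], dtype=float)
        return float(vals.mean()), float(vals.std())

    @property
    def mean_auc(self) -> float:
        return self._stat("auc")[0]

    @property
    def sd_auc(self) -> float:
        return self._stat("auc")[1]

    @property
    def mean_accuracy(self) -> float:
        return self._stat("accuracy")[0]

    def summary(self) -> dict:
        out = {"split_mode": self.split_mode, "n_folds": len(self.folds)}
        for name in ("auc", "accuracy", "recall", "precision"):
            m, s = self._stat(name)
            out[f"mean_{name}"] = round(m, 4)
            out[f"sd_{name}"] = round(s, 4)
        return out

    def to_json(self, path) -> None:
        doc = self.summary()
        doc["folds"] = [
            {
                "fold": f.fold,
                "auc": f.auc,
                "accuracy": f.accuracy,
                "recall": f.recall,
                "precision": f.precision,
                "train_loss": f.train_loss,
                "val_loss": f.val_loss,
                "n_test": f.n_test,
                "roc": {"fpr": list(map(float, f.fpr)),
                        "tpr": list(map(float, f.tpr))},
            }
            for f in self.folds
        ]
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def build_model(config: ModelConfig) -> SequentialNet:
    """Assemble the seeded, untrained network from a config.

    Identical configs (same seed) produce identical initial weights; the
    parameter count is a deterministic function of the config alone.
    """
    rng = np.random.default_rng(config.seed)
    h, w, c = config.input_dims
    layers = []
    in_ch = c
    for f in config.conv_filters:
        layers += [
            Conv2D(in_ch, f, config.kernel, rng),
            ReLU(),
            MaxPool2x2(),
            Dropout(config.dropout_conv),
        ]
        in_ch = f
    flat = (h // 16) * (w // 16) * in_ch
    layers += [
        Flatten(),
        Dense(flat, config.dense_width, rng),
        ReLU(),
        Dropout(config.dropout_dense),
        Dense(config.dense_width, 1, rng),
    ]
    opt = (
        Adam(lr=config.learning_rate)
        if config.optimizer == "adam"
        else SGD(lr=config.learning_rate)
    )
    return SequentialNet(layers, opt)


def evaluate(scores: Sequence[float], labels: Sequence[int]) -> dict:
    """ROC/AUC and threshold-0.5 metrics for one set of probabilities.

    The ROC curve sweeps the thresholds induced by the unique scores; AUC
    is the trapezoidal area, equivalently the concordant positive/negative
    pair fraction with ties counted half.  Accuracy, recall and precision
    are computed at the fixed threshold 0.5 (precision is 0 when nothing
    is predicted positive).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise DataError("scores and labels must be equal-length 1-D")
    if len(np.unique(labels)) < 2:
        raise DataError("evaluate needs at least one positive and one negative")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores)
    roc_auc = float(_sk_auc(fpr, tpr))
    pred = scores >= 0.5
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    accuracy = float(np.mean(pred == (labels == 1)))
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    return {
        "fpr": fpr,
        "tpr": tpr,
        "thresholds": thresholds,
        "auc": roc_auc,
        "accuracy": accuracy,
        "recall": float(recall),
        "precision": float(precision),
    }


def participant_split(
    manifest: CohortManifest, k: int = 3, seed: int = 0
) -> list[tuple[set[str], set[str]]]:
    """Class-stratified k-fold partition over participant IDs.

    Returns k (train_ids, test_ids) pairs; every participant appears in
    exactly one test set and never on both sides of a fold.  Images and
    augmented variants must follow their participant, which
    :func:`train_crossval` enforces.
    """
    ids = np.array([p.participant_id for p in manifest.participants])
    groups = np.array([p.group for p in manifest.participants])
    for g in np.unique(groups):
        if np.sum(groups == g) < k:
            raise DataError(
                f"need at least {k} participants per class; group {g!r} has "
                f"{int(np.sum(groups == g))}"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (set(ids[tr]), set(ids[te])) for tr, te in skf.split(ids, groups)
    ]


def _dataset_arrays(
    images: Sequence[ScanpathImage], manifest: CohortManifest
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = np.stack([img.pixels for img in images]).astype(np.float32)[..., None]
    y = np.array([manifest.label(img.participant_id) for img in images], dtype=float)
    pids = np.array([img.participant_id for img in images])
    return x, y, pids


def train_crossval(
    manifest: CohortManifest,
    images: Sequence[ScanpathImage],
    config: ModelConfig,
    split_mode: str = PARTICIPANT_WISE,
    augmented: Sequence[ScanpathImage] | None = None,
) -> tuple[list[SequentialNet], EvaluationReport]:
    """k-fold cross-validated training of the scanpath CNN.

    ``images`` are the preprocessed originals (model input dims);
    ``augmented`` variants, when given, join the training side of each
    fold only, and only when their source participant trains there --
    test participants' variants are excluded entirely.  Within each fold,
    ``validation_fraction`` of the training images is held out to monitor
    the loss per epoch.  Everything is seeded from ``config.seed``.
    """
    if split_mode not in (IMAGE_WISE, PARTICIPANT_WISE):
        raise ConfigError(f"unknown split_mode {split_mode!r}")
    if not images:
        raise DataError("train_crossval needs a non-empty image set")
    h, w, _ = config.input_dims
    for img in images:
        if img.pixels.shape != (h, w):
            raise DataError(
                f"image {img.name} has dims {img.pixels.shape}, expected {(h, w)}"
            )
    x, y, pids = _dataset_arrays(images, manifest)
    if augmented:
        xa, ya, pa = _dataset_arrays(augmented, manifest)
    folds: list[tuple[np.ndarray, np.ndarray]] = []
    if split_mode == PARTICIPANT_WISE:
        for train_ids, test_ids in participant_split(
            manifest, config.folds, config.seed
        ):
            tr = np.nonzero(np.isin(pids, list(train_ids)))[0]
            te = np.nonzero(np.isin(pids, list(test_ids)))[0]
            folds.append((tr, te))
    else:
        skf = StratifiedKFold(
            n_splits=config.folds, shuffle=True, random_state=config.seed
        )
        folds = [(tr, te) for tr, te in skf.split(x, y.astype(int))]

    models: list[SequentialNet] = []
    results: list[FoldResult] = []
    for fold_idx, (tr, te) in enumerate(folds):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise DataError(f"fold {fold_idx} is single-class; cannot train/score")
        xtr, ytr, ptr = x[tr], y[tr], pids[tr]
        if augmented:
            keep = np.isin(pa, np.unique(ptr))
            if split_mode == IMAGE_WISE:
                # image-wise: variants of training images only
                src = {images[i].name for i in tr}
                keep = np.array(
                    [a.augmented_from.split(":")[0] in src for a in augmented]
                )
            xtr = np.concatenate([xtr, xa[keep]])
            ytr = np.concatenate([ytr, ya[keep]])
        # hold out a validation slice of the training images for loss
        # monitoring
        rng = np.random.default_rng([config.seed, fold_idx])
        order = rng.permutation(len(xtr))
        n_val = int(round(config.validation_fraction * len(xtr)))
        val_idx, fit_idx = order[:n_val], order[n_val:]
        xval, yval = xtr[val_idx], ytr[val_idx]
        xfit, yfit = xtr[fit_idx], ytr[fit_idx]

        model = build_model(
            ModelConfig(**{**asdict(config), "seed": int(config.seed + fold_idx)})
        )
        train_losses, val_losses = [], []
        epoch_rng = np.random.default_rng([config.seed, fold_idx, 1])
        for _ in range(config.epochs):
            train_losses.append(
                model.fit_epoch(xfit, yfit, config.batch_size, epoch_rng)
            )
            val_losses.append(
                bce_loss(model.predict_proba(xval), yval) if n_val else float("nan")
            )
            model.optimizer.lr *= config.lr_decay
        probs = model.predict_proba(x[te])
        m = evaluate(probs, y[te].astype(int))
        results.append(
            FoldResult(
                fold=fold_idx,
                fpr=m["fpr"],
                tpr=m["tpr"],
                auc=m["auc"],
                accuracy=m["accuracy"],
                recall=m["recall"],
                precision=m["precision"],
                train_loss=train_losses,
                val_loss=val_losses,
                n_test=len(te),
            )
        )
        models.append(model)
    return models, EvaluationReport(folds=results, split_mode=split_mode)


def save_model(model: SequentialNet, config: ModelConfig, path) -> None:
    """Serialize weights + config to a single ``.npz`` archive."""
    arrays = {}
    for li, layer in enumerate(model.layers):
        for name, param in layer.params.items():
            arrays[f"layer{li}_{name}"] = param
    arrays["config_json"] = np.array(json.dumps(asdict(config)))
    np.savez(path, **arrays)


def load_model(path) -> tuple[SequentialNet, ModelConfig]:
    """Rebuild a serialized model; inference-equivalent to the original."""
    with np.load(path, allow_pickle=False) as data:
        cfg_doc = json.loads(str(data["config_json"]))
        for key in ("conv_filters", "input_dims"):
            cfg_doc[key] = tuple(cfg_doc[key])
        config = ModelConfig(**cfg_doc)
        model = build_model(config)
        for li, layer in enumerate(model.layers):
            for name in layer.params:
                layer.params[name][...] = data[f"layer{li}_{name}"]
    return model, config


def predict(model: SequentialNet, images) -> np.ndarray | float:
    """Probability of the ASD class for one image or a batch.

    Order-preserving for batches; deterministic (dropout is inference-off).
    """
    single = isinstance(images, ScanpathImage)
    batch = [images] if single else list(images)
    x = np.stack([img.pixels for img in batch]).astype(np.float32)[..., None]
    probs = model.predict_proba(x)
    return float(probs[0]) if single else probs
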