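"""Experiment protocol: splits, cross-validation, training, and metrics.

The screening experiments follow a fixed recipe: undersample to a balanced
set, stratified 80/20 train/test split (or stratified 10-fold
cross-validation), train with binary cross-entropy, and report the
confusion matrix with accuracy, sensitivity (recall), specificity, and
precision.  The British Diabetic Association screening guideline asks at
least 80% sensitivity and 95% specificity of such systems, which is why
sensitivity/specificity — not accuracy alone — are first-class outputs.

`run_end_to_end` packages the whole loop on synthetic data, with either raw
images or the preprocessed representation (enhanced green channel plus
vessel and exudate candidate masks) as network input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize
from sklearn.model_selection import StratifiedKFold

from dedscreen import enhancement as enh
from dedscreen import segmentation as seg
from dedscreen.models import CnnSpec, build_proposed_cnn
from dedscreen.nn import NumpyCnn
from dedscreen.synthetic_fundus import GroundTruth, SynthConfig, generate_dataset


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters (defaults are the study settings)."""

    image_side: int = 224
    optimizer: str = "rmsprop"
    batch_size: int = 32
    cv_folds: int = 10
    learning_rate: float = 3e-4
    loss: str = "bce"
    epochs: int = 50
    split_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.split_fraction < 1):
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class Metrics:
    """Confusion-matrix metrics; a ``None`` field means its denominator was
    zero and the metric is undefined (never silently reported as 0)."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None


# --------------------------------------------------------------------------
# Splitting and sampling (index-based; callers slice their own containers)
# --------------------------------------------------------------------------


def split_data(labels, fraction: float = 0.8, seed: int = 0):
    """Stratified train/test split; returns (train_idx, test_idx).

    Per class, the train share is ``round(fraction * n_class)`` clamped so
    both sides stay non-empty (hence within 1 of the exact fraction).
    """
    labels = np.asarray(labels)
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 items")
        idx = rng.permutation(idx)
        n_train = int(np.clip(round(fraction * len(idx)), 1, len(idx) - 1))
        train.extend(idx[:n_train])
        test.extend(idx[n_train:])
    return np.sort(np.array(train)), np.sort(np.array(test))


def kfold(labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Stratified k-fold assignment: entry i is the fold of item i.

    Folds are disjoint, tile the dataset exactly once, and differ in size
    by at most one.
    """
    labels = np.asarray(labels)
    if len(labels) < k:
        raise ValueError(f"need at least k={k} items, got {len(labels)}")
    if len(np.unique(labels)) > 1:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        assignment = np.empty(len(labels), dtype=np.int64)
        for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            assignment[test_idx] = fold
        return assignment
    # single-class degenerate case (e.g. leave-one-out on one label)
    rng = np.random.default_rng(seed)
    assignment = np.array([i % k for i in range(len(labels))])
    return rng.permutation(assignment)


def undersample(labels, n_per_class: int, seed: int = 0) -> np.ndarray:
    """Indices of a balanced subsample with exactly n_per_class per class."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    chosen = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < n_per_class:
            raise ValueError(f"class {cls!r} has {len(idx)} items, "
                             f"fewer than n_per_class={n_per_class}")
        chosen.extend(rng.choice(idx, size=n_per_class, replace=False))
    return np.sort(np.array(chosen))


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------


def confusion(y_true, y_pred, positive=1) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences must have equal length")
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionMatrix(
        tp=int((pos_t & pos_p).sum()),
        fn=int((pos_t & ~pos_p).sum()),
        fp=int((~pos_t & pos_p).sum()),
        tn=int((~pos_t & ~pos_p).sum()),
    )


def metrics(cm: ConfusionMatrix) -> Metrics:
    """Accuracy, sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision
    TP/(TP+FP); undefined ratios come back as None."""

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return Metrics(
        accuracy=ratio(cm.tp + cm.tn, cm.n),
        sensitivity=ratio(cm.tp, cm.tp + cm.fn),
        specificity=ratio(cm.tn, cm.tn + cm.fp),
        precision=ratio(cm.tp, cm.tp + cm.fp),
    )


def roc_points(y_true, scores) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(fpr, tpr, thresholds) by threshold sweep over the predicted scores."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(np.asarray(y_true), np.asarray(scores))
    return fpr, tpr, thr


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------


def train_model(spec: CnnSpec, data: tuple[np.ndarray, np.ndarray],
                cfg: TrainConfig | None = None) -> tuple[NumpyCnn, list[dict]]:
    """Train a model from a spec; returns (fitted model, per-epoch history)."""
    cfg = cfg or TrainConfig()
    x, y = data
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) == 0:
        raise ValueError("training data must be non-empty")
    if x.shape[1:] != spec.input_size:
        raise ValueError(f"data shape {x.shape[1:]} does not match "
                         f"spec input {spec.input_size}")
    model = NumpyCnn(spec, seed=cfg.seed)
    history = model.fit(
        x, y,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        optimizer=cfg.optimizer,
        lr=cfg.learning_rate,
        shuffle_seed=cfg.seed + 1,
    )
    return model, history


# --------------------------------------------------------------------------
# End-to-end synthetic screening experiment
# --------------------------------------------------------------------------


def _resize_to(img: np.ndarray, side: int) -> np.ndarray:
    if img.shape[0] == side and img.shape[1] == side:
        return img.astype(np.float32)
    out = resize(img.astype(np.float64), (side, side) + img.shape[2:],
                 order=1, preserve_range=True, anti_aliasing=True)
    return out.astype(np.float32)


def preprocess_for_training(img: np.ndarray, gt_side: int | None = None) -> np.ndarray:
    """The preprocessed network input: enhanced green channel plus vessel
    and exudate-candidate masks as three uint8-range channels."""
    g = enh.extract_green(img)
    e = enh.clahe(g)
    e = enh.correct_illumination(e)
    vessels = seg.segment_vessels(img)
    try:
        _, disc_mask = seg.detect_optic_disc(img)
    except seg.DetectionFailureError:
        disc_mask = np.zeros(g.shape, dtype=bool)
    exudates = seg.detect_exudates(img, disc_mask, vessels)
    return np.stack([
        e.astype(np.float32),
        vessels.astype(np.float32) * 255.0,
        exudates.astype(np.float32) * 255.0,
    ], axis=-1)


@dataclass(frozen=True)
class ExperimentResult:
    confusion: ConfusionMatrix
    metrics: Metrics
    history: list[dict]
    n_train: int
    n_test: int


def run_end_to_end(
    n_per_class: int = 100,
    classes: tuple[str, str] = ("normal", "mild_dme"),
    input_side: int = 64,
    base_filters: int = 8,
    epochs: int = 10,
    batch_size: int = 8,
    seed: int = 0,
    preprocessed: bool = False,
    synth: SynthConfig | None = None,
    items: list[tuple[np.ndarray, GroundTruth]] | None = None,
) -> ExperimentResult:
    """Generate a balanced synthetic set, split 80/20 stratified, train a
    reduced-width screening CNN, and score the held-out images.

    The whole experiment is scaled to desktop CPU budgets: a narrow 64 px
    variant of the screening CNN, few epochs, and a mini-batch size scaled
    down with the dataset (the full-size study trains with batch 32 on
    larger sets; 160 training images at batch 8 give the optimizer a
    comparable number of update steps per epoch).

    ``preprocessed=True`` feeds the enhancement+segmentation representation
    instead of the raw RGB image; pass ``items`` to reuse an already
    generated dataset across arms of a comparison.
    """
    synth = synth or SynthConfig(seed=seed)
    if items is None:
        items = generate_dataset(synth, n_per_class, classes)
    labels = np.array([gt.label for _, gt in items])
    y = (labels == classes[1]).astype(np.int64)

    if preprocessed:
        feats = [preprocess_for_training(img) for img, _ in items]
    else:
        feats = [img.astype(np.float32) for img, _ in items]
    x = np.stack([_resize_to(f, input_side) for f in feats]) / 255.0

    train_idx, test_idx = split_data(y, fraction=0.8, seed=seed)
    spec = build_proposed_cnn(input_side=input_side, n_classes=2,
                              base_filters=base_filters)
    cfg = TrainConfig(image_side=input_side, epochs=epochs,
                      batch_size=batch_size, seed=seed)
    model, history = train_model(spec, (x[train_idx], y[train_idx]), cfg)
    y_pred = model.predict(x[test_idx])
    cm = confusion(y[test_idx], y_pred)
    return ExperimentResult(
        confusion=cm,
        metrics=metrics(cm),
        history=history,
        n_train=len(train_idx),
        n_test=len(test_idx),
    )
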