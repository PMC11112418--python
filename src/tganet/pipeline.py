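"""Training and evaluation harness: stratified k-fold cross-validation,
cross-entropy training with Adam, best-epoch checkpoint selection, and the
end-to-end segmentation -> masking -> classification run.

Defaults follow the training protocol used throughout this package: Adam at
learning rate 1e-4, 20 epochs, batch size 20, 5-fold CV, with the training
split of each fold class-balanced by augmentation before training (balanced
copies never leak into the fold's validation set).
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .attention_viz import panel
from .augmentation import AugmentConfig, balance_classes
from .metrics import MetricSet, evaluate_predictions, summarize_cv
from .model import TGANet, save_tganet
from .nn import F32, bilinear_resize
from .segmentation import apply_mask, binarize, load_unet, predict_probs
from .synthetic_data import TASKS, LabeledImage, load_image, load_mask, save_image


@dataclass(frozen=True)
class TrainConfig:
    task: str = "coating"
    lr: float = 1e-4
    epochs: int = 20
    batch_size: int = 20
    k_folds: int = 5
    seed: int = 0
    pretrained: bool = False
    width_multiplier: float = 1.0
    input_size: int = 64              # images are bilinearly resized to this
    balance_training: bool = True
    balance_validation: bool = False  # optional, mirrors train/val balancing
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")

    @property
    def n_classes(self) -> int:
        return len(TASKS[self.task])


@dataclass
class CVReport:
    per_fold: list[MetricSet]
    summary: dict[str, tuple[float, float]]
    fold_assignment: np.ndarray
    config: TrainConfig
    histories: list[list[dict]]
    models: list = field(default_factory=list, repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"metric": m, "mean": mu, "sd": sd}
                for m, (mu, sd) in self.summary.items()]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def make_folds(labels, k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment.

    Within each class the sample indices are shuffled and dealt round-robin
    across folds, so per-fold class counts differ by at most one.  Classes
    with fewer than k members are distributed as evenly as possible (with a
    warning).  Returns an int array of fold ids, one per sample.
    """
    y = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assignment = np.full(y.size, -1, dtype=int)
    offset = 0
    for c in sorted(np.unique(y)):
        idx = np.flatnonzero(y == c)
        if idx.size < k:
            warnings.warn(f"class {c} has {idx.size} < k={k} samples; "
                          f"distributing as evenly as possible", stacklevel=2)
        idx = rng.permutation(idx)
        # rotate the starting fold per class so small classes spread out
        assignment[idx] = (np.arange(idx.size) + offset) % k
        offset += idx.size % k
    assert (assignment >= 0).all()
    return assignment


def _check_partition(assignment: np.ndarray, labels: np.ndarray, k: int) -> None:
    assert assignment.min() >= 0 and assignment.max() < k, "fold id out of range"
    for c in np.unique(labels):
        counts = np.bincount(assignment[labels == c], minlength=k)
        assert counts.max() - counts.min() <= 1, (
            f"class {c} not stratified across folds: {counts}")


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _to_batch(images: list[np.ndarray], size: int) -> np.ndarray:
    """Stack HxWx3 [0,1] images into an NCHW batch, resizing if needed."""
    out = np.empty((len(images), 3, size, size), dtype=F32)
    for i, im in enumerate(images):
        x = np.ascontiguousarray(im.transpose(2, 0, 1), dtype=F32)
        if x.shape[1:] != (size, size):
            x = bilinear_resize(x[None], (size, size))[0]
        out[i] = x
    return out


def predict_batch(model: TGANet, x: np.ndarray, batch_size: int = 32
                  ) -> tuple[np.ndarray, np.ndarray]:
    """(predicted labels, class probabilities) for an NCHW batch."""
    probs = []
    for s in range(0, x.shape[0], batch_size):
        probs.append(model.forward(x[s:s + batch_size], cache=False).probs)
    p = np.concatenate(probs, axis=0)
    return p.argmax(axis=1), p


def train_classifier(model: TGANet, train_data: tuple[np.ndarray, np.ndarray],
                     val_data: tuple[np.ndarray, np.ndarray],
                     config: TrainConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[TGANet, list[dict]]:
    """Train with softmax cross-entropy + Adam; return the epoch checkpoint
    with the best validation accuracy (ties -> earliest epoch).

    ``train_data`` / ``val_data`` are (NCHW images in [0,1], integer labels).
    """
    x_tr, y_tr = train_data
    x_va, y_va = val_data
    for y in (y_tr, y_va):
        if np.asarray(y).size and (np.min(y) < 0 or np.max(y) >= config.n_classes):
            raise ValueError(f"labels outside [0, {config.n_classes}) for "
                             f"task {config.task!r}")
    if x_tr.shape[0] == 0:
        raise ValueError("empty training set")
    if config.epochs == 0:
        return model, []
    rng = rng or np.random.default_rng(config.seed)
    opt = nn.Adam(model.params, lr=config.lr)
    history: list[dict] = []
    best: tuple[float, int, list[np.ndarray]] | None = None
    y_tr = np.asarray(y_tr, dtype=int)
    for epoch in range(config.epochs):
        order = rng.permutation(x_tr.shape[0])
        losses = []
        for s in range(0, order.size, config.batch_size):
            idx = order[s:s + config.batch_size]
            opt.zero_grad()
            pred = model.forward(x_tr[idx])
            loss, dlogits = nn.softmax_cross_entropy(pred.logits, y_tr[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        yhat, _ = predict_batch(model, x_va)
        val_acc = float((yhat == np.asarray(y_va)).mean())
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_acc": val_acc})
        if best is None or val_acc > best[0]:
            best = (val_acc, epoch, [p.value.copy() for p in model.params])
    for p, v in zip(model.params, best[2]):
        p.value[...] = v
    assert best[0] == max(h["val_acc"] for h in history)
    return model, history


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def run_cv(items: list[LabeledImage], config: TrainConfig) -> CVReport:
    """Stratified k-fold cross-validation of TGANet on labeled images.

    Per fold: the training split is class-balanced by augmentation (balanced
    copies stay inside the training split), a fresh model is trained, and all
    metrics are computed on the untouched validation fold.  Per-fold seeds
    derive deterministically from ``config.seed``.
    """
    task = config.task
    for it in items:
        if task not in it.labels:
            raise ValueError(f"sample {it.id!r} lacks a {task!r} label")
    labels = np.array([it.labels[task] for it in items], dtype=int)
    assignment = make_folds(labels, config.k_folds, config.seed)
    _check_partition(assignment, labels, config.k_folds)

    per_fold: list[MetricSet] = []
    histories: list[list[dict]] = []
    models: list[TGANet] = []
    for fold in range(config.k_folds):
        tr = [it for it, a in zip(items, assignment) if a != fold]
        va = [it for it, a in zip(items, assignment) if a == fold]
        fold_rng = np.random.default_rng([config.seed, fold])
        if config.balance_training:
            tr = balance_classes(tr, task, config.augment, fold_rng)
        if config.balance_validation:
            va = balance_classes(va, task, config.augment, fold_rng)
        val_ids = {it.id for it in va}
        assert not any(it.meta.get("augmented_from") in val_ids for it in tr), \
            "augmented copy of a validation sample leaked into training"
        x_tr = _to_batch([it.image for it in tr], config.input_size)
        y_tr = np.array([it.labels[task] for it in tr], dtype=int)
        x_va = _to_batch([it.image for it in va], config.input_size)
        y_va = np.array([it.labels[task] for it in va], dtype=int)
        model = TGANet(config.n_classes, config.width_multiplier,
                       seed=int(fold_rng.integers(2 ** 31)),
                       pretrained=config.pretrained)
        model, hist = train_classifier(model, (x_tr, y_tr), (x_va, y_va),
                                       config, rng=fold_rng)
        yhat, probs = predict_batch(model, x_va)
        per_fold.append(evaluate_predictions(y_va, yhat, probs, config.n_classes))
        histories.append(hist)
        models.append(model)
    return CVReport(per_fold=per_fold, summary=summarize_cv(per_fold),
                    fold_assignment=assignment, config=config,
                    histories=histories, models=models)


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------

def end_to_end(image_dir: str | Path, labels_csv: str | Path,
               config: TrainConfig, masks_dir: str | Path | None = None,
               unet_checkpoint: str | Path | None = None,
               skip_segmentation: bool = False,
               out_dir: str | Path | None = None) -> CVReport:
    """Full pipeline: segment (or accept provided masks), apply the mask,
    then cross-validate the classifier.  Optionally writes the report CSV,
    the best fold model checkpoint, and attention-overlay panels."""
    image_dir = Path(image_dir)
    table = pd.read_csv(labels_csv, dtype={"id": str})
    if config.task not in table.columns:
        raise ValueError(f"labels CSV has no {config.task!r} column")
    table = table[pd.to_numeric(table[config.task], errors="coerce").notna()]
    missing = [i for i in table["id"] if not (image_dir / f"{i}.png").exists()]
    if missing:
        raise FileNotFoundError(f"images referenced by the label table are "
                                f"missing: {missing}")
    unet = load_unet(unet_checkpoint) if (unet_checkpoint and not skip_segmentation) else None
    if unet is None and not skip_segmentation and masks_dir is None:
        raise ValueError("provide masks_dir, a unet_checkpoint, or skip_segmentation")

    items: list[LabeledImage] = []
    for _, row in table.iterrows():
        sid = row["id"]
        try:
            img = load_image(image_dir / f"{sid}.png")
        except Exception as exc:
            raise IOError(f"could not read image for sample {sid!r}: {exc}") from exc
        if skip_segmentation and masks_dir is None:
            mask = None
            masked = img
        else:
            if masks_dir is not None:
                mask = load_mask(Path(masks_dir) / f"{sid}.png")
            else:
                mask = binarize(predict_probs(unet, img))
            masked = apply_mask(img, mask)
        items.append(LabeledImage(image=masked, mask=mask,
                                  labels={config.task: int(row[config.task])},
                                  id=sid))
    report = run_cv(items, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_frame().to_csv(out / "report.csv", index=False)
        best_fold = int(np.argmax([m.acc for m in report.per_fold]))
        best_model = report.models[best_fold]
        save_tganet(best_model, out / "best_model.npz")
        _write_panels(best_model, items, report.fold_assignment, best_fold,
                      config, out / "panels")
    return report


def _write_panels(model: TGANet, items, assignment, fold, config,
                  panel_dir: Path, limit: int = 6) -> None:
    panel_dir.mkdir(parents=True, exist_ok=True)
    val_items = [it for it, a in zip(items, assignment) if a == fold][:limit]
    for it in val_items:
        x = _to_batch([it.image], config.input_size)
        pred = model.forward(x, cache=False)
        img = x[0].transpose(1, 2, 0)
        save_image(panel(img, pred.attention_b2[0, 0], pred.attention_b4[0, 0]),
                   panel_dir / f"{it.id}.png")
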