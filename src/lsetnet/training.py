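"""Supervised training: cross-entropy, Adam with step decay, early stopping
on validation macro-F1, and grouped stratified k-fold cross-validation.

The learning-rate schedule is pinned at both endpoints (1e-3 at epoch 0,
1e-4 from the last scheduled step on) and decays by a factor of
10^(-1/3) every 15 epochs, i.e. three steps over a 50-epoch run.

Cross-validation folds are stratified by class and grouped by
augmentation parentage: an original and all its augmented children stay
on the same side of every fold boundary, so no fold is evaluated on a
near-duplicate of its own training data.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .architecture import LSeTNet, build_lsetnet
from .config import RunConfig
from .evaluation import class_report, confusion
from .manifest import DatasetManifest, LeakageError
from .nn import Adam
from .nn.layers import softmax
from .split_augment import audit_leakage

logger = logging.getLogger("lsetnet")

F32 = np.float32


# ---------------------------------------------------------------------------
# loss and schedule
# ---------------------------------------------------------------------------

def cross_entropy(y_true: np.ndarray, y_pred: np.ndarray, eps: float = 1e-12,
                  strict: bool = True) -> float:
    """Categorical cross-entropy in nats: -sum_i y_i log(p_i).

    ``y_true`` is one-hot, ``y_pred`` probabilities on the simplex
    (clamped at ``eps`` for log safety).  For a batch the mean per-sample
    loss is returned.  In strict mode a prediction that is not normalized
    to within 1e-3 is fatal.
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch between labels and predictions")
    if strict:
        sums = y_pred.sum(axis=-1)
        if np.abs(sums - 1.0).max() > 1e-3:
            raise ValueError("predictions are not normalized probability vectors")
    p = np.clip(y_pred, eps, None)
    per_sample = -(y_true * np.log(p)).sum(axis=-1)
    return float(per_sample.mean())


def lr_schedule(epoch: int, initial: float = 1e-3, final: float = 1e-4,
                step_epochs: int = 15, n_steps: int = 3) -> float:
    """Step decay: lr = initial * (final/initial)^(k/n_steps), k = epoch//step.

    Monotone non-increasing; reaches ``final`` exactly at the last step
    (epoch 45 with the defaults) and stays there.
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    k = min(epoch // step_epochs, n_steps)
    return initial * (final / initial) ** (k / n_steps)


# ---------------------------------------------------------------------------
# histories and results
# ---------------------------------------------------------------------------

@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)  # per-epoch metric rows
    best_epoch: int = -1
    stop_reason: str = ""
    seed: int = 0
    monitor: str = "val_macro_f1"

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        cols = list(self.epochs[0].keys()) if self.epochs else ["epoch"]
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.DictWriter(fh, fieldnames=cols)
            w.writeheader()
            w.writerows(self.epochs)


@dataclass
class FoldResult:
    fold: int
    held_out_size: int
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _as_onehot(y: np.ndarray, k: int) -> np.ndarray:
    return np.eye(k, dtype=F32)[np.asarray(y, dtype=int)]


def _evaluate(model: LSeTNet, x: np.ndarray, y: np.ndarray, classes: list[str],
              batch_size: int) -> dict:
    probs = model.predict_proba(x, batch_size=batch_size)
    pred = probs.argmax(axis=1)
    onehot = _as_onehot(y, probs.shape[1])
    loss = cross_entropy(onehot, probs, strict=False)
    cm = confusion([classes[i] for i in y], [classes[i] for i in pred], classes)
    rep = class_report(cm)
    return {"loss": loss, "accuracy": rep.accuracy, "macro_f1": rep.macro_f1,
            "macro_precision": rep.macro_precision, "macro_recall": rep.macro_recall}


def train(model: LSeTNet, train_data: tuple[np.ndarray, np.ndarray],
          val_data: tuple[np.ndarray, np.ndarray], config: RunConfig,
          classes: list[str] | None = None,
          train_manifest: DatasetManifest | None = None,
          val_manifest: DatasetManifest | None = None,
          monitor: str = "val_macro_f1",
          verbose: bool = False) -> TrainHistory:
    """Train with Adam + step decay + early stopping; best weights restored.

    ``train_data``/``val_data`` are (X, y) with X standardized float
    arrays (NHWC) and y integer labels.  When manifests are supplied, a
    leakage audit runs first and any violation refuses to train.  The
    monitored metric (validation macro-F1 by default, maximized; any
    ``*loss`` monitor is minimized) drives early stopping with
    ``config.patience``.
    """
    if train_manifest is not None or val_manifest is not None:
        combined = DatasetManifest(
            records=(list(train_manifest.records) if train_manifest else [])
            + (list(val_manifest.records) if val_manifest else [])
        )
        report = audit_leakage(combined)
        train_ids = {r.image_id for r in train_manifest.records} if train_manifest else set()
        val_ids = {r.image_id for r in val_manifest.records} if val_manifest else set()
        overlap = train_ids & val_ids
        if overlap or not report.passed:
            raise LeakageError(
                f"leakage audit failed: overlap={sorted(overlap)[:3]} "
                f"violations={report.violations[:3]}"
            )

    x_train, y_train = np.asarray(train_data[0], dtype=F32), np.asarray(train_data[1])
    x_val, y_val = np.asarray(val_data[0], dtype=F32), np.asarray(val_data[1])
    k = model.config.num_classes
    classes = classes or [str(i) for i in range(k)]
    minimize = monitor.endswith("loss")

    opt = Adam(model, lr=config.initial_lr, beta1=config.beta1, beta2=config.beta2)
    rng = np.random.default_rng(config.seed)
    history = TrainHistory(seed=config.seed, monitor=monitor)
    best_metric = np.inf if minimize else -np.inf
    best_state = model.state_dict()
    since_best = 0

    for epoch in range(config.max_epochs):
        opt.lr = lr_schedule(epoch, config.initial_lr, config.final_lr)
        order = rng.permutation(len(x_train))
        losses = []
        hits = 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits = model.forward(xb, training=True)
            probs = softmax(logits)
            onehot = _as_onehot(yb, k)
            losses.append(cross_entropy(onehot, probs, strict=False))
            hits += int((probs.argmax(axis=1) == yb).sum())
            model.backward((probs - onehot) / F32(len(idx)))
            opt.step()
        val = _evaluate(model, x_val, y_val, classes, config.batch_size)
        row = {
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": float(np.mean(losses)),
            "train_acc": hits / len(x_train),
            "val_loss": val["loss"],
            "val_acc": val["accuracy"],
            "val_macro_f1": val["macro_f1"],
        }
        history.epochs.append(row)
        if verbose:
            logger.info("epoch %d: train_loss=%.4f val_acc=%.4f val_f1=%.4f",
                        epoch, row["train_loss"], row["val_acc"], row["val_macro_f1"])

        metric = row[monitor]
        improved = metric < best_metric if minimize else metric > best_metric
        if improved:
            best_metric = metric
            best_state = model.state_dict()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                history.stop_reason = "early_stop"
                break
    if not history.stop_reason:
        history.stop_reason = "max_epochs"
    model.load_state_dict(best_state)
    return history


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def make_folds(manifest: DatasetManifest, k: int, seed: int) -> list[list[str]]:
    """Partition record ids into k folds, stratified by class, grouped by parent.

    Groups (an original plus its augmented children) are shuffled per
    class with a seeded RNG and dealt to the currently smallest fold, so
    fold sizes per class are as equal as the group sizes allow.  The
    partition is a pure function of (manifest, k, seed).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    folds: list[list[str]] = [[] for _ in range(k)]
    for ci, cls in enumerate(manifest.classes):
        recs = [r for r in manifest.records if r.label == cls]
        groups: dict[str, list[str]] = {}
        for r in recs:
            groups.setdefault(r.parent, []).append(r.image_id)
        names = sorted(groups)
        if len(names) < k:
            raise ValueError(
                f"class {cls!r} has {len(names)} parent groups, fewer than k={k}"
            )
        rng = np.random.default_rng([seed, ci])
        order = rng.permutation(len(names))
        sizes = [0] * k
        for gi in order:
            g = groups[names[gi]]
            target = int(np.argmin(sizes))
            folds[target].extend(g)
            sizes[target] += len(g)
    return [sorted(f) for f in folds]


def kfold_cv(manifest: DatasetManifest, data: dict[str, tuple[np.ndarray, int]],
             config: RunConfig, k: int | None = None,
             model_factory=None, classes: list[str] | None = None,
             monitor: str = "val_macro_f1") -> list[FoldResult]:
    """Stratified, parentage-grouped k-fold CV over a training manifest.

    ``data`` maps image_id -> (standardized array, label index).  Each
    fold trains a fresh model (via ``model_factory(seed)``) on k-1 parts
    and is evaluated on the held-out part with the evaluation module.
    """
    k = k or config.k_folds
    classes = classes or manifest.classes
    folds = make_folds(manifest, k, config.seed)
    if model_factory is None:
        model_factory = lambda seed: build_lsetnet(seed=seed)  # noqa: E731

    results = []
    for fi, held in enumerate(folds):
        held_set = set(held)
        train_ids = [r.image_id for r in manifest.records if r.image_id not in held_set]
        x_tr = np.stack([data[i][0] for i in train_ids])
        y_tr = np.asarray([data[i][1] for i in train_ids])
        x_ho = np.stack([data[i][0] for i in held])
        y_ho = np.asarray([data[i][1] for i in held])
        model = model_factory(config.seed + fi)
        train(model, (x_tr, y_tr), (x_ho, y_ho), config, classes=classes, monitor=monitor)
        ev = _evaluate(model, x_ho, y_ho, classes, config.batch_size)
        results.append(FoldResult(
            fold=fi, held_out_size=len(held), accuracy=ev["accuracy"],
            macro_precision=ev["macro_precision"], macro_recall=ev["macro_recall"],
            macro_f1=ev["macro_f1"],
        ))
        logger.info("fold %d: n=%d acc=%.4f f1=%.4f", fi, len(held),
                    ev["accuracy"], ev["macro_f1"])
    return results
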