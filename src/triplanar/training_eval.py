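"""Subject-wise cross-validation, the training loop, metrics and baselines.

Fold assignment is always at the subject level: all of one subject's
samples land in exactly one of train / validation / test within a fold, so
no individual leaks across the split.  Per fold, ~1/k of the subjects are
test, 10% of the remainder are validation and the rest train.

Training follows a fixed recipe: Adam with a step-decayed learning rate
``lr(e) = base * 0.5 ** floor(e / halve_every)`` (defaults 0.0025 and 50),
categorical cross-entropy, a checkpoint of the epoch with the best
validation result, and early stopping once the training loss has not
improved on its running minimum for ``patience`` (default 6) consecutive
epochs.  The checkpointed — not the last — model is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    precision_score,
)
from sklearn.svm import LinearSVC

from .architectures import (
    ArchitectureConfig,
    build_model,
    reference_config,
    transform_batch,
)
from .io_volumes import MOVEMENT_CLASSES, Sample3D
from .nn import Adam
from .preprocessing import apply_normalization, fit_normalization
from .slicing import flatten_for_svm

LABEL_TO_INDEX = {lab: i for i, lab in enumerate(MOVEMENT_CLASSES)}


@dataclass
class FoldSplit:
    fold_id: int
    train_subjects: list[str]
    val_subjects: list[str]
    test_subjects: list[str]

    def __post_init__(self):
        parts = [set(self.train_subjects), set(self.val_subjects), set(self.test_subjects)]
        for i in range(3):
            for j in range(i + 1, 3):
                if parts[i] & parts[j]:
                    raise ValueError(
                        f"fold {self.fold_id}: subject(s) {parts[i] & parts[j]} in two partitions"
                    )


@dataclass
class TrainConfig:
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 6
    base_lr: float = 0.0025
    halve_every: int = 50
    monitor: str = "accuracy"  # or "loss": which validation result to checkpoint
    seed: int = 0


@dataclass
class TrainState:
    epoch: int = 0
    learning_rate: float = 0.0025
    best_val_metric: float = -np.inf
    best_epoch: int = -1
    epochs_without_train_improvement: int = 0


@dataclass
class MetricsReport:
    accuracy: float
    precision: float  # macro-averaged
    f1: float  # macro-averaged
    confusion: np.ndarray

    def as_row(self, fold: int, model: str) -> dict:
        return {
            "fold": fold,
            "model": model,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "f1": self.f1,
        }


@dataclass
class CrossvalResult:
    model_kind: str
    reports: list[MetricsReport]
    splits: list[FoldSplit]
    models: list | None = None  # per-fold trained models, when requested

    def mean_std(self, metric: str) -> tuple[float, float]:
        vals = np.array([getattr(r, metric) for r in self.reports])
        return float(vals.mean()), float(vals.std())

    def summary(self) -> str:
        lines = []
        for metric in ("accuracy", "precision", "f1"):
            m, s = self.mean_std(metric)
            lines.append(f"{metric}: {100 * m:.2f} ± {100 * s:.2f} %")
        return "\n".join(lines)


def split_subjectwise(
    subject_ids, k: int = 5, seed: int = 0, val_fraction: float = 0.1
) -> list[FoldSplit]:
    """Deterministic subject-level k-fold splits with a nested validation set."""
    subjects = list(dict.fromkeys(subject_ids))  # unique, stable order
    if len(subjects) < k:
        raise ValueError(f"need at least k={k} subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    test_groups = [list(g) for g in np.array_split(np.array(order, dtype=object), k)]
    folds = []
    for fold_id, test in enumerate(test_groups):
        remaining = [s for s in order if s not in set(test)]
        n_val = max(1, round(val_fraction * len(remaining)))
        folds.append(
            FoldSplit(
                fold_id=fold_id,
                train_subjects=remaining[n_val:],
                val_subjects=remaining[:n_val],
                test_subjects=list(test),
            )
        )
    return folds


def lr_at_epoch(epoch: int, base_lr: float = 0.0025, halve_every: int = 50) -> float:
    """Step decay: base_lr * 0.5 ** floor(epoch / halve_every)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return base_lr * 0.5 ** (epoch // halve_every)


def _take(X, idx):
    return tuple(x[idx] for x in X) if isinstance(X, tuple) else X[idx]


def _n_samples(X) -> int:
    return X[0].shape[0] if isinstance(X, tuple) else X.shape[0]


def predict_proba(model, X, batch_size: int = 64) -> np.ndarray:
    """Evaluation-mode forward pass, batched."""
    n = _n_samples(X)
    out = []
    for lo in range(0, n, batch_size):
        out.append(model.forward(_take(X, slice(lo, lo + batch_size)), training=False))
    return np.concatenate(out, axis=0)


def cross_entropy(probs: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    return float(-np.mean(np.log(np.clip(probs[np.arange(len(y)), y], eps, None))))


def train(model, train_data, val_data, config: TrainConfig | None = None):
    """Fit ``model`` on ``train_data=(X, y)``, checkpointing on ``val_data``.

    Returns ``(model, history)`` with the best-validation weights restored;
    ``history`` is a list of per-epoch dicts (epoch, lr, train_loss,
    val_accuracy, val_loss).
    """
    cfg = config or TrainConfig()
    X_tr, y_tr = train_data
    X_val, y_val = val_data
    n = _n_samples(X_tr)
    if n == 0 or _n_samples(X_val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng([cfg.seed, 0x7E57])
    opt = Adam(model)
    state = TrainState()
    best_train_loss = np.inf
    best_state = None
    history = []
    sign = 1.0 if cfg.monitor == "accuracy" else -1.0
    for epoch in range(cfg.max_epochs):
        lr = lr_at_epoch(epoch, cfg.base_lr, cfg.halve_every)
        state.epoch, state.learning_rate = epoch, lr
        perm = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            idx = perm[lo : lo + cfg.batch_size]
            xb, yb = _take(X_tr, idx), y_tr[idx]
            probs = model.forward(xb, training=True)
            loss = cross_entropy(probs, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} (lr={lr}); aborting"
                )
            losses.append(loss)
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(yb)), yb] = 1.0
            dprobs = -(onehot / np.clip(probs, 1e-12, None)) / len(yb)
            model.backward(dprobs)
            opt.step(lr)
        train_loss = float(np.mean(losses))
        val_probs = predict_proba(model, X_val)
        val_pred = val_probs.argmax(axis=1)
        val_acc = float(np.mean(val_pred == y_val))
        val_loss = cross_entropy(val_probs, y_val)
        history.append(
            {
                "epoch": epoch,
                "lr": lr,
                "train_loss": train_loss,
                "val_accuracy": val_acc,
                "val_loss": val_loss,
            }
        )
        metric = sign * (val_acc if cfg.monitor == "accuracy" else val_loss)
        if metric > state.best_val_metric:  # ties keep the earliest epoch
            state.best_val_metric = metric
            state.best_epoch = epoch
            best_state = model.state_dict()
        if train_loss < best_train_loss:
            best_train_loss = train_loss
            state.epochs_without_train_improvement = 0
        else:
            state.epochs_without_train_improvement += 1
            if state.epochs_without_train_improvement >= cfg.patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def metrics_from_predictions(y_true, y_pred, n_classes: int = 5) -> MetricsReport:
    labels = np.arange(n_classes)
    return MetricsReport(
        accuracy=float(accuracy_score(y_true, y_pred)),
        precision=float(precision_score(y_true, y_pred, labels=labels, average="macro", zero_division=0)),
        f1=float(f1_score(y_true, y_pred, labels=labels, average="macro", zero_division=0)),
        confusion=confusion_matrix(y_true, y_pred, labels=labels),
    )


def evaluate(model, test_data, n_classes: int = 5) -> MetricsReport:
    X, y = test_data
    if _n_samples(X) == 0:
        raise ValueError("test set is empty")
    pred = predict_proba(model, X).argmax(axis=1)
    return metrics_from_predictions(y, pred, n_classes)


def pca_svm_baseline(
    train_data, test_data, n_components: int = 500, C: float = 1.0, seed: int = 0
) -> MetricsReport:
    """PCA projection of the flattened voxels, then a linear L2 SVM."""
    X_tr, y_tr = train_data
    X_te, y_te = test_data
    max_comp = min(X_tr.shape[0], X_tr.shape[1])
    if n_components > max_comp:
        warnings.warn(
            f"n_components={n_components} exceeds min(n_samples, n_features)={max_comp}; clamping"
        )
        n_components = max_comp
    pca = PCA(n_components=n_components, random_state=seed)
    z_tr = pca.fit_transform(X_tr)
    z_te = pca.transform(X_te)
    svm = LinearSVC(C=C, random_state=seed)
    svm.fit(z_tr, y_tr)
    return metrics_from_predictions(y_te, svm.predict(z_te))


def encode_labels(samples: list[Sample3D]) -> np.ndarray:
    return np.array([LABEL_TO_INDEX[s.label] for s in samples])


def fold_arrays(
    samples: list[Sample3D], split: FoldSplit, norm: str = "all_samples"
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-partition ``(volumes, labels)`` arrays for one fold.

    ``norm="all_samples"`` fits the voxel z-scoring statistics on the full
    sample set (the historical behavior, which lets test voxels influence
    the statistics); ``norm="train_only"`` fits them on the fold's
    training 80% (train + validation subjects) and applies them unchanged
    to the test subjects, so no test statistic touches training.
    ``norm="none"`` skips standardization.
    """
    if norm not in ("all_samples", "train_only", "none"):
        raise ValueError("norm must be 'all_samples', 'train_only' or 'none'")
    subject_ids = [s.subject_id for s in samples]
    y_all = encode_labels(samples)
    in_part = {
        **{s: "train" for s in split.train_subjects},
        **{s: "val" for s in split.val_subjects},
        **{s: "test" for s in split.test_subjects},
    }
    idx = {part: [] for part in ("train", "val", "test")}
    for i, sid in enumerate(subject_ids):
        idx[in_part[sid]].append(i)
    if norm == "all_samples":
        stats = fit_normalization(samples)
        samples = apply_normalization(samples, stats)
    elif norm == "train_only":
        fit_on = [samples[i] for i in idx["train"] + idx["val"]]
        stats = fit_normalization(fit_on, source="train_only")
        samples = apply_normalization(samples, stats)
    return {
        part: (
            np.stack([samples[i].volume for i in idx[part]]).astype(np.float32),
            y_all[idx[part]],
        )
        for part in idx
    }


def crossval(
    model_kind: str,
    samples: list[Sample3D],
    k: int = 5,
    seed: int = 0,
    norm: str = "all_samples",
    train_config: TrainConfig | None = None,
    arch_config: ArchitectureConfig | None = None,
    return_models: bool = False,
) -> CrossvalResult:
    """Subject-wise k-fold cross-validation of one model kind.

    ``model_kind`` is one of the six architectures or ``"pca_svm"``;
    ``norm`` is passed to :func:`fold_arrays`.  With ``return_models`` the
    per-fold trained models are kept on the result (neural kinds only).
    """
    subject_ids = [s.subject_id for s in samples]
    splits = split_subjectwise(subject_ids, k=k, seed=seed)
    volume_shape = samples[0].volume.shape
    reports = []
    models = []
    for split in splits:
        arrays = fold_arrays(samples, split, norm=norm)
        vols = {part: arrays[part][0] for part in arrays}
        ys = {part: arrays[part][1] for part in arrays}
        if model_kind == "pca_svm":
            flat = {p: np.stack([flatten_for_svm(v) for v in vols[p]]) for p in vols}
            report = pca_svm_baseline(
                (np.concatenate([flat["train"], flat["val"]]), np.concatenate([ys["train"], ys["val"]])),
                (flat["test"], ys["test"]),
                seed=seed,
            )
        else:
            config = arch_config or reference_config(model_kind, volume_shape)
            X = {p: transform_batch(config, vols[p]) for p in vols}
            model = build_model(config, np.random.default_rng([seed, split.fold_id]))
            tcfg = train_config or TrainConfig()
            tcfg = TrainConfig(**{**tcfg.__dict__, "seed": seed * 1000 + split.fold_id})
            model, _ = train(model, (X["train"], ys["train"]), (X["val"], ys["val"]), tcfg)
            report = evaluate(model, (X["test"], ys["test"]), n_classes=config.n_classes)
            if return_models:
                models.append(model)
        reports.append(report)
    return CrossvalResult(
        model_kind=model_kind,
        reports=reports,
        splits=splits,
        models=models if return_models else None,
    )
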