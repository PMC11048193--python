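"""Backpropagation neural-network classification of particle feature tables.

The classifier is a multilayer perceptron with five hidden layers
(64-128-256-128-64 neurons by default), trained with backpropagation on
z-scored features.  The labeled table is split 60/20/20 into training,
validation, and test partitions, stratified by label; training minimizes
softmax cross-entropy with an adaptive-moment optimizer, and the model
state with the lowest validation loss is kept (early stopping).

Evaluation is a confusion matrix (rows = actual category, columns =
predicted category) with overall accuracy = trace / total and per-class
one-vs-rest TP/FN/FP/TN counts, from which the binary accuracy
(TP+TN)/(TP+FP+TN+FN) is recovered per class.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import log_loss
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

from .features import feature_columns, feature_frame
from .pulse_processing import StokesTrace

__all__ = [
    "MLPConfig",
    "SplitSpec",
    "ConfusionMatrix",
    "TrainedClassifier",
    "split_dataset",
    "train_classifier",
    "evaluate",
    "compare_pac_pfec",
]


@dataclass(frozen=True)
class MLPConfig:
    """Hyperparameters of the backpropagation network."""

    hidden_sizes: tuple[int, ...] = (64, 128, 256, 128, 64)
    activation: str = "relu"
    learning_rate: float = 1e-3
    epochs: int = 300
    batch_size: int = 64
    patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden layer sizes must be positive")
        if self.epochs <= 0 or self.patience <= 0 or self.batch_size <= 0:
            raise ValueError("epochs, patience and batch_size must be positive")


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test partition fractions (default 60/20/20)."""

    train: float = 0.6
    validation: float = 0.2
    test: float = 0.2
    stratify: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.train + self.validation + self.test
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {total}")
        if min(self.train, self.validation, self.test) <= 0:
            raise ValueError("all split fractions must be positive")


@dataclass
class ConfusionMatrix:
    """K x K confusion counts; rows are actual, columns predicted."""

    classes: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        K = len(self.classes)
        if self.counts.shape != (K, K):
            raise ValueError("counts must be K x K for K classes")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        """Overall accuracy: correctly classified fraction (trace / total)."""
        return float(np.trace(self.counts)) / self.total

    def one_vs_rest(self, cls) -> dict[str, int]:
        """Per-class TP / FN / FP / TN counts."""
        k = self.classes.index(cls)
        tp = int(self.counts[k, k])
        fn = int(self.counts[k].sum() - tp)
        fp = int(self.counts[:, k].sum() - tp)
        tn = self.total - tp - fn - fp
        return {"TP": tp, "FN": fn, "FP": fp, "TN": tn}

    def class_accuracy(self, cls) -> float:
        """Binary accuracy (TP+TN)/(TP+FP+TN+FN) for one class vs the rest."""
        c = self.one_vs_rest(cls)
        return (c["TP"] + c["TN"]) / self.total

    def recall(self, cls) -> float:
        """Within-class correct fraction (the per-class diagonal rate)."""
        c = self.one_vs_rest(cls)
        denom = c["TP"] + c["FN"]
        return c["TP"] / denom if denom else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    def report(self) -> str:
        lines = ["Confusion matrix (rows = actual, columns = predicted):",
                 self.to_frame().to_string(),
                 f"Overall accuracy: {self.accuracy:.4f}"]
        for cls in self.classes:
            c = self.one_vs_rest(cls)
            lines.append(
                f"  {cls}: recall={self.recall(cls):.4f} "
                f"TP={c['TP']} FN={c['FN']} FP={c['FP']} TN={c['TN']}"
            )
        return "\n".join(lines)


def split_dataset(
    features: pd.DataFrame, spec: SplitSpec = SplitSpec(), label_col: str = "label"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition a labeled table into disjoint train/validation/test tables.

    Stratified by label when ``spec.stratify`` (the default) and
    deterministic under ``spec.seed``.
    """
    if label_col not in features.columns:
        raise ValueError(f"missing label column {label_col!r}")
    y = features[label_col]
    strat = y if spec.stratify else None
    rest_frac = spec.validation + spec.test
    train_df, rest = train_test_split(
        features, test_size=rest_frac, stratify=strat, random_state=spec.seed
    )
    strat_rest = rest[label_col] if spec.stratify else None
    val_df, test_df = train_test_split(
        rest,
        test_size=spec.test / rest_frac,
        stratify=strat_rest,
        random_state=spec.seed,
    )
    return train_df, val_df, test_df


@dataclass
class TrainedClassifier:
    """A fitted network plus the preprocessing needed to apply it."""

    model: MLPClassifier
    feature_names: list[str]
    classes: list
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    config: MLPConfig
    history: dict = field(default_factory=dict)

    def _matrix(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in features.columns]
        extra = [
            c for c in features.columns
            if c not in self.feature_names and c not in ("label", "qc_imputed", "sample_id")
        ]
        if missing:
            raise ValueError(
                f"feature schema mismatch: missing columns {missing}; unexpected {extra}"
            )
        X = features[self.feature_names].to_numpy(dtype=float)
        return (X - self.scaler_mean) / self.scaler_std

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        proba = self.model.predict_proba(self._matrix(features))
        # deterministic tie-break: lowest class index wins
        idx = np.argmax(proba, axis=1)
        return np.asarray(self.classes, dtype=object)[idx]

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "model": self.model,
                "feature_names": self.feature_names,
                "classes": self.classes,
                "scaler_mean": self.scaler_mean,
                "scaler_std": self.scaler_std,
                "config": asdict(self.config),
                "history": self.history,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        payload = joblib.load(path)
        cfg = payload["config"]
        cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
        return cls(
            model=payload["model"],
            feature_names=payload["feature_names"],
            classes=payload["classes"],
            scaler_mean=payload["scaler_mean"],
            scaler_std=payload["scaler_std"],
            config=MLPConfig(**cfg),
            history=payload.get("history", {}),
        )


def train_classifier(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    cfg: MLPConfig = MLPConfig(),
    label_col: str = "label",
) -> TrainedClassifier:
    """Fit the backpropagation network with validation-based early stopping.

    Features are z-scored with statistics of the training partition only.
    The network trains one epoch at a time; after each epoch the softmax
    cross-entropy on the validation partition is measured, and the weights
    with the lowest validation loss are restored at the end.  Training
    stops early when the validation loss has not improved for
    ``cfg.patience`` epochs.
    """
    cols = feature_columns(train)
    if not cols:
        raise ValueError("no recognized feature columns in the training table")
    y_train = train[label_col].to_numpy()
    classes = sorted(pd.unique(y_train).tolist())
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")

    X_train = train[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(X_train)):
        raise ValueError("non-finite training features")
    mean = X_train.mean(axis=0)
    std = X_train.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    Xt = (X_train - mean) / std
    Xv = (validation[cols].to_numpy(dtype=float) - mean) / std
    yv = validation[label_col].to_numpy()

    model = MLPClassifier(
        hidden_layer_sizes=cfg.hidden_sizes,
        activation=cfg.activation,
        solver="adam",
        learning_rate_init=cfg.learning_rate,
        batch_size=min(cfg.batch_size, len(Xt)),
        max_iter=1,
        warm_start=True,
        shuffle=True,
        random_state=cfg.seed,
    )

    best_loss = np.inf
    best_state = None
    best_epoch = -1
    val_losses: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for epoch in range(cfg.epochs):
            model.fit(Xt, y_train)
            loss = log_loss(yv, model.predict_proba(Xv), labels=model.classes_)
            val_losses.append(float(loss))
            if loss < best_loss - 1e-12:
                best_loss = float(loss)
                best_epoch = epoch
                best_state = (
                    copy.deepcopy(model.coefs_),
                    copy.deepcopy(model.intercepts_),
                )
            elif epoch - best_epoch >= cfg.patience:
                break
    if best_state is not None:
        model.coefs_, model.intercepts_ = best_state

    return TrainedClassifier(
        model=model,
        feature_names=cols,
        classes=list(model.classes_),
        scaler_mean=mean,
        scaler_std=std,
        config=cfg,
        history={"val_loss": val_losses, "best_epoch": best_epoch,
                 "best_val_loss": best_loss},
    )


def evaluate(y_true, y_pred, classes=None) -> ConfusionMatrix:
    """Confusion matrix and accuracy for predicted vs actual categories."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.size == 0:
        raise ValueError("empty evaluation input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    unknown = [v for v in np.concatenate([y_true, y_pred]) if v not in index]
    if unknown:
        raise ValueError(f"labels outside the class list: {sorted(set(unknown))}")
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(classes=classes, counts=counts)


def train_and_evaluate(
    features: pd.DataFrame,
    cfg: MLPConfig = MLPConfig(),
    spec: SplitSpec = SplitSpec(),
) -> tuple[TrainedClassifier, ConfusionMatrix]:
    """Split, train, and evaluate on the held-out test partition."""
    train_df, val_df, test_df = split_dataset(features, spec)
    clf = train_classifier(train_df, val_df, cfg)
    cm = evaluate(test_df["label"].to_numpy(), clf.predict(test_df), clf.classes)
    return clf, cm


def compare_pac_pfec(
    traces: list[StokesTrace],
    labels,
    cfg: MLPConfig = MLPConfig(),
    spec: SplitSpec = SplitSpec(),
) -> dict:
    """Train the network on the same particles featurized two ways.

    The pulse-average (6-feature) and pulse feature-enhanced (38-feature)
    tables are built from identical traces and split with identical
    partitions (same row indices), so the comparison isolates the value of
    the pulse-shape statistics.  Returns both confusion matrices and the
    per-class and overall accuracy deltas (enhanced minus average).
    """
    pfec = feature_frame(traces, mode="pfec", labels=labels)
    pac = feature_frame(traces, mode="pac", labels=labels)
    train_idx, val_idx, test_idx = (
        df.index for df in split_dataset(pfec, spec)
    )
    results = {}
    for name, table in (("pac", pac), ("pfec", pfec)):
        clf = train_classifier(table.loc[train_idx], table.loc[val_idx], cfg)
        test = table.loc[test_idx]
        results[name] = evaluate(test["label"].to_numpy(), clf.predict(test), clf.classes)
    cm_pac, cm_pfec = results["pac"], results["pfec"]
    deltas = {
        cls: cm_pfec.recall(cls) - cm_pac.recall(cls) for cls in cm_pfec.classes
    }
    return {
        "pac": cm_pac,
        "pfec": cm_pfec,
        "overall_delta": cm_pfec.accuracy - cm_pac.accuracy,
        "class_deltas": deltas,
    }
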