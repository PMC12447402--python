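"""Classifiers and evaluation: CNN, SVM/RF baselines, leave-one-out CV.

Four classification tasks are defined over the molecule labels:

* ``category9`` — the nine odorant categories;
* ``oxygen2`` — presence of oxygen atoms;
* ``oxygen_count3`` — number of oxygen atoms (0 / 1 / 2);
* ``ring2`` — presence of a ring structure.

The CNN consumes the normalized 40 x 14 x 3 tensors; its final conv
layer always exposes 16 activation maps (the Score-CAM contract).  The
SVM (RBF kernel) and random-forest baselines consume the 168-dim
hand-crafted features at scikit-learn defaults.  All evaluation is
leave-one-out cross-validation: every sample is predicted by a model
retrained from scratch on the remaining samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, f1_score
from sklearn.svm import SVC

from .nn import SmallCNN
from .preprocess import FeatureVector, InputTensor, assemble_normalize
from .sensor_sim import MoleculeSpec, OdorSample

__all__ = [
    "CnnConfig",
    "TaskSpec",
    "TASKS",
    "TrainedClassifier",
    "EvalReport",
    "build_cnn",
    "train",
    "loocv",
    "loocv_tensors",
    "baseline_fit_predict",
]

logger = logging.getLogger(__name__)

N_FINAL_MAPS = 16  # activation maps exposed by the final conv layer


@dataclass
class CnnConfig:
    """Hyperparameters of the reference CNN.

    Two conv blocks (8 then 16 filters, 3x3 kernels, ReLU), 2x1 pooling
    over time after each, dense 32, softmax output — the smallest
    architecture that exposes 16 final-layer activation maps and trains
    in seconds at n ~ 45.  The final conv block must have 16 filters.
    """

    conv_filters: tuple[int, ...] = (8, 16)
    kernel: tuple[int, int] = (3, 3)
    dense: int = 32
    dropout: float = 0.0
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conv_filters[-1] != N_FINAL_MAPS:
            raise ValueError(
                f"final conv block must have {N_FINAL_MAPS} filters, "
                f"got {self.conv_filters[-1]}"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class TaskSpec:
    """A classification task: a name and a label extractor on MoleculeSpec."""

    name: str
    extract: Callable[[MoleculeSpec], str]
    n_classes: int


TASKS: dict[str, TaskSpec] = {
    "category9": TaskSpec("category9", lambda m: m.category, 9),
    "oxygen2": TaskSpec("oxygen2", lambda m: "has_oxygen" if m.has_oxygen else "no_oxygen", 2),
    "oxygen_count3": TaskSpec("oxygen_count3", lambda m: str(m.n_oxygen), 3),
    "ring2": TaskSpec("ring2", lambda m: "has_ring" if m.has_ring else "no_ring", 2),
}


class TrainedClassifier:
    """A trained CNN plus its label vocabulary.

    Exposes class probabilities, final-conv activation maps, and a
    forward-pass counter (``n_forward`` counts individual inputs run
    through the network — one per tensor scored, one per activation-map
    extraction), which lets callers audit the cost of explanation
    procedures.
    """

    def __init__(self, net: SmallCNN, classes: Sequence[str]) -> None:
        if len(classes) != net.n_classes:
            raise ValueError("vocabulary size does not match network output")
        self.net = net
        self.classes = list(classes)
        self.n_forward = 0

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Probabilities for one (H,W,C) input or a batch (N,H,W,C)."""
        x = np.asarray(x, float)
        self.n_forward += 1 if x.ndim == 3 else x.shape[0]
        return self.net.predict_proba(x)

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        self.n_forward += 1 if x.ndim == 3 else x.shape[0]
        return self.net.predict_logits(x)

    def activation_maps(self, x: np.ndarray) -> np.ndarray:
        """Final-conv post-ReLU maps for one input: (16, h_f, w_f)."""
        self.n_forward += 1
        return self.net.activation_maps(x)

    def predict(self, x: np.ndarray) -> str | list[str]:
        p = self.predict_proba(x)
        if p.ndim == 1:
            return self.classes[int(np.argmax(p))]
        return [self.classes[i] for i in np.argmax(p, axis=1)]

    def class_index(self, label: str) -> int:
        try:
            return self.classes.index(label)
        except ValueError:
            raise KeyError(f"unknown class label {label!r}") from None

    @property
    def loss_history(self) -> list[float]:
        return self.net.loss_history


@dataclass
class EvalReport:
    """Held-out predictions and summary metrics for one task."""

    task: str
    sample_ids: list[str]
    y_true: list[str]
    y_pred: list[str]
    fold_ids: list[int]
    classes: list[str]
    accuracy: float = field(init=False)
    macro_f1: float = field(init=False)
    confusion: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.y_true)
        if not (len(self.y_pred) == len(self.sample_ids) == len(self.fold_ids) == n):
            raise ValueError("prediction record lengths differ")
        self.accuracy = float(np.mean([t == p for t, p in zip(self.y_true, self.y_pred)]))
        self.macro_f1 = float(
            f1_score(self.y_true, self.y_pred, labels=self.classes, average="macro", zero_division=0)
        )
        self.confusion = confusion_matrix(self.y_true, self.y_pred, labels=self.classes)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "classes": self.classes,
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "confusion": self.confusion.tolist(),
            "records": [
                {"sample_id": s, "true": t, "pred": p, "fold": f}
                for s, t, p, f in zip(self.sample_ids, self.y_true, self.y_pred, self.fold_ids)
            ],
        }


def build_cnn(config: CnnConfig, n_classes: int) -> SmallCNN:
    """Construct the untrained CNN for 40 x 14 x 3 inputs."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if config.conv_filters[-1] != N_FINAL_MAPS:
        raise ValueError(f"final conv block must have {N_FINAL_MAPS} filters")
    return SmallCNN(
        input_shape=(40, 14, 3),
        conv_filters=config.conv_filters,
        kernel=config.kernel,
        dense=config.dense,
        n_classes=n_classes,
        seed=config.seed,
        lr=config.learning_rate,
        dropout=config.dropout,
    )


def train(
    tensors: Sequence[InputTensor | np.ndarray],
    labels: Sequence[str],
    config: CnnConfig,
) -> TrainedClassifier:
    """Train the CNN on input tensors with string labels.

    Deterministic given ``config.seed`` (single-threaded NumPy, seeded
    initialization, shuffling and dropout).  The per-epoch training loss
    is recorded on the returned classifier's ``loss_history``.
    """
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("training set must contain at least 2 classes")
    x = np.stack([t.values if isinstance(t, InputTensor) else np.asarray(t, float) for t in tensors])
    y = np.array([classes.index(l) for l in labels])
    net = build_cnn(config, len(classes))
    net.fit(x, y, epochs=config.epochs, batch_size=config.batch_size)
    return TrainedClassifier(net, classes)


def loocv_tensors(
    tensors: Sequence[InputTensor | np.ndarray],
    labels: Sequence[str],
    config: CnnConfig,
    sample_ids: Sequence[str] | None = None,
    task_name: str = "task",
    keep_models: bool = False,
) -> tuple[EvalReport, dict[str, TrainedClassifier]]:
    """Leave-one-out CV over pre-built tensors.

    Fold ``i`` trains on all samples but ``i`` (with a fold-derived
    seed) and predicts sample ``i``.  With ``keep_models`` the per-fold
    classifiers are returned keyed by the held-out sample id, as needed
    to explain each sample with the model that never saw it.
    """
    n = len(tensors)
    labels = list(labels)
    classes = sorted(set(labels))
    if n < len(classes) + 1:
        raise ValueError("need at least n_classes + 1 samples for LOOCV")
    if sample_ids is None:
        sample_ids = [f"S{i:03d}" for i in range(n)]
    x = np.stack([t.values if isinstance(t, InputTensor) else np.asarray(t, float) for t in tensors])

    preds: list[str] = []
    models: dict[str, TrainedClassifier] = {}
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        train_labels = [labels[j] for j in range(n) if mask[j]]
        if len(set(train_labels)) < len(classes):
            logger.warning(
                "fold %d: training set lacks class(es) %s",
                i, sorted(set(classes) - set(train_labels)),
            )
        fold_seed = int(np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % (2**31))
        fold_cfg = CnnConfig(**{**config.__dict__, "seed": fold_seed})
        clf = train([x[j] for j in range(n) if mask[j]], train_labels, fold_cfg)
        preds.append(clf.predict(x[i]))
        if keep_models:
            models[sample_ids[i]] = clf
    report = EvalReport(
        task=task_name,
        sample_ids=list(sample_ids),
        y_true=labels,
        y_pred=preds,
        fold_ids=list(range(n)),
        classes=classes,
    )
    return report, models


def loocv(
    samples: Sequence[OdorSample],
    task: TaskSpec,
    config: CnnConfig,
    keep_models: bool = False,
) -> tuple[EvalReport, dict[str, TrainedClassifier]]:
    """Leave-one-out CV of the CNN on odor samples for one task."""
    tensors = [assemble_normalize(s) for s in samples]
    labels = [task.extract(s.molecule) for s in samples]
    ids = [s.sample_id for s in samples]
    return loocv_tensors(tensors, labels, config, sample_ids=ids,
                         task_name=task.name, keep_models=keep_models)


def baseline_fit_predict(
    features: Sequence[FeatureVector | np.ndarray],
    labels: Sequence[str],
    kind: str,
    seed: int = 0,
    sample_ids: Sequence[str] | None = None,
    task_name: str = "task",
) -> tuple[EvalReport, np.ndarray | None]:
    """LOOCV of a baseline classifier on the 168-dim features.

    ``kind`` is ``"svm"`` (RBF support-vector classifier) or ``"rf"``
    (random forest), each at scikit-learn defaults.  For the random
    forest the impurity-based per-feature importances of a model fit on
    the full dataset are returned as a 168-vector summing to 1.
    """
    if kind not in ("svm", "rf"):
        raise ValueError(f"kind must be 'svm' or 'rf', got {kind!r}")
    labels = list(labels)
    classes = sorted(set(labels))
    n = len(features)
    if n < len(classes) + 1:
        raise ValueError("need at least n_classes + 1 samples for LOOCV")
    if sample_ids is None:
        sample_ids = [f"S{i:03d}" for i in range(n)]
    x = np.stack([f.values if isinstance(f, FeatureVector) else np.asarray(f, float) for f in features])
    y = np.array(labels)

    def make():
        if kind == "svm":
            return SVC(random_state=seed)
        return RandomForestClassifier(random_state=seed)

    preds = []
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        clf = make().fit(x[mask], y[mask])
        preds.append(str(clf.predict(x[i:i + 1])[0]))

    report = EvalReport(
        task=task_name,
        sample_ids=list(sample_ids),
        y_true=labels,
        y_pred=preds,
        fold_ids=list(range(n)),
        classes=classes,
    )
    importances = None
    if kind == "rf":
        importances = make().fit(x, y).feature_importances_
    return report, importances
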