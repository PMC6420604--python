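"""Random-forest network-state classifier with the 2x confidence rule.

Epochs are assigned to one of four states (baseline, interictal bursting,
discrete seizures, continuous epileptiform activity) from their 20-feature
vectors.  To exclude ambiguous periods, an epoch is accepted only if the top
class probability is at least twice the second-highest; otherwise it is
deemed MIXED.  The same rule gates closed-loop trials: a trial enters the
paired analysis only if the 10 s immediately preceding the trigger classify
confidently as the discrete-seizure state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional
from warnings import warn

import joblib
import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score, precision_recall_fscore_support, roc_curve

from .features import FEATURE_NAMES, epoch_at, extract_features
from .types import EcogRecording, StateLabel, StimulationEvent

__all__ = [
    "StateModel",
    "ClassificationResult",
    "train",
    "classify_epoch",
    "classify_features",
    "evaluate",
    "lda_project",
    "gate_pre_stimulation",
    "save_model",
    "load_model",
]

_MODEL_FORMAT_VERSION = 1


@dataclass
class StateModel:
    """Fitted ensemble plus the metadata needed to apply it safely."""

    estimator: RandomForestClassifier
    classes: list  # of StateLabel, in estimator order
    feature_names: tuple = FEATURE_NAMES
    metadata: dict = field(default_factory=dict)


@dataclass
class ClassificationResult:
    label: StateLabel
    probabilities: dict
    confident: bool


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        missing = [c for c in FEATURE_NAMES if c not in features.columns]
        if missing:
            raise ValueError(f"feature matrix lacks columns: {missing}")
        return features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"expected {len(FEATURE_NAMES)} features, got {x.shape[1]}")
    return x


def _as_labels(labels) -> list:
    return [lab if isinstance(lab, StateLabel) else StateLabel(lab) for lab in labels]


def train(
    features,
    labels,
    seed: int = 0,
    n_estimators: int = 200,
    max_depth: Optional[int] = None,
    **hyperparams,
) -> StateModel:
    """Fit the random forest on labeled (non-MIXED) epochs.

    Deterministic given ``seed``.  Defaults: 200 trees, unlimited depth.
    """
    X = _as_matrix(features)
    y = _as_labels(labels)
    if len(y) != len(X):
        raise ValueError("features and labels length mismatch")
    if any(lab is StateLabel.MIXED for lab in y):
        raise ValueError("MIXED is a classifier output, not a training label")
    if len(set(y)) < 2:
        raise ValueError("training needs at least two classes")
    est = RandomForestClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        random_state=int(seed) % (2**31),
        **hyperparams,
    )
    est.fit(X, [lab.value for lab in y])
    return StateModel(
        estimator=est,
        classes=[StateLabel(c) for c in est.classes_],
        metadata={
            "n_epochs": len(X),
            "seed": int(seed),
            "n_estimators": n_estimators,
            "max_depth": max_depth,
        },
    )


def _apply_confidence_rule(proba: np.ndarray, classes) -> tuple:
    """The 2x rule: top probability strictly less than twice the runner-up
    means the epoch is mixed; equality counts as confident."""
    order = np.argsort(proba)[::-1]
    top, second = proba[order[0]], proba[order[1]] if len(proba) > 1 else 0.0
    confident = top >= 2.0 * second
    label = classes[order[0]] if confident else StateLabel.MIXED
    return label, confident


def classify_features(model: StateModel, features) -> list:
    """Classify one or more 20-feature vectors with the 2x confidence rule."""
    X = _as_matrix(features)
    proba = model.estimator.predict_proba(X)
    out = []
    for p in proba:
        label, confident = _apply_confidence_rule(p, model.classes)
        out.append(
            ClassificationResult(
                label=label,
                probabilities={c: float(v) for c, v in zip(model.classes, p)},
                confident=confident,
            )
        )
    return out


def classify_epoch(model: StateModel, feature_vector) -> ClassificationResult:
    """Classify a single epoch's feature vector."""
    return classify_features(model, feature_vector)[0]


def evaluate(model: StateModel, features, labels) -> dict:
    """Held-out evaluation: per-class precision/recall/f1, macro f1, ROC points.

    The caller is responsible for splitting by animal (no epochs of a test
    animal may appear in training).
    """
    X = _as_matrix(features)
    y = [lab.value for lab in _as_labels(labels)]
    if len(y) == 0:
        raise ValueError("empty test set")
    pred = model.estimator.predict(X)
    classes = [c.value for c in model.classes]
    prec, rec, f1, support = precision_recall_fscore_support(
        y, pred, labels=classes, zero_division=0
    )
    proba = model.estimator.predict_proba(X)
    roc = {}
    for i, c in enumerate(classes):
        fpr, tpr, _ = roc_curve([1 if v == c else 0 for v in y], proba[:, i])
        roc[c] = (fpr, tpr)
    return {
        "per_class": pd.DataFrame(
            {"precision": prec, "recall": rec, "f1": f1, "support": support},
            index=classes,
        ),
        "macro_f1": float(f1_score(y, pred, labels=classes, average="macro", zero_division=0)),
        "roc": roc,
    }


def lda_project(features, labels, n_components: int = 3):
    """Project the 20 features to (at most) 3 linear discriminants.

    With fewer than ``n_components + 1`` classes, returns the maximum
    available number of discriminants with a warning.  A small shrinkage
    regularization makes the projection stable under duplicated (rank
    deficient) feature columns.
    """
    X = _as_matrix(features)
    y = [lab.value for lab in _as_labels(labels)]
    n_classes = len(set(y))
    k = min(n_components, n_classes - 1)
    if k < n_components:
        warn(
            f"only {n_classes} classes present; returning {k} discriminants",
            stacklevel=2,
        )
    lda = LinearDiscriminantAnalysis(
        solver="eigen", shrinkage=1e-6, n_components=k
    )
    return lda.fit_transform(X, y)


def gate_pre_stimulation(
    model: StateModel,
    recording: EcogRecording,
    stim: StimulationEvent,
    prominence: float = 0.05,
    baseline_band: float = 0.02,
) -> bool:
    """True iff the 10 s before the trigger classify confidently as State 2.

    ``recording`` must be min-max scaled.  Trials with less than 10 s of
    pre-trigger data are rejected.
    """
    start = stim.detection_time - 10.0
    if start < 0:
        return False
    ep = epoch_at(recording, start)
    fv = extract_features(ep, prominence, baseline_band)
    res = classify_epoch(model, fv)
    return res.confident and res.label is StateLabel.S2_ICTAL


def save_model(model: StateModel, path) -> None:
    """Serialize as a versioned archive with class order and feature names."""
    joblib.dump(
        {
            "format_version": _MODEL_FORMAT_VERSION,
            "estimator": model.estimator,
            "classes": [c.value for c in model.classes],
            "feature_names": list(model.feature_names),
            "metadata": model.metadata,
        },
        path,
    )


def load_model(path) -> StateModel:
    blob = joblib.load(path)
    if blob.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model archive version")
    if tuple(blob["feature_names"]) != tuple(FEATURE_NAMES):
        raise ValueError("model feature names do not match this package's features")
    return StateModel(
        estimator=blob["estimator"],
        classes=[StateLabel(c) for c in blob["classes"]],
        feature_names=tuple(blob["feature_names"]),
        metadata=blob["metadata"],
    )
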