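"""Classifiers mapping feature vectors to label ids.

Two classifiers are supported:

* a random forest (scikit-learn) with Gini splitting, max depth 16,
  unlimited leaves and sqrt feature subsampling; only the number of
  trees (16/32/64) is tunable;
* a two-hidden-layer feedforward net with leaky ReLU activations,
  softmax cross-entropy output, Adam, dropout, early stopping, and
  normally distributed weight init with zero biases.  Tunable: layer
  sizes, dropout rate, init stddev, minibatch size.

Both are deterministic under a fixed seed.  Predictions break score ties
toward the lowest label id.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from voxelseg.features import FeatureConfig
from voxelseg.volume import LabelMap

RF_TREE_CHOICES = (16, 32, 64)
NN_LAYER_CHOICES = (32, 64, 128, 256)
NN_MINIBATCH_CHOICES = (4, 8, 16, 32, 64)
NN_DROPOUT_RANGE = (0.0, 0.5)
NN_INIT_STDDEV_RANGE = (0.0001, 1.0)

RF_MAX_DEPTH = 16


@dataclass(frozen=True)
class RandomForestSpec:
    """Random forest hyperparameters; everything but ``n_trees`` is fixed."""

    n_trees: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees not in RF_TREE_CHOICES:
            raise ValueError(
                f"n_trees must be one of {RF_TREE_CHOICES}, got {self.n_trees}"
            )

    kind = "random_forest"

    def build(self, n_jobs: int = 1) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            criterion="gini",
            max_depth=RF_MAX_DEPTH,
            max_leaf_nodes=None,
            max_features="sqrt",
            random_state=self.seed,
            n_jobs=n_jobs,
        )

    def to_dict(self) -> dict:
        return {"kind": self.kind, "n_trees": self.n_trees, "seed": self.seed}


@dataclass(frozen=True)
class NeuralNetSpec:
    """Feedforward net hyperparameters, validated against the search ranges."""

    layer1: int = 64
    layer2: int = 64
    dropout: float = 0.25
    init_stddev: float = 0.01
    minibatch: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layer1 not in NN_LAYER_CHOICES:
            raise ValueError(f"layer1 must be one of {NN_LAYER_CHOICES}")
        if self.layer2 not in NN_LAYER_CHOICES:
            raise ValueError(f"layer2 must be one of {NN_LAYER_CHOICES}")
        if not NN_DROPOUT_RANGE[0] <= self.dropout <= NN_DROPOUT_RANGE[1]:
            raise ValueError(f"dropout must lie in {NN_DROPOUT_RANGE}")
        if not NN_INIT_STDDEV_RANGE[0] <= self.init_stddev <= NN_INIT_STDDEV_RANGE[1]:
            raise ValueError(f"init_stddev must lie in {NN_INIT_STDDEV_RANGE}")
        if self.minibatch not in NN_MINIBATCH_CHOICES:
            raise ValueError(f"minibatch must be one of {NN_MINIBATCH_CHOICES}")

    kind = "neural_net"

    def build(self, n_jobs: int = 1) -> "MLPClassifier":
        return MLPClassifier(self)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "layer1": self.layer1,
            "layer2": self.layer2,
            "dropout": self.dropout,
            "init_stddev": self.init_stddev,
            "minibatch": self.minibatch,
            "seed": self.seed,
        }


def spec_from_dict(d: dict) -> "RandomForestSpec | NeuralNetSpec":
    d = dict(d)
    kind = d.pop("kind")
    if kind == "random_forest":
        return RandomForestSpec(**d)
    if kind == "neural_net":
        return NeuralNetSpec(**d)
    raise ValueError(f"unknown classifier kind {kind!r}")


# --------------------------------------------------------------------------
# Minimal feedforward net
# --------------------------------------------------------------------------

LEAKY_SLOPE = 0.01
ADAM_LR = 1e-3
MAX_EPOCHS = 100
PATIENCE = 5
VALIDATION_FRACTION = 0.1


class MLPClassifier:
    """Two-hidden-layer softmax net trained with Adam and early stopping.

    Inputs are standardised internally (mean/std learned on the training
    data).  Training holds out a fraction of the data for the early
    stopping criterion; the weights of the best validation epoch are
    restored at the end.  Fully deterministic given the spec's seed.
    """

    def __init__(self, spec: NeuralNetSpec):
        self.spec = spec
        self.classes_: np.ndarray | None = None
        self.params_: list[np.ndarray] | None = None
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None
        self.history_: dict[str, Any] = {}

    # forward pieces -------------------------------------------------------

    @staticmethod
    def _leaky(x: np.ndarray) -> np.ndarray:
        return np.where(x > 0, x, LEAKY_SLOPE * x)

    @staticmethod
    def _leaky_grad(x: np.ndarray) -> np.ndarray:
        return np.where(x > 0, 1.0, LEAKY_SLOPE)

    @staticmethod
    def _softmax(z: np.ndarray) -> np.ndarray:
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def _forward(self, x: np.ndarray, params: list[np.ndarray]):
        w1, b1, w2, b2, w3, b3 = params
        a1 = x @ w1 + b1
        h1 = self._leaky(a1)
        a2 = h1 @ w2 + b2
        h2 = self._leaky(a2)
        logits = h2 @ w3 + b3
        return a1, h1, a2, h2, logits

    # training -------------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if len(X) == 0:
            raise ValueError("cannot train on an empty feature matrix")
        rng = np.random.default_rng(self.spec.seed)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = len(self.classes_)

        self.mean_ = X.mean(axis=0)
        self.std_ = X.std(axis=0)
        self.std_[self.std_ == 0] = 1.0
        Xs = (X - self.mean_) / self.std_

        # validation holdout for early stopping
        n = len(Xs)
        perm = rng.permutation(n)
        n_val = max(1, int(round(n * VALIDATION_FRACTION))) if n > 10 else 0
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if len(tr_idx) == 0:
            tr_idx = perm
            val_idx = perm[:0]
        Xtr, ytr = Xs[tr_idx], y_idx[tr_idx]
        Xval, yval = Xs[val_idx], y_idx[val_idx]

        d = Xs.shape[1]
        sd = self.spec.init_stddev
        sizes = [(d, self.spec.layer1), (self.spec.layer1, self.spec.layer2),
                 (self.spec.layer2, n_classes)]
        params: list[np.ndarray] = []
        for fan_in, fan_out in sizes:
            params.append(rng.normal(0.0, sd, size=(fan_in, fan_out)))
            params.append(np.zeros(fan_out))

        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        keep = 1.0 - self.spec.dropout
        best_loss = np.inf
        best_params = [p.copy() for p in params]
        best_epoch = 0
        bad_epochs = 0
        val_losses = []

        for epoch in range(MAX_EPOCHS):
            order = rng.permutation(len(Xtr))
            for i0 in range(0, len(order), self.spec.minibatch):
                idx = order[i0:i0 + self.spec.minibatch]
                xb, yb = Xtr[idx], ytr[idx]
                w1, b1, w2, b2, w3, b3 = params
                a1 = xb @ w1 + b1
                h1 = self._leaky(a1)
                if keep < 1.0:
                    mask1 = (rng.random(h1.shape) < keep) / keep
                    h1 = h1 * mask1
                a2 = h1 @ w2 + b2
                h2 = self._leaky(a2)
                if keep < 1.0:
                    mask2 = (rng.random(h2.shape) < keep) / keep
                    h2 = h2 * mask2
                logits = h2 @ w3 + b3
                probs = self._softmax(logits)
                nb = len(xb)
                dlogits = probs
                dlogits[np.arange(nb), yb] -= 1.0
                dlogits /= nb
                g_w3 = h2.T @ dlogits
                g_b3 = dlogits.sum(axis=0)
                dh2 = dlogits @ w3.T
                if keep < 1.0:
                    dh2 = dh2 * mask2
                da2 = dh2 * self._leaky_grad(a2)
                g_w2 = h1.T @ da2
                g_b2 = da2.sum(axis=0)
                dh1 = da2 @ w2.T
                if keep < 1.0:
                    dh1 = dh1 * mask1
                da1 = dh1 * self._leaky_grad(a1)
                g_w1 = xb.T @ da1
                g_b1 = da1.sum(axis=0)
                grads = [g_w1, g_b1, g_w2, g_b2, g_w3, g_b3]
                step += 1
                for j, g in enumerate(grads):
                    m[j] = beta1 * m[j] + (1 - beta1) * g
                    v[j] = beta2 * v[j] + (1 - beta2) * g * g
                    mhat = m[j] / (1 - beta1 ** step)
                    vhat = v[j] / (1 - beta2 ** step)
                    params[j] = params[j] - ADAM_LR * mhat / (np.sqrt(vhat) + eps)

            # early stopping on validation loss (training loss if no holdout)
            Xev, yev = (Xval, yval) if len(val_idx) else (Xtr, ytr)
            *_, logits = self._forward(Xev, params)
            probs = self._softmax(logits)
            loss = -np.mean(np.log(probs[np.arange(len(yev)), yev] + 1e-12))
            val_losses.append(float(loss))
            if loss < best_loss - 1e-6:
                best_loss = loss
                best_params = [p.copy() for p in params]
                best_epoch = epoch
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= PATIENCE:
                    break

        self.params_ = best_params
        self.history_ = {
            "val_losses": val_losses,
            "best_epoch": best_epoch,
            "best_loss": float(best_loss),
            "final_loss": val_losses[-1],
        }
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.params_ is None:
            raise RuntimeError("classifier is not fitted")
        X = (np.asarray(X, dtype=np.float64) - self.mean_) / self.std_
        *_, logits = self._forward(X, self.params_)
        return self._softmax(logits)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# --------------------------------------------------------------------------
# Trained model bundle
# --------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to reapply it: feature
    recipe, label map, and the training volume's intensity bounds."""

    kind: str
    spec: RandomForestSpec | NeuralNetSpec
    classifier: Any
    feature_config: FeatureConfig | None = None
    label_map: LabelMap | None = None
    intensity_bounds: tuple[float, float] | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        if self.feature_config is not None:
            return self.feature_config.total_length
        return int(self.metadata["n_features"])

    def _check_width(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"feature width mismatch: model expects {self.n_features} "
                f"columns, got {X.shape[1] if X.ndim == 2 else X.shape}"
            )
        return X

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-label score rows over *all* label-map ids (columns in id
        order); rows are non-negative and sum to 1."""
        X = self._check_width(X)
        raw = self.classifier.predict_proba(X)
        classes = np.asarray(self.classifier.classes_, dtype=np.int64)
        if self.label_map is not None:
            n_out = self.label_map.n_labels
        else:
            n_out = int(classes.max()) + 1
        out = np.zeros((len(X), n_out))
        out[:, classes] = raw
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Label ids; ties in the class scores go to the lowest id."""
        return np.argmax(self.predict_proba(X), axis=1).astype(np.int64)


def train_classifier(
    spec: RandomForestSpec | NeuralNetSpec,
    features: np.ndarray,
    labels: np.ndarray,
    feature_config: FeatureConfig | None = None,
    label_map: LabelMap | None = None,
    intensity_bounds: tuple[float, float] | None = None,
    n_jobs: int = 1,
) -> TrainedModel:
    """Fit a classifier on feature rows; deterministic under a fixed seed.

    Single-class input yields a degenerate (constant) predictor; empty
    input is an error.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if features.ndim != 2 or len(features) == 0:
        raise ValueError("training features must be a non-empty 2D matrix")
    if len(features) != len(labels):
        raise ValueError("features and labels disagree in length")
    if not np.all(np.isfinite(features)):
        raise ValueError("training features contain non-finite values")
    clf = spec.build(n_jobs=n_jobs)
    clf.fit(features, labels)
    meta = {
        "n_features": features.shape[1],
        "n_train": len(features),
        "seed": spec.seed,
    }
    return TrainedModel(
        kind=spec.kind,
        spec=spec,
        classifier=clf,
        feature_config=feature_config,
        label_map=label_map,
        intensity_bounds=intensity_bounds,
        metadata=meta,
    )


def predict_labels(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    return model.predict(features)


def predict_proba(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    return model.predict_proba(features)


# --------------------------------------------------------------------------
# Serialisation: JSON manifest + joblib classifier
# --------------------------------------------------------------------------

MANIFEST_NAME = "manifest.json"
CLASSIFIER_NAME = "classifier.joblib"


def save_model(model: TrainedModel, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": 1,
        "kind": model.kind,
        "spec": model.spec.to_dict(),
        "feature_config": (
            model.feature_config.to_dict() if model.feature_config else None
        ),
        "label_map": model.label_map.to_dict() if model.label_map else None,
        "intensity_bounds": (
            list(model.intensity_bounds) if model.intensity_bounds else None
        ),
        "metadata": model.metadata,
    }
    (directory / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2))
    joblib.dump(model.classifier, directory / CLASSIFIER_NAME)
    return directory


def load_model(directory: str | Path) -> TrainedModel:
    directory = Path(directory)
    manifest = json.loads((directory / MANIFEST_NAME).read_text())
    spec = spec_from_dict(manifest["spec"])
    classifier = joblib.load(directory / CLASSIFIER_NAME)
    fc = manifest.get("feature_config")
    lm = manifest.get("label_map")
    bounds = manifest.get("intensity_bounds")
    return TrainedModel(
        kind=manifest["kind"],
        spec=spec,
        classifier=classifier,
        feature_config=FeatureConfig.from_dict(fc) if fc else None,
        label_map=LabelMap.from_dict(lm) if lm else None,
        intensity_bounds=tuple(bounds) if bounds else None,
        metadata=manifest.get("metadata", {}),
    )
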