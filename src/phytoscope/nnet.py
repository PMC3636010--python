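"""Feed-forward neural network with Elliott activation and RPROP training.

The classifier is a fully-connected network whose hidden and output layers
use the symmetric Elliott activation ``f(x) = x / (1 + |x|)`` — a cheap
sigmoid with outputs in (-1, 1) that pairs naturally with min-max input
normalization to [-1, 1] and one-hot targets coded +1 / -1.

Training uses full-batch resilient propagation (RPROP-): each weight keeps
its own step size, grown by ``eta_plus`` while the gradient sign persists
and shrunk by ``eta_minus`` on a sign flip (the gradient is zeroed for that
step so the flip is not acted on twice).  Training stops at the first
iteration whose winner-take-all misclassification fraction reaches the
target error (0 by default) or after ``max_iterations``.

The per-feature normalization rules observed on the training data are part
of the persisted model, so predictions on raw feature vectors are always
normalized exactly as during training.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1


def elliott(x: np.ndarray) -> np.ndarray:
    """Symmetric Elliott activation x / (1 + |x|), outputs in (-1, 1)."""
    x = np.asarray(x, dtype=np.float64)
    return x / (1.0 + np.abs(x))


def elliott_derivative(x: np.ndarray) -> np.ndarray:
    """Derivative of the Elliott activation: 1 / (1 + |x|)^2."""
    x = np.asarray(x, dtype=np.float64)
    return 1.0 / (1.0 + np.abs(x)) ** 2


@dataclass
class NormalizationRules:
    """Per-feature (min, max) observed on training data, target [-1, 1]."""

    mins: np.ndarray
    maxs: np.ndarray

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Map raw values to [-1, 1]; constant features map to 0 and values
        outside the training range are clipped."""
        x = np.asarray(x, dtype=np.float64)
        span = self.maxs - self.mins
        safe = np.where(span > 0, span, 1.0)
        out = 2.0 * (x - self.mins) / safe - 1.0
        out = np.where(span > 0, out, 0.0)
        return np.clip(out, -1.0, 1.0)


def fit_normalization(values: np.ndarray) -> NormalizationRules:
    """Observe per-column min/max on a (n_samples, n_features) array."""
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2 or values.shape[0] == 0:
        raise ValueError("need a nonempty 2-d array of training values")
    return NormalizationRules(mins=values.min(axis=0), maxs=values.max(axis=0))


@dataclass
class TrainingConfig:
    """RPROP training schedule.

    ``target_error`` is the winner-take-all misclassification fraction on
    the training set at which training stops (the default 0 demands a
    perfect fit); ``max_iterations`` bounds the run regardless.
    """

    max_iterations: int = 3000
    target_error: float = 0.0
    delta0: float = 0.1
    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta_max: float = 50.0
    delta_min: float = 1e-6
    rng_seed: int = 0
    init_scale: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_error <= 1.0:
            raise ValueError("target_error must lie in [0, 1]")
        if not self.eta_minus < 1.0 < self.eta_plus:
            raise ValueError("need eta_minus < 1 < eta_plus")


@dataclass
class NetworkModel:
    """A trained (or freshly initialized) fully-connected network."""

    layer_sizes: list[int]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    class_labels: list[str]
    normalization: NormalizationRules
    feature_names: list[str]
    activation_id: str = "elliott_symmetric"

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.layer_sizes) - 1:
            raise ValueError("weight count does not match layer_sizes")
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            expect = (self.layer_sizes[i], self.layer_sizes[i + 1])
            if w.shape != expect:
                raise ValueError(
                    f"layer {i}: weight shape {w.shape} != {expect}")
            if b.shape != (self.layer_sizes[i + 1],):
                raise ValueError(f"layer {i}: bias shape mismatch")
        if len(self.class_labels) != self.layer_sizes[-1]:
            raise ValueError("class_labels length must equal output size")
        if len(self.feature_names) != self.layer_sizes[0]:
            raise ValueError("feature_names length must equal input size")


def init_model(feature_names: list[str], hidden: tuple[int, ...],
               class_labels: list[str], normalization: NormalizationRules,
               rng_seed: int = 0, init_scale: float = 0.5) -> NetworkModel:
    """Random uniform(+-init_scale) initialization of all weights."""
    sizes = [len(feature_names), *hidden, len(class_labels)]
    rng = np.random.default_rng(rng_seed)
    weights = [rng.uniform(-init_scale, init_scale, size=(sizes[i], sizes[i + 1]))
               for i in range(len(sizes) - 1)]
    biases = [rng.uniform(-init_scale, init_scale, size=sizes[i + 1])
              for i in range(len(sizes) - 1)]
    return NetworkModel(layer_sizes=sizes, weights=weights, biases=biases,
                        class_labels=list(class_labels),
                        normalization=normalization,
                        feature_names=list(feature_names))


def forward(model: NetworkModel, x: np.ndarray) -> np.ndarray:
    """Forward pass on normalized inputs; x is (n_features,) or 2-d batch."""
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    a = x[None, :] if single else x
    if a.shape[1] != model.layer_sizes[0]:
        raise ValueError(
            f"input length {a.shape[1]} != input layer {model.layer_sizes[0]}")
    for w, b in zip(model.weights, model.biases):
        a = elliott(a @ w + b)
    return a[0] if single else a


def _forward_cached(model: NetworkModel, x: np.ndarray):
    """Forward pass keeping pre-activations for backprop."""
    a = x
    acts = [a]
    zs = []
    for w, b in zip(model.weights, model.biases):
        z = a @ w + b
        zs.append(z)
        a = elliott(z)
        acts.append(a)
    return acts, zs


def loss_and_gradients(model: NetworkModel, x: np.ndarray, t: np.ndarray):
    """Half summed-squared-error loss and its gradients over a batch.

    ``t`` holds +-1 one-hot targets.  Returns (loss, grad_w, grad_b, output).
    """
    acts, zs = _forward_cached(model, x)
    out = acts[-1]
    diff = out - t
    loss = 0.5 * float((diff ** 2).sum())
    grad_w = [np.zeros_like(w) for w in model.weights]
    grad_b = [np.zeros_like(b) for b in model.biases]
    delta = diff * elliott_derivative(zs[-1])
    for layer in range(len(model.weights) - 1, -1, -1):
        grad_w[layer] = acts[layer].T @ delta
        grad_b[layer] = delta.sum(axis=0)
        if layer > 0:
            delta = (delta @ model.weights[layer].T) * \
                elliott_derivative(zs[layer - 1])
    return loss, grad_w, grad_b, out


def misclassification(outputs: np.ndarray, targets: np.ndarray) -> float:
    """Winner-take-all error fraction (ties break toward lower index)."""
    return float((outputs.argmax(axis=1) != targets.argmax(axis=1)).mean())


def one_hot_targets(labels, class_labels: list[str]) -> np.ndarray:
    """+-1 one-hot coding over the model's ordered class labels."""
    index = {c: i for i, c in enumerate(class_labels)}
    unknown = sorted({l for l in labels if l not in index})
    if unknown:
        raise ValueError(f"label(s) not in class_labels: {unknown}")
    t = -np.ones((len(labels), len(class_labels)))
    for row, lab in enumerate(labels):
        t[row, index[lab]] = 1.0
    return t


def train_rprop(model: NetworkModel, x: np.ndarray, t: np.ndarray,
                config: TrainingConfig | None = None):
    """Full-batch RPROP- training.

    Per-weight step sizes start at ``delta0``; a persisting gradient sign
    multiplies the step by ``eta_plus`` (capped at ``delta_max``), a sign
    flip multiplies by ``eta_minus`` (floored at ``delta_min``) and zeroes
    the stored gradient so the flip is not reacted to twice.  Stops at the
    first iteration whose training misclassification fraction is at or
    below ``target_error``.  Returns (model, error_history).
    """
    config = config or TrainingConfig()
    x = np.asarray(x, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if x.shape[0] == 0:
        raise ValueError("empty training set")
    params = model.weights + model.biases
    deltas = [np.full_like(p, config.delta0) for p in params]
    prev_grad = [np.zeros_like(p) for p in params]
    history: list[float] = []
    for _ in range(config.max_iterations):
        _, grad_w, grad_b, out = loss_and_gradients(model, x, t)
        err = misclassification(out, t)
        history.append(err)
        if err <= config.target_error:
            break
        grads = grad_w + grad_b
        for p, g, d, pg in zip(params, grads, deltas, prev_grad):
            sign = np.sign(g * pg)
            np.multiply(d, np.where(sign > 0, config.eta_plus,
                                    np.where(sign < 0, config.eta_minus, 1.0)),
                        out=d)
            np.clip(d, config.delta_min, config.delta_max, out=d)
            g = np.where(sign < 0, 0.0, g)
            p -= np.sign(g) * d
            pg[...] = g
    return model, history


def fit_classifier(table: pd.DataFrame, feature_names: list[str],
                   class_labels: list[str], hidden: tuple[int, ...] = (50, 30),
                   config: TrainingConfig | None = None):
    """Normalize a labeled feature table and train a network on it.

    ``table`` must carry a ``class_label`` column plus the feature columns.
    Returns (model, error_history).
    """
    config = config or TrainingConfig()
    missing = [n for n in feature_names if n not in table.columns]
    if missing:
        raise KeyError(f"feature column(s) missing from table: {missing}")
    raw = table[list(feature_names)].to_numpy(dtype=np.float64)
    rules = fit_normalization(raw)
    x = rules.apply(raw)
    t = one_hot_targets(table["class_label"].tolist(), class_labels)
    model = init_model(feature_names, hidden, class_labels, rules,
                       rng_seed=config.rng_seed, init_scale=config.init_scale)
    return train_rprop(model, x, t, config)


def predict_class(model: NetworkModel, raw: pd.Series | dict | np.ndarray):
    """Classify one raw feature vector; returns (label, output activations).

    Named inputs are reordered to the model's feature order; an absent
    feature raises an error naming it.  Ties break toward the lower class
    index.
    """
    if isinstance(raw, (pd.Series, dict)):
        raw = pd.Series(raw)
        missing = [n for n in model.feature_names if n not in raw.index]
        if missing:
            raise KeyError(f"missing feature(s): {missing}")
        vec = raw[model.feature_names].to_numpy(dtype=np.float64)
    else:
        vec = np.asarray(raw, dtype=np.float64)
        if vec.shape != (len(model.feature_names),):
            raise ValueError(
                f"expected {len(model.feature_names)} features, "
                f"got shape {vec.shape}")
    out = forward(model, model.normalization.apply(vec))
    return model.class_labels[int(out.argmax())], out


def predict_batch(model: NetworkModel, table: pd.DataFrame) -> list[str]:
    """Winner-take-all labels for every row of a raw feature table."""
    raw = table[model.feature_names].to_numpy(dtype=np.float64)
    out = forward(model, model.normalization.apply(raw))
    return [model.class_labels[i] for i in out.argmax(axis=1)]


def search_architecture(table: pd.DataFrame, feature_names: list[str],
                        class_labels: list[str],
                        candidates: list[tuple[int, ...]],
                        config: TrainingConfig | None = None):
    """Pick the hidden-layer layout with the lowest validation error.

    The table is split 80/20 stratified by label (from the config seed); one
    model is trained per candidate and evaluated on the held-out fifth.
    Ties break toward fewer total hidden neurons.  Returns
    (best_hidden, {candidate: validation_error}).
    """
    config = config or TrainingConfig()
    if len(candidates) < 2:
        if not candidates:
            raise ValueError("need at least one candidate architecture")
    counts = table["class_label"].value_counts()
    too_small = counts[counts < 5]
    if len(too_small):
        raise ValueError(
            f"class(es) with < 5 samples: {sorted(too_small.index)}")
    rng = np.random.default_rng(config.rng_seed)
    val_idx = []
    for _, group in table.groupby("class_label"):
        idx = group.index.to_numpy()
        rng.shuffle(idx)
        n_val = max(1, int(round(0.2 * len(idx))))
        val_idx.extend(idx[:n_val])
    val_mask = table.index.isin(val_idx)
    train_tab = table[~val_mask]
    val_tab = table[val_mask]
    errors: dict[tuple[int, ...], float] = {}
    for hidden in candidates:
        model, _ = fit_classifier(train_tab, feature_names, class_labels,
                                  hidden=tuple(hidden), config=config)
        pred = predict_batch(model, val_tab)
        truth = val_tab["class_label"].tolist()
        errors[tuple(hidden)] = float(
            np.mean([p != t for p, t in zip(pred, truth)]))
    best = min(errors, key=lambda h: (errors[h], sum(h)))
    return best, errors


def permutation_importance(model: NetworkModel, table: pd.DataFrame,
                           rng_seed: int = 0) -> pd.Series:
    """Input ranking by accuracy drop under per-feature permutation.

    A substitute for black-box input-significance scores: each feature
    column is shuffled in turn and the increase in misclassification on the
    given (labeled) table is reported.
    """
    rng = np.random.default_rng(rng_seed)
    truth = table["class_label"].tolist()
    base = np.mean([p != t for p, t in
                    zip(predict_batch(model, table), truth)])
    scores = {}
    for name in model.feature_names:
        shuffled = table.copy()
        col = shuffled[name].to_numpy().copy()
        rng.shuffle(col)
        shuffled[name] = col
        err = np.mean([p != t for p, t in
                       zip(predict_batch(model, shuffled), truth)])
        scores[name] = float(err - base)
    return pd.Series(scores).sort_values(ascending=False)


# ---------------------------------------------------------------------------
# persistence

def save_model(model: NetworkModel, path: str) -> None:
    """Serialize a model (weights, labels, normalization rules) to JSON."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "activation_id": model.activation_id,
        "layer_sizes": model.layer_sizes,
        "class_labels": model.class_labels,
        "feature_names": model.feature_names,
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "normalization": {
            "mins": model.normalization.mins.tolist(),
            "maxs": model.normalization.maxs.tolist(),
        },
    }
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str) -> NetworkModel:
    """Load a model saved by :func:`save_model`, validating its schema."""
    with open(path) as fh:
        payload = json.load(fh)
    required = {"schema_version", "layer_sizes", "class_labels",
                "feature_names", "weights", "biases", "normalization"}
    missing = required - payload.keys()
    if missing:
        raise ValueError(f"model file missing field(s): {sorted(missing)}")
    try:
        model = NetworkModel(
            layer_sizes=list(payload["layer_sizes"]),
            weights=[np.array(w, dtype=np.float64)
                     for w in payload["weights"]],
            biases=[np.array(b, dtype=np.float64)
                    for b in payload["biases"]],
            class_labels=list(payload["class_labels"]),
            normalization=NormalizationRules(
                mins=np.array(payload["normalization"]["mins"]),
                maxs=np.array(payload["normalization"]["maxs"]),
            ),
            feature_names=list(payload["feature_names"]),
            activation_id=payload.get("activation_id", "elliott_symmetric"),
        )
    except ValueError as exc:
        raise ValueError(f"invalid model file {path}: {exc}") from exc
    return model
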