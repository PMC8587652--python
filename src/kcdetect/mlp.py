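"""From-scratch multilayer perceptron with an arctan activation.

The classifier head is a 2-unit softmax; the cost is binary cross-entropy
on the positive-class probability,

    L = -(1/N) sum_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ],

which for a 2-class softmax coincides with categorical cross-entropy, so
the output-layer error simplifies to (p - y).  Hidden layers use tanh,
sigmoid or arctan (derivative 1/(1+x^2)) - arctan is the reason this MLP
is hand-written: mainstream frameworks do not ship it.  Optimization is
plain stochastic gradient descent with batch size 1 (one randomly ordered
example per update) at a constant learning rate; a full-batch gradient
descent mode is available.  Model selection keeps the epoch snapshot with
the lowest cost on the evaluation set.

:class:`MLPNetClassifier` exposes all of this with the scikit-learn
estimator protocol (fit / predict / predict_proba, trailing-underscore
fitted attributes), so it drops into sklearn pipelines and model
selection.  The module-level functions (init_mlp, forward, bce_loss,
backward, train, evaluate) are thin functional views of the same code.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

_EPS = 1e-12

ACTIVATIONS = ("tanh", "sigmoid", "arctan")


def _activation(name: str):
    if name == "tanh":
        return np.tanh, lambda z: 1.0 - np.tanh(z) ** 2
    if name == "sigmoid":
        from scipy.special import expit

        return expit, lambda z: expit(z) * (1.0 - expit(z))
    if name == "arctan":
        return np.arctan, lambda z: 1.0 / (1.0 + z**2)
    raise ValueError(f"unknown activation {name!r}; choose from {ACTIVATIONS}")


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - np.max(z, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=-1, keepdims=True)


@dataclass
class MLPModel:
    """Weights and shape of a trained or initialized network."""

    layer_sizes: tuple[int, ...]
    activation: str
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    seed: int | None = None

    def copy(self) -> "MLPModel":
        return MLPModel(
            self.layer_sizes,
            self.activation,
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            self.seed,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "layer_sizes": list(self.layer_sizes),
                "activation": self.activation,
                "seed": self.seed,
                "weights": [w.ravel().tolist() for w in self.weights],
                "biases": [b.tolist() for b in self.biases],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MLPModel":
        d = json.loads(text)
        sizes = tuple(d["layer_sizes"])
        weights = [
            np.array(w).reshape(sizes[i], sizes[i + 1])
            for i, w in enumerate(d["weights"])
        ]
        biases = [np.array(b) for b in d["biases"]]
        return cls(sizes, d["activation"], weights, biases, d.get("seed"))


def init_mlp(
    layer_sizes: tuple[int, ...], activation: str, seed: int | None = None
) -> MLPModel:
    """Uniform(-1/sqrt(fan_in), +1/sqrt(fan_in)) weights, zero biases."""
    if len(layer_sizes) < 3:
        raise ValueError("need at least (input, one hidden, output) layer sizes")
    if activation not in ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}; choose from {ACTIVATIONS}")
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return MLPModel(tuple(layer_sizes), activation, weights, biases, seed)


def _forward_full(model: MLPModel, X: np.ndarray):
    """Probabilities plus cached pre-activations/activations for backprop."""
    act, _ = _activation(model.activation)
    a = X
    zs, acts = [], [a]
    last = len(model.weights) - 1
    for i, (W, b) in enumerate(zip(model.weights, model.biases)):
        z = a @ W + b
        zs.append(z)
        a = softmax(z) if i == last else act(z)
        acts.append(a)
    return a, zs, acts


def forward(model: MLPModel, x: np.ndarray) -> np.ndarray:
    """Class-probability vector for a single input (softmax head)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    if x.shape[-1] != model.layer_sizes[0]:
        raise ValueError(
            f"input length {x.shape[-1]} != model input size {model.layer_sizes[0]}"
        )
    p, _, _ = _forward_full(model, np.atleast_2d(x))
    return p[0] if x.ndim == 1 else p


def bce_loss(y: np.ndarray, p: np.ndarray) -> float:
    """Binary cross-entropy of positive-class probabilities.

    ``y`` may be 0/1 labels or one-hot rows; ``p`` the matching
    probability of class 1 (or full probability rows).  Probabilities are
    clipped to [eps, 1-eps] before the logs.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.ndim == 2:  # one-hot
        y = y[:, 1] if y.shape[1] == 2 else np.argmax(y, axis=1).astype(float)
    if p.ndim == 2:
        p = p[:, 1]
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def backward(
    model: MLPModel, x: np.ndarray, y: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Exact gradients of the cross-entropy for one batch.

    The softmax/cross-entropy pairing makes the output-layer error
    (p - y); hidden errors backpropagate through the activation
    derivative.
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    Y = np.atleast_2d(np.asarray(y, dtype=float))
    if Y.shape[1] != model.layer_sizes[-1]:
        raise ValueError("y must be one-hot rows matching the output layer")
    _, dact = _activation(model.activation)
    p, zs, acts = _forward_full(model, X)
    n = X.shape[0]
    delta = (p - Y) / n
    grads_W = [np.empty_like(W) for W in model.weights]
    grads_b = [np.empty_like(b) for b in model.biases]
    for i in range(len(model.weights) - 1, -1, -1):
        grads_W[i] = acts[i].T @ delta
        grads_b[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ model.weights[i].T) * dact(zs[i - 1])
    return grads_W, grads_b


def _one_hot(y: np.ndarray, n_classes: int = 2) -> np.ndarray:
    out = np.zeros((y.size, n_classes))
    out[np.arange(y.size), y.astype(int)] = 1.0
    return out


@dataclass
class TrainConfig:
    """Training protocol (defaults follow the batch-1 SGD recipe)."""

    lr: float = 1e-5
    epochs: int = 100
    batch: int = 1
    seed: int | None = None
    selection_rule: str = "lowest-test-cost"
    full_batch: bool = False

    def __post_init__(self) -> None:
        if not self.lr >= 0:
            raise ValueError("lr must be nonnegative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainHistory:
    train_cost: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    test_cost: list[float] = field(default_factory=list)
    test_acc: list[float] = field(default_factory=list)
    selected_epoch: int = -1


def _set_metrics(model: MLPModel, X: np.ndarray, Y: np.ndarray) -> tuple[float, float]:
    p, _, _ = _forward_full(model, X)
    cost = bce_loss(Y, p)
    acc = float(np.mean(np.argmax(p, axis=1) == np.argmax(Y, axis=1)))
    return cost, acc


def train(
    model: MLPModel,
    train_set: tuple[np.ndarray, np.ndarray],
    eval_set: tuple[np.ndarray, np.ndarray] | None,
    cfg: TrainConfig,
) -> tuple[MLPModel, TrainHistory]:
    """SGD training loop with per-epoch history and snapshot selection.

    Each epoch visits the training examples in a fresh random order with
    single-example updates w <- w - lr * grad (or one full-batch update in
    ``full_batch`` mode).  The returned model is the epoch snapshot with
    the lowest evaluation cost (training cost when no eval set is given).
    """
    X, y = train_set
    X = np.asarray(X, dtype=float)
    Y = _one_hot(np.asarray(y))
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if eval_set is not None:
        Xe, ye = eval_set
        Xe = np.asarray(Xe, dtype=float)
        Ye = _one_hot(np.asarray(ye))
        if Xe.shape[0] == 0:
            raise ValueError("empty evaluation set")
    rng = np.random.default_rng(cfg.seed)
    work = model.copy()
    hist = TrainHistory()
    best_cost = np.inf
    best = work.copy()
    for epoch in range(cfg.epochs):
        if cfg.full_batch:
            gW, gb = backward(work, X, Y)
            for i in range(len(work.weights)):
                work.weights[i] -= cfg.lr * gW[i]
                work.biases[i] -= cfg.lr * gb[i]
        else:
            order = rng.permutation(X.shape[0])
            for start in range(0, order.size, cfg.batch):
                idx = order[start : start + cfg.batch]
                gW, gb = backward(work, X[idx], Y[idx])
                for i in range(len(work.weights)):
                    work.weights[i] -= cfg.lr * gW[i]
                    work.biases[i] -= cfg.lr * gb[i]
        tr_cost, tr_acc = _set_metrics(work, X, Y)
        if not np.isfinite(tr_cost):
            raise FloatingPointError(
                f"training diverged at epoch {epoch}: cost={tr_cost}"
            )
        hist.train_cost.append(tr_cost)
        hist.train_acc.append(tr_acc)
        if eval_set is not None:
            te_cost, te_acc = _set_metrics(work, Xe, Ye)
            hist.test_cost.append(te_cost)
            hist.test_acc.append(te_acc)
            sel_cost = te_cost
        else:
            sel_cost = tr_cost
        if sel_cost < best_cost:
            best_cost = sel_cost
            best = work.copy()
            hist.selected_epoch = epoch
    return best, hist


@dataclass
class EvalReport:
    accuracy: float
    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    micro_f1: float

    def normalized_confusion(self) -> np.ndarray:
        row = self.confusion.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.confusion / row


def evaluate(model: MLPModel, dataset: tuple[np.ndarray, np.ndarray]) -> EvalReport:
    """Accuracy, confusion matrix and per-class precision/recall/F1."""
    X, y = dataset
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.shape[0] == 0:
        raise ValueError("empty dataset")
    p, _, _ = _forward_full(model, X)
    pred = np.argmax(p, axis=1)
    return classification_report(y, pred, n_classes=model.layer_sizes[-1])


def classification_report(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = 2
) -> EvalReport:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    conf = np.zeros((n_classes, n_classes), dtype=int)
    for t, q in zip(y_true, y_pred):
        conf[t, q] += 1
    accuracy = float(np.trace(conf)) / y_true.size
    precision = np.full(n_classes, np.nan)
    recall = np.full(n_classes, np.nan)
    f1 = np.full(n_classes, np.nan)
    for c in range(n_classes):
        tp = conf[c, c]
        pred_c = conf[:, c].sum()
        true_c = conf[c, :].sum()
        if pred_c > 0:
            precision[c] = tp / pred_c
        if true_c > 0:
            recall[c] = tp / true_c
        else:
            warnings.warn(
                f"class {c} absent from the ground truth; recall undefined",
                stacklevel=2,
            )
        if pred_c > 0 and true_c > 0 and (precision[c] + recall[c]) > 0:
            f1[c] = 2 * precision[c] * recall[c] / (precision[c] + recall[c])
        elif pred_c > 0 and true_c > 0:
            f1[c] = 0.0
    # micro-average: pooled counts (equals accuracy for single-label tasks)
    micro_f1 = accuracy
    return EvalReport(accuracy, conf, precision, recall, f1, micro_f1)


class MLPNetClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn estimator wrapper of the from-scratch MLP.

    Parameters mirror the training protocol: ``hidden_layer_sizes``
    (default six hidden layers of eight units), ``activation`` in
    {tanh, sigmoid, arctan}, constant ``learning_rate`` (default 1e-5),
    ``epochs`` (default 100) and ``batch_size`` (default 1).  When an
    ``eval_set`` is passed to :meth:`fit`, the epoch snapshot with the
    lowest evaluation cost is kept (the protocol's selection rule);
    otherwise the lowest training cost is used.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (8, 8, 8, 8, 8, 8),
        activation: str = "arctan",
        learning_rate: float = 1e-5,
        epochs: int = 100,
        batch_size: int = 1,
        full_batch: bool = False,
        random_state: int | None = None,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.full_batch = full_batch
        self.random_state = random_state

    def fit(self, X, y, eval_set=None):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if self.classes_.size > 2:
            raise ValueError("binary classifier: at most two classes supported")
        y01 = np.searchsorted(self.classes_, y)
        sizes = (X.shape[1], *self.hidden_layer_sizes, 2)
        model = init_mlp(sizes, self.activation, self.random_state)
        cfg = TrainConfig(
            lr=self.learning_rate,
            epochs=self.epochs,
            batch=self.batch_size,
            seed=self.random_state,
            full_batch=self.full_batch,
        )
        if eval_set is not None:
            Xe, ye = eval_set
            eval_set = (np.asarray(Xe), np.searchsorted(self.classes_, ye))
        self.model_, self.history_ = train(model, (X, y01), eval_set, cfg)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = check_array(X)
        p, _, _ = _forward_full(self.model_, X)
        return p

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)
        return self.classes_[np.argmax(p, axis=1)]

    def evaluate(self, X, y) -> EvalReport:
        check_is_fitted(self, "model_")
        y01 = np.searchsorted(self.classes_, np.asarray(y))
        return evaluate(self.model_, (np.asarray(X), y01))
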