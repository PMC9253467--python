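"""Feedforward backpropagation network, written from first principles.

This module implements the surrogate-model machinery: a small fully
connected network (two hidden layers in all study configurations), the
forward pass, analytic backpropagation gradients, and two trainers —
Levenberg-Marquardt ("trainlm"-style, the default) and plain full-batch
gradient descent.  Training uses a train/validation/test split with
validation-based early stopping and always returns the weights from the
best-validation epoch.

The implementation is deliberately self-contained (numpy only): the network
itself is the subject of the package, not a step to delegate.  Established
libraries are used everywhere else in the package, but here the forward
pass, Jacobian and damping schedule are spelled out so they can be checked
against finite differences and closed-form special cases.

Activation tags follow the toolbox nomenclature common in this literature:
``tansig`` (hyperbolic-tangent sigmoid), ``logsig`` (logistic sigmoid) and
``purelin`` (identity).
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "NetworkSpec",
    "Network",
    "TrainingReport",
    "SurrogateModel",
    "activation",
    "activation_derivative",
    "init_network",
    "forward",
    "loss_and_gradient",
    "jacobian",
    "train",
    "train_surrogate",
    "min_hidden_nodes",
]

MODEL_FORMAT_TAG = "leukotransit-net-v1"


# ---------------------------------------------------------------------------
# specs and containers
# ---------------------------------------------------------------------------


@dataclass
class NetworkSpec:
    """Architecture and training hyper-parameters of one surrogate net.

    ``layer_sizes`` lists every layer including input and output, e.g.
    ``[2, 5, 10, 1]`` for the transit-time model.  ``goal`` is the target
    training MSE (on normalized data); ``min_grad`` and ``max_fail`` are the
    gradient-norm and validation-patience stopping criteria.
    """

    layer_sizes: Sequence[int]
    hidden_activation: str = "tansig"
    output_activation: str = "purelin"
    trainer: str = "trainlm"  # or "gd"
    learning_rate: float = 0.03
    max_epochs: int = 1000
    goal: float = 1e-5
    min_grad: float = 1e-7
    max_fail: int = 6
    mu_init: float = 1e-3
    mu_inc: float = 10.0
    mu_dec: float = 0.1
    mu_max: float = 1e10
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = [int(s) for s in self.layer_sizes]
        if len(sizes) < 2 or any(s < 1 for s in sizes):
            raise ValueError(f"layer_sizes must be >=2 positive ints, got {sizes}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.trainer not in ("trainlm", "gd"):
            raise ValueError(f"unknown trainer {self.trainer!r}")
        self.layer_sizes = sizes


@dataclass
class Network:
    """Weights and biases of a feedforward net, plus its spec."""

    weights: list  # per layer, shape (fan_in, fan_out)
    biases: list  # per layer, shape (fan_out,)
    spec: NetworkSpec

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def n_params(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def copy(self) -> "Network":
        return Network(
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            copy.deepcopy(self.spec),
        )

    def layer_activation(self, layer: int) -> str:
        if layer == self.n_layers - 1:
            return self.spec.output_activation
        return self.spec.hidden_activation


@dataclass
class TrainingReport:
    """Per-epoch error history and the reason training stopped."""

    train_mse: list = field(default_factory=list)
    val_mse: list = field(default_factory=list)
    test_mse: list = field(default_factory=list)
    best_epoch: int = 0
    best_val_mse: float = math.inf
    stop_reason: str = "max-epochs"
    final_grad_norm: float = math.nan

    @property
    def n_epochs(self) -> int:
        return len(self.train_mse)


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

_ACTIVATIONS = ("logsig", "tansig", "purelin")


def activation(x, tag: str):
    """Apply a named activation elementwise.

    logsig(x) = 1/(1+exp(-x)); tansig(x) = 2/(1+exp(-2x)) - 1 (== tanh(x));
    purelin(x) = x.
    """
    x = np.asarray(x, dtype=float)
    if tag == "logsig":
        out = 1.0 / (1.0 + np.exp(-x))
    elif tag == "tansig":
        out = np.tanh(x)
    elif tag == "purelin":
        out = x
    else:
        raise ValueError(f"unknown activation tag {tag!r}; expected one of {_ACTIVATIONS}")
    return out if out.ndim else float(out)


def activation_derivative(a, tag: str):
    """Derivative of the activation expressed through its output value ``a``."""
    a = np.asarray(a, dtype=float)
    if tag == "logsig":
        return a * (1.0 - a)
    if tag == "tansig":
        return 1.0 - a * a
    if tag == "purelin":
        return np.ones_like(a)
    raise ValueError(f"unknown activation tag {tag!r}; expected one of {_ACTIVATIONS}")


# ---------------------------------------------------------------------------
# initialization, forward, gradients
# ---------------------------------------------------------------------------


def init_network(spec: NetworkSpec, seed: int | None = None) -> Network:
    """Seeded random initialization (Nguyen-Widrow-style scaling).

    Symmetric small random weights break the weight symmetry that would
    otherwise make hidden units redundant; hidden-layer weight columns are
    scaled so the sigmoids start in their active region.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    sizes = spec.layer_sizes
    weights, biases = [], []
    for li, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        w = rng.uniform(-1.0, 1.0, size=(fan_in, fan_out))
        if li < len(sizes) - 2:  # hidden layer: Nguyen-Widrow magnitude
            beta = 0.7 * fan_out ** (1.0 / fan_in)
            w *= beta / np.maximum(np.linalg.norm(w, axis=0, keepdims=True), 1e-12)
            b = beta * rng.uniform(-1.0, 1.0, size=fan_out)
        else:
            w *= 0.5
            b = 0.1 * rng.uniform(-1.0, 1.0, size=fan_out)
        weights.append(w)
        biases.append(b)
    return Network(weights, biases, spec)


def forward(net: Network, x):
    """Forward pass.

    Each layer computes an affine map followed by its activation,
    ``a_next = g(a @ W + b)``.  Accepts a single input vector or an
    ``(n_samples, n_inputs)`` batch; returns ``(output, activations)`` where
    ``activations[0]`` is the input and ``activations[-1]`` the output
    (the cache consumed by backpropagation).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != net.spec.layer_sizes[0]:
        raise ValueError(
            f"input has {x.shape[1]} features, network expects {net.spec.layer_sizes[0]}"
        )
    acts = [x]
    a = x
    for li, (w, b) in enumerate(zip(net.weights, net.biases)):
        a = activation(a @ w + b, net.layer_activation(li))
        acts.append(a)
    return a, acts


def _backprop_deltas(net: Network, acts, seed_delta):
    """Backpropagate output-side sensitivities through the cached layers."""
    deltas = [None] * net.n_layers
    delta = seed_delta * activation_derivative(acts[-1], net.layer_activation(net.n_layers - 1))
    deltas[-1] = delta
    for li in range(net.n_layers - 2, -1, -1):
        delta = (delta @ net.weights[li + 1].T) * activation_derivative(
            acts[li + 1], net.layer_activation(li)
        )
        deltas[li] = delta
    return deltas


def loss_and_gradient(net: Network, x, y):
    """Mean squared error and its analytic gradient over a batch.

    The per-sample error is ``e_k = Y_k - O_k``; the summed squared error
    ``E = 1/2 sum e^2`` drives backpropagation, and the reported loss is the
    standard unweighted MSE (mean of ``e^2`` over samples and outputs).
    Returns ``(mse, grads)`` with ``grads`` a list of ``(dW, db)`` matching
    the layers, the gradient of the MSE.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] != x.shape[0]:
        raise ValueError("x and y batch sizes differ")
    if x.shape[0] == 0:
        raise ValueError("empty batch")
    out, acts = forward(net, x)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite network output during loss evaluation")
    err = out - y  # d(MSE)/d(out) up to 2/n
    n = err.size
    mse = float(np.mean(err**2))
    deltas = _backprop_deltas(net, acts, (2.0 / n) * err)
    grads = []
    for li in range(net.n_layers):
        dw = acts[li].T @ deltas[li]
        db = deltas[li].sum(axis=0)
        grads.append((dw, db))
    return mse, grads


def jacobian(net: Network, x):
    """Jacobian of per-sample residuals w.r.t. all parameters.

    For a single-output net returns ``(J, out)`` with ``J`` of shape
    ``(n_samples * n_outputs, n_params)``; column order follows the packing
    ``[W0, b0, W1, b1, ...]`` (row-major weights).  This is the exact
    Gauss-Newton Jacobian used by the Levenberg-Marquardt trainer.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    out, acts = forward(net, x)
    n_samples, n_out = out.shape
    rows = []
    for k in range(n_out):
        seed = np.zeros_like(out)
        seed[:, k] = 1.0
        deltas = _backprop_deltas(net, acts, seed)
        cols = []
        for li in range(net.n_layers):
            jw = acts[li][:, :, None] * deltas[li][:, None, :]
            cols.append(jw.reshape(n_samples, -1))
            cols.append(deltas[li])
        rows.append(np.concatenate(cols, axis=1))
    J = np.stack(rows, axis=1).reshape(n_samples * n_out, -1)
    return J, out


def _pack(net: Network) -> np.ndarray:
    parts = []
    for w, b in zip(net.weights, net.biases):
        parts.append(w.ravel())
        parts.append(b.ravel())
    return np.concatenate(parts)


def _unpack(net: Network, theta: np.ndarray) -> None:
    i = 0
    for li, (w, b) in enumerate(zip(net.weights, net.biases)):
        net.weights[li] = theta[i : i + w.size].reshape(w.shape)
        i += w.size
        net.biases[li] = theta[i : i + b.size].reshape(b.shape)
        i += b.size


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _split_arrays(table):
    """Pull normalized (X, Y) arrays for each split from a SampleTable."""
    out = {}
    for split in ("train", "val", "test"):
        X, Y = table.normalized_arrays(split)
        out[split] = (X, Y)
    if out["train"][0].shape[0] == 0:
        raise ValueError("training split is empty")
    return out


def _mse(net: Network, x, y) -> float:
    if x.shape[0] == 0:
        return math.nan
    out, _ = forward(net, x)
    return float(np.mean((out - y) ** 2))


def train(net: Network, table, spec: NetworkSpec | None = None):
    """Train a network on a SampleTable; return best-validation weights.

    The default trainer is Levenberg-Marquardt with adaptive damping
    (multiply ``mu`` by ``mu_inc`` on a rejected step, by ``mu_dec`` on an
    accepted one); ``trainer='gd'`` runs plain full-batch gradient descent
    with rate ``learning_rate``.  Stopping reasons, in precedence order:
    ``goal`` (training MSE below target), ``min-grad``, ``max-fail``
    (validation error rose ``max_fail`` epochs past its best), ``mu-max``
    (LM damping exhausted) and ``max-epochs``.

    Returns ``(best_net, report)``; ``best_net`` carries the weights of the
    epoch with the lowest validation MSE (final weights if no validation
    rows are present).
    """
    spec = spec or net.spec
    if all(np.all(w == 0) for w in net.weights):
        raise ValueError(
            "all-zero initial weights: symmetric-weight degeneracy, every hidden "
            "unit would stay identical; use init_network for a seeded random start"
        )
    data = _split_arrays(table)
    x_tr, y_tr = data["train"]
    x_va, y_va = data["val"]
    x_te, y_te = data["test"]
    has_val = x_va.shape[0] > 0

    report = TrainingReport()
    best = net.copy()
    fails = 0
    mu = spec.mu_init
    theta = _pack(net)
    n_resid = y_tr.size

    out, _ = forward(net, x_tr)
    sse = float(np.sum((out - y_tr) ** 2))

    for epoch in range(spec.max_epochs):
        if spec.trainer == "trainlm":
            J, out = jacobian(net, x_tr)
            r = (out - y_tr).reshape(-1)
            g = (2.0 / n_resid) * (J.T @ r)
            grad_norm = float(np.linalg.norm(g, np.inf))
            JTJ = J.T @ J
            accepted = False
            while mu <= spec.mu_max:
                A = JTJ + mu * np.eye(JTJ.shape[0])
                try:
                    step = np.linalg.solve(A, J.T @ r)
                except np.linalg.LinAlgError:
                    mu *= spec.mu_inc
                    continue
                theta_new = theta - step
                _unpack(net, theta_new)
                out_new, _ = forward(net, x_tr)
                if not np.all(np.isfinite(out_new)):
                    _unpack(net, theta)
                    raise FloatingPointError(
                        f"training diverged (non-finite loss) at epoch {epoch}"
                    )
                sse_new = float(np.sum((out_new - y_tr) ** 2))
                if sse_new < sse:
                    theta, sse = theta_new, sse_new
                    mu = max(mu * spec.mu_dec, 1e-20)
                    accepted = True
                    break
                _unpack(net, theta)
                mu *= spec.mu_inc
            if not accepted:
                report.stop_reason = "mu-max"
                report.final_grad_norm = grad_norm
                break
        else:  # full-batch gradient descent per the printed update rule
            mse_tr, grads = loss_and_gradient(net, x_tr, y_tr)
            grad_norm = max(
                float(max(np.abs(dw).max(), np.abs(db).max())) for dw, db in grads
            )
            for li, (dw, db) in enumerate(grads):
                net.weights[li] -= spec.learning_rate * dw
                net.biases[li] -= spec.learning_rate * db
            theta = _pack(net)
            sse = mse_tr * n_resid  # pre-update value; refreshed below

        mse_tr = _mse(net, x_tr, y_tr)
        report.train_mse.append(mse_tr)
        report.val_mse.append(_mse(net, x_va, y_va) if has_val else math.nan)
        report.test_mse.append(_mse(net, x_te, y_te) if x_te.shape[0] else math.nan)
        report.final_grad_norm = grad_norm
        sse = mse_tr * n_resid

        if has_val:
            v = report.val_mse[-1]
            if v < report.best_val_mse:
                report.best_val_mse = v
                report.best_epoch = epoch
                best = net.copy()
                fails = 0
            else:
                fails += 1
        else:
            report.best_epoch = epoch
            best = net.copy()

        if mse_tr <= spec.goal:
            report.stop_reason = "goal"
            break
        if grad_norm <= spec.min_grad:
            report.stop_reason = "min-gradient"
            break
        if has_val and fails >= spec.max_fail:
            report.stop_reason = "max-fail"
            break
    else:
        report.stop_reason = "max-epochs"

    return best, report


def min_hidden_nodes(M: int, h: int) -> int:
    """Smallest hidden-node count by the combinatorial capacity rule.

    Returns the least integer ``I`` with ``sum_{n=0..M} C(I, n) > h``, where
    ``C`` is the binomial coefficient (zero for ``n > I``): the hidden layer
    must offer more dichotomies than there are training samples.  For two
    inputs and 115 samples this gives 15 nodes.
    """
    if M < 1 or h < 1:
        raise ValueError("M and h must be >= 1")
    I = 1
    while True:
        if sum(math.comb(I, n) for n in range(0, M + 1)) > h:
            return I
        I += 1


# ---------------------------------------------------------------------------
# surrogate wrapper (network + normalization), text serialization
# ---------------------------------------------------------------------------


@dataclass
class SurrogateModel:
    """A trained network bundled with its normalization, self-contained.

    ``norm`` maps every column (inputs and target) to its (lo, hi) min-max
    range fitted on the training split; predictions accept and return raw
    physical units.
    """

    network: Network
    input_columns: list
    target_column: str
    norm: dict
    meta: dict = field(default_factory=dict)

    def _norm_col(self, values, col):
        lo, hi = self.norm[col]
        return 2.0 * (np.asarray(values, dtype=float) - lo) / (hi - lo) - 1.0

    def predict(self, X) -> np.ndarray:
        """Predict the target in physical units from raw inputs.

        ``X`` is a DataFrame with the input columns, or an array whose
        columns follow ``input_columns`` order.
        """
        if hasattr(X, "columns"):
            cols = [np.asarray(X[c], dtype=float) for c in self.input_columns]
        else:
            arr = np.atleast_2d(np.asarray(X, dtype=float))
            cols = [arr[:, i] for i in range(len(self.input_columns))]
        Xn = np.column_stack(
            [self._norm_col(v, c) for v, c in zip(cols, self.input_columns)]
        )
        out, _ = forward(self.network, Xn)
        lo, hi = self.norm[self.target_column]
        return (out[:, 0] + 1.0) / 2.0 * (hi - lo) + lo

    def save(self, path) -> None:
        spec = self.network.spec
        payload = {
            "format": MODEL_FORMAT_TAG,
            "spec": {
                "layer_sizes": list(spec.layer_sizes),
                "hidden_activation": spec.hidden_activation,
                "output_activation": spec.output_activation,
                "trainer": spec.trainer,
                "learning_rate": spec.learning_rate,
                "max_epochs": spec.max_epochs,
                "goal": spec.goal,
                "min_grad": spec.min_grad,
                "max_fail": spec.max_fail,
                "seed": spec.seed,
            },
            "weights": [w.tolist() for w in self.network.weights],
            "biases": [b.tolist() for b in self.network.biases],
            "input_columns": list(self.input_columns),
            "target_column": self.target_column,
            "norm": {k: list(v) for k, v in self.norm.items()},
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path) -> "SurrogateModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != MODEL_FORMAT_TAG:
            raise ValueError(f"unrecognized model format {payload.get('format')!r}")
        spec = NetworkSpec(**payload["spec"])
        net = Network(
            [np.asarray(w, dtype=float) for w in payload["weights"]],
            [np.asarray(b, dtype=float) for b in payload["biases"]],
            spec,
        )
        return cls(
            network=net,
            input_columns=list(payload["input_columns"]),
            target_column=payload["target_column"],
            norm={k: tuple(v) for k, v in payload["norm"].items()},
            meta=payload.get("meta", {}),
        )


def train_surrogate(table, spec: NetworkSpec, seed: int | None = None):
    """Initialize, train and bundle a surrogate for one SampleTable.

    Returns ``(SurrogateModel, TrainingReport)``.
    """
    sizes = list(spec.layer_sizes)
    if sizes[0] != len(table.input_columns):
        raise ValueError(
            f"network expects {sizes[0]} inputs but table has "
            f"{len(table.input_columns)} ({table.input_columns})"
        )
    net = init_network(spec, seed)
    best, report = train(net, table, spec)
    model = SurrogateModel(
        network=best,
        input_columns=list(table.input_columns),
        target_column=table.target_column,
        norm=dict(table.norm),
        meta={
            "stop_reason": report.stop_reason,
            "best_epoch": report.best_epoch,
            "best_val_mse": report.best_val_mse,
            "n_train": int(table.split_counts().get("train", 0)),
        },
    )
    return model, report
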