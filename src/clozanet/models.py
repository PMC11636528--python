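"""The sparse per-modality neural network, LRP importance, and SVM baseline.

Architecture.  The classifier is a feed-forward network of nine (or fewer)
parallel subnetworks, one per feature block: every input of a block connects
to its own ten dedicated first-hidden-layer nodes, those ten connect to the
block's single second-hidden-layer node, and the second-layer nodes connect
to a common sigmoid output.  There are no connections across blocks before
the output layer, so the unequal feature counts per modality cannot bias the
fusion, and each second-layer activation directly reflects one modality's
contribution.  Every node uses the logistic activation.

Training is mini-batch ADAM on binary cross-entropy: by default 10 000
iterations of batch 10 at learning rate 1e-4.  Only the structurally
non-zero weights exist in memory (see `_nnkernels`), so the zero pattern is
invariant under training by construction.

Importance is computed with layer-wise relevance propagation using the
epsilon-stabilized proportional redistribution rule: the output activation
is redistributed layer by layer to the inputs in proportion to each
connection's contribution to the downstream pre-activation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from . import _nnkernels as K

__all__ = [
    "NetworkSpec",
    "NetworkWeights",
    "TrainConfig",
    "build_network",
    "init_weights",
    "train_network",
    "predict",
    "lrp_relevance",
    "train_svm_baseline",
    "predict_svm",
]

FAN_OUT = 10  # dedicated first-layer nodes per input

#: epsilon stabilizer of the LRP redistribution rule
LRP_EPS = 1e-6


@dataclass(frozen=True)
class NetworkSpec:
    """Topology of the sparse network: ordered blocks and their input counts."""

    layout: tuple[tuple[str, int], ...]
    fan_out: int = FAN_OUT

    @property
    def block_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.layout)

    @property
    def n_inputs(self) -> int:
        return sum(c for _, c in self.layout)

    @property
    def n_blocks(self) -> int:
        return len(self.layout)

    @property
    def n_first_layer(self) -> int:
        return self.fan_out * self.n_inputs

    def block_of_input(self) -> np.ndarray:
        """Block index of every input, in stacking order."""
        return np.repeat(np.arange(self.n_blocks),
                         [c for _, c in self.layout]).astype(np.int64)


def build_network(layout) -> NetworkSpec:
    """Build the network spec for a modality layout.

    ``layout`` is a mapping block name -> input count, or the
    ``FeatureSet.layout`` mapping of (start, stop) ranges.
    """
    items = []
    for name, v in dict(layout).items():
        count = (v[1] - v[0]) if isinstance(v, (tuple, list)) else int(v)
        if count < 1:
            raise ValueError(f"block {name!r} has no inputs")
        items.append((name, count))
    if not items:
        raise ValueError("empty layout")
    return NetworkSpec(layout=tuple(items))


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the ADAM training loop."""

    iterations: int = 10_000
    batch_size: int = 10
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0
    log_every: int = 100

    def __post_init__(self) -> None:
        if min(self.iterations, self.batch_size) < 1 \
                or self.learning_rate <= 0:
            raise ValueError("iterations, batch size and learning rate "
                             "must be positive")


@dataclass
class NetworkWeights:
    """Trained (or initial) weights in the compact per-group layout."""

    spec: NetworkSpec
    W1: np.ndarray  # (D, K)
    b1: np.ndarray  # (D, K)
    W2: np.ndarray  # (D, K)
    b2: np.ndarray  # (B,)
    w3: np.ndarray  # (B,)
    b3: float
    seed: int = 0
    config: TrainConfig | None = None
    loss_curve: np.ndarray = field(default_factory=lambda: np.empty(0))


def init_weights(spec: NetworkSpec, seed: int = 0) -> NetworkWeights:
    """Scaled uniform initialization, U(+-sqrt(6/(fan_in+fan_out))) per
    connection group; biases start at zero."""
    rng = np.random.default_rng(seed)
    D, Kf, B = spec.n_inputs, spec.fan_out, spec.n_blocks
    lim1 = np.sqrt(6.0 / (1 + Kf))
    W1 = rng.uniform(-lim1, lim1, size=(D, Kf))
    # fan-in of a second-layer node = fan_out x its block's input count
    block_of = spec.block_of_input()
    fan_in2 = np.array([c for _, c in spec.layout]) * Kf
    lim2 = np.sqrt(6.0 / (fan_in2 + 1))
    W2 = rng.uniform(-1, 1, size=(D, Kf)) * lim2[block_of][:, None]
    lim3 = np.sqrt(6.0 / (B + 1))
    w3 = rng.uniform(-lim3, lim3, size=B)
    return NetworkWeights(spec=spec, W1=W1, b1=np.zeros((D, Kf)), W2=W2,
                          b2=np.zeros(B), w3=w3, b3=0.0, seed=seed)


def _validate(spec: NetworkSpec, X: np.ndarray, y: np.ndarray | None) -> None:
    if X.ndim != 2 or X.shape[1] != spec.n_inputs:
        raise ValueError(f"feature width {X.shape[-1]} does not match the "
                         f"network's {spec.n_inputs} inputs")
    if y is not None and not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")


def train_network(spec: NetworkSpec, X, y,
                  cfg: TrainConfig = TrainConfig()) -> NetworkWeights:
    """Train the sparse network with mini-batch ADAM; deterministic per seed."""
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate(spec, X, y)
    if cfg.batch_size > X.shape[0]:
        raise ValueError("batch size exceeds training-set size")
    w = init_weights(spec, cfg.seed)
    b3, losses = K.train_adam(
        X, y, w.W1, w.b1, w.W2, w.b2, w.w3, w.b3, spec.block_of_input(),
        cfg.iterations, cfg.batch_size, cfg.learning_rate,
        cfg.beta1, cfg.beta2, cfg.adam_eps,
        cfg.seed % (2**31 - 1), cfg.log_every)
    w.b3 = float(b3)
    w.config = cfg
    w.loss_curve = losses
    return w


def forward(weights: NetworkWeights, X):
    """Activations (A1, A2, output) of the network for a batch of rows."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    _validate(weights.spec, X, None)
    return K.forward(np.ascontiguousarray(X), weights.W1, weights.b1,
                     weights.W2, weights.b2, weights.w3, weights.b3,
                     weights.spec.block_of_input())


def predict(weights: NetworkWeights, X) -> tuple[np.ndarray, np.ndarray]:
    """Class (score >= 0.5 -> 1) and output-node score for each row."""
    _, _, score = forward(weights, X)
    return (score >= 0.5).astype(int), score


def loss_and_grads(weights: NetworkWeights, X, y):
    """Mean BCE loss and analytic gradients for one batch (for checking
    against finite differences)."""
    X = np.ascontiguousarray(np.atleast_2d(X), dtype=float)
    y = np.asarray(y, dtype=float)
    _validate(weights.spec, X, y)
    return K.loss_and_grads(X, y, weights.W1, weights.b1, weights.W2,
                            weights.b2, weights.w3, weights.b3,
                            weights.spec.block_of_input())


def _stab(z: np.ndarray | float, eps: float):
    return z + eps * np.where(np.asarray(z) >= 0, 1.0, -1.0)


def lrp_relevance(weights: NetworkWeights, x, target_class: int = 1,
                  eps: float = LRP_EPS) -> np.ndarray:
    """Epsilon-rule relevance of every input for the target class.

    The output activation (class 1) or its complement (class 0) is
    redistributed backwards: at each node, incoming relevance is split among
    the contributions ``a_i * w_ij`` in proportion to their share of the
    stabilized pre-activation.  Inputs whose outgoing weights are all zero
    receive exactly zero relevance.
    """
    x = np.asarray(x, dtype=float).ravel()
    spec = weights.spec
    if x.shape[0] != spec.n_inputs:
        raise ValueError("input width does not match the network")
    A1, A2, out = forward(weights, x[None])
    a1, a2, p = A1[0], A2[0], out[0]
    block_of = spec.block_of_input()

    # output layer: redistribute p (or 1-p) over second-layer contributions
    contrib3 = a2 * weights.w3
    z3 = contrib3.sum() + weights.b3
    if target_class == 1:
        R_out = p
        R2 = contrib3 / _stab(z3, eps) * R_out
    else:
        R_out = 1.0 - p
        R2 = -contrib3 / _stab(-z3, eps) * R_out

    # second layer: each block's relevance over its first-layer nodes
    contrib2 = a1 * weights.W2  # (D, K)
    z2 = np.zeros(spec.n_blocks)
    np.add.at(z2, block_of, contrib2.sum(axis=1))
    z2 += weights.b2
    R1 = contrib2 / _stab(z2[block_of], eps)[:, None] * R2[block_of][:, None]

    # first layer: node (i, k) has the single input contribution x_i * W1[i,k]
    contrib1 = x[:, None] * weights.W1
    z1 = contrib1 + weights.b1
    R_in = (contrib1 / _stab(z1, eps) * R1).sum(axis=1)
    return R_in


def save_weights(weights: NetworkWeights, path) -> None:
    """Portable archive: a JSON header (topology, seed, hyperparameters)
    next to the binary weight arrays."""
    import json

    header = {
        "layout": list(weights.spec.layout),
        "fan_out": weights.spec.fan_out,
        "seed": weights.seed,
        "config": None if weights.config is None else {
            "iterations": weights.config.iterations,
            "batch_size": weights.config.batch_size,
            "learning_rate": weights.config.learning_rate,
            "seed": weights.config.seed,
        },
    }
    np.savez(path, header=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8),
        W1=weights.W1, b1=weights.b1, W2=weights.W2, b2=weights.b2,
        w3=weights.w3, b3=np.array(weights.b3),
        loss_curve=weights.loss_curve)


def load_weights(path) -> NetworkWeights:
    import json

    with np.load(path) as z:
        header = json.loads(bytes(z["header"].tobytes()).decode())
        spec = NetworkSpec(layout=tuple((n, int(c))
                                        for n, c in header["layout"]),
                           fan_out=int(header["fan_out"]))
        cfg = header["config"]
        return NetworkWeights(
            spec=spec, W1=z["W1"], b1=z["b1"], W2=z["W2"], b2=z["b2"],
            w3=z["w3"], b3=float(z["b3"]), seed=int(header["seed"]),
            config=None if cfg is None else TrainConfig(**cfg),
            loss_curve=z["loss_curve"])


def train_svm_baseline(X, y) -> SVC:
    """Linear soft-margin SVM baseline (C = 1), deterministic."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    model = SVC(kernel="linear", C=1.0)
    model.fit(X, y.astype(int))
    return model


def predict_svm(model: SVC, X) -> np.ndarray:
    return model.predict(np.atleast_2d(np.asarray(X, dtype=float)))
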