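"""BP neural-network and PSO-BP baselines for the model comparison.

A single-hidden-layer perceptron maps the 5-D kinematic feature vector to
four output nodes (one per riding phase; argmax decides, ties go to the
lowest phase index).  Both layers use the logistic sigmoid and the loss is
squared error, trained by full-batch gradient backpropagation at a fixed
learning rate (default 0.7) until an epoch cap or a global-error target.

Hidden-layer size follows m = round(sqrt(n + l)) + alpha_const, which with
n = 5 inputs, l = 4 outputs and alpha_const = 3 gives the reference
configuration of 6 hidden nodes.  (The literal sum reading n + l + alpha,
selectable via ``rule="sum"``, would give 12 and contradicts that
configuration.)

PSO-BP replaces gradient training by a particle swarm searching the
flattened weight-and-threshold vector (n*m + m + m*l + l = 64 dimensions
for the reference sizes), scored by K-fold validation accuracy of the
fixed network; an optional polish step runs BP from the swarm's best
weights.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .features import LabeledDataset
from .pso import FitnessSpec, SwarmConfig, cv_fitness, optimize

__all__ = [
    "MlpSpec",
    "MlpModel",
    "hidden_size",
    "init_mlp",
    "train_bp",
    "train_pso_bp",
    "predict_mlp",
]

N_PHASES = 4


def hidden_size(n: int, l: int, alpha_const: int = 3, rule: str = "sqrt") -> int:
    """Hidden-node count from input count n and output count l.

    ``sqrt`` (default): m = round(sqrt(n + l)) + alpha_const;
    ``sum``: m = n + l + alpha_const.
    """
    if n < 1 or l < 1:
        raise ValueError("n and l must be >= 1")
    if rule == "sqrt":
        return int(round(np.sqrt(n + l))) + int(alpha_const)
    if rule == "sum":
        return n + l + int(alpha_const)
    raise ValueError(f"unknown hidden-size rule {rule!r}")


@dataclass(frozen=True)
class MlpSpec:
    """Network shape and training hyperparameters."""

    n_input: int = 5
    n_output: int = N_PHASES
    alpha_const: int = 3
    hidden: int | None = None  # None -> hidden_size(n_input, n_output, alpha_const)
    rule: str = "sqrt"
    learning_rate: float = 0.7
    max_epochs: int = 500
    target_error: float = 1e-3
    seed: int = 0

    @property
    def m(self) -> int:
        if self.hidden is not None:
            return int(self.hidden)
        return hidden_size(self.n_input, self.n_output, self.alpha_const, self.rule)

    @property
    def n_weights(self) -> int:
        """Flattened parameter count: n*m + m + m*l + l."""
        n, m, l = self.n_input, self.m, self.n_output
        return n * m + m + m * l + l


@dataclass
class MlpModel:
    """Weights and node thresholds of the two layers."""

    W1: np.ndarray  # (m, n)
    b1: np.ndarray  # (m,)
    W2: np.ndarray  # (l, m)
    b2: np.ndarray  # (l,)

    def copy(self) -> "MlpModel":
        return MlpModel(self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy())


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def init_mlp(spec: MlpSpec) -> MlpModel:
    """Seeded uniform(-0.5, 0.5) initialization."""
    rng = np.random.default_rng(spec.seed)
    n, m, l = spec.n_input, spec.m, spec.n_output
    return MlpModel(
        W1=rng.uniform(-0.5, 0.5, size=(m, n)),
        b1=rng.uniform(-0.5, 0.5, size=m),
        W2=rng.uniform(-0.5, 0.5, size=(l, m)),
        b2=rng.uniform(-0.5, 0.5, size=l),
    )


def forward(model: MlpModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hidden and output activations for rows of X."""
    P = np.atleast_2d(np.asarray(X, dtype=float))
    if P.shape[1] != model.W1.shape[1]:
        raise ValueError("feature dimension mismatch with the network")
    H = _sigmoid(P @ model.W1.T + model.b1)
    O = _sigmoid(H @ model.W2.T + model.b2)
    return H, O


def _one_hot(y: np.ndarray, l: int) -> np.ndarray:
    Y = np.zeros((len(y), l))
    Y[np.arange(len(y)), np.asarray(y, dtype=int) - 1] = 1.0
    return Y


def global_error(model: MlpModel, X: np.ndarray, Y: np.ndarray) -> float:
    """Mean over samples of half the squared output error."""
    _, O = forward(model, X)
    return float(0.5 * np.mean(np.sum((Y - O) ** 2, axis=1)))


def _backprop(model: MlpModel, X: np.ndarray, Y: np.ndarray, spec: MlpSpec) -> MlpModel:
    """In-place full-batch gradient descent with the spec's stopping rules."""
    n = len(X)
    lr = spec.learning_rate
    for _ in range(spec.max_epochs):
        H, O = forward(model, X)
        err = O - Y
        E = float(0.5 * np.mean(np.sum(err**2, axis=1)))
        if not np.isfinite(E):
            raise RuntimeError("BP training diverged (non-finite loss)")
        if E < spec.target_error:
            break
        dO = err * O * (1.0 - O) / n
        dH = (dO @ model.W2) * H * (1.0 - H)
        model.W2 -= lr * dO.T @ H
        model.b2 -= lr * dO.sum(axis=0)
        model.W1 -= lr * dH.T @ X
        model.b1 -= lr * dH.sum(axis=0)
    return model


def train_bp(ds: LabeledDataset, spec: MlpSpec | None = None) -> MlpModel:
    """Full-batch gradient backpropagation on squared error.

    Stops at ``max_epochs`` or once the global error drops below
    ``target_error``; zero epochs returns the random initialization.
    Deterministic under ``spec.seed``.
    """
    spec = spec or MlpSpec()
    X = np.asarray(ds.X, dtype=float)
    Y = _one_hot(ds.y, spec.n_output)
    return _backprop(init_mlp(spec), X, Y, spec)


def predict_mlp(model: MlpModel, X) -> np.ndarray | int:
    """Argmax over the four output activations; ties -> lowest phase."""
    _, O = forward(model, X)
    labels = np.argmax(O, axis=1) + 1  # argmax takes the first maximum
    if np.ndim(X) == 1:
        return int(labels[0])
    return labels


# -- PSO-trained network ----------------------------------------------------

def pack_weights(model: MlpModel) -> np.ndarray:
    return np.concatenate(
        [model.W1.ravel(), model.b1, model.W2.ravel(), model.b2]
    )


def unpack_weights(vec: np.ndarray, spec: MlpSpec) -> MlpModel:
    n, m, l = spec.n_input, spec.m, spec.n_output
    vec = np.asarray(vec, dtype=float)
    if vec.size != spec.n_weights:
        raise ValueError(f"expected {spec.n_weights} parameters, got {vec.size}")
    i = 0
    W1 = vec[i : i + m * n].reshape(m, n); i += m * n
    b1 = vec[i : i + m]; i += m
    W2 = vec[i : i + l * m].reshape(l, m); i += l * m
    b2 = vec[i : i + l]
    return MlpModel(W1=W1, b1=b1, W2=W2, b2=b2)


class _FixedMlp:
    """A weight-encoded network posing as a fit/predict classifier so the
    swarm fitness can score it fold-by-fold (fit is a no-op)."""

    def __init__(self, model: MlpModel):
        self.model = model

    def fit(self, X, y):
        return self

    def predict(self, X):
        return predict_mlp(self.model, X)


def train_pso_bp(
    ds: LabeledDataset,
    spec: MlpSpec | None = None,
    swarm: SwarmConfig | None = None,
    n_folds: int = 10,
    weight_bound: float = 5.0,
    polish: bool = False,
) -> MlpModel:
    """Optimize the network's weights and thresholds by particle swarm.

    The search space is the flattened parameter vector in
    [-weight_bound, weight_bound]^D; fitness is the K-fold validation
    accuracy of the fixed network.  ``polish`` runs BP afterwards starting
    from the swarm's best weights.
    """
    spec = spec or MlpSpec()
    D = spec.n_weights
    lo = np.full(D, -weight_bound)
    hi = np.full(D, weight_bound)
    if swarm is None:
        swarm = SwarmConfig(n_particles=20, max_iter=100, bounds=(lo, hi),
                            seed=spec.seed)
    else:
        import dataclasses

        swarm = dataclasses.replace(swarm, bounds=(lo, hi), velocity_clamp=None)

    fit_spec = FitnessSpec(
        dataset=ds,
        n_folds=n_folds,
        family=lambda pos: _FixedMlp(unpack_weights(pos, spec)),
        fold_seed=swarm.seed,
    )
    res = optimize(lambda pos: cv_fitness(pos, fit_spec), swarm)
    model = unpack_weights(res.best_x, spec)
    if polish:
        model = _polish_bp(model, ds, spec)
    return model


def _polish_bp(model: MlpModel, ds: LabeledDataset, spec: MlpSpec) -> MlpModel:
    """BP fine-tuning from given weights (same stopping rules as train_bp)."""
    X = np.asarray(ds.X, dtype=float)
    Y = _one_hot(ds.y, spec.n_output)
    return _backprop(model.copy(), X, Y, spec)
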