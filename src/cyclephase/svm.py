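"""Binary kernel SVM and the three-node binary-tree phase classifier.

The decision function of each binary machine is

    f(P) = sgn( sum_i Q_i alpha_i* K(P_i, P) + b* )

with support labels Q_i in {+1, -1}, dual coefficients 0 <= alpha_i* <= C
and bias b*.  The quadratic-programming solve is delegated to a standard
soft-margin implementation (scikit-learn's SVC); this module owns the
kernels, the explicit decision-function evaluation, the multiclass tree
and serialization.

Four phases are separated by peeling one class per node: SVM1 splits
pedaling from the rest, SVM2 splits lower buffer from {relaxation, upper
buffer}, SVM3 splits relaxation from upper buffer; a sample rejected by
all three nodes is upper buffer.  Each node only ever sees the samples the
previous nodes rejected, so training sets shrink monotonically down the
tree.  A decision value of exactly zero maps to +1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .features import LabeledDataset

__all__ = [
    "KernelSpec",
    "SvmModel",
    "PhaseTreeModel",
    "PEEL_ORDER",
    "kernel_eval",
    "train_binary",
    "predict_binary",
    "train_tree",
    "predict_tree",
    "kernel_grid_report",
    "tree_to_json",
    "tree_from_json",
]

KERNEL_KINDS = ("polynomial", "rbf", "linear", "sigmoid")  # s = 0, 1, 2, 3

#: classes peeled off by SVM1, SVM2, SVM3; the residual class is 4
PEEL_ORDER = (1, 2, 3)
RESIDUAL_LABEL = 4


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and parameters (gamma = bandwidth, gamma > 0 for the
    nonlinear kernels; degree/coef0 only matter for polynomial/sigmoid)."""

    kind: str = "rbf"
    gamma: float = 1.0
    degree: int = 3
    coef0: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}; one of {KERNEL_KINDS}")
        if self.kind != "linear" and not self.gamma > 0:
            raise ValueError(f"gamma must be > 0 for {self.kind} kernel")

    @property
    def sklearn_name(self) -> str:
        return {"polynomial": "poly", "rbf": "rbf", "linear": "linear",
                "sigmoid": "sigmoid"}[self.kind]


def kernel_eval(spec: KernelSpec, u, v) -> np.ndarray | float:
    """Evaluate K(u, v); 2-D inputs give the full Gram matrix.

    rbf: exp(-gamma ||u-v||^2); linear: u.v;
    polynomial: (gamma u.v + coef0)^degree; sigmoid: tanh(gamma u.v + coef0).
    """
    U = np.atleast_2d(np.asarray(u, dtype=float))
    V = np.atleast_2d(np.asarray(v, dtype=float))
    if U.shape[1] != V.shape[1]:
        raise ValueError(f"dimension mismatch: {U.shape[1]} vs {V.shape[1]}")
    if spec.kind == "rbf":
        sq = (
            np.sum(U**2, axis=1)[:, None]
            + np.sum(V**2, axis=1)[None, :]
            - 2.0 * U @ V.T
        )
        out = np.exp(-spec.gamma * np.maximum(sq, 0.0))
    elif spec.kind == "linear":
        out = U @ V.T
    elif spec.kind == "polynomial":
        out = (spec.gamma * (U @ V.T) + spec.coef0) ** spec.degree
    else:  # sigmoid
        out = np.tanh(spec.gamma * (U @ V.T) + spec.coef0)
    if np.ndim(u) == 1 and np.ndim(v) == 1:
        return float(out[0, 0])
    return out


@dataclass
class SvmModel:
    """A trained soft-margin binary SVM in support-vector form."""

    support_vectors: np.ndarray  # (n_sv, d)
    alpha: np.ndarray  # alpha_i* >= 0
    Q: np.ndarray  # support labels, +-1
    bias: float
    kernel: KernelSpec
    C: float
    n_train: int = 0

    @property
    def q_alpha(self) -> np.ndarray:
        """Signed dual coefficients Q_i * alpha_i*."""
        return self.Q * self.alpha


def train_binary(
    X: np.ndarray, y: np.ndarray, C: float, kernel: KernelSpec
) -> SvmModel:
    """Fit a soft-margin binary SVM on +-1 labels.

    The dual solve uses scikit-learn's SVC; the returned model exposes the
    support-vector expansion so decision values can be recomputed by an
    explicit sum.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not C > 0:
        raise ValueError(f"penalty C must be > 0, got {C}")
    classes = np.unique(y)
    if not np.array_equal(np.sort(classes), [-1, 1]):
        raise ValueError("training labels must contain both +1 and -1")
    clf = SVC(
        C=C,
        kernel=kernel.sklearn_name,
        gamma=kernel.gamma,
        degree=kernel.degree,
        coef0=kernel.coef0,
    )
    clf.fit(X, y)
    # classes_ is sorted [-1, +1], so positive decision values vote +1 and
    # dual_coef_[0] already equals Q_i * alpha_i*
    q_alpha = clf.dual_coef_[0]
    return SvmModel(
        support_vectors=clf.support_vectors_.copy(),
        alpha=np.abs(q_alpha),
        Q=np.sign(q_alpha).astype(int),
        bias=float(clf.intercept_[0]),
        kernel=kernel,
        C=float(C),
        n_train=len(X),
    )


def decision_values(model: SvmModel, X) -> np.ndarray | float:
    """sum_i Q_i alpha_i* K(P_i, P) + b* for each row of X."""
    P = np.atleast_2d(np.asarray(X, dtype=float))
    if P.shape[1] != model.support_vectors.shape[1]:
        raise ValueError("feature dimension mismatch with the trained model")
    K = kernel_eval(model.kernel, model.support_vectors, P)
    vals = model.q_alpha @ K + model.bias
    if np.ndim(X) == 1:
        return float(vals[0])
    return vals


def predict_binary(model: SvmModel, X):
    """Predicted +-1 labels and raw decision values; ties (value 0) -> +1."""
    vals = decision_values(model, X)
    labels = np.where(np.asarray(vals) >= 0.0, 1, -1)
    if np.ndim(X) == 1:
        return int(labels), float(vals)
    return labels, vals


@dataclass
class PhaseTreeModel:
    """Ordered triple of binary SVMs peeling pedaling, lower buffer and
    relaxation; whatever survives all three is upper buffer."""

    nodes: list[SvmModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.nodes) != 3:
            raise ValueError("the phase tree has exactly three binary nodes")


def _node_params(params, i: int) -> tuple[float, float]:
    """Per-node (C, gamma): a single pair is shared across nodes."""
    if np.ndim(params[0]) == 0:
        return float(params[0]), float(params[1])
    return float(params[i][0]), float(params[i][1])


def train_tree(
    ds: LabeledDataset,
    params: Sequence = (2.0, 1.0),
    kind: str = "rbf",
    degree: int = 3,
    coef0: float = 0.0,
) -> PhaseTreeModel:
    """Train the three-node peeling tree.

    ``params`` is either one (C, gamma) pair shared by all nodes or a
    sequence of three pairs.  Node i is trained on the samples not peeled
    by earlier nodes, with the peeled class as +1 and the rest as -1.
    """
    missing = [p for p in (1, 2, 3, 4) if p not in ds.y]
    if missing:
        raise ValueError(f"all four phases must be present; missing {missing}")
    nodes = []
    X, y = ds.X, ds.y
    for i, phase in enumerate(PEEL_ORDER):
        C, gamma = _node_params(params, i)
        spec = KernelSpec(kind=kind, gamma=gamma, degree=degree, coef0=coef0)
        target = np.where(y == phase, 1, -1)
        nodes.append(train_binary(X, target, C, spec))
        keep = y != phase
        X, y = X[keep], y[keep]
    return PhaseTreeModel(nodes=nodes)


def predict_tree(model: PhaseTreeModel, X) -> np.ndarray | int:
    """Sequential tree prediction: first node voting +1 wins its phase;
    a sample rejected by all three nodes is upper buffer.  Later nodes are
    only evaluated on the samples earlier nodes rejected."""
    single = np.ndim(X) == 1
    P = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.full(len(P), RESIDUAL_LABEL, dtype=int)
    remaining = np.arange(len(P))
    for phase, node in zip(PEEL_ORDER, model.nodes):
        if len(remaining) == 0:
            break
        labels, _ = predict_binary(node, P[remaining])
        fired = np.asarray(labels) == 1
        out[remaining[fired]] = phase
        remaining = remaining[~fired]
    if single:
        return int(out[0])
    return out


def tree_accuracy(model: PhaseTreeModel, ds: LabeledDataset) -> float:
    """Fraction of correctly recognized samples."""
    return float(np.mean(predict_tree(model, ds.X) == ds.y))


def kernel_grid_report(
    ds_train: LabeledDataset,
    ds_test: LabeledDataset,
    param_pairs: Sequence[tuple[float, float]] = ((2, 1), (1, 1), (2, 0.5), (3, 2)),
    kinds: Sequence[str] = KERNEL_KINDS,
) -> pd.DataFrame:
    """Test accuracy (%) of the tree per kernel family and (C, gamma) pair.

    Rows are kernel kinds, columns ``C=../g=..`` -- the layout of the
    kernel-comparison experiment.
    """
    cols = [f"C={C:g}/g={g:g}" for C, g in param_pairs]
    table = pd.DataFrame(index=list(kinds), columns=cols, dtype=float)
    for kind in kinds:
        for (C, gamma), col in zip(param_pairs, cols):
            model = train_tree(ds_train, (C, gamma), kind=kind)
            table.loc[kind, col] = 100.0 * tree_accuracy(model, ds_test)
    return table


# -- serialization: portable structured text -------------------------------

def _model_to_dict(m: SvmModel) -> dict:
    return {
        "support_vectors": m.support_vectors.tolist(),
        "alpha": m.alpha.tolist(),
        "Q": m.Q.tolist(),
        "bias": m.bias,
        "C": m.C,
        "n_train": m.n_train,
        "kernel": {"kind": m.kernel.kind, "gamma": m.kernel.gamma,
                   "degree": m.kernel.degree, "coef0": m.kernel.coef0},
    }


def _model_from_dict(d: dict) -> SvmModel:
    return SvmModel(
        support_vectors=np.asarray(d["support_vectors"], dtype=float),
        alpha=np.asarray(d["alpha"], dtype=float),
        Q=np.asarray(d["Q"], dtype=int),
        bias=float(d["bias"]),
        kernel=KernelSpec(**d["kernel"]),
        C=float(d["C"]),
        n_train=int(d.get("n_train", 0)),
    )


def tree_to_json(model: PhaseTreeModel, path=None) -> str:
    text = json.dumps({"nodes": [_model_to_dict(m) for m in model.nodes]}, indent=1)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def tree_from_json(source) -> PhaseTreeModel:
    """Load a tree from a JSON string or file path."""
    text = source
    if isinstance(source, str) and not source.lstrip().startswith("{"):
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    elif not isinstance(source, str):
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    d = json.loads(text)
    return PhaseTreeModel(nodes=[_model_from_dict(m) for m in d["nodes"]])
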