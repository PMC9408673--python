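"""Second-order gradient-boosted decision trees, implemented from scratch.

The model is an additive ensemble: after round t the margin of sample i is

    yhat_i^(t) = yhat_i^(t-1) + f_t(x_i)

where each regression tree f_t is grown on the second-order Taylor expansion
of the regularized objective

    Obj = sum_i l(y_i, yhat_i) + sum_t [ gamma * T_t + (lambda/2) * sum_j w_tj^2 ]

with per-sample gradient g_i and hessian h_i of the logistic loss at the
previous margin.  Collecting samples per leaf j gives the per-leaf quadratic
G_j w_j + (1/2)(H_j + lambda) w_j^2 + gamma, minimized by the closed-form
leaf weight w_j* = -G_j / (H_j + lambda); a split's structure-score gain is

    1/2 [ G_L^2/(H_L+lambda) + G_R^2/(H_R+lambda) - (G_L+G_R)^2/(H_L+H_R+lambda) ] - gamma

Split search is exact greedy over all features with thresholds at midpoints
of consecutive distinct values; ties route left; growth is depth-wise.
No subsampling, histograms, or multi-class — the learner is deliberately
the minimal faithful form of the objective above.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "TrainConfig",
    "TreeNode",
    "BoostedModel",
    "sigmoid",
    "logistic_grad_hess",
    "leaf_weight",
    "best_split",
    "train",
    "predict_margin",
    "predict",
    "classify",
    "save_model",
    "load_model",
]

FORMAT_VERSION = 1


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of the boosted ensemble.

    ``lambda_reg`` is the L2 penalty on leaf weights, ``gamma_reg`` the
    per-leaf complexity cost; ``base_score`` is the initial margin (None
    means the log-odds of the training base rate).  Defaults mirror common
    gradient-boosting practice: eta 0.3, depth 3, 50 rounds, lambda 1.
    """

    n_rounds: int = 50
    learning_rate: float = 0.3
    max_depth: int = 3
    lambda_reg: float = 1.0
    gamma_reg: float = 0.0
    min_child_hessian: float = 0.0
    base_score: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rounds < 0:
            raise ValueError("n_rounds must be >= 0")
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning_rate must be in (0,1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.lambda_reg < 0 or self.gamma_reg < 0 or self.min_child_hessian < 0:
            raise ValueError("regularization terms must be >= 0")


@dataclass
class TreeNode:
    """Either an internal split (feature, threshold, children) or a leaf.

    Leaf ``weight`` is the closed form -G/(H+lambda) over the samples routed
    to it at fit time, times the learning rate.
    """

    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    weight: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.weight is not None

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves() + self.right.n_leaves()

    def leaf_weights(self) -> list[float]:
        if self.is_leaf:
            return [self.weight]
        return self.left.leaf_weights() + self.right.leaf_weights()


@dataclass
class BoostedModel:
    trees: list[TreeNode]
    base_score: float
    config: TrainConfig
    importance: dict[int, float]
    n_features: int
    objective_trace: list[float] = field(default_factory=list)

    def feature_importance(self) -> dict[int, float]:
        """Total structure-score gain accumulated per feature index."""
        return dict(self.importance)


def logistic_grad_hess(labels, margins) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample first and second derivatives of the logistic loss.

    With p = sigmoid(margin): g = p - label, h = p(1-p).
    """
    p = sigmoid(margins)
    labels = np.asarray(labels, dtype=float)
    return p - labels, p * (1.0 - p)


def leaf_weight(G: float, H: float, lambda_reg: float) -> float:
    """Optimal leaf weight -G/(H+lambda) of the per-leaf quadratic."""
    if H + lambda_reg <= 0:
        raise ValueError("H + lambda must be > 0")
    return -G / (H + lambda_reg)


def _structure_score(G: float, H: float, lam: float) -> float:
    return G * G / (H + lam)


def best_split(
    X: np.ndarray,
    g: np.ndarray,
    h: np.ndarray,
    lambda_reg: float,
    gamma_reg: float,
    min_child_hessian: float = 0.0,
) -> tuple[int, float, float] | None:
    """Exact greedy search over all features and midpoint thresholds.

    Returns ``(feature, threshold, gain)`` for the best positive-gain split
    or None when no split improves the objective.  Samples with feature
    value <= threshold route left.
    """
    n, d = X.shape
    if n < 2:
        return None
    G, H = g.sum(), h.sum()
    parent = _structure_score(G, H, lambda_reg)
    best: tuple[int, float, float] | None = None
    for j in range(d):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        xs = col[order]
        # candidate boundaries between distinct consecutive values
        distinct = np.nonzero(np.diff(xs) > 0)[0]
        if distinct.size == 0:
            continue
        gl = np.cumsum(g[order])[distinct]
        hl = np.cumsum(h[order])[distinct]
        gr = G - gl
        hr = H - hl
        valid = (hl >= min_child_hessian) & (hr >= min_child_hessian)
        if not valid.any():
            continue
        gains = 0.5 * (
            _structure_score(gl, hl, lambda_reg)
            + _structure_score(gr, hr, lambda_reg)
            - parent
        ) - gamma_reg
        gains = np.where(valid, gains, -np.inf)
        k = int(np.argmax(gains))
        if gains[k] > 0 and (best is None or gains[k] > best[2]):
            thr = 0.5 * (xs[distinct[k]] + xs[distinct[k] + 1])
            best = (j, float(thr), float(gains[k]))
    return best


def _grow_tree(
    X: np.ndarray,
    g: np.ndarray,
    h: np.ndarray,
    config: TrainConfig,
    depth: int,
    importance: dict[int, float],
) -> TreeNode:
    split = None
    if depth < config.max_depth:
        split = best_split(
            X, g, h, config.lambda_reg, config.gamma_reg, config.min_child_hessian
        )
    if split is None:
        w = leaf_weight(g.sum(), h.sum(), config.lambda_reg)
        return TreeNode(weight=config.learning_rate * w)
    j, thr, gain = split
    importance[j] = importance.get(j, 0.0) + gain
    mask = X[:, j] <= thr
    left = _grow_tree(X[mask], g[mask], h[mask], config, depth + 1, importance)
    right = _grow_tree(X[~mask], g[~mask], h[~mask], config, depth + 1, importance)
    return TreeNode(feature=j, threshold=thr, left=left, right=right)


def _tree_predict(node: TreeNode, X: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape[0])
    stack = [(node, np.arange(X.shape[0]))]
    while stack:
        nd, idx = stack.pop()
        if nd.is_leaf:
            out[idx] = nd.weight
            continue
        mask = X[idx, nd.feature] <= nd.threshold
        stack.append((nd.left, idx[mask]))
        stack.append((nd.right, idx[~mask]))
    return out


def _objective(
    labels: np.ndarray,
    margins: np.ndarray,
    trees: Sequence[TreeNode],
    config: TrainConfig,
) -> float:
    """Regularized objective: logistic loss + gamma*T + (lambda/2) sum w^2."""
    p = np.clip(sigmoid(margins), 1e-15, 1 - 1e-15)
    loss = -(labels * np.log(p) + (1 - labels) * np.log(1 - p)).sum()
    reg = 0.0
    for t in trees:
        ws = np.asarray(t.leaf_weights())
        reg += config.gamma_reg * t.n_leaves() + 0.5 * config.lambda_reg * (ws**2).sum()
    return float(loss + reg)


def train(X, y, config: TrainConfig = TrainConfig()) -> BoostedModel:
    """Fit the boosted ensemble on a {0,1}-labelled feature matrix.

    Each round computes (g, h) at the current margin, grows one tree by
    exact greedy search, and adds its (learning-rate-scaled) leaf weights to
    the margins.  The regularized objective is recorded per round.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per label")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("labels must be 0/1")
    if classes.size < 2:
        raise ValueError("training requires both classes present")

    if config.base_score is None:
        rate = y.mean()
        base = math.log(rate / (1.0 - rate))
    else:
        base = float(config.base_score)

    margins = np.full(X.shape[0], base)
    trees: list[TreeNode] = []
    importance: dict[int, float] = {}
    trace = [_objective(y, margins, trees, config)]
    for _ in range(config.n_rounds):
        g, h = logistic_grad_hess(y, margins)
        tree = _grow_tree(X, g, h, config, 0, importance)
        trees.append(tree)
        margins = margins + _tree_predict(tree, X)
        trace.append(_objective(y, margins, trees, config))
    return BoostedModel(
        trees=trees,
        base_score=base,
        config=config,
        importance=importance,
        n_features=X.shape[1],
        objective_trace=trace,
    )


def predict_margin(model: BoostedModel, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1] if X.ndim == 2 else 'non-2D'}"
        )
    m = np.full(X.shape[0], model.base_score)
    for t in model.trees:
        m += _tree_predict(t, X)
    return m


def predict(model: BoostedModel, X) -> np.ndarray:
    """Probability of the positive class (false information) per row."""
    return sigmoid(predict_margin(model, X))


def classify(probabilities, threshold: float = 0.5) -> list[str]:
    """Map falsity probabilities to labels; ties at the threshold are false.

    ``threshold`` must lie strictly inside (0,1).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0,1)")
    probs = np.asarray(probabilities, dtype=float)
    return ["false_info" if p >= threshold else "true_info" for p in probs]


# ---------------------------------------------------------------------------
# persistence

def _node_to_json(n: TreeNode) -> dict:
    if n.is_leaf:
        return {"weight": n.weight}
    return {
        "feature": n.feature,
        "threshold": n.threshold,
        "left": _node_to_json(n.left),
        "right": _node_to_json(n.right),
    }


def _node_from_json(d: dict) -> TreeNode:
    if "weight" in d:
        return TreeNode(weight=d["weight"])
    return TreeNode(
        feature=d["feature"],
        threshold=d["threshold"],
        left=_node_from_json(d["left"]),
        right=_node_from_json(d["right"]),
    )


def save_model(model: BoostedModel, path: str | Path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "base_score": model.base_score,
        "n_features": model.n_features,
        "config": asdict(model.config),
        "importance": {str(k): v for k, v in model.importance.items()},
        "objective_trace": model.objective_trace,
        "trees": [_node_to_json(t) for t in model.trees],
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def load_model(path: str | Path) -> BoostedModel:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("format_version") != FORMAT_VERSION:
        raise ValueError("unsupported model format version")
    return BoostedModel(
        trees=[_node_from_json(t) for t in doc["trees"]],
        base_score=doc["base_score"],
        config=TrainConfig(**doc["config"]),
        importance={int(k): v for k, v in doc["importance"].items()},
        n_features=doc["n_features"],
        objective_trace=list(doc["objective_trace"]),
    )
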