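"""Regression models: GA-initialized backpropagation network, random
forest, and RBF support-vector regression.

The GA-BP network is the centerpiece and is implemented here in full: a
one-hidden-layer perceptron (sigmoid hidden units, linear output) whose
initial weights and biases are evolved by a genetic algorithm before
gradient refinement.  Plain backpropagation from a random start is
sensitive to its initialization; the GA's population search picks a good
basin first, and full-batch gradient descent then polishes the best
chromosome.

The forest and kernel regressors wrap scikit-learn estimators behind the
same fit/predict surface, parameterized with the study settings
(1000 trees / min leaf 3; RBF kernel with gamma 0.001, cost 1000).

Inputs to ``gabp_fit`` are expected pre-scaled to comparable magnitude
(the evaluation stage min-max scales features and target to [0, 1]);
weights live in a clipped box so the GA search space stays bounded.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.svm import SVR

__all__ = [
    "GABPConfig",
    "GABPModel",
    "gabp_fit",
    "gabp_predict",
    "ForestConfig",
    "KernelConfig",
    "forest_fit",
    "kernel_fit",
    "save_gabp",
    "load_gabp",
    "save_sklearn_model",
    "load_sklearn_model",
]


@dataclasses.dataclass(frozen=True)
class GABPConfig:
    """GA-BP settings.

    ``hidden_nodes`` (7), ``max_bp_iterations`` (1000), ``population_size``
    (40), ``error_threshold`` (1e-6) and ``max_generations`` (50) follow
    the study's parameter table.  GA operator rates, the weight box
    [-3, 3] and the backprop learning rate are package defaults, all
    exposed here.  ``max_generations=0`` degenerates to plain BP from a
    random initialization (useful as a baseline).
    """

    hidden_nodes: int = 7
    max_bp_iterations: int = 1000
    population_size: int = 40
    error_threshold: float = 1e-6
    max_generations: int = 50
    crossover_rate: float = 0.7
    mutation_rate: float = 0.05
    mutation_sd: float = 0.1
    learning_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_nodes < 1 or self.max_bp_iterations < 1:
            raise ValueError("hidden_nodes and max_bp_iterations must be positive")
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population_size must be a positive even number")
        if self.max_generations < 0:
            raise ValueError("max_generations must be >= 0")
        for name in ("crossover_rate", "mutation_rate"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.error_threshold <= 0 or self.mutation_sd <= 0 or self.learning_rate <= 0:
            raise ValueError("error_threshold, mutation_sd, learning_rate must be > 0")


@dataclasses.dataclass(eq=False)
class GABPModel:
    """Fitted one-hidden-layer network plus its training record."""

    W1: np.ndarray                       # (hidden, inputs)
    b1: np.ndarray                       # (hidden,)
    W2: np.ndarray                       # (1, hidden)
    b2: float
    ga_best_fitness_trace: np.ndarray    # best fitness per generation (non-decreasing)
    bp_final_mse: float
    converged: bool

    def predict(self, X: np.ndarray) -> np.ndarray:
        return gabp_predict(self, X)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _chromosome_length(n_inputs: int, hidden: int) -> int:
    return hidden * n_inputs + hidden + hidden + 1


def _decode(chrom: np.ndarray, n_inputs: int, hidden: int):
    h, d = hidden, n_inputs
    W1 = chrom[: h * d].reshape(h, d)
    b1 = chrom[h * d: h * d + h]
    W2 = chrom[h * d + h: h * d + 2 * h].reshape(1, h)
    b2 = float(chrom[-1])
    return W1, b1, W2, b2


def _forward(chrom: np.ndarray, X: np.ndarray, hidden: int) -> np.ndarray:
    W1, b1, W2, b2 = _decode(chrom, X.shape[1], hidden)
    a1 = _sigmoid(X @ W1.T + b1)
    return (a1 @ W2.T).ravel() + b2


def _mse(chrom: np.ndarray, X: np.ndarray, y: np.ndarray, hidden: int) -> float:
    e = _forward(chrom, X, hidden) - y
    return float(e @ e) / y.size


def _ga_search(X: np.ndarray, y: np.ndarray, cfg: GABPConfig,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Evolve chromosomes; return (best chromosome, best-fitness trace)."""
    n, d = X.shape
    L = _chromosome_length(d, cfg.hidden_nodes)
    pop = rng.uniform(-1.0, 1.0, size=(cfg.population_size, L))
    if cfg.max_generations == 0:
        return pop[0], np.array([])

    trace = np.empty(cfg.max_generations)
    best_chrom = None
    best_fit = -np.inf
    for gen in range(cfg.max_generations):
        mse = np.array([_mse(c, X, y, cfg.hidden_nodes) for c in pop])
        if not np.all(np.isfinite(mse)):
            raise FloatingPointError(f"non-finite GA loss at generation {gen}")
        fitness = 1.0 / (mse + 1e-12)
        gbest = int(np.argmax(fitness))
        if fitness[gbest] > best_fit:
            best_fit = float(fitness[gbest])
            best_chrom = pop[gbest].copy()
        trace[gen] = best_fit  # elitism makes this non-decreasing

        # fitness-proportional (roulette) parent selection
        p = fitness / fitness.sum()
        parents = pop[rng.choice(cfg.population_size, size=cfg.population_size, p=p)]
        children = parents.copy()
        for i in range(0, cfg.population_size - 1, 2):
            if rng.random() < cfg.crossover_rate:
                alpha = rng.random()
                a, b = parents[i], parents[i + 1]
                children[i] = alpha * a + (1 - alpha) * b
                children[i + 1] = alpha * b + (1 - alpha) * a
        mut = rng.random(children.shape) < cfg.mutation_rate
        children = children + mut * rng.normal(0.0, cfg.mutation_sd, children.shape)
        children = np.clip(children, -3.0, 3.0)
        children[0] = best_chrom  # elite carried unchanged
        pop = children
    return best_chrom, trace


def _bp_refine(chrom: np.ndarray, X: np.ndarray, y: np.ndarray,
               cfg: GABPConfig) -> tuple[np.ndarray, float, bool]:
    """Full-batch gradient descent on MSE with a monotone accepted step.

    A trial step that would increase the loss is rejected and the step
    size halved; successful steps grow the step size by 5% (capped).
    Descent is therefore monotone from the GA-best starting point.
    """
    h = cfg.hidden_nodes
    n, d = X.shape
    params = chrom.copy()
    lr = cfg.learning_rate
    mse = _mse(params, X, y, h)
    converged = mse <= cfg.error_threshold
    it = 0
    while it < cfg.max_bp_iterations and not converged:
        it += 1
        W1, b1, W2, b2 = _decode(params, d, h)
        z1 = X @ W1.T + b1
        a1 = _sigmoid(z1)
        pred = (a1 @ W2.T).ravel() + b2
        err = pred - y
        if not np.all(np.isfinite(err)):
            raise FloatingPointError(f"non-finite BP loss at iteration {it}")
        dpred = 2.0 * err / n                      # dMSE/dpred
        gW2 = dpred @ a1                           # (hidden,)
        gb2 = float(dpred.sum())
        da1 = np.outer(dpred, W2.ravel())          # (n, hidden)
        dz1 = da1 * a1 * (1.0 - a1)
        gW1 = dz1.T @ X                            # (hidden, d)
        gb1 = dz1.sum(axis=0)
        grad = np.concatenate([gW1.ravel(), gb1, gW2.ravel(), [gb2]])

        trial = params - lr * grad
        trial_mse = _mse(trial, X, y, h)
        if trial_mse <= mse:
            params, mse = trial, trial_mse
            lr = min(lr * 1.05, 1.0)
        else:
            lr *= 0.5
            if lr < 1e-12:
                break
        converged = mse <= cfg.error_threshold
    return params, mse, converged


def gabp_fit(X: np.ndarray, y: np.ndarray, cfg: GABPConfig = GABPConfig()) -> GABPModel:
    """Fit the GA-BP network on (pre-scaled) features and target.

    The chromosome is the flattened (W1, b1, W2, b2) — length
    ``hidden*(d + 2) + 1`` — initialized uniform on [-1, 1].  GA fitness
    is ``1 / (training MSE + 1e-12)`` with roulette selection, one elite
    carried unchanged, arithmetic crossover and per-gene Gaussian
    mutation, genes clipped to [-3, 3].  The best chromosome is then
    refined by full-batch gradient descent, stopping early once the MSE
    reaches ``error_threshold``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per target value")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")
    if X.shape[0] < cfg.hidden_nodes:
        raise ValueError("need at least as many samples as hidden nodes")

    rng = np.random.default_rng(cfg.seed)
    best, trace = _ga_search(X, y, cfg, rng)
    params, mse, converged = _bp_refine(best, X, y, cfg)
    W1, b1, W2, b2 = _decode(params, X.shape[1], cfg.hidden_nodes)
    return GABPModel(W1=W1, b1=b1, W2=W2, b2=b2,
                     ga_best_fitness_trace=trace,
                     bp_final_mse=mse, converged=converged)


def gabp_predict(model: GABPModel, X: np.ndarray) -> np.ndarray:
    """Deterministic forward pass ``W2 @ sigmoid(W1 x + b1) + b2`` per row."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.W1.shape[1]:
        raise ValueError(
            f"X must have {model.W1.shape[1]} columns, got {X.shape}")
    a1 = _sigmoid(X @ model.W1.T + model.b1)
    return (a1 @ model.W2.T).ravel() + model.b2


@dataclasses.dataclass(frozen=True)
class ForestConfig:
    """Random-forest settings (study values: 1000 trees, min leaf 3)."""

    n_trees: int = 1000
    min_leaf: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.min_leaf < 1:
            raise ValueError("n_trees and min_leaf must be positive")


@dataclasses.dataclass(frozen=True)
class KernelConfig:
    """RBF support-vector regression settings (study values: gamma 0.001,
    cost 1000); the epsilon tube width is a package default."""

    gamma: float = 0.001
    cost: float = 1000.0
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.cost <= 0 or self.epsilon < 0:
            raise ValueError("gamma and cost must be > 0, epsilon >= 0")


def forest_fit(X: np.ndarray, y: np.ndarray,
               cfg: ForestConfig = ForestConfig()) -> RandomForestRegressor:
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("empty design matrix")
    model = RandomForestRegressor(n_estimators=cfg.n_trees,
                                  min_samples_leaf=cfg.min_leaf,
                                  random_state=cfg.seed, n_jobs=1)
    return model.fit(X, np.asarray(y, dtype=float).ravel())


def kernel_fit(X: np.ndarray, y: np.ndarray,
               cfg: KernelConfig = KernelConfig()) -> SVR:
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("empty design matrix")
    model = SVR(kernel="rbf", gamma=cfg.gamma, C=cfg.cost, epsilon=cfg.epsilon)
    return model.fit(X, np.asarray(y, dtype=float).ravel())


def save_gabp(model: GABPModel, path: str | Path) -> Path:
    """Serialize GA-BP weights and training record as JSON."""
    path = Path(path)
    payload = {
        "format": "leafspec-gabp-v1",
        "W1": model.W1.tolist(),
        "b1": model.b1.tolist(),
        "W2": model.W2.tolist(),
        "b2": model.b2,
        "ga_best_fitness_trace": model.ga_best_fitness_trace.tolist(),
        "bp_final_mse": model.bp_final_mse,
        "converged": model.converged,
    }
    path.write_text(json.dumps(payload))
    return path


def load_gabp(path: str | Path) -> GABPModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "leafspec-gabp-v1":
        raise ValueError(f"{path}: not a leafspec GA-BP model file")
    return GABPModel(
        W1=np.array(payload["W1"]),
        b1=np.array(payload["b1"]),
        W2=np.array(payload["W2"]),
        b2=float(payload["b2"]),
        ga_best_fitness_trace=np.array(payload["ga_best_fitness_trace"]),
        bp_final_mse=float(payload["bp_final_mse"]),
        converged=bool(payload["converged"]),
    )


def save_sklearn_model(model, path: str | Path) -> Path:
    """Persist a fitted forest/kernel regressor (joblib blob)."""
    path = Path(path)
    joblib.dump({"format": "leafspec-sklearn-v1", "model": model}, path)
    return path


def load_sklearn_model(path: str | Path):
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != "leafspec-sklearn-v1":
        raise ValueError(f"{path}: not a leafspec model blob")
    return payload["model"]
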