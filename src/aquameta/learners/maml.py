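"""Model-agnostic meta-learning (first-order by default).

The meta-learner is generic over a :class:`MamlProblem` — anything exposing
an initial parameter vector and a loss/gradient — so its update rules can be
verified against closed forms on scalar toy problems.  The QSAR-facing
:class:`MamlLearner` instantiates it with the numpy MLP on chemical +
duration features, one task per species.
"""

from __future__ import annotations

import dataclasses
from typing import Protocol, Sequence

import numpy as np

from ..preprocess import MODE_SINGLE, ModelTable
from . import _mlp
from .base import Learner
from .nets import _Scaler

__all__ = ["MamlProblem", "MamlConfig", "MamlState", "MamlDivergence",
           "inner_adapt", "maml_fit", "MLPRegressionProblem", "MamlLearner"]


class MamlDivergence(RuntimeError):
    """Raised when any MAML loss becomes non-finite (known instability)."""


class MamlProblem(Protocol):
    def init_params(self, rng: np.random.Generator) -> np.ndarray: ...
    def loss_grad(self, theta: np.ndarray, X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]: ...
    def predict(self, theta: np.ndarray, X: np.ndarray) -> np.ndarray: ...


@dataclasses.dataclass(frozen=True)
class MamlConfig:
    inner_lr: float = 1e-2
    outer_lr: float = 1e-3
    inner_steps: int = 3
    task_batch: int = 8
    meta_iterations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inner_lr <= 0 or self.outer_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.inner_steps < 0:
            raise ValueError("inner step count must be >= 0")


@dataclasses.dataclass
class MamlState:
    """Learned initialization vector plus the schedule that produced it."""

    theta: np.ndarray
    config: MamlConfig


def _check_finite(loss: float) -> None:
    if not np.isfinite(loss):
        raise MamlDivergence(
            "MAML loss diverged to a non-finite value; lower the learning "
            "rates or the inner step count")


def inner_adapt(problem: MamlProblem, theta: np.ndarray, X: np.ndarray,
                y: np.ndarray, lr: float, steps: int) -> np.ndarray:
    """Plain gradient descent from theta on one task; steps=0 returns theta."""
    theta = np.array(theta, dtype=float, copy=True)
    for _ in range(steps):
        loss, grad = problem.loss_grad(theta, X, y)
        _check_finite(loss)
        theta = theta - lr * grad
    return theta


def maml_fit(problem: MamlProblem, tasks: Sequence[tuple[np.ndarray, np.ndarray]],
             config: MamlConfig) -> MamlState:
    """First-order MAML over a list of (X, y) tasks.

    Each meta-iteration samples a task batch, adapts the initialization with
    ``inner_steps`` gradient steps per task, and moves the initialization
    along the mean post-adaptation gradient.
    """
    if len(tasks) < 2:
        raise ValueError("MAML meta-training needs at least 2 tasks")
    rng = np.random.default_rng(config.seed)
    theta = np.asarray(problem.init_params(rng), dtype=float)
    n_tasks = len(tasks)
    for _ in range(config.meta_iterations):
        batch = rng.choice(n_tasks, size=min(config.task_batch, n_tasks), replace=False)
        outer_grad = np.zeros_like(theta)
        for t in batch:
            X, y = tasks[t]
            adapted = inner_adapt(problem, theta, X, y, config.inner_lr, config.inner_steps)
            loss, grad = problem.loss_grad(adapted, X, y)
            _check_finite(loss)
            # first-order approximation: gradient taken at the adapted point
            outer_grad += grad
        theta = theta - config.outer_lr * outer_grad / len(batch)
    return MamlState(theta=theta, config=config)


class MLPRegressionProblem:
    """Flat-vector view of the numpy MLP for the MAML loops."""

    def __init__(self, n_in: int, hidden: tuple[int, ...] = (64, 64)):
        self.sizes = [n_in, *hidden, 1]
        self.shapes: list[tuple] = []
        for a, b in zip(self.sizes[:-1], self.sizes[1:]):
            self.shapes.extend([(a, b), (b,)])

    def init_params(self, rng: np.random.Generator) -> np.ndarray:
        return _mlp.flatten(_mlp.init_params(self.sizes, rng))

    def loss_grad(self, theta, X, y):
        params = _mlp.unflatten(np.asarray(theta, dtype=float), self.shapes)
        loss, grads = _mlp.loss_grad(params, X, y.reshape(-1, 1))
        return loss, _mlp.flatten(grads)

    def predict(self, theta, X):
        params = _mlp.unflatten(np.asarray(theta, dtype=float), self.shapes)
        return _mlp.forward(params, X)[:, 0]


class MamlLearner(Learner):
    """MAML wrapped in the uniform learner contract.

    Fit = meta-train the initialization over per-species tasks, then adapt
    it to every training species.  Prediction for an unseen species uses the
    unadapted shared initialization.
    """

    family = "maml"
    table_mode = MODE_SINGLE

    def __init__(self, seed: int = 0, hidden: tuple[int, ...] = (64, 64),
                 **config_kwargs):
        super().__init__(seed)
        self.hidden = tuple(hidden)
        self.config = MamlConfig(seed=seed, **config_kwargs)

    def _task_arrays(self, table: ModelTable):
        X = self.x_scaler_.transform(table.feature_matrix())
        y = (table.y - self.y_mean_) / self.y_std_
        return X, y

    def _fit(self, table: ModelTable) -> None:
        self.x_scaler_ = _Scaler().fit(table.feature_matrix())
        self.y_mean_ = float(np.mean(table.y))
        self.y_std_ = float(np.std(table.y)) or 1.0
        X, y = self._task_arrays(table)
        tasks = []
        species = np.unique(table.species)
        for s in species:
            rows = table.species == s
            tasks.append((X[rows], y[rows]))
        self.problem_ = MLPRegressionProblem(X.shape[1], self.hidden)
        self.state_ = maml_fit(self.problem_, tasks, self.config)
        self.adapted_: dict = {
            s: inner_adapt(self.problem_, self.state_.theta, Xs, ys,
                           self.config.inner_lr, self.config.inner_steps)
            for s, (Xs, ys) in zip(species, tasks)
        }

    def adapt(self, table: ModelTable) -> "MamlLearner":
        """Run the inner loop on additional per-species data (post-fit)."""
        X, y = self._task_arrays(table)
        for s in np.unique(table.species):
            rows = table.species == s
            self.adapted_[s] = inner_adapt(self.problem_, self.state_.theta,
                                           X[rows], y[rows],
                                           self.config.inner_lr,
                                           self.config.inner_steps)
        return self

    def _predict(self, table: ModelTable) -> np.ndarray:
        X = self.x_scaler_.transform(table.feature_matrix())
        out = np.empty(len(table))
        for s in np.unique(table.species):
            rows = table.species == s
            theta = self.adapted_.get(s, self.state_.theta)
            out[rows] = self.problem_.predict(theta, X[rows])
        return out * self.y_std_ + self.y_mean_
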