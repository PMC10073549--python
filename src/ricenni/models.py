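"""Extreme Learning Machine regression and the Bald Eagle Search optimizer.

An ELM is a single-hidden-layer feed-forward network whose input-to-hidden
weights W and biases b are drawn once at random and never trained; only the
hidden-to-output weights β are solved, in closed form, as the minimum-norm
least-squares solution of H β = y with H = sigmoid(X W + b).

Because the random (W, b) draw decides the quality of the hidden basis, the
Bald Eagle Search (BES) metaheuristic is used to optimize it. BES evolves a
population of candidate positions through three phases per iteration —
*select* (contract toward the best solution), *search* (polar-spiral moves
around the population) and *swoop* (hyperbolic-spiral dives toward the best) —
with greedy acceptance, so the best fitness trace never increases. In the
hybrid BES-ELM, a position is a flattened (W, b), its fitness is the
validation-set RMSE of the ELM built from it (β solved on the training set),
and the returned model is the ELM rebuilt from the best position found.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ElmModel",
    "BesConfig",
    "elm_train",
    "elm_predict",
    "bes_optimize",
    "bes_elm_train",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass
class ElmModel:
    """ELM weights: random hidden layer (W, b) and solved output weights β."""

    w: np.ndarray       # (n_features, n_hidden)
    b: np.ndarray       # (n_hidden,)
    beta: np.ndarray    # (n_hidden,)

    @property
    def n_hidden(self) -> int:
        return self.w.shape[1]

    def to_json(self) -> str:
        return json.dumps({"w": self.w.tolist(), "b": self.b.tolist(),
                           "beta": self.beta.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "ElmModel":
        d = json.loads(text)
        return cls(np.array(d["w"]), np.array(d["b"]), np.array(d["beta"]))


@dataclass(frozen=True)
class BesConfig:
    """Bald Eagle Search hyperparameters.

    ``alpha`` controls the select-phase step toward the population mean,
    ``spiral_a`` / ``spiral_r`` shape the search-phase polar spiral, and
    ``c1`` / ``c2`` (in [1, 2]) set the swoop intensity toward the mean and
    best positions.
    """

    population: int = 30
    iterations: int = 50
    alpha: float = 2.0
    spiral_a: float = 10.0
    spiral_r: float = 1.5
    c1: float = 2.0
    c2: float = 2.0
    lower: float = -1.0
    upper: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.lower >= self.upper:
            raise ValueError("lower bound must be below upper bound")


def elm_train(X: np.ndarray, y: np.ndarray, n_hidden: int = 20,
              seed: int | None = 0,
              weights: tuple[np.ndarray, np.ndarray] | None = None) -> ElmModel:
    """Train an ELM: random (or supplied) hidden layer, pseudo-inverse output solve.

    W and b are drawn uniformly on [−1, 1] from ``seed`` unless ``weights``
    supplies them; β is the SVD-based minimum-norm least-squares solution of
    sigmoid(X W + b) β = y.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty 2-D matrix")
    if X.shape[0] != y.shape[0] or X.shape[0] < 2:
        raise ValueError("need >= 2 samples with matching target length")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    if weights is not None:
        w, b = (np.asarray(weights[0], float), np.asarray(weights[1], float))
        if w.shape != (X.shape[1], w.shape[1]) or b.shape != (w.shape[1],):
            raise ValueError("supplied (W, b) shapes inconsistent with X")
    else:
        rng = np.random.default_rng(seed)
        w = rng.uniform(-1.0, 1.0, size=(X.shape[1], n_hidden))
        b = rng.uniform(-1.0, 1.0, size=n_hidden)
    h = _sigmoid(X @ w + b)
    beta, *_ = np.linalg.lstsq(h, y, rcond=None)
    return ElmModel(w=w, b=b, beta=beta)


def elm_predict(model: ElmModel, X: np.ndarray) -> np.ndarray:
    """Forward pass: sigmoid(X W + b) β."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.w.shape[0]:
        raise ValueError(
            f"X has {X.shape[1]} features, model expects {model.w.shape[0]}")
    return _sigmoid(X @ model.w + model.b) @ model.beta


def bes_optimize(fitness, dim: int, cfg: BesConfig,
                 init_positions: np.ndarray | None = None):
    """Minimize ``fitness`` over a box with the three-phase Bald Eagle Search.

    Per iteration each member passes through the select, search and swoop
    moves; a move is accepted only if it improves that member's fitness
    (greedy), positions are clipped to [lower, upper] after every move, and
    the incumbent best is updated after each phase. Fully seeded.

    ``init_positions`` optionally fixes the first rows of the initial
    population (e.g. a warm start); remaining members are drawn uniformly.

    Returns ``(best_position, best_fitness, trace)`` where ``trace`` holds the
    best fitness after initialization and after every iteration (length
    ``iterations + 1``, non-increasing).
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.lower, cfg.upper
    npop = cfg.population
    pos = rng.uniform(lo, hi, size=(npop, dim))
    if init_positions is not None:
        init_positions = np.atleast_2d(np.asarray(init_positions, float))
        m = min(len(init_positions), npop)
        pos[:m] = np.clip(init_positions[:m], lo, hi)

    def evaluate(p: np.ndarray) -> float:
        f = float(fitness(p))
        if not np.isfinite(f):
            raise RuntimeError(
                f"fitness returned non-finite value {f!r} at position {p[:5]}...")
        return f

    fit = np.array([evaluate(p) for p in pos])
    best_idx = int(np.argmin(fit))
    best_pos, best_fit = pos[best_idx].copy(), float(fit[best_idx])
    trace = [best_fit]

    def greedy_update(new_pos: np.ndarray) -> None:
        nonlocal best_pos, best_fit
        new_pos = np.clip(new_pos, lo, hi)
        for i in range(npop):
            f_new = evaluate(new_pos[i])
            if f_new < fit[i]:
                pos[i], fit[i] = new_pos[i], f_new
                if f_new < best_fit:
                    best_pos, best_fit = new_pos[i].copy(), f_new

    for _ in range(cfg.iterations):
        # --- select: contract toward the mean around the incumbent best
        mean = pos.mean(axis=0)
        r = rng.uniform(0.0, 1.0, size=(npop, 1))
        greedy_update(best_pos + cfg.alpha * r * (mean - pos))

        # --- search: polar-spiral exploration around neighbours and the mean
        mean = pos.mean(axis=0)
        theta = cfg.spiral_a * np.pi * rng.uniform(0.0, 1.0, size=npop)
        rad = theta + cfg.spiral_r * rng.uniform(0.0, 1.0, size=npop)
        xr, yr = rad * np.sin(theta), rad * np.cos(theta)
        x = (xr / np.max(np.abs(xr)))[:, None]
        y = (yr / np.max(np.abs(yr)))[:, None]
        neighbour = np.roll(pos, -1, axis=0)
        greedy_update(pos + y * (pos - neighbour) + x * (pos - mean))

        # --- swoop: hyperbolic-spiral dive toward the best position
        mean = pos.mean(axis=0)
        theta = cfg.spiral_a * np.pi * rng.uniform(0.0, 1.0, size=npop)
        xr, yr = theta * np.sinh(theta), theta * np.cosh(theta)
        x1 = (xr / np.max(np.abs(xr)))[:, None]
        y1 = (yr / np.max(np.abs(yr)))[:, None]
        rand = rng.uniform(0.0, 1.0, size=(npop, 1))
        greedy_update(rand * best_pos + x1 * (pos - cfg.c1 * mean)
                      + y1 * (pos - cfg.c2 * best_pos))

        trace.append(best_fit)

    return best_pos, best_fit, np.asarray(trace)


def _unflatten(position: np.ndarray, n_features: int, n_hidden: int):
    w = position[: n_features * n_hidden].reshape(n_features, n_hidden)
    b = position[n_features * n_hidden:]
    return w, b


def bes_elm_train(X_train: np.ndarray, y_train: np.ndarray,
                  X_val: np.ndarray, y_val: np.ndarray,
                  n_hidden: int = 20, cfg: BesConfig = BesConfig(),
                  include_baseline: bool = True):
    """BES-optimized ELM: hidden weights searched by validation-set RMSE.

    The search space is the flattened (W, b) of the hidden layer, bounded to
    [−1, 1]; a position's fitness is the RMSE on the validation set of the ELM
    whose β is solved on the training set. With ``include_baseline`` the
    initial population contains the plain seeded ELM's (W, b) as a founder, so
    greedy acceptance guarantees the returned model's validation RMSE never
    exceeds that baseline's.

    Returns ``(model, best_fitness, trace)``.
    """
    X_train = np.asarray(X_train, float)
    X_val = np.asarray(X_val, float)
    y_val = np.asarray(y_val, float)
    if X_val.shape[0] == 0:
        raise ValueError("validation set is empty")
    n_features = X_train.shape[1]
    dim = n_features * n_hidden + n_hidden

    def fitness(position: np.ndarray) -> float:
        w, b = _unflatten(position, n_features, n_hidden)
        model = elm_train(X_train, y_train, n_hidden=n_hidden, weights=(w, b))
        resid = y_val - elm_predict(model, X_val)
        return float(np.sqrt(np.mean(resid**2)))

    init = None
    if include_baseline:
        baseline = elm_train(X_train, y_train, n_hidden=n_hidden, seed=cfg.seed)
        init = np.concatenate([baseline.w.ravel(), baseline.b])[None, :]

    best_pos, best_fit, trace = bes_optimize(fitness, dim, cfg, init_positions=init)
    w, b = _unflatten(best_pos, n_features, n_hidden)
    model = elm_train(X_train, y_train, n_hidden=n_hidden, weights=(w, b))
    return model, best_fit, trace
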