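"""Sparse-autoencoder feature extraction and MLR-based configuration selection.

A single-hidden-layer autoencoder with sigmoid activations on both encoder and
decoder compresses each (min–max scaled) spectrum into ``n_features`` hidden
activations. Training minimizes the classical sparse-autoencoder objective

    L = 1/(2n) Σ_i ‖x_i − x̂_i‖²  +  λ/2 · Σ w²  +  β · Σ_j KL(ρ ‖ ρ̂_j),

where ρ̂_j is hidden unit j's mean activation over the batch, ρ the sparsity
target (default 0.1), λ the weight decay (default 0.001) and β the sparsity
penalty weight (default 3) — the parameterization those defaults belong to
(the reconstruction error is summed over bands, so the three terms are
commensurate on spectra with hundreds of bands). The
optimizer is deterministic full-batch gradient descent with a fixed learning
rate and seeded initialization.

Because the autoencoder is unsupervised, competing feature widths are ranked
by the held-out RMSE of a multiple linear regression of NNI on the encoded
features; the width with the smallest validation RMSE wins (ties go to the
narrower encoder).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AeConfig",
    "AeModel",
    "FeatureMatrix",
    "MlrModel",
    "MinMaxScaler",
    "train_sparse_autoencoder",
    "encode",
    "mlr_fit",
    "mlr_predict",
    "select_feature_config",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass(frozen=True)
class AeConfig:
    """Sparse-autoencoder hyperparameters.

    ``sparsity_target`` (ρ), ``weight_decay`` (λ) and ``sparsity_weight`` (β)
    default to the triple (0.1, 0.001, 3).
    """

    n_features: int = 30
    sparsity_target: float = 0.1
    weight_decay: float = 0.001
    sparsity_weight: float = 3.0
    epochs: int = 5000
    learning_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if not 0.0 < self.sparsity_target < 1.0:
            raise ValueError("sparsity_target must lie in (0, 1)")
        if self.weight_decay < 0 or self.sparsity_weight < 0:
            raise ValueError("penalty weights must be non-negative")
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("epochs >= 1 and learning_rate > 0 required")


@dataclass
class AeModel:
    """Trained autoencoder: encoder/decoder weights and the loss trace."""

    w_enc: np.ndarray   # (bands, n_features)
    b_enc: np.ndarray   # (n_features,)
    w_dec: np.ndarray   # (n_features, bands)
    b_dec: np.ndarray   # (bands,)
    config: AeConfig
    loss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_features(self) -> int:
        return self.w_enc.shape[1]


@dataclass
class FeatureMatrix:
    """Encoded features, (samples × n_features), each value in (0, 1)."""

    values: np.ndarray
    sample_ids: list
    source_kind: str = ""


@dataclass
class MlrModel:
    """Ordinary least-squares regression of a target on encoded features."""

    coefficients: np.ndarray   # (n_features,)
    intercept: float
    r2: float
    rmse: float


@dataclass
class MinMaxScaler:
    """Per-band min–max scaling to [0, 1], fitted on training rows only.

    Constant bands map to 0 (unit denominator guard) instead of dividing by
    zero; transformed test rows may fall slightly outside [0, 1] and are left
    untouched.
    """

    mins: np.ndarray = None
    ranges: np.ndarray = None

    def fit(self, X: np.ndarray) -> "MinMaxScaler":
        X = np.asarray(X, float)
        self.mins = X.min(axis=0)
        rng = X.max(axis=0) - self.mins
        self.ranges = np.where(rng > 0, rng, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mins) / self.ranges


def train_sparse_autoencoder(X: np.ndarray, cfg: AeConfig) -> AeModel:
    """Train the sparse autoencoder on rows of ``X`` (expected scaled to ~[0, 1]).

    Full-batch gradient descent; the recorded loss trace is sampled every 50
    epochs plus the final epoch. Same ``X`` and config (including seed) give
    bit-identical weights.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    n, d = X.shape
    k = cfg.n_features
    if k >= d:
        logger.warning("n_features (%d) >= band count (%d): no compression", k, d)

    rng = np.random.default_rng(cfg.seed)
    lim_e = np.sqrt(6.0 / (d + k))
    lim_d = np.sqrt(6.0 / (k + d))
    w_enc = rng.uniform(-lim_e, lim_e, size=(d, k))
    w_dec = rng.uniform(-lim_d, lim_d, size=(k, d))
    b_enc = np.zeros(k)
    b_dec = np.zeros(d)

    rho, lam, beta, lr = (cfg.sparsity_target, cfg.weight_decay,
                          cfg.sparsity_weight, cfg.learning_rate)
    trace = []
    for epoch in range(cfg.epochs):
        h = _sigmoid(X @ w_enc + b_enc)              # (n, k)
        xhat = _sigmoid(h @ w_dec + b_dec)           # (n, d)
        err = xhat - X
        rho_hat = np.clip(h.mean(axis=0), 1e-8, 1 - 1e-8)

        if epoch % 50 == 0 or epoch == cfg.epochs - 1:
            recon = 0.5 * float(np.sum(err**2)) / n
            kl = float(np.sum(rho * np.log(rho / rho_hat)
                              + (1 - rho) * np.log((1 - rho) / (1 - rho_hat))))
            l2 = 0.5 * float(np.sum(w_enc**2) + np.sum(w_dec**2))
            trace.append(recon + lam * l2 + beta * kl)

        delta_out = (err / n) * xhat * (1 - xhat)                  # (n, d)
        g_wdec = h.T @ delta_out + lam * w_dec
        g_bdec = delta_out.sum(axis=0)
        back = delta_out @ w_dec.T                                  # (n, k)
        kl_grad = beta * (-(rho / rho_hat) + (1 - rho) / (1 - rho_hat)) / n
        delta_hid = (back + kl_grad) * h * (1 - h)
        g_wenc = X.T @ delta_hid + lam * w_enc
        g_benc = delta_hid.sum(axis=0)

        w_enc -= lr * g_wenc
        b_enc -= lr * g_benc
        w_dec -= lr * g_wdec
        b_dec -= lr * g_bdec

    return AeModel(w_enc, b_enc, w_dec, b_dec, cfg, np.asarray(trace))


def encode(model: AeModel, X: np.ndarray, sample_ids: list | None = None,
           source_kind: str = "") -> FeatureMatrix:
    """Hidden-layer activations of ``X`` under the trained encoder."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.w_enc.shape[0]:
        raise ValueError(
            f"X has {X.shape[1]} bands, encoder expects {model.w_enc.shape[0]}")
    h = _sigmoid(X @ model.w_enc + model.b_enc)
    if sample_ids is None:
        sample_ids = list(range(X.shape[0]))
    return FeatureMatrix(values=h, sample_ids=list(sample_ids),
                         source_kind=source_kind)


def reconstruct(model: AeModel, X: np.ndarray) -> np.ndarray:
    """Decoder output (reconstruction) for inputs ``X``."""
    h = encode(model, X).values
    return _sigmoid(h @ model.w_dec + model.b_dec)


def mlr_fit(features: FeatureMatrix | np.ndarray, y: np.ndarray) -> MlrModel:
    """Multiple linear regression (OLS with intercept) of ``y`` on the features.

    Requires more rows than coefficients. Exactly collinear feature columns
    fall back to the minimum-norm least-squares solution with a warning.
    """
    F = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    y = np.asarray(y, dtype=float)
    n, k = F.shape
    if len(y) != n:
        raise ValueError("feature rows and target length differ")
    if n <= k + 1:
        raise ValueError(f"underdetermined: {n} rows for {k} features + intercept")
    A = np.column_stack([np.ones(n), F])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        logger.warning("collinear features (rank %d < %d): minimum-norm solution",
                       rank, A.shape[1])
    yhat = A @ coef
    resid = y - yhat
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sstot if sstot > 0 else 0.0
    rmse = float(np.sqrt(np.mean(resid**2)))
    return MlrModel(coefficients=coef[1:], intercept=float(coef[0]),
                    r2=r2, rmse=rmse)


def mlr_predict(model: MlrModel, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    F = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    return model.intercept + F @ model.coefficients


def select_feature_config(candidates: list, X_train: np.ndarray,
                          y_train: np.ndarray, X_test: np.ndarray,
                          y_test: np.ndarray):
    """Choose the feature width with the smallest held-out MLR RMSE.

    ``candidates`` is a list of ``(AeConfig, AeModel)`` pairs (models trained
    on the training rows). For each candidate the training rows are encoded,
    an MLR of NNI on the features is fitted, and its RMSE on the encoded test
    rows ranks the candidate; ties break toward fewer features.

    Returns ``(config, model, mlr, report)`` where ``report`` is a list of
    per-candidate dicts (n_features, train/test r2 and rmse).
    """
    if not candidates:
        raise ValueError("no candidates supplied")
    report = []
    best = None
    for cfg, model in candidates:
        f_tr = encode(model, X_train)
        f_te = encode(model, X_test)
        mlr = mlr_fit(f_tr, y_train)
        pred = mlr_predict(mlr, f_te)
        resid = y_test - pred
        rmse_test = float(np.sqrt(np.mean(resid**2)))
        sstot = float(np.sum((y_test - np.mean(y_test)) ** 2))
        r2_test = 1.0 - float(np.sum(resid**2)) / sstot if sstot > 0 else 0.0
        report.append({"n_features": cfg.n_features, "r2_train": mlr.r2,
                       "rmse_train": mlr.rmse, "r2_test": r2_test,
                       "rmse_test": rmse_test})
        key = (rmse_test, cfg.n_features)
        if best is None or key < best[0]:
            best = (key, cfg, model, mlr)
    return best[1], best[2], best[3], report
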