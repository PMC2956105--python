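"""Bayesian-regularized two-layer neural network with PCA preprocessing.

The network (tanh hidden layer, linear output) is trained by
Levenberg-Marquardt on the regularized objective

    F(w) = beta * E_D + alpha * E_W,
    E_D  = 1/2 sum(residual^2),   E_W = 1/2 sum(w^2),

where alpha (weight-decay precision) and beta (noise precision) are
re-estimated within the evidence framework after every accepted LM cycle
using the Gauss-Newton Hessian H = beta J'J + alpha I:

    gamma = N_w - alpha * tr(H^-1)      (effective number of parameters)
    alpha = gamma / (2 E_W)
    beta  = (n - gamma) / (2 E_D)

Training stops when the log evidence stops increasing (or at max_epochs).
Inputs are mapped to [-1, 1] and the response is standardized internally;
``noise_precision`` reports beta back on the raw response scale.  Because a
single training is sensitive to its random start, predictions are averaged
over independently seeded repeats (50 by default).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import NumericError, UsageError

__all__ = [
    "BRNNConfig",
    "BRNNModel",
    "PCABasis",
    "pca_reduce",
    "init_nguyen_widrow",
    "train_brnn",
    "repeat_average_predict",
    "derive_seeds",
]


# ------------------------------------------------------------------ PCA front
@dataclass
class PCABasis:
    components: np.ndarray  # (k, p) orthonormal rows
    mean: np.ndarray
    explained_variance: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.components.T


def pca_reduce(X: np.ndarray, n_pcs: int) -> tuple[np.ndarray, PCABasis]:
    """Scores on the top-variance principal components of (autoscaled) X.

    Deterministic sign convention: each component's largest-magnitude
    element is positive.  ``n_pcs`` beyond rank(X) is truncated with a
    warning.
    """
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if n_pcs > rank:
        warnings.warn(f"n_pcs truncated from {n_pcs} to rank(X) = {rank}", stacklevel=2)
        n_pcs = rank
    if n_pcs < 1:
        raise UsageError("need at least one principal component")
    comp = Vt[:n_pcs]
    for i in range(n_pcs):
        j = int(np.argmax(np.abs(comp[i])))
        if comp[i, j] < 0:
            comp[i] = -comp[i]
            U[:, i] = -U[:, i]
    scores = U[:, :n_pcs] * s[:n_pcs]
    expl = s[:n_pcs] ** 2 / max(X.shape[0] - 1, 1)
    return scores, PCABasis(components=comp, mean=mean, explained_variance=expl)


# ------------------------------------------------------------- configuration
@dataclass
class BRNNConfig:
    """Architecture and training settings.

    Defaults follow the study: 5 hidden units and 50 averaged repeats; the
    input-PC count is endpoint-specific (5 for the alpha set, 11 for beta,
    14 for selectivity).
    """

    n_pcs: int = 5
    n_hidden: int = 5
    repeats: int = 50
    max_epochs: int = 200
    seed: int = 0

    def __post_init__(self):
        if min(self.n_pcs, self.n_hidden, self.repeats, self.max_epochs) < 1:
            raise UsageError("all BRNN configuration counts must be positive")


def init_nguyen_widrow(n_inputs: int, n_hidden: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Nguyen-Widrow initialization for a tanh hidden layer on [-1, 1] inputs.

    Each hidden unit's input-weight vector is rescaled to magnitude
    0.7 * H^(1/I); the biases are spread uniformly across the input range.
    """
    if n_inputs < 1 or n_hidden < 1:
        raise UsageError("layer sizes must be positive")
    rng = np.random.default_rng(seed)
    magnitude = 0.7 * n_hidden ** (1.0 / n_inputs)
    W = rng.uniform(-1.0, 1.0, size=(n_hidden, n_inputs))
    norms = np.linalg.norm(W, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    W = magnitude * W / norms
    if n_hidden == 1:
        b = np.array([0.0])
    else:
        b = magnitude * np.linspace(-1.0, 1.0, n_hidden)
    return W, b


# -------------------------------------------------------------------- model
@dataclass
class BRNNModel:
    n_inputs: int
    n_hidden: int
    weights: np.ndarray  # flat: [W1 (H*I), b1 (H), w2 (H), b2 (1)]
    alpha: float
    beta: float
    gamma: float
    x_mid: np.ndarray
    x_half: np.ndarray
    y_mean: float
    y_std: float
    activation: str = "tanh"
    trace: list[dict] = field(default_factory=list)

    @property
    def n_weights(self) -> int:
        return len(self.weights)

    @property
    def noise_precision(self) -> float:
        """beta expressed on the raw response scale (1/variance units)."""
        return self.beta / self.y_std**2

    def _unpack(self, w: np.ndarray):
        H, I = self.n_hidden, self.n_inputs
        W1 = w[: H * I].reshape(H, I)
        b1 = w[H * I : H * I + H]
        w2 = w[H * I + H : H * I + 2 * H]
        b2 = w[-1]
        return W1, b1, w2, b2

    def _forward_scaled(self, Xs: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        W1, b1, w2, b2 = self._unpack(w)
        a = Xs @ W1.T + b1
        z = np.tanh(a) if self.activation == "tanh" else a
        return z @ w2 + b2, z

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.x_mid) / self.x_half
        ys, _ = self._forward_scaled(Xs, self.weights)
        return ys * self.y_std + self.y_mean


def _jacobian(model: BRNNModel, Xs: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Jacobian of the scaled network output w.r.t. the flat weight vector."""
    H, I = model.n_hidden, model.n_inputs
    W1, b1, w2, b2 = model._unpack(w)
    a = Xs @ W1.T + b1
    if model.activation == "tanh":
        z = np.tanh(a)
        dz = 1.0 - z**2
    else:
        z = a
        dz = np.ones_like(a)
    n = Xs.shape[0]
    J = np.empty((n, len(w)))
    # dW1: w2_h * dz_h * x_i
    J[:, : H * I] = ((w2 * dz)[:, :, None] * Xs[:, None, :]).reshape(n, H * I)
    J[:, H * I : H * I + H] = w2 * dz
    J[:, H * I + H : H * I + 2 * H] = z
    J[:, -1] = 1.0
    yhat = z @ w2 + b2
    return J, yhat


def train_brnn(
    X: np.ndarray,
    y: np.ndarray,
    n_hidden: int = 5,
    seed: int = 0,
    max_epochs: int = 200,
    activation: str = "tanh",
    alpha0: float = 0.01,
    beta0: float = 1.0,
    fixed_alpha: float | None = None,
    fixed_beta: float | None = None,
    patience: int = 8,
) -> BRNNModel:
    """Train one Bayesian-regularized network by Levenberg-Marquardt.

    ``fixed_alpha`` / ``fixed_beta`` pin the corresponding hyperparameter
    (disabling its evidence re-estimation); with ``fixed_alpha=0`` and
    ``activation='identity'`` the network converges to the least-squares
    solution, a useful degenerate check.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 4:
        raise UsageError("need at least 4 training samples")
    if np.isnan(X).any() or np.isnan(y).any():
        raise UsageError("NaN in training data")

    x_min, x_max = X.min(axis=0), X.max(axis=0)
    x_mid = (x_max + x_min) / 2.0
    x_half = np.where(x_max > x_min, (x_max - x_min) / 2.0, 1.0)
    y_mean, y_std = float(y.mean()), float(y.std()) or 1.0
    Xs = (X - x_mid) / x_half
    ys = (y - y_mean) / y_std

    I = X.shape[1]
    W1, b1 = init_nguyen_widrow(I, n_hidden, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    w2 = rng.uniform(-0.5, 0.5, size=n_hidden) / math.sqrt(n_hidden)
    b2 = np.array([0.0])
    w = np.concatenate([W1.ravel(), b1, w2, b2])
    N_w = len(w)

    model = BRNNModel(
        n_inputs=I,
        n_hidden=n_hidden,
        weights=w,
        alpha=float(fixed_alpha) if fixed_alpha is not None else alpha0,
        beta=float(fixed_beta) if fixed_beta is not None else beta0,
        gamma=float(N_w),
        x_mid=x_mid,
        x_half=x_half,
        y_mean=y_mean,
        y_std=y_std,
        activation=activation,
    )

    alpha, beta = model.alpha, model.beta
    mu = 1e-3
    best_evidence = -np.inf
    stall = 0

    def objective(wv: np.ndarray) -> tuple[float, float, float]:
        yhat, _ = model._forward_scaled(Xs, wv)
        e_d = 0.5 * float(((yhat - ys) ** 2).sum())
        e_w = 0.5 * float(wv @ wv)
        return beta * e_d + alpha * e_w, e_d, e_w

    F, E_D, E_W = objective(w)
    for epoch in range(max_epochs):
        J, yhat = _jacobian(model, Xs, w)
        r = yhat - ys
        grad = beta * (J.T @ r) + alpha * w
        if np.linalg.norm(grad) < 1e-10:
            break
        Hgn = beta * (J.T @ J) + alpha * np.eye(N_w)
        accepted = False
        for _ in range(30):
            try:
                step = np.linalg.solve(Hgn + mu * np.eye(N_w), -grad)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            w_new = w + step
            F_new, e_d_new, e_w_new = objective(w_new)
            if np.isfinite(F_new) and F_new < F:
                w, F, E_D, E_W = w_new, F_new, e_d_new, e_w_new
                mu = max(mu / 10.0, 1e-12)
                accepted = True
                break
            mu *= 10.0
        if not accepted and mu > 1e12:
            break  # no further descent possible

        # evidence-framework re-estimation on the Gauss-Newton Hessian
        J, yhat = _jacobian(model, Xs, w)
        Hgn = beta * (J.T @ J) + alpha * np.eye(N_w)
        try:
            H_inv_tr = float(np.trace(np.linalg.inv(Hgn)))
        except np.linalg.LinAlgError:
            H_inv_tr = float(np.trace(np.linalg.pinv(Hgn)))
        gamma = N_w - alpha * H_inv_tr
        gamma = min(max(gamma, 0.0), float(N_w))
        if fixed_alpha is None:
            alpha = min(max(gamma / (2.0 * max(E_W, 1e-12)), 1e-8), 1e8)
        if fixed_beta is None:
            beta = min(max((n - gamma) / (2.0 * max(E_D, 1e-12)), 1e-8), 1e8)
        F, E_D, E_W = objective(w)

        sign, logdet = np.linalg.slogdet(beta * (J.T @ J) + alpha * np.eye(N_w))
        if sign <= 0:
            logdet = float("inf")
        evidence = (
            -alpha * E_W
            - beta * E_D
            - 0.5 * logdet
            + 0.5 * N_w * math.log(max(alpha, 1e-300))
            + 0.5 * n * math.log(max(beta, 1e-300))
        )
        model.trace.append(
            {
                "epoch": epoch,
                "F": F,
                "E_D": E_D,
                "E_W": E_W,
                "alpha": alpha,
                "beta": beta,
                "gamma": gamma,
                "evidence": evidence,
            }
        )
        model.weights, model.alpha, model.beta, model.gamma = w, alpha, beta, gamma
        if fixed_alpha is None or fixed_beta is None:
            if evidence > best_evidence + 1e-9:
                best_evidence = evidence
                stall = 0
            else:
                stall += 1
                if stall >= patience:
                    break
        if not accepted:
            break

    if not np.all(np.isfinite(w)):
        raise NumericError("training diverged (non-finite weights); see model.trace")
    model.weights, model.alpha, model.beta = w, alpha, beta
    return model


def derive_seeds(master_seed: int, count: int) -> list[int]:
    """Derive independent per-repeat seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(count)]


def repeat_average_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_eval: np.ndarray,
    config: BRNNConfig,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Average the predictions of independently initialized networks.

    Trains ``config.repeats`` networks with seeds derived from the master
    seed, averages their predictions on ``X_eval`` and reports the per-point
    standard deviation across repeats.  Individual failures are excluded; at
    least 80% of the repeats must succeed.
    """
    seeds = derive_seeds(config.seed, config.repeats)
    preds = []
    for s in seeds:
        try:
            m = train_brnn(
                X_train,
                y_train,
                n_hidden=config.n_hidden,
                seed=s,
                max_epochs=config.max_epochs,
            )
            preds.append(m.predict(X_eval))
        except Exception:  # noqa: BLE001 - single-repeat isolation
            continue
    if len(preds) < math.ceil(0.8 * config.repeats):
        raise NumericError(
            f"only {len(preds)}/{config.repeats} repeats trained successfully"
        )
    P = np.vstack(preds)
    return P.mean(axis=0), P.std(axis=0), len(preds)
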