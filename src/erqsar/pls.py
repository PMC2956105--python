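"""NIPALS partial-least-squares regression with VIP scores.

PLS projects the autoscaled descriptor matrix onto a few latent factors
chosen to covary maximally with the response — the workhorse for QSAR
tables where descriptors outnumber compounds and are heavily collinear.
This module implements the classical NIPALS algorithm with deflation,
per-factor explained-variance bookkeeping, latent-factor selection against
an external test split, variable importance in projection (VIP), and an
applicability-domain outlier flagger.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, NumericError, UsageError
from .metrics import compute_fit_report, loo_q2
from .som import DataSplit

__all__ = [
    "Scaler",
    "autoscale",
    "PLSModel",
    "fit_pls",
    "select_factors",
    "vip_scores",
    "flag_outliers",
]


@dataclass
class Scaler:
    """Column-wise autoscaling x -> (x - mean) / std, with n-1 std."""

    mean: np.ndarray
    std: np.ndarray

    def transform(self, A: np.ndarray) -> np.ndarray:
        return (np.asarray(A, dtype=float) - self.mean) / self.std

    def inverse(self, A: np.ndarray) -> np.ndarray:
        return np.asarray(A, dtype=float) * self.std + self.mean


def autoscale(A: np.ndarray) -> tuple[np.ndarray, Scaler]:
    """Center to mean 0 and scale to unit (n-1) standard deviation."""
    A = np.asarray(A, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    mean = A.mean(axis=0)
    std = A.std(axis=0, ddof=1)
    bad = np.flatnonzero(std == 0)
    if bad.size:
        raise DomainError(f"constant column(s) at index {bad.tolist()}; prune before scaling")
    return (A - mean) / std, Scaler(mean=mean, std=std)


@dataclass
class PLSModel:
    n_factors: int
    W: np.ndarray  # x weights (p, a), unit columns
    P: np.ndarray  # x loadings (p, a)
    T: np.ndarray  # x scores (n, a)
    q: np.ndarray  # y loadings (a,)
    x_scaler: Scaler
    y_scaler: Scaler
    explained_x: np.ndarray  # per-factor fraction of scaled-X variance
    explained_y: np.ndarray  # per-factor fraction of scaled-y variance
    feature_names: list[str] | None = None
    train_residual_sd: float = float("nan")

    @property
    def coef_(self) -> np.ndarray:
        """Regression vector in autoscaled space: b = W (P'W)^-1 q."""
        return self.W @ np.linalg.solve(self.P.T @ self.W, self.q)

    def _design(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame) and self.feature_names is not None:
            X = X[self.feature_names]
        return np.asarray(X, dtype=float)

    def scores(self, X) -> np.ndarray:
        Xs = self.x_scaler.transform(self._design(X))
        return Xs @ self.W @ np.linalg.inv(self.P.T @ self.W)

    def predict(self, X) -> np.ndarray:
        Xs = self.x_scaler.transform(self._design(X))
        ys = Xs @ self.coef_
        return self.y_scaler.inverse(ys[:, None]).ravel()


def fit_pls(X, y, n_factors: int, tol: float = 1e-12, max_iter: int = 10_000) -> PLSModel:
    """Fit a PLS1 model by NIPALS with deflation.

    X and y are autoscaled internally (the scalers ride along on the model,
    so :meth:`PLSModel.predict` takes raw descriptor values).  Weight vectors
    follow the sign convention that their first nonzero element is positive.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_factors < 1 or n_factors > rank:
        raise UsageError(f"n_factors must be in [1, rank(X)={rank}]")
    Xs, x_scaler = autoscale(X)
    ys_mat, y_scaler = autoscale(y)
    ys = ys_mat.ravel()

    ssx_total = float((Xs**2).sum())
    ssy_total = float((ys**2).sum())
    Xd, yd = Xs.copy(), ys.copy()
    W = np.zeros((p, n_factors))
    P = np.zeros((p, n_factors))
    T = np.zeros((n, n_factors))
    q = np.zeros(n_factors)
    explained_x = np.zeros(n_factors)
    explained_y = np.zeros(n_factors)

    for a in range(n_factors):
        u = yd.copy()
        w = np.zeros(p)
        for _ in range(max_iter):
            w_new = Xd.T @ u
            nrm = np.linalg.norm(w_new)
            if nrm == 0:
                raise NumericError(f"factor {a + 1}: zero weight vector (y fully deflated)")
            w_new /= nrm
            t = Xd @ w_new
            q_a = float(yd @ t / (t @ t))
            u_new = yd  # PLS1: the y block is a single column
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w, u = w_new, u_new
        else:
            raise NumericError(f"NIPALS did not converge for factor {a + 1}")
        t = Xd @ w
        # sign convention: first nonzero weight element positive
        nz = np.flatnonzero(np.abs(w) > 1e-14)
        if nz.size and w[nz[0]] < 0:
            w, t = -w, -t
        tt = float(t @ t)
        p_a = Xd.T @ t / tt
        q_a = float(yd @ t / tt)
        Xd = Xd - np.outer(t, p_a)
        yd = yd - t * q_a
        W[:, a], P[:, a], T[:, a], q[a] = w, p_a, t, q_a
        explained_x[a] = tt * float(p_a @ p_a) / ssx_total
        explained_y[a] = q_a**2 * tt / ssy_total if ssy_total > 0 else 0.0

    resid_sd = float(np.std(yd, ddof=1)) if n > 1 else float("nan")
    return PLSModel(
        n_factors=n_factors,
        W=W,
        P=P,
        T=T,
        q=q,
        x_scaler=x_scaler,
        y_scaler=y_scaler,
        explained_x=explained_x,
        explained_y=explained_y,
        feature_names=names,
        train_residual_sd=resid_sd,
    )


def select_factors(
    X,
    y,
    split: DataSplit,
    max_factors: int = 10,
    compute_loo: bool = True,
) -> tuple[int, pd.DataFrame]:
    """Profile 1..max_factors and pick the count maximizing external Q^2.

    Returns the chosen factor count (ties broken toward fewer factors) and a
    per-factor diagnostics table with training R^2, external Q^2 and LOO Q^2
    — the numerical analogue of the factor-selection curves.  ``compute_loo``
    can be switched off to skip the (n-fold) cross-validation column in
    large simulation loops.
    """
    X = pd.DataFrame(X)
    y = pd.Series(np.asarray(y, dtype=float).ravel(), index=X.index)
    X_tr, y_tr = X.loc[split.train_ids], y.loc[split.train_ids].to_numpy()
    X_te, y_te = X.loc[split.test_ids], y.loc[split.test_ids].to_numpy()
    rank = np.linalg.matrix_rank(X_tr.to_numpy() - X_tr.to_numpy().mean(axis=0))
    if max_factors > rank:
        warnings.warn(f"max_factors truncated to rank(X_train) = {rank}", stacklevel=2)
        max_factors = rank

    rows = []
    for a in range(1, max_factors + 1):
        model = fit_pls(X_tr, y_tr, a)
        rep = compute_fit_report(
            y_tr, model.predict(X_tr), y_te, model.predict(X_te), p=a, model=f"PLS-{a}"
        )
        q2_cv = (
            loo_q2(
                lambda Xa, ya, a=a: fit_pls(pd.DataFrame(Xa, columns=X.columns), ya, a).predict,
                X_tr.to_numpy(),
                y_tr,
            )
            if compute_loo
            else float("nan")
        )
        rows.append(
            {
                "n_factors": a,
                "r2_train": rep.r2_train,
                "q2_test": rep.q2_test,
                "q2_loo": q2_cv,
                "explained_y": float(model.explained_y.sum()),
                "explained_x": float(model.explained_x.sum()),
            }
        )
    curve = pd.DataFrame(rows).set_index("n_factors")
    best = int(curve["q2_test"].round(12).idxmax())  # ties -> fewer factors via idxmax order
    return best, curve


def vip_scores(model: PLSModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt(p * sum_a w_ja^2 SSY_a / sum_a SSY_a), so the squared
    scores average to exactly 1 over the p descriptors.
    """
    ssy = model.explained_y
    if ssy.sum() <= 0:
        raise DomainError("model explains no y-variance; VIP undefined")
    p = model.W.shape[0]
    contrib = (model.W**2) @ ssy
    return np.sqrt(p * contrib / ssy.sum())


def flag_outliers(
    model: PLSModel,
    X_test,
    y_test,
    threshold: float = 2.5,
    ids: list | None = None,
) -> list:
    """Flag test compounds outside the model's applicability domain.

    A compound is flagged when its absolute standardized prediction residual
    (training residual SD as the unit) exceeds ``threshold`` or its leverage
    in the latent-score space exceeds 3p/n.
    """
    Xt = model._design(X_test)
    y_test = np.asarray(y_test, dtype=float).ravel()
    if len(y_test) == 0:
        return []
    if ids is None:
        ids = list(range(len(y_test)))
    resid = (y_test - model.predict(X_test)) / model.y_scaler.std[0]
    scale = model.train_residual_sd if model.train_residual_sd > 0 else 1.0
    std_resid = resid / scale
    T = model.T
    n = T.shape[0]
    G = np.linalg.inv(T.T @ T)
    t_new = model.scores(Xt)
    leverage = np.einsum("ij,jk,ik->i", t_new, G, t_new) + 1.0 / n
    lev_cut = 3.0 * model.n_factors / n
    return [
        ids[i]
        for i in range(len(y_test))
        if abs(std_resid[i]) > threshold or leverage[i] > lev_cut
    ]
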