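"""Validation statistics shared by all model families.

Definitions (training set of size n with p model terms, test set held out):

* R^2          = 1 - RSS/TSS on the training set
* SEE          = sqrt(RSS / (n - p - 1))
* F            = (SSreg/p) / (RSS/(n - p - 1))
* Q^2 (test)   = 1 - sum (y_te - yhat_te)^2 / sum (y_te - mean(y_train))^2
* SEP          = sqrt(sum (y_te - yhat_te)^2 / n_test)
* Q^2 (LOO)    = 1 - PRESS/TSS, each point predicted from the other n-1

Every external/cross-validated Q^2 denominator is anchored at the *training*
mean, so predicting that mean everywhere scores exactly zero.  Because some
neural-network reports in this field quote correlation-style R values, the
squared Pearson correlation is also emitted as ``r2_corr``.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable

import numpy as np

from .errors import UsageError

__all__ = ["FitReport", "compute_fit_report", "loo_q2"]


@dataclass
class FitReport:
    n_train: int
    r2_train: float
    see: float
    f_stat: float
    sse_train: float
    r2_corr_train: float
    n_test: int | None = None
    q2_test: float | None = None
    sep: float | None = None
    sse_test: float | None = None
    r2_corr_test: float | None = None
    q2_loo: float | None = None
    sse_validation: float | None = None
    endpoint: str | None = None
    model: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _r2_corr(y: np.ndarray, yhat: np.ndarray) -> float:
    if np.std(y) == 0 or np.std(yhat) == 0:
        return 0.0
    return float(np.corrcoef(y, yhat)[0, 1] ** 2)


def compute_fit_report(
    y_train: np.ndarray,
    yhat_train: np.ndarray,
    y_test: np.ndarray | None = None,
    yhat_test: np.ndarray | None = None,
    p: int = 1,
    endpoint: str | None = None,
    model: str | None = None,
) -> FitReport:
    """Assemble the standard fit report for one model on one data split."""
    y_train = np.asarray(y_train, dtype=float)
    yhat_train = np.asarray(yhat_train, dtype=float)
    n = len(y_train)
    if n <= p + 1:
        raise UsageError(f"need n_train > p + 1 (got n={n}, p={p})")
    ybar = y_train.mean()
    rss = float(((y_train - yhat_train) ** 2).sum())
    tss = float(((y_train - ybar) ** 2).sum())
    ssreg = tss - rss
    dof = n - p - 1
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    see = float(np.sqrt(rss / dof))
    f_stat = float((ssreg / p) / (rss / dof)) if rss > 0 else float("inf")
    report = FitReport(
        n_train=n,
        r2_train=r2,
        see=see,
        f_stat=f_stat,
        sse_train=rss,
        r2_corr_train=_r2_corr(y_train, yhat_train),
        endpoint=endpoint,
        model=model,
    )
    if y_test is not None and len(y_test) > 0:
        y_test = np.asarray(y_test, dtype=float)
        yhat_test = np.asarray(yhat_test, dtype=float)
        press = float(((y_test - yhat_test) ** 2).sum())
        denom = float(((y_test - ybar) ** 2).sum())
        report.n_test = len(y_test)
        report.q2_test = 1.0 - press / denom if denom > 0 else float("nan")
        report.sep = float(np.sqrt(press / len(y_test)))
        report.sse_test = press
        report.r2_corr_test = _r2_corr(y_test, yhat_test)
    return report


def loo_q2(
    fit: Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]],
    X: np.ndarray,
    y: np.ndarray,
) -> float:
    """Leave-one-out cross-validated Q^2.

    ``fit(X_train, y_train)`` must return a predictor callable.  Each point
    is predicted by a model trained on the remaining n-1; Q^2 = 1 - PRESS/TSS.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise UsageError("LOO needs n >= 3")
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            predictor = fit(X[mask], y[mask])
            pred = float(np.asarray(predictor(X[i : i + 1])).ravel()[0])
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"LOO fold {i} failed: {exc}") from exc
        press += (y[i] - pred) ** 2
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / tss
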