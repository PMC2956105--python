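"""Stepwise multiple linear regression and the published fixed equations.

The study's three affinity/selectivity models are small stepwise-MLR
equations over named descriptors.  This module provides the stepwise search
(forward entry / backward removal on partial-F p-values), exact evaluators
for the three published fixed-coefficient equations, and a refit of the
published descriptor sets on self-computed descriptor values.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import UsageError
from .metrics import FitReport, compute_fit_report

__all__ = [
    "LinearModel",
    "PublishedEquation",
    "PUBLISHED_EQUATIONS",
    "stepwise_mlr",
    "predict_published",
    "refit_published_form",
]


@dataclass
class LinearModel:
    """Fixed linear predictor: intercept + sum(coefficient * descriptor)."""

    intercept: float
    terms: list[tuple[str, float, float]]  # (descriptor, coefficient, std. error)
    fit_stats: FitReport | None = None
    skipped: list[str] = field(default_factory=list)

    @property
    def descriptor_names(self) -> list[str]:
        return [t[0] for t in self.terms]

    def predict(self, descriptors) -> np.ndarray | float:
        """Evaluate on a DataFrame, mapping, or aligned 2-D array."""
        if isinstance(descriptors, dict):
            missing = [n for n in self.descriptor_names if n not in descriptors]
            if missing:
                raise KeyError(f"missing descriptor value(s): {missing}")
            return self.intercept + sum(
                coef * float(descriptors[name]) for name, coef, _ in self.terms
            )
        if isinstance(descriptors, pd.DataFrame):
            missing = [n for n in self.descriptor_names if n not in descriptors.columns]
            if missing:
                raise KeyError(f"missing descriptor column(s): {missing}")
            X = descriptors[self.descriptor_names].to_numpy(dtype=float)
        else:
            X = np.asarray(descriptors, dtype=float)
            if X.ndim == 1:
                X = X[None, :]
            if X.shape[1] != len(self.terms):
                raise UsageError("array input must align with the model terms")
        coefs = np.array([c for _, c, _ in self.terms])
        return self.intercept + X @ coefs


@dataclass(frozen=True)
class PublishedEquation:
    """One of the three printed fixed-coefficient equations."""

    tag: str  # eq3 / eq4 / eq5
    endpoint: str  # alpha / beta / selectivity
    model: LinearModel


# The printed coefficients (value, standard error) of the three equations.
PUBLISHED_EQUATIONS: dict[str, PublishedEquation] = {
    "eq3": PublishedEquation(
        "eq3",
        "alpha",
        LinearModel(
            intercept=2.181,
            terms=[
                ("JGI10", 44.287, 11.238),
                ("E1p", -9.883, 2.266),
                ("R4u", 2.998, 0.397),
                ("BLTA96", -0.577, 0.090),  # printed as BELTA96; same descriptor
            ],
        ),
    ),
    "eq4": PublishedEquation(
        "eq4",
        "beta",
        LinearModel(
            intercept=41.527,
            terms=[
                ("JGI10", 47.096, 16.457),
                ("E1p", -19.060, 3.445),
                ("BEHe6", -10.963, 1.742),
                ("EEig09x", -0.592, 0.159),
                ("nCb-", 0.585, 0.057),
            ],
        ),
    ),
    "eq5": PublishedEquation(
        "eq5",
        "selectivity",
        LinearModel(
            intercept=22.489,
            terms=[
                ("BEHe6", -7.709, 1.107),
                ("BEHm5", -2.602, 0.552),
                ("EEig03r", 2.513, 0.612),
                ("DISPe", -0.823, 0.280),
                ("CIC2", -0.804, 0.142),
            ],
        ),
    ),
}

_ALIASES = {"BELTA96": "BLTA96"}

# The fit statistics printed alongside the three equations, kept for
# informational comparison against refits on self-computed descriptors.
PUBLISHED_FIT_STATS: dict[str, dict[str, float]] = {
    "eq3": {"r2": 0.72, "q2": 0.63, "see": 0.36, "sep": 0.44, "f": 36.01, "n_tr": 61, "n_te": 21},
    "eq4": {"r2": 0.75, "q2": 0.75, "see": 0.46, "sep": 0.46, "f": 32.35, "n_tr": 61, "n_te": 21},
    "eq5": {"r2": 0.74, "q2": 0.80, "see": 0.25, "sep": 0.21, "f": 25.56},
}


def _ols(X: np.ndarray, y: np.ndarray):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def stepwise_mlr(
    X: pd.DataFrame,
    y: np.ndarray,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
) -> LinearModel:
    """Forward-entry / backward-removal stepwise OLS on partial-F p-values.

    At each cycle the candidate with the smallest entry p-value below
    ``alpha_enter`` is added, then any included term whose p-value exceeds
    ``alpha_remove`` is dropped (worst first); iteration stops when neither
    move applies.  Rank-deficient candidates are skipped and recorded.
    """
    if alpha_enter > alpha_remove:
        raise UsageError("alpha_enter must be <= alpha_remove")
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    included: list[str] = []
    skipped: list[str] = []
    n = len(y)
    tss = float(((y - y.mean()) ** 2).sum())
    seen_models: set[frozenset] = set()

    while True:
        changed = False
        # forward step; once the fit is numerically perfect the partial-F
        # p-values of further candidates are 0/0 noise, so entry stops
        if included:
            rss_now = float((_ols(X[included].to_numpy(dtype=float), y).resid ** 2).sum())
        else:
            rss_now = tss
        perfect = rss_now <= 1e-12 * max(tss, 1.0)
        candidates = (
            [] if perfect else [c for c in X.columns if c not in included and c not in skipped]
        )
        best_p, best_c = 1.0, None
        for c in candidates:
            cols = included + [c]
            if n <= len(cols) + 1:
                continue
            design = X[cols].to_numpy(dtype=float)
            if np.linalg.matrix_rank(np.column_stack([np.ones(n), design])) < len(cols) + 1:
                skipped.append(c)
                continue
            res = _ols(design, y)
            p_val = res.pvalues[-1]
            if p_val < best_p:
                best_p, best_c = p_val, c
        if best_c is not None and best_p < alpha_enter:
            included.append(best_c)
            changed = True
        # backward step
        while len(included) > 0:
            res = _ols(X[included].to_numpy(dtype=float), y)
            pvals = res.pvalues[1:]
            worst = int(np.argmax(pvals))
            if pvals[worst] > alpha_remove:
                included.pop(worst)
                changed = True
            else:
                break
        state = frozenset(included)
        if not changed or state in seen_models:  # cycle guard for entry/removal ping-pong
            break
        seen_models.add(state)

    if included:
        res = _ols(X[included].to_numpy(dtype=float), y)
        intercept = float(res.params[0])
        terms = [
            (name, float(res.params[i + 1]), float(res.bse[i + 1]))
            for i, name in enumerate(included)
        ]
        yhat = np.asarray(res.fittedvalues)
    else:
        intercept = float(y.mean())
        terms = []
        yhat = np.full(n, intercept)
    model = LinearModel(intercept=intercept, terms=terms, skipped=skipped)
    if terms and n > len(terms) + 1:
        model.fit_stats = compute_fit_report(y, yhat, p=len(terms), model="MLR")
    return model


def predict_published(eq: PublishedEquation | str, descriptors) -> np.ndarray | float:
    """Evaluate a published equation at named descriptor values (no rescaling)."""
    if isinstance(eq, str):
        eq = PUBLISHED_EQUATIONS[eq]
    if isinstance(descriptors, dict):
        descriptors = {_ALIASES.get(k, k): v for k, v in descriptors.items()}
    elif isinstance(descriptors, pd.DataFrame):
        descriptors = descriptors.rename(columns=_ALIASES)
    return eq.model.predict(descriptors)


def refit_published_form(
    X: pd.DataFrame,
    y: np.ndarray,
    eq: PublishedEquation | str,
) -> LinearModel:
    """Re-estimate a published equation's coefficients on given descriptors.

    Uses exactly the published descriptor set, fit by OLS on self-computed
    (raw-scale) descriptor values; the returned model carries a fit report
    for comparison against the printed statistics.
    """
    if isinstance(eq, str):
        eq = PUBLISHED_EQUATIONS[eq]
    X = pd.DataFrame(X).rename(columns=_ALIASES)
    names = eq.model.descriptor_names
    missing = [n for n in names if n not in X.columns]
    if missing:
        raise KeyError(f"descriptor matrix lacks column(s) {missing}")
    y = np.asarray(y, dtype=float)
    design = X[names].to_numpy(dtype=float)
    res = _ols(design, y)
    model = LinearModel(
        intercept=float(res.params[0]),
        terms=[
            (name, float(res.params[i + 1]), float(res.bse[i + 1]))
            for i, name in enumerate(names)
        ],
    )
    model.fit_stats = compute_fit_report(
        y, np.asarray(res.fittedvalues), p=len(names), model="MLR-refit", endpoint=eq.endpoint
    )
    return model
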