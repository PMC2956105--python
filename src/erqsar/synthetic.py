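"""Seeded generators with the statistical structure each modeling stage assumes.

Each generator emulates one aspect of a small-sample QSAR descriptor matrix:

* :func:`gen_linear` — descriptor-like columns with a planted linear signal
  and optional pairwise collinearity (stepwise-regression recovery tests),
* :func:`gen_latent` — low-rank latent-structure X/y pairs, supporting more
  descriptors than compounds (PLS factor-selection tests),
* :func:`gen_nonlinear` — smooth nonlinear regression surfaces
  (neural-network recovery tests),
* :func:`gen_clusters` — Gaussian cluster mixtures (self-organizing-map
  splitting tests).

Defaults mirror the study scale (n about 82 samples, around 11 descriptor
columns), so tests exercise the same small-n regime as the real analysis.
All generators are pure functions of their arguments including the seed.
"""
from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .errors import UsageError

__all__ = ["gen_linear", "gen_latent", "gen_nonlinear", "gen_clusters"]


def gen_linear(
    n: int = 82,
    p: int = 11,
    coefs: Sequence[float] | None = None,
    noise_sd: float = 0.3,
    collinearity: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standard-normal descriptor columns with y = X beta + eps.

    ``collinearity`` sets the target pairwise correlation between columns via
    a shared latent factor: x_j = sqrt(c) g + sqrt(1-c) z_j.
    """
    if not (0.0 <= collinearity <= 0.99):
        raise UsageError("collinearity must be in [0, 0.99]")
    rng = np.random.default_rng(seed)
    beta = np.zeros(p)
    if coefs is not None:
        coefs = np.asarray(coefs, dtype=float)
        if len(coefs) > p:
            raise UsageError("more coefficients than columns")
        beta[: len(coefs)] = coefs
    Z = rng.standard_normal((n, p))
    if collinearity > 0:
        g = rng.standard_normal((n, 1))
        X = np.sqrt(collinearity) * g + np.sqrt(1 - collinearity) * Z
    else:
        X = Z
    y = X @ beta + noise_sd * rng.standard_normal(n)
    return X, y, beta


def gen_latent(
    n: int = 82,
    p: int = 11,
    rank: int = 3,
    noise_x: float = 0.05,
    noise_y: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Low-rank X = T P' + E with y = T q + f; supports p > n.

    T has orthonormal columns scaled by a decaying singular-value profile and
    P has orthonormal columns, so the singular values of the noiseless X are
    exactly the planted profile linspace(1, 0.5, rank) * sqrt(n).  The
    response loads on every factor with magnitude in [0.5, 1.5] (random
    sign), so no planted factor is spuriously weak.
    """
    if rank > min(n, p):
        raise UsageError("rank cannot exceed min(n, p)")
    rng = np.random.default_rng(seed)
    T, _ = np.linalg.qr(rng.standard_normal((n, rank)))
    sv = np.linspace(1.0, 0.5, rank) * np.sqrt(n)
    T = T * sv
    P, _ = np.linalg.qr(rng.standard_normal((p, rank)))
    q = rng.uniform(0.5, 1.5, rank) * rng.choice([-1.0, 1.0], rank)
    X = T @ P.T + noise_x * rng.standard_normal((n, p))
    y = T @ q + noise_y * rng.standard_normal(n)
    return X, y, rank


_NONLINEAR_TAGS = ("sin1d", "xor2d", "saturating")


def gen_nonlinear(
    n: int = 200,
    tag: str = "sin1d",
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, Callable[[np.ndarray], np.ndarray]]:
    """Smooth nonlinear regression surfaces y = f(X) + eps.

    Tags: ``sin1d`` (sine on [-3, 3]), ``xor2d`` (smooth XOR surface
    x1*x2 on [-1, 1]^2, linearly inseparable), ``saturating`` (tanh ramp).
    The oracle f is returned for independent evaluation.
    """
    if tag not in _NONLINEAR_TAGS:
        raise UsageError(f"unknown tag {tag!r}; expected one of {_NONLINEAR_TAGS}")
    rng = np.random.default_rng(seed)
    if tag == "sin1d":
        X = rng.uniform(-3.0, 3.0, size=(n, 1))
        f = lambda Z: np.sin(np.asarray(Z)[:, 0])  # noqa: E731
    elif tag == "xor2d":
        X = rng.uniform(-1.0, 1.0, size=(n, 2))
        f = lambda Z: np.asarray(Z)[:, 0] * np.asarray(Z)[:, 1] * 4.0  # noqa: E731
    else:
        X = rng.uniform(-3.0, 3.0, size=(n, 1))
        f = lambda Z: np.tanh(2.0 * np.asarray(Z)[:, 0])  # noqa: E731
    y = f(X) + noise_sd * rng.standard_normal(n)
    return X, y, f


def gen_clusters(
    n_per: int = 40,
    centers: Sequence[Sequence[float]] = ((0.0, 0.0), (6.0, 6.0)),
    sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian cluster mixture for topology-preserving-map tests."""
    rng = np.random.default_rng(seed)
    centers = np.asarray(centers, dtype=float)
    X = np.vstack(
        [c + sd * rng.standard_normal((n_per, centers.shape[1])) for c in centers]
    )
    labels = np.repeat(np.arange(len(centers)), n_per)
    return X, labels
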