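"""Kohonen self-organizing-map training and representative data splitting.

The study stratifies its train/test split by chemical-space position: a
small Kohonen map (5x5 for the per-subtype affinity sets, 4x4 for the
selectivity set) clusters the standardized descriptor vectors, and from each
occupied map cell the compounds nearest the cell prototype go to the
training set while the farthest go to the independent test set.  The neural
network's internal validation set is then carved out of the training set at
a 2:1 ratio.

Training uses the deterministic batch Kohonen update (Gaussian neighborhood
with an exponentially decaying radius).  The batch variant is preferred over
the online one because it is reproducible without an update-order
convention and, for a single-cell map, converges exactly to the data mean.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UsageError

__all__ = ["SOMGrid", "DataSplit", "train_som", "split_by_cells", "subsplit_validation"]


@dataclass
class SOMGrid:
    rows: int
    cols: int
    codebook: np.ndarray  # (rows*cols, dim)
    seed: int
    epochs: int
    radius_start: float
    radius_end: float
    initial_qe: float
    final_qe: float

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    def cell_positions(self) -> np.ndarray:
        rr, cc = np.meshgrid(np.arange(self.rows), np.arange(self.cols), indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)

    def bmu(self, X: np.ndarray) -> np.ndarray:
        """Best-matching cell index for every sample."""
        d = ((np.asarray(X)[:, None, :] - self.codebook[None, :, :]) ** 2).sum(axis=2)
        return d.argmin(axis=1)

    def quantization_error(self, X: np.ndarray) -> float:
        d = ((np.asarray(X)[:, None, :] - self.codebook[None, :, :]) ** 2).sum(axis=2)
        return float(np.sqrt(d.min(axis=1)).mean())


@dataclass
class DataSplit:
    """Disjoint, exhaustive partition of compound ids."""

    train_ids: list
    test_ids: list
    validation_ids: list = field(default_factory=list)
    seed: int | None = None

    def assert_valid(self, all_ids: list) -> None:
        parts = [set(self.train_ids), set(self.test_ids), set(self.validation_ids)]
        union = set().union(*parts)
        if union != set(all_ids):
            raise ValueError("split does not cover the input compound set")
        if sum(len(p) for p in parts) != len(union):
            raise ValueError("split sets overlap")


def _quantization_error(X: np.ndarray, codebook: np.ndarray) -> float:
    d = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d.min(axis=1)).mean())


def train_som(
    X: np.ndarray,
    shape: tuple[int, int],
    seed: int = 0,
    epochs: int = 100,
    radius_end: float = 0.5,
    refine_epochs: int = 10,
) -> SOMGrid:
    """Train a Kohonen map on (standardized) descriptor vectors.

    Batch update: each epoch every sample is assigned to its best-matching
    cell, and every cell prototype is recomputed as the Gaussian-neighborhood
    weighted mean of the data.  The neighborhood radius decays exponentially
    from max(shape)/2 to ``radius_end``; a short zero-radius refinement phase
    (Lloyd iterations) then sharpens each prototype onto its own members,
    which monotonically reduces the quantization error.  Deterministic for a
    fixed seed.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise UsageError("X must be a nonempty 2-D array")
    if np.isnan(X).any():
        raise UsageError("X contains NaN")
    rows, cols = shape
    if rows < 1 or cols < 1:
        raise UsageError("grid shape must have at least one cell per axis")
    n, dim = X.shape
    n_cells = rows * cols
    rng = np.random.default_rng(seed)

    # init: random data points (with replacement when cells outnumber samples)
    init_idx = rng.choice(n, size=n_cells, replace=n_cells > n)
    codebook = X[init_idx].copy() + 1e-9 * rng.standard_normal((n_cells, dim))
    initial_qe = _quantization_error(X, codebook)

    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    pos = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    grid_d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)

    radius_start = max(max(rows, cols) / 2.0, radius_end)
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        radius = radius_start * (radius_end / radius_start) ** frac
        d = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
        bmu = d.argmin(axis=1)
        h = np.exp(-grid_d2[bmu] / (2.0 * radius**2))  # (n, n_cells)
        denom = h.sum(axis=0)
        num = h.T @ X
        update = denom > 1e-12
        codebook[update] = num[update] / denom[update, None]

    def _lloyd(cb: np.ndarray) -> np.ndarray:
        cb = cb.copy()
        for _ in range(refine_epochs):
            d = ((X[:, None, :] - cb[None, :, :]) ** 2).sum(axis=2)
            bmu = d.argmin(axis=1)
            moved = False
            for c in range(n_cells):
                members = X[bmu == c]
                if len(members):
                    new = members.mean(axis=0)
                    if not np.allclose(new, cb[c]):
                        cb[c] = new
                        moved = True
            if not moved:
                break
        return cb

    codebook = _lloyd(codebook)
    # the smoothing phase can occasionally leave prototypes worse than the
    # random-data-point start; never return a codebook above that baseline
    if _quantization_error(X, codebook) > initial_qe:
        alt = _lloyd(X[init_idx].copy())
        if _quantization_error(X, alt) < _quantization_error(X, codebook):
            codebook = alt

    return SOMGrid(
        rows=rows,
        cols=cols,
        codebook=codebook,
        seed=seed,
        epochs=epochs,
        radius_start=radius_start,
        radius_end=radius_end,
        initial_qe=initial_qe,
        final_qe=_quantization_error(X, codebook),
    )


def split_by_cells(
    grid: SOMGrid,
    X: np.ndarray,
    train_fraction: float,
    seed: int = 0,
    ids: list | None = None,
) -> DataSplit:
    """Representative train/test split from a trained map.

    Within every occupied cell, members are ranked by distance to the cell
    prototype; the nearest go to training and the farthest to test.  Per-cell
    quotas (largest-remainder allocation, at least one training member per
    multi-member cell, single-member cells entirely in training) are adjusted
    so the global training count equals round(train_fraction * n).
    """
    if not (0.0 < train_fraction < 1.0):
        raise UsageError("train_fraction must lie in (0, 1)")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if ids is None:
        ids = list(range(n))
    if len(ids) != n:
        raise UsageError("ids length must match X")
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)

    bmu = grid.bmu(X)
    dists = np.sqrt(((X - grid.codebook[bmu]) ** 2).sum(axis=1))
    cells: dict[int, list[int]] = {}
    for i, c in enumerate(bmu):
        cells.setdefault(int(c), []).append(i)
    # deterministic member order: distance to prototype, index as tie-break
    for c in cells:
        cells[c].sort(key=lambda i: (dists[i], i))

    cell_ids = sorted(cells)
    sizes = {c: len(cells[c]) for c in cell_ids}
    quota = {c: 1 for c in cell_ids}  # every occupied cell keeps >= 1 in training
    remainder = sorted(
        cell_ids,
        key=lambda c: (train_fraction * sizes[c]) % 1.0,
        reverse=True,
    )
    for c in cell_ids:
        quota[c] = max(1, int(np.floor(train_fraction * sizes[c])))
    # adjust the total to the global target, preferring cells with the largest
    # fractional remainder when adding and the smallest when removing
    total = sum(quota.values())
    add_order = [c for c in remainder if quota[c] < sizes[c]]
    while total < n_train:
        progressed = False
        for c in add_order:
            if quota[c] < sizes[c]:
                quota[c] += 1
                total += 1
                progressed = True
                if total == n_train:
                    break
        if not progressed:
            break
    remove_order = list(reversed(remainder))
    while total > n_train:
        progressed = False
        for c in remove_order:
            if quota[c] > 1 and sizes[c] > 1:
                quota[c] -= 1
                total -= 1
                progressed = True
                if total == n_train:
                    break
        if not progressed:
            # degenerate: every cell is at its floor; demote singletons
            for c in remove_order:
                if quota[c] > 0 and total > n_train:
                    quota[c] -= 1
                    total -= 1
            break

    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in cell_ids:
        members = cells[c]
        train_idx.extend(members[: quota[c]])
        test_idx.extend(members[quota[c] :])
    train_idx.sort()
    test_idx.sort()
    return DataSplit(
        train_ids=[ids[i] for i in train_idx],
        test_ids=[ids[i] for i in test_idx],
        seed=seed,
    )


def subsplit_validation(
    split: DataSplit, ratio: tuple[int, int] = (2, 1), seed: int = 0
) -> DataSplit:
    """Carve a validation set out of the training ids at the given ratio.

    The training ids are partitioned by a seeded uniform draw; test ids are
    untouched.  With the default 2:1 ratio, round(2/3 * n_train) ids remain
    in training.
    """
    tr_share, val_share = ratio
    if tr_share <= 0 or val_share < 0:
        raise UsageError("ratio parts must be positive (validation share may be 0)")
    n = len(split.train_ids)
    if n < 3:
        raise UsageError("need at least 3 training compounds to sub-split")
    if val_share == 0:
        return DataSplit(list(split.train_ids), list(split.test_ids), [], seed=seed)
    n_keep = int(round(tr_share / (tr_share + val_share) * n))
    n_keep = min(max(n_keep, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    keep = sorted(perm[:n_keep])
    drop = sorted(perm[n_keep:])
    return DataSplit(
        train_ids=[split.train_ids[i] for i in keep],
        test_ids=list(split.test_ids),
        validation_ids=[split.train_ids[i] for i in drop],
        seed=seed,
    )
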