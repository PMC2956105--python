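"""Independent brute-force oracles for descriptor definitions.

Everything here is deliberately written with explicit loops, its own BFS
topological distances, and dense matrices, so it shares no code path with
the package implementation beyond the basic linear-algebra routines.
"""
from __future__ import annotations

import math

import numpy as np


def graph_from_structure(structure, heavy: bool = True):
    """(symbols, bonds) with bonds as (i, j, bond_type_str) triples."""
    mol = structure.heavy_mol if heavy else structure.mol
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), str(b.GetBondType()))
        for b in mol.GetBonds()
    ]
    degrees = [a.GetDegree() for a in mol.GetAtoms()]
    return symbols, bonds, degrees


def bfs_distances(n: int, bonds) -> np.ndarray:
    adj = [[] for _ in range(n)]
    for i, j, _ in bonds:
        adj[i].append(j)
        adj[j].append(i)
    D = np.full((n, n), np.inf)
    for s in range(n):
        D[s, s] = 0
        queue = [s]
        while queue:
            nxt = []
            for u in queue:
                for v in adj[u]:
                    if D[s, v] == np.inf:
                        D[s, v] = D[s, u] + 1
                        nxt.append(v)
            queue = nxt
    return D


def brute_ggi(structure, order: int, mean: bool = False) -> float:
    symbols, bonds, _ = graph_from_structure(structure)
    n = len(symbols)
    A = np.zeros((n, n))
    for i, j, _ in bonds:
        A[i, j] = A[j, i] = 1.0
    D = bfs_distances(n, bonds)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if k != j and np.isfinite(D[k, j]) and D[k, j] > 0:
                    M[i, j] += A[i, k] / D[k, j] ** 2
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] == order:
                total += abs(M[i, j] - M[j, i])
    return total / (n - 1) if mean else total


_BOND_TENTH = {"SINGLE": 0.1, "DOUBLE": 0.2, "TRIPLE": 0.3, "AROMATIC": 0.15}


def brute_burden(structure, prop_fn, scheme: str, k: int, end: str = "highest") -> float:
    symbols, bonds, _ = graph_from_structure(structure)
    n = len(symbols)
    B = [[0.001 for _ in range(n)] for _ in range(n)]
    for i in range(n):
        B[i][i] = prop_fn(symbols[i], scheme)
    for i, j, t in bonds:
        B[i][j] = B[j][i] = _BOND_TENTH[t]
    eig = sorted(np.linalg.eigvalsh(np.array(B)))
    return float(eig[-k]) if end == "highest" else float(eig[k - 1])


_RES = {"SINGLE": 1.0, "AROMATIC": 1.5, "DOUBLE": 2.0, "TRIPLE": 3.0}


def brute_eeig(structure, prop_fn, weight: str, k: int) -> float:
    symbols, bonds, degrees = graph_from_structure(structure)
    m = len(bonds)
    E = [[0.0 for _ in range(m)] for _ in range(m)]
    for a, (ia, ja, t) in enumerate(bonds):
        if weight == "x":
            E[a][a] = (degrees[ia] - 1) + (degrees[ja] - 1)
        elif weight == "r":
            E[a][a] = _RES[t]
        else:
            E[a][a] = abs(prop_fn(symbols[ia], "e") - prop_fn(symbols[ja], "e"))
        for b, (ib, jb, _) in enumerate(bonds):
            if a != b and len({ia, ja} & {ib, jb}) > 0:
                E[a][b] = 1.0
    eig = sorted(np.linalg.eigvalsh(np.array(E)))
    return float(eig[-k])


def brute_ic(structure, order: int, variant: str = "IC") -> float:
    symbols, bonds, degrees = graph_from_structure(structure, heavy=False)
    n = len(symbols)
    neigh = [[] for _ in range(n)]
    bond_of = [[] for _ in range(n)]
    for i, j, t in bonds:
        neigh[i].append(j)
        neigh[j].append(i)
        bond_of[i].append(t)
        bond_of[j].append(t)
    colors = [(symbols[i], degrees[i], tuple(sorted(bond_of[i]))) for i in range(n)]
    for _ in range(order):
        colors = [
            (colors[i], tuple(sorted(colors[j] for j in neigh[i]))) for i in range(n)
        ]
    counts: dict = {}
    for c in colors:
        counts[c] = counts.get(c, 0) + 1
    ic = 0.0
    for c, cnt in counts.items():
        p = cnt / n
        ic -= p * math.log2(p)
    return ic if variant == "IC" else math.log2(n) - ic


def brute_whim(structure, prop_fn, scheme: str, index: str) -> float:
    X = structure.coords
    symbols = [a.GetSymbol() for a in structure.mol.GetAtoms()]
    n = len(symbols)
    w = np.array([prop_fn(s, scheme) for s in symbols])
    w = w / w.sum()
    center = np.zeros(3)
    for i in range(n):
        center += w[i] * X[i]
    S = np.zeros((3, 3))
    for i in range(n):
        d = X[i] - center
        S += w[i] * np.outer(d, d)
    vals, vecs = np.linalg.eigh(S)
    lam1 = vals[-1]
    if index == "L1":
        return float(lam1)
    v1 = vecs[:, -1]
    t4 = sum(float((X[i] - center) @ v1) ** 4 for i in range(n))
    return float(lam1**2 * n / t4)


def brute_getaway(structure, prop_fn, scheme: str, family: str, lag: int) -> float:
    X = structure.coords
    mol = structure.mol
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    n = len(symbols)
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), "") for b in mol.GetBonds()]
    D = bfs_distances(n, bonds)
    Xc = X - X.mean(axis=0)
    H = Xc @ np.linalg.pinv(Xc.T @ Xc) @ Xc.T
    h = [max(min(H[i, i], 1.0), 0.0) for i in range(n)]
    w = [prop_fn(s, scheme) for s in symbols]
    best = 0.0
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            r = float(np.linalg.norm(X[i] - X[j]))
            rterm = math.sqrt(h[i] * h[j]) / r * w[i] * w[j]
            if family == "RT+":
                best = max(best, rterm)
                continue
            if D[i, j] != lag:
                continue
            if family == "R":
                total += rterm
            elif family == "R+":
                best = max(best, rterm)
            elif family == "HATS":
                total += (h[i] * w[i]) * (h[j] * w[j])
            elif family == "H":
                total += h[i] * h[j] * w[i] * w[j]
    return best if family in ("R+", "RT+") else total


def brute_rdf(structure, prop_fn, radius_index: int, scheme: str, beta: float) -> float:
    X = structure.coords
    symbols = [a.GetSymbol() for a in structure.mol.GetAtoms()]
    w = [prop_fn(s, scheme) for s in symbols]
    R = radius_index / 10.0
    total = 0.0
    for i in range(len(symbols)):
        for j in range(i + 1, len(symbols)):
            r = float(np.linalg.norm(X[i] - X[j]))
            total += w[i] * w[j] * math.exp(-beta * (R - r) ** 2)
    return total


def brute_dispe(structure, prop_fn) -> float:
    X = structure.coords
    symbols = [a.GetSymbol() for a in structure.mol.GetAtoms()]
    w = [prop_fn(s, "e") for s in symbols]
    geo = X.mean(axis=0)
    wc = np.zeros(3)
    for i, wi in enumerate(w):
        wc += wi * X[i]
    wc /= sum(w)
    return float(np.linalg.norm(geo - wc))


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS coefficients (with intercept) by explicit normal equations."""
    A = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(A.T @ A, A.T @ y)
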