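"""Molecular descriptor families used by the receptor-binding QSAR models.

Implements, from their literature definitions, the descriptor families that
appear in the fixed published equations and the PLS importance lists:

* topological charge indices (GGI/JGI) on the heavy-atom graph,
* Burden-matrix eigenvalue descriptors (BEHwk / BELwk),
* edge-adjacency-matrix eigenvalues (EEig, edge-degree / resonance / dipole
  weighted),
* neighborhood-symmetry information content (IC/CIC, hydrogen-included),
* WHIM directional size and accessibility indices (L1/E1),
* GETAWAY leverage autocorrelations (R, HATS, R+, RT+, H),
* the COMMA2 displacement DISPe,
* radial distribution function (RDF) descriptors,
* the Moriguchi MLOGP estimate and the derived baseline-toxicity transform
  BLTA96,
* aromatic-substitution and unsaturation counts (nCb-, nPyridines, nDB).

Graph conventions follow the descriptor literature: topological descriptors
(JGI, BEH/BEL, EEig) operate on the hydrogen-depleted graph, information
content on the hydrogen-included graph, and 3D descriptors on all atoms of
the embedded conformer.  Exact numerical agreement with any proprietary
descriptor binary is not promised (conformers and unstated conventions
differ); every value here is definition-faithful and oracle-tested.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .dataset import CompoundTable
from .errors import DomainError, UsageError
from .structures import (
    DEFAULT_EMBED_SEED,
    MolecularStructure,
    atom_property,
    atom_weights,
    embed_conformer,
)

__all__ = [
    "CORE_DESCRIPTORS",
    "DescriptorMatrix",
    "topological_charge_index",
    "burden_eigenvalue",
    "edge_adjacency_eigenvalue",
    "information_content",
    "whim_directional",
    "getaway_index",
    "comma2_displacement",
    "rdf_descriptor",
    "mlogp",
    "blta96",
    "mlogp_blta96",
    "group_counts",
    "descriptor_value",
    "compute_matrix",
]

# Union of the descriptors in the three published fixed-coefficient equations.
CORE_DESCRIPTORS = [
    "JGI10",
    "E1p",
    "R4u",
    "BLTA96",
    "BEHe6",
    "BEHm5",
    "EEig09x",
    "EEig03r",
    "DISPe",
    "CIC2",
    "nCb-",
]

# Burden-matrix off-diagonal conventions (bond order / 10; tiny non-bonded fill)
_BURDEN_BOND = {
    Chem.BondType.SINGLE: 0.1,
    Chem.BondType.DOUBLE: 0.2,
    Chem.BondType.TRIPLE: 0.3,
    Chem.BondType.AROMATIC: 0.15,
}
_BURDEN_FILL = 0.001

# resonance-integral-style edge weights by bond type (relative to a single bond)
_RESONANCE_WEIGHT = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.AROMATIC: 1.5,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
}

RDF_BETA = 100.0  # Gaussian smoothing, 1/Angstrom^2
BLTA96_SLOPE = 0.90  # baseline algae toxicity: BLTA96 = slope*MLOGP + intercept
BLTA96_INTERCEPT = 1.07


# --------------------------------------------------------------------------
# topological descriptors (hydrogen-depleted graph)
# --------------------------------------------------------------------------
def topological_charge_index(
    structure: MolecularStructure, order: int, mean: bool = False
) -> float:
    """Galvez topological charge index GGI_k (or its mean JGI_k).

    Builds M = A @ D* where A is the heavy-atom adjacency matrix and D* holds
    reciprocal squared topological distances (zero diagonal).  The charge
    term CT_ij = M_ij - M_ji is summed as |CT_ij| over atom pairs at
    topological distance ``order``; JGI_k divides by (heavy atoms - 1).
    """
    if order < 1:
        raise UsageError("topological charge index order must be >= 1")
    A = structure.heavy_adjacency()
    n = A.shape[0]
    if n < 2:
        raise DomainError("need at least 2 heavy atoms")
    D = structure.heavy_distance_matrix()
    with np.errstate(divide="ignore"):
        Dstar = np.where(D > 0, 1.0 / D**2, 0.0)
    M = A @ Dstar
    CT = M - M.T
    iu = np.triu_indices(n, k=1)
    mask = D[iu] == order
    ggi = float(np.abs(CT[iu][mask]).sum())
    return ggi / (n - 1) if mean else ggi


def burden_eigenvalue(
    structure: MolecularStructure, weight: str, k: int, end: str = "highest"
) -> float:
    """k-th eigenvalue (from either end) of the weighted Burden matrix.

    Diagonal: carbon-relative atomic property of each heavy atom.
    Bonded off-diagonal: bond order / 10 (single 0.1, double 0.2, triple 0.3,
    aromatic 0.15); all other entries 0.001.
    """
    heavy = structure.heavy_mol
    n = heavy.GetNumAtoms()
    if k < 1 or k > n:
        raise DomainError(f"rank {k} unavailable for a {n}-heavy-atom molecule")
    w = atom_weights(heavy, weight)
    B = np.full((n, n), _BURDEN_FILL)
    np.fill_diagonal(B, w)
    for bond in heavy.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        val = _BURDEN_BOND.get(bond.GetBondType(), 0.1)
        B[i, j] = B[j, i] = val
    eig = np.sort(np.linalg.eigvalsh(B))
    return float(eig[-k]) if end == "highest" else float(eig[k - 1])


def _edge_list(heavy: Chem.Mol) -> list[tuple[int, int, Chem.Bond]]:
    return [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b) for b in heavy.GetBonds()]


def edge_adjacency_eigenvalue(structure: MolecularStructure, weight: str, k: int) -> float:
    """k-th largest eigenvalue of the weighted edge-adjacency matrix.

    Edges are adjacent iff they share a vertex (off-diagonal 1); the chosen
    weights sit on the diagonal: ``x`` edge degrees (deg_i-1)+(deg_j-1),
    ``r`` bond-order-derived resonance-integral weights, ``d`` absolute
    Sanderson-electronegativity difference of the two endpoints.
    """
    heavy = structure.heavy_mol
    edges = _edge_list(heavy)
    m = len(edges)
    if k < 1 or k > m:
        raise DomainError(f"rank {k} unavailable: molecule has {m} edges")
    E = np.zeros((m, m))
    for a in range(m):
        ia, ja, bond = edges[a]
        if weight == "x":
            E[a, a] = (heavy.GetAtomWithIdx(ia).GetDegree() - 1) + (
                heavy.GetAtomWithIdx(ja).GetDegree() - 1
            )
        elif weight == "r":
            E[a, a] = _RESONANCE_WEIGHT.get(bond.GetBondType(), 1.0)
        elif weight == "d":
            E[a, a] = abs(
                atom_property(heavy.GetAtomWithIdx(ia).GetSymbol(), "e")
                - atom_property(heavy.GetAtomWithIdx(ja).GetSymbol(), "e")
            )
        else:
            raise UsageError(f"unknown edge weight {weight!r}; expected x, r or d")
        for b in range(a + 1, m):
            ib, jb, _ = edges[b]
            if {ia, ja} & {ib, jb}:
                E[a, b] = E[b, a] = 1.0
    eig = np.sort(np.linalg.eigvalsh(E))
    return float(eig[-k])


def information_content(structure: MolecularStructure, order: int, variant: str = "IC") -> float:
    """Neighborhood-symmetry information content IC_k / CIC_k in bits.

    Atoms of the hydrogen-included graph are partitioned by iterated
    neighborhood refinement to radius ``order`` (seed invariant: element,
    degree, sorted incident bond orders); IC_k is the Shannon entropy of the
    class sizes and CIC_k = log2(A) - IC_k.
    """
    if order < 0:
        raise UsageError("information content order must be >= 0")
    mol = structure.mol
    n = mol.GetNumAtoms()
    inv: list = []
    for atom in mol.GetAtoms():
        bonds = tuple(sorted(str(b.GetBondType()) for b in atom.GetBonds()))
        inv.append((atom.GetSymbol(), atom.GetDegree(), bonds))
    codes = _relabel(inv)
    for _ in range(order):
        new = []
        for atom in mol.GetAtoms():
            nb = tuple(sorted(codes[x.GetIdx()] for x in atom.GetNeighbors()))
            new.append((codes[atom.GetIdx()], nb))
        codes = _relabel(new)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / n
    ic = float(-(p * np.log2(p)).sum())
    if variant == "IC":
        return ic
    if variant == "CIC":
        return math.log2(n) - ic
    raise UsageError(f"unknown information-content variant {variant!r}")


def _relabel(invariants: Sequence) -> list[int]:
    # first-seen integer labels; the induced partition (all that matters for
    # the entropy and for further refinement) is invariant to atom order
    mapping: dict = {}
    out = []
    for v in invariants:
        if v not in mapping:
            mapping[v] = len(mapping)
        out.append(mapping[v])
    return out


# --------------------------------------------------------------------------
# geometrical descriptors (all atoms, embedded conformer)
# --------------------------------------------------------------------------
def _all_atom_weights(structure: MolecularStructure, scheme: str) -> np.ndarray:
    return atom_weights(structure.mol, scheme)


def whim_directional(structure: MolecularStructure, weight: str, index: str) -> float:
    """WHIM directional descriptor: L1 (size) or E1 (accessibility).

    Eigen-decomposition of the weighted covariance of centered coordinates
    (weights carbon-relative, normalized to sum 1).  L1 is the leading
    eigenvalue; E1 is the inverse kurtosis of the axis-1 scores,
    E1 = lambda_1^2 * A / sum_i t_i1^4.  Both are rigid-motion invariant.
    """
    X = structure.coords
    n = X.shape[0]
    w = _all_atom_weights(structure, weight)
    w = w / w.sum()
    center = w @ X
    Xc = X - center
    if np.allclose(Xc, 0.0):
        raise DomainError("degenerate geometry: all atoms coincident")
    S = (Xc * w[:, None]).T @ Xc
    vals, vecs = np.linalg.eigh(S)
    lam1 = float(vals[-1])
    if index == "L1":
        return lam1
    if index == "E1":
        t = Xc @ vecs[:, -1]
        return lam1**2 * n / float((t**4).sum())
    raise UsageError(f"unknown WHIM index {index!r}; expected L1 or E1")


def _leverages(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    H = Xc @ np.linalg.pinv(Xc.T @ Xc) @ Xc.T
    return np.clip(np.diag(H), 0.0, 1.0)


def getaway_index(
    structure: MolecularStructure, weight: str, family: str, lag: int = 0
) -> float:
    """GETAWAY descriptors from the molecular influence (leverage) matrix.

    With leverages h_i from H = M(M'M)^-1 M' of centered coordinates and
    carbon-relative weights w, pairs at topological distance ``lag``:

    * ``R``:     sum sqrt(h_i h_j)/r_ij * w_i w_j
    * ``HATS``:  sum (h_i w_i)(h_j w_j)
    * ``H``:     sum h_i h_j w_i w_j
    * ``R+``:    max of the R pair terms at that lag
    * ``RT+``:   max of the R pair terms over all pairs (lag ignored)

    A lag beyond the topological diameter yields 0 (empty sum).
    """
    X = structure.coords
    n = X.shape[0]
    if n < 2:
        raise DomainError("need at least 2 atoms")
    h = _leverages(X)
    w = atom_weights(structure.mol, weight)
    D = np.asarray(Chem.GetDistanceMatrix(structure.mol))
    G = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    iu = np.triu_indices(n, k=1)
    rterm = np.sqrt(h[iu[0]] * h[iu[1]]) / G[iu] * w[iu[0]] * w[iu[1]]
    if family == "RT+":
        return float(rterm.max(initial=0.0))
    at_lag = D[iu] == lag
    if family == "R":
        return float(rterm[at_lag].sum())
    if family == "R+":
        return float(rterm[at_lag].max(initial=0.0))
    if family == "HATS":
        return float(((h * w)[iu[0]] * (h * w)[iu[1]])[at_lag].sum())
    if family == "H":
        return float((h[iu[0]] * h[iu[1]] * w[iu[0]] * w[iu[1]])[at_lag].sum())
    raise UsageError(f"unknown GETAWAY family {family!r}")


def comma2_displacement(structure: MolecularStructure, weight: str = "e") -> float:
    """COMMA2 displacement: distance between the geometric and the
    property-weighted centroid (default weights: Sanderson electronegativity).
    """
    X = structure.coords
    w = atom_weights(structure.mol, weight)
    if w.sum() <= 0:
        raise DomainError("zero total weight")
    return float(np.linalg.norm(X.mean(axis=0) - (w[:, None] * X).sum(axis=0) / w.sum()))


def rdf_descriptor(
    structure: MolecularStructure, radius_index: int, weight: str = "u", beta: float = RDF_BETA
) -> float:
    """Radial distribution function descriptor at R = radius_index/10 Angstrom.

    RDF_R(w) = sum_{i<j} w_i w_j exp(-beta (R - r_ij)^2).
    """
    X = structure.coords
    n = X.shape[0]
    w = atom_weights(structure.mol, weight)
    R = radius_index / 10.0
    iu = np.triu_indices(n, k=1)
    r = np.linalg.norm(X[iu[0]] - X[iu[1]], axis=1)
    return float((w[iu[0]] * w[iu[1]] * np.exp(-beta * (R - r) ** 2)).sum())


# --------------------------------------------------------------------------
# constitutional / lipophilicity descriptors
# --------------------------------------------------------------------------
_MORIGUCHI_ELEMENTS = {"H", "C", "N", "O", "F", "Cl", "Br", "I", "S", "P"}
_CX_WEIGHT = {"C": 1.0, "F": 0.5, "Cl": 1.0, "Br": 1.5, "I": 2.0}


def mlogp(structure: MolecularStructure) -> float:
    """Moriguchi estimate of log P (octanol/water) from 13 structural terms.

    MLOGP = -1.041 + 1.244 CX^0.6 - 1.017 NO^0.9 + 0.406 PRX - 0.145 UB^0.8
            + 0.511 HB + 0.268 POL - 2.215 AMP + 0.912 ALK - 0.392 RNG
            - 3.684 QN + 0.474 NO2 + 1.582 NCS + 0.773 BLM

    with CX the halogen-weighted carbon count, NO the N+O count, PRX the N/O
    proximity score, UB the non-nitro unsaturated-bond count on the
    Kekulized graph, and the remaining terms indicator/count features (see
    docs/methods.md for the structural interpretations adopted).
    """
    heavy = structure.heavy_mol
    symbols = [a.GetSymbol() for a in heavy.GetAtoms()]
    outside = set(symbols) - _MORIGUCHI_ELEMENTS
    if outside:
        raise DomainError(f"element(s) {sorted(outside)} outside the MLOGP parameterization")

    cx = sum(_CX_WEIGHT.get(s, 0.0) for s in symbols)
    no = sum(1 for s in symbols if s in ("N", "O"))

    D = np.asarray(Chem.GetDistanceMatrix(heavy))
    no_idx = [i for i, s in enumerate(symbols) if s in ("N", "O")]
    prx = 0.0
    for a in range(len(no_idx)):
        for b in range(a + 1, len(no_idx)):
            d = D[no_idx[a], no_idx[b]]
            if d == 1:
                prx += 2.0
            elif d == 2:
                prx += 1.0
    # carboxamide / ester correction: the two oxygens (or O and N) of the
    # group sit at distance 2 but act as one polar center
    for smarts in ("[CX3](=O)[OX2]", "[CX3](=O)[NX3]"):
        prx -= len(heavy.GetSubstructMatches(Chem.MolFromSmarts(smarts)))

    kek = Chem.Mol(heavy)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    nitro = Chem.MolFromSmarts("[N+](=O)[O-]")
    nitro_bonds = set()
    for match in kek.GetSubstructMatches(nitro):
        for i in match:
            for b in kek.GetAtomWithIdx(i).GetBonds():
                nitro_bonds.add(b.GetIdx())
    ub = sum(
        1
        for b in kek.GetBonds()
        if b.GetBondType() in (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE)
        and b.GetIdx() not in nitro_bonds
    )

    hb = 1.0 if _has_intramolecular_hbond(heavy) else 0.0
    pol = _aromatic_polar_substituents(heavy)
    amp = _amphoteric_score(heavy)
    alk = 1.0 if _is_alkane_alkene(heavy) else 0.0
    rng = 1.0 if _has_nonbenzenoid_ring(heavy) else 0.0
    qn = _quaternary_n_score(heavy)
    no2 = len(heavy.GetSubstructMatches(nitro))
    ncs = len(heavy.GetSubstructMatches(Chem.MolFromSmarts("N=C=S"))) + 0.5 * len(
        heavy.GetSubstructMatches(Chem.MolFromSmarts("[SX2]C#N"))
    )
    blm = 1.0 if heavy.HasSubstructMatch(Chem.MolFromSmarts("[CX3]1(=O)[NX3][CX4][CX4]1")) else 0.0

    return (
        -1.041
        + 1.244 * cx**0.6
        - 1.017 * no**0.9
        + 0.406 * prx
        - 0.145 * ub**0.8
        + 0.511 * hb
        + 0.268 * pol
        - 2.215 * amp
        + 0.912 * alk
        - 0.392 * rng
        - 3.684 * qn
        + 0.474 * no2
        + 1.582 * ncs
        + 0.773 * blm
    )


def _has_intramolecular_hbond(mol: Chem.Mol) -> bool:
    # donor and acceptor substituents on ortho ring atoms of the same aromatic ring
    donors = {
        m[0] for m in mol.GetSubstructMatches(Chem.MolFromSmarts("[OX2H1,NX3H1,NX3H2]"))
    }
    acceptors = {m[0] for m in mol.GetSubstructMatches(Chem.MolFromSmarts("[OX1,OX2,NX2,NX3]"))}
    for ring in mol.GetRingInfo().AtomRings():
        if not all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            continue
        ring_set = set(ring)
        subst: dict[int, list[int]] = {}
        for i in ring:
            for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                if nb.GetIdx() not in ring_set:
                    subst.setdefault(i, []).append(nb.GetIdx())
        ring_list = list(ring)
        n = len(ring_list)
        for a in range(n):
            for b in range(n):
                if a == b:
                    continue
                i, j = ring_list[a], ring_list[b]
                if not mol.GetBondBetweenAtoms(i, j):
                    continue  # only ortho pairs
                for d in subst.get(i, []):
                    for acc in subst.get(j, []):
                        if d in donors and acc in acceptors and d != acc:
                            return True
    return False


def _aromatic_polar_substituents(mol: Chem.Mol) -> float:
    """Count polar substituents attached to aromatic ring atoms."""
    count = 0
    for atom in mol.GetAtoms():
        if not atom.GetIsAromatic():
            continue
        for nb in atom.GetNeighbors():
            if nb.GetIsAromatic():
                continue
            sym = nb.GetSymbol()
            if sym in ("N", "O", "F", "Cl", "Br", "I", "S"):
                count += 1
            elif sym == "C":
                # carbon substituent carrying a multiple bond to N or O (C=O, C#N)
                for b in nb.GetBonds():
                    other = b.GetOtherAtom(nb)
                    if other.GetIdx() == atom.GetIdx():
                        continue
                    if b.GetBondTypeAsDouble() >= 2 and other.GetSymbol() in ("N", "O"):
                        count += 1
                        break
    return float(count)


def _amphoteric_score(mol: Chem.Mol) -> float:
    if mol.HasSubstructMatch(Chem.MolFromSmarts("[NX3;H2,H1][CX4][CX3](=O)[OX2H1,OX1-]")):
        return 1.0
    if mol.HasSubstructMatch(Chem.MolFromSmarts("[NX3;H2,H1]c1ccccc1")) and mol.HasSubstructMatch(
        Chem.MolFromSmarts("c[CX3](=O)[OX2H1,OX1-]")
    ):
        return 0.5
    if mol.HasSubstructMatch(Chem.MolFromSmarts("n")) and mol.HasSubstructMatch(
        Chem.MolFromSmarts("c[CX3](=O)[OX2H1,OX1-]")
    ):
        return 0.5
    return 0.0


def _is_alkane_alkene(mol: Chem.Mol) -> bool:
    if any(a.GetSymbol() != "C" for a in mol.GetAtoms()):
        return False
    if mol.GetRingInfo().NumRings() > 0:
        return False
    n_double = sum(1 for b in mol.GetBonds() if b.GetBondType() == Chem.BondType.DOUBLE)
    n_triple = sum(1 for b in mol.GetBonds() if b.GetBondType() == Chem.BondType.TRIPLE)
    return n_triple == 0 and n_double <= 1


def _has_nonbenzenoid_ring(mol: Chem.Mol) -> bool:
    for ring in mol.GetRingInfo().AtomRings():
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        if not (
            len(ring) == 6
            and all(a.GetIsAromatic() and a.GetSymbol() == "C" for a in atoms)
        ):
            return True
    return False


def _quaternary_n_score(mol: Chem.Mol) -> float:
    score = 0.0
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "N":
            continue
        if atom.GetDegree() == 4:
            score += 1.0
        elif atom.GetFormalCharge() == 1 and any(
            nb.GetSymbol() == "O" and nb.GetFormalCharge() == -1 for nb in atom.GetNeighbors()
        ):
            score += 0.5  # N-oxide (incl. nitro N)
    return score


def blta96(structure: MolecularStructure) -> float:
    """Baseline algae toxicity estimate: an affine transform of MLOGP."""
    return BLTA96_SLOPE * mlogp(structure) + BLTA96_INTERCEPT


def mlogp_blta96(structure: MolecularStructure) -> tuple[float, float]:
    m = mlogp(structure)
    return m, BLTA96_SLOPE * m + BLTA96_INTERCEPT


def group_counts(structure: MolecularStructure) -> dict[str, int]:
    """Aromatic substitution and unsaturation counts: nCb-, nPyridines, nDB.

    nCb-: aromatic carbons of six-membered carbocyclic aromatic rings bearing
    a non-hydrogen substituent (ring-fusion carbons count as substituted).
    nPyridines: six-membered aromatic rings with exactly one ring nitrogen.
    nDB: non-aromatic double bonds.
    """
    heavy = structure.heavy_mol
    rings = heavy.GetRingInfo().AtomRings()

    ncb = set()
    for ring in rings:
        atoms = [heavy.GetAtomWithIdx(i) for i in ring]
        if len(ring) != 6 or not all(a.GetIsAromatic() and a.GetSymbol() == "C" for a in atoms):
            continue
        ring_set = set(ring)
        for i in ring:
            if any(nb.GetIdx() not in ring_set for nb in heavy.GetAtomWithIdx(i).GetNeighbors()):
                ncb.add(i)

    npyr = 0
    for ring in rings:
        atoms = [heavy.GetAtomWithIdx(i) for i in ring]
        if len(ring) == 6 and all(a.GetIsAromatic() for a in atoms):
            syms = [a.GetSymbol() for a in atoms]
            if syms.count("N") == 1 and syms.count("C") == 5:
                npyr += 1

    ndb = sum(
        1
        for b in heavy.GetBonds()
        if b.GetBondType() == Chem.BondType.DOUBLE and not b.GetIsAromatic()
    )
    return {"nCb-": len(ncb), "nPyridines": npyr, "nDB": ndb}


# --------------------------------------------------------------------------
# named-descriptor dispatch and matrix assembly
# --------------------------------------------------------------------------
_NAME_PATTERNS: list[tuple[re.Pattern, Callable[[MolecularStructure, re.Match], float]]] = []


def _register(pattern: str):
    def deco(fn):
        _NAME_PATTERNS.append((re.compile(pattern), fn))
        return fn

    return deco


@_register(r"^(JGI|GGI)(\d+)$")
def _d_jgi(s, m):
    return topological_charge_index(s, int(m.group(2)), mean=m.group(1) == "JGI")


@_register(r"^(BEH|BEL)([umepv])(\d+)$")
def _d_burden(s, m):
    end = "highest" if m.group(1) == "BEH" else "lowest"
    return burden_eigenvalue(s, m.group(2), int(m.group(3)), end=end)


@_register(r"^EEig(\d+)([xrd])$")
def _d_eeig(s, m):
    return edge_adjacency_eigenvalue(s, m.group(2), int(m.group(1)))


@_register(r"^(C?IC)(\d+)$")
def _d_ic(s, m):
    return information_content(s, int(m.group(2)), variant=m.group(1))


@_register(r"^(L1|E1)([umepv])$")
def _d_whim(s, m):
    return whim_directional(s, m.group(2), m.group(1))


@_register(r"^RT([umepv])\+$")
def _d_rtplus(s, m):
    return getaway_index(s, m.group(1), "RT+")


@_register(r"^R(\d+)([umepv])(\+?)$")
def _d_r(s, m):
    fam = "R+" if m.group(3) else "R"
    return getaway_index(s, m.group(2), fam, int(m.group(1)))


@_register(r"^HATS(\d+)([umepv])$")
def _d_hats(s, m):
    return getaway_index(s, m.group(2), "HATS", int(m.group(1)))


@_register(r"^H(\d+)([umepv])$")
def _d_hk(s, m):
    return getaway_index(s, m.group(2), "H", int(m.group(1)))


@_register(r"^RDF(\d+)([ume])$")
def _d_rdf(s, m):
    return rdf_descriptor(s, int(m.group(1)), m.group(2))


@_register(r"^DISP([umepv])$")
def _d_disp(s, m):
    return comma2_displacement(s, m.group(1))


@_register(r"^MLOGP$")
def _d_mlogp(s, m):
    return mlogp(s)


@_register(r"^(BLTA96|BELTA96)$")  # the printed equation spells it BELTA96
def _d_blta(s, m):
    return blta96(s)


@_register(r"^nCb-$")
def _d_ncb(s, m):
    return float(group_counts(s)["nCb-"])


@_register(r"^nPyridines$")
def _d_npyr(s, m):
    return float(group_counts(s)["nPyridines"])


@_register(r"^nDB$")
def _d_ndb(s, m):
    return float(group_counts(s)["nDB"])


def descriptor_value(structure: MolecularStructure, name: str) -> float:
    """Compute a descriptor by its conventional name (e.g. 'JGI10', 'BEHe6')."""
    for pattern, fn in _NAME_PATTERNS:
        m = pattern.match(name)
        if m:
            return float(fn(structure, m))
    raise UsageError(f"unknown descriptor name {name!r}")


@dataclass
class DescriptorMatrix:
    """Compounds x descriptors value grid with pruning provenance."""

    compound_ids: list[str]
    names: list[str]
    values: np.ndarray
    pruned: dict[str, str] = field(default_factory=dict)
    failed_compounds: dict[str, str] = field(default_factory=dict)
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.compound_ids, columns=self.names)

    def active_frame(self) -> pd.DataFrame:
        keep = [n for n in self.names if n not in self.pruned]
        return self.to_frame()[keep]

    def pruning_report(self) -> dict[str, str]:
        return dict(self.pruned)


def _prune_reason(col: np.ndarray, near_constant_fraction: float) -> str | None:
    if np.all(col == col[0]):
        return "constant"
    if np.std(col) < 1e-12:
        return "zero-std"
    _, counts = np.unique(col, return_counts=True)
    if counts.max() / len(col) > near_constant_fraction:
        return "near-constant"
    return None


def compute_matrix(
    table: CompoundTable,
    descriptor_set: Sequence[str] | None = None,
    seed: int = DEFAULT_EMBED_SEED,
    near_constant_fraction: float = 0.95,
) -> DescriptorMatrix:
    """Compute a named descriptor set for every compound of a table.

    One conformer is embedded per compound (deterministic for a fixed seed).
    Compounds whose structure fails to embed or whose descriptors cannot be
    evaluated are excluded from the matrix and reported in
    ``failed_compounds``.  Columns that are constant, have zero standard
    deviation, or are near-constant (more than ``near_constant_fraction``
    identical values) are flagged as pruned with their reason.
    """
    names = list(descriptor_set) if descriptor_set is not None else list(CORE_DESCRIPTORS)
    needs_3d = any(
        re.match(r"^(L1|E1|R\d|RT|HATS|H\d|RDF|DISP)", n) for n in names
    )
    ids, rows = [], []
    failed: dict[str, str] = {}
    for rec in table:
        try:
            struct = MolecularStructure.from_smiles(rec.smiles)
            if needs_3d:
                struct = embed_conformer(struct, seed=seed)
                if struct.embed_failed:
                    raise DomainError("3D embedding failed")
            rows.append([descriptor_value(struct, n) for n in names])
            ids.append(rec.compound_id)
        except Exception as exc:  # noqa: BLE001 - per-compound isolation
            failed[rec.compound_id] = str(exc)
    if not rows:
        raise DomainError("no compound yielded a descriptor row")
    values = np.asarray(rows, dtype=float)
    pruned = {}
    for j, name in enumerate(names):
        reason = _prune_reason(values[:, j], near_constant_fraction)
        if reason:
            pruned[name] = reason
    return DescriptorMatrix(
        compound_ids=ids,
        names=names,
        values=values,
        pruned=pruned,
        failed_compounds=failed,
        seed=seed,
    )
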