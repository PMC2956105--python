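import math

import numpy as np
import pytest
from rdkit import Chem

import oracles
from erqsar import descriptors as d
from erqsar.errors import DomainError, UsageError
from erqsar.structures import MolecularStructure, atom_property, embed_conformer


def _rigid_motion(structure, seed=0):
    """Copy of a structure with randomly rotated + translated coordinates."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    shift = rng.uniform(-5, 5, 3)
    mol = Chem.Mol(structure.mol)
    conf = mol.GetConformer()
    X = structure.coords @ Q.T + shift
    for i, pos in enumerate(X):
        conf.SetAtomPosition(i, pos.tolist())
    return MolecularStructure(mol=mol, embed_seed=structure.embed_seed)


def _permuted(structure, seed=0):
    rng = np.random.default_rng(seed)
    mol = Chem.RemoveHs(structure.mol)
    order = [int(i) for i in rng.permutation(mol.GetNumAtoms())]
    renum = Chem.RenumberAtoms(mol, order)
    return MolecularStructure(mol=Chem.AddHs(renum))


class TestEmbedding:
    def test_benzene_planar(self):
        s = embed_conformer(MolecularStructure.from_smiles("c1ccccc1"), seed=7)
        heavy = s.coords[:6]
        _, sv, _ = np.linalg.svd(heavy - heavy.mean(axis=0))
        assert sv[-1] < 0.1

    def test_deterministic_for_fixed_seed(self):
        a = embed_conformer(MolecularStructure.from_smiles("OCCc1ccccc1"), seed=3)
        b = embed_conformer(MolecularStructure.from_smiles("OCCc1ccccc1"), seed=3)
        assert np.array_equal(a.coords, b.coords)

    def test_fixture_compound_bond_lengths_sane(self, fixture_table):
        rec = fixture_table["compound36"]
        s = embed_conformer(MolecularStructure.from_smiles(rec.smiles))
        X = s.coords
        for bond in s.mol.GetBonds():
            i, j = bond.GetBeginAtom(), bond.GetEndAtom()
            if i.GetSymbol() == "H" or j.GetSymbol() == "H":
                continue
            length = np.linalg.norm(X[i.GetIdx()] - X[j.GetIdx()])
            assert 1.2 <= length <= 1.6


class TestBruteForceEquivalence:
    """Every descriptor equals an explicit-loop evaluation of its definition."""

    def test_topological_charge_vs_oracle(self, small_structures):
        for name, s in small_structures.items():
            for order in (1, 2, 3):
                assert d.topological_charge_index(s, order) == pytest.approx(
                    oracles.brute_ggi(s, order), abs=1e-10
                ), name
                assert d.topological_charge_index(s, order, mean=True) == pytest.approx(
                    oracles.brute_ggi(s, order, mean=True), abs=1e-10
                )

    def test_burden_vs_oracle(self, small_structures):
        for name, s in small_structures.items():
            n = s.heavy_mol.GetNumAtoms()
            for scheme in ("u", "m", "e", "p", "v"):
                for k in range(1, min(n, 3) + 1):
                    for end in ("highest", "lowest"):
                        assert d.burden_eigenvalue(s, scheme, k, end) == pytest.approx(
                            oracles.brute_burden(s, atom_property, scheme, k, end),
                            abs=1e-10,
                        ), (name, scheme, k, end)

    def test_edge_adjacency_vs_oracle(self, small_structures):
        for name, s in small_structures.items():
            m = s.heavy_mol.GetNumBonds()
            for weight in ("x", "r", "d"):
                for k in range(1, min(m, 3) + 1):
                    assert d.edge_adjacency_eigenvalue(s, weight, k) == pytest.approx(
                        oracles.brute_eeig(s, atom_property, weight, k), abs=1e-10
                    ), (name, weight, k)

    def test_information_content_vs_oracle(self, small_structures):
        for name, s in small_structures.items():
            for order in (0, 1, 2):
                for variant in ("IC", "CIC"):
                    assert d.information_content(s, order, variant) == pytest.approx(
                        oracles.brute_ic(s, order, variant), abs=1e-10
                    ), (name, order, variant)

    def test_whim_vs_oracle(self, small_structures):
        for name, s in small_structures.items():
            for scheme in ("u", "m", "e", "p"):
                for index in ("L1", "E1"):
                    assert d.whim_directional(s, scheme, index) == pytest.approx(
                        oracles.brute_whim(s, atom_property, scheme, index), abs=1e-10
                    ), (name, scheme, index)

    def test_getaway_vs_oracle(self, small_structures):
        for name, s in small_structures.items():
            for scheme in ("u", "e"):
                for family, lag in (("R", 1), ("R", 2), ("HATS", 2), ("H", 1), ("R+", 1), ("RT+", 0)):
                    assert d.getaway_index(s, scheme, family, lag) == pytest.approx(
                        oracles.brute_getaway(s, atom_property, scheme, family, lag),
                        abs=1e-10,
                    ), (name, scheme, family, lag)

    def test_rdf_and_dispe_vs_oracle(self, small_structures):
        for name, s in small_structures.items():
            for idx in (10, 15, 25):
                assert d.rdf_descriptor(s, idx, "m") == pytest.approx(
                    oracles.brute_rdf(s, atom_property, idx, "m", d.RDF_BETA), abs=1e-10
                ), name
            assert d.comma2_displacement(s) == pytest.approx(
                oracles.brute_dispe(s, atom_property), abs=1e-10
            )


class TestClosedForms:
    def test_benzene_symmetry_kills_charge_terms(self):
        benzene = MolecularStructure.from_smiles("c1ccccc1")
        for k in (1, 2, 3):
            assert d.topological_charge_index(benzene, k) == pytest.approx(0.0, abs=1e-12)

    def test_jgi_beyond_diameter_is_zero(self):
        pentane = MolecularStructure.from_smiles("CCCCC")
        assert d.topological_charge_index(pentane, 10, mean=True) == 0.0

    def test_burden_ethane_closed_form(self):
        ethane = MolecularStructure.from_smiles("CC")
        # 2x2 matrix [[1, .1], [.1, 1]] -> eigenvalues 0.9 and 1.1
        assert d.burden_eigenvalue(ethane, "m", 1, "highest") == pytest.approx(1.1)
        assert d.burden_eigenvalue(ethane, "m", 1, "lowest") == pytest.approx(0.9)

    def test_eeig_propane_closed_form(self):
        propane = MolecularStructure.from_smiles("CCC")
        # two adjacent single bonds, edge degree diagonal = 1 -> eigenvalues 1 +- 1
        assert d.edge_adjacency_eigenvalue(propane, "x", 1) == pytest.approx(2.0)
        assert d.edge_adjacency_eigenvalue(propane, "x", 2) == pytest.approx(0.0, abs=1e-12)

    def test_ic_benzene_hand_entropy(self):
        benzene = MolecularStructure.from_smiles("c1ccccc1")
        assert d.information_content(benzene, 2, "IC") == pytest.approx(1.0)
        assert d.information_content(benzene, 2, "CIC") == pytest.approx(math.log2(12) - 1)

    def test_ic_entropy_bounds(self, small_structures):
        for s in small_structures.values():
            n = s.mol.GetNumAtoms()
            for order in (0, 1, 2):
                ic = d.information_content(s, order, "IC")
                assert -1e-12 <= ic <= math.log2(n) + 1e-12

    def test_burden_rank_error(self):
        ethane = MolecularStructure.from_smiles("CC")
        with pytest.raises(DomainError):
            d.burden_eigenvalue(ethane, "m", 3)

    def test_getaway_beyond_diameter_zero(self, small_structures):
        s = small_structures["ethane"]
        assert d.getaway_index(s, "u", "R", 40) == 0.0

    def test_trace_of_influence_matrix_is_coordinate_rank(self, small_structures):
        s = small_structures["n-pentane"]
        Xc = s.coords - s.coords.mean(axis=0)
        H = Xc @ np.linalg.pinv(Xc.T @ Xc) @ Xc.T
        assert np.trace(H) == pytest.approx(np.linalg.matrix_rank(Xc))


class TestInvariances:
    @pytest.mark.parametrize("name", ["JGI10", "BEHe6", "BEHm5", "EEig03r", "CIC2", "nCb-", "MLOGP"])
    def test_2d_descriptors_invariant_to_atom_permutation(self, fixture_table, name):
        for cid in ("compound1", "compound43", "compound82"):
            s = MolecularStructure.from_smiles(fixture_table[cid].smiles)
            p = _permuted(s, seed=hash(cid) % 2**31)
            ref = d.descriptor_value(s, name)
            assert d.descriptor_value(p, name) == pytest.approx(ref, abs=1e-9), cid

    @pytest.mark.parametrize("name", ["E1p", "R4u", "DISPe", "RDF015m", "HATS5e"])
    def test_3d_descriptors_invariant_to_rigid_motion(self, small_structures, name):
        s = small_structures["acetamide"]
        moved = _rigid_motion(s, seed=5)
        assert d.descriptor_value(moved, name) == pytest.approx(
            d.descriptor_value(s, name), abs=1e-8
        )

    def test_beh_sequence_non_increasing(self, fixture_table):
        s = MolecularStructure.from_smiles(fixture_table["compound1"].smiles)
        vals = [d.burden_eigenvalue(s, "e", k) for k in range(1, 7)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestMlogp:
    def test_ordering_hexane_benzene_phenol(self):
        vals = {
            smi: d.mlogp(MolecularStructure.from_smiles(smi))
            for smi in ("CCCCCC", "c1ccccc1", "Oc1ccccc1")
        }
        assert vals["CCCCCC"] > vals["c1ccccc1"] > vals["Oc1ccccc1"]

    def test_hydroxyl_decreases_mlogp(self):
        pairs = [("CCCCCC", "OCCCCCC"), ("c1ccccc1", "Oc1ccccc1"), ("CCC", "CCCO")]
        for base, with_oh in pairs:
            assert d.mlogp(MolecularStructure.from_smiles(with_oh)) < d.mlogp(
                MolecularStructure.from_smiles(base)
            )

    def test_blta96_affine_in_mlogp(self, fixture_table):
        ms = [d.mlogp_blta96(MolecularStructure.from_smiles(r.smiles)) for r in fixture_table.records[:20]]
        m, b = np.array([x[0] for x in ms]), np.array([x[1] for x in ms])
        assert np.corrcoef(m, b)[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_element_outside_parameterization_flagged(self):
        silane = MolecularStructure.from_smiles("C[Si](C)(C)C")
        with pytest.raises(DomainError):
            d.mlogp(silane)


class TestGroupCounts:
    def test_benzene_and_toluene(self):
        assert d.group_counts(MolecularStructure.from_smiles("c1ccccc1"))["nCb-"] == 0
        assert d.group_counts(MolecularStructure.from_smiles("Cc1ccccc1"))["nCb-"] == 1

    def test_quinoline_ring_counts(self, fixture_table):
        c43 = MolecularStructure.from_smiles(fixture_table["compound43"].smiles)
        assert d.group_counts(c43)["nPyridines"] == 1

    def test_genistein_has_nonaromatic_double_bonds(self, fixture_table):
        c82 = MolecularStructure.from_smiles(fixture_table["compound82"].smiles)
        assert d.group_counts(c82)["nDB"] >= 1


class TestMatrix:
    def test_fixture_core_matrix_shape_and_no_nan(self, core_matrix):
        assert core_matrix.values.shape == (82, 11)
        active = core_matrix.active_frame()
        assert not active.isna().any().any()
        assert core_matrix.failed_compounds == {}

    def test_constant_column_pruned(self, fixture_table):
        from erqsar.dataset import CompoundTable

        naphthalenes = CompoundTable(
            [r for r in fixture_table.records if "n" not in r.smiles.replace("nan", "")][:12]
        )
        m = d.compute_matrix(naphthalenes, ["nPyridines", "JGI10"])
        assert m.pruned.get("nPyridines") in ("constant", "near-constant", "zero-std")

    def test_deterministic_under_seed(self, fixture_table):
        from erqsar.dataset import CompoundTable

        sub = CompoundTable(fixture_table.records[:5])
        a = d.compute_matrix(sub, ["E1p", "R4u"], seed=99)
        b = d.compute_matrix(sub, ["E1p", "R4u"], seed=99)
        assert np.array_equal(a.values, b.values)

    def test_unknown_descriptor_name(self):
        s = MolecularStructure.from_smiles("CCO")
        with pytest.raises(UsageError):
            d.descriptor_value(s, "NOPE42")
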