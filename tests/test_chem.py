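import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from _oracles import bfs_ball, morgan_identifier_count
from salqsar import chem


class TestParseSmiles:
    @pytest.mark.parametrize(
        "smiles, n_atoms, n_bonds",
        [("C", 1, 0), ("CCO", 3, 2), ("c1ccccc1", 6, 6)],
    )
    def test_atom_and_bond_counts(self, smiles, n_atoms, n_bonds):
        g = chem.parse_smiles(smiles)
        assert g.n_atom == n_atoms
        assert len(g.bonds) == n_bonds

    def test_benzene_is_fully_aromatic(self):
        g = chem.parse_smiles("c1ccccc1")
        assert all(a.aromatic for a in g.atoms)

    @pytest.mark.parametrize("bad", ["", "  ", "C(", "C(C)(C)(C)(C)C", "not-smiles"])
    def test_invalid_smiles_raise_named_error(self, bad):
        with pytest.raises(chem.SmilesParseError):
            chem.parse_smiles(bad)

    def test_atom_indices_follow_input_order(self):
        g = chem.parse_smiles("OCC")  # O first in the string -> atom 0
        assert g.atoms[0].element == "O"
        assert g.atoms[1].element == "C"


class TestEcfp4:
    def test_invariant_to_atom_order_spelling(self):
        assert chem.ecfp4_from_smiles("CCO") == chem.ecfp4_from_smiles("OCC")

    def test_single_atom_sets_a_bit(self):
        assert chem.ecfp4_from_smiles("C").popcount >= 1

    def test_pentane_popcount_matches_morgan_oracle(self):
        # independent radius-2 Morgan identifier loop: 7 distinct environments
        assert morgan_identifier_count("CCCCC") == 7
        assert chem.ecfp4_from_smiles("CCCCC").popcount == 7

    @pytest.mark.parametrize(
        "smiles", ["CCO", "c1ccccc1", "CC(=O)N", "S(=O)(=O)N", "c1ccncc1CC"]
    )
    def test_popcount_matches_morgan_oracle(self, smiles):
        assert chem.ecfp4_from_smiles(smiles).popcount == morgan_identifier_count(
            smiles
        )

    def test_invariant_under_random_renumbering(self):
        base = "CC(=O)Nc1ccc(S(N)(=O)=O)cc1"
        ref = chem.ecfp4_from_smiles(base)
        mol = Chem.MolFromSmiles(base)
        rng = np.random.default_rng(0)
        for _ in range(100):
            perm = rng.permutation(mol.GetNumAtoms()).tolist()
            renum = Chem.RenumberAtoms(mol, perm)
            smiles = Chem.MolToSmiles(renum, canonical=False)
            assert chem.ecfp4_from_smiles(smiles) == ref


class TestTanimoto:
    def test_handbuilt_examples(self):
        fp = lambda bits: chem.BitFingerprint(frozenset(bits), 16)
        assert chem.tanimoto(fp({1, 2, 3}), fp({2, 3, 4})) == 0.5
        assert chem.tanimoto(fp({1}), fp({2})) == 0.0
        assert chem.tanimoto(fp(set()), fp(set())) == 1.0

    def test_mismatched_lengths_raise(self):
        a = chem.BitFingerprint(frozenset({1}), 16)
        b = chem.BitFingerprint(frozenset({1}), 32)
        with pytest.raises(ValueError):
            chem.tanimoto(a, b)

    @given(
        a=st.sets(st.integers(0, 63)),
        b=st.sets(st.integers(0, 63)),
    )
    @settings(deadline=None, derandomize=True)
    def test_symmetric_bounded_and_reflexive(self, a, b):
        fa = chem.BitFingerprint(frozenset(a), 64)
        fb = chem.BitFingerprint(frozenset(b), 64)
        s = chem.tanimoto(fa, fb)
        assert 0.0 <= s <= 1.0
        assert s == chem.tanimoto(fb, fa)
        assert chem.tanimoto(fa, fa) == 1.0


class TestNeighborhoods:
    def test_methane_is_its_own_neighborhood(self):
        g = chem.parse_smiles("C")
        nb = chem.atom_neighborhood(g, 0)
        assert nb.members == frozenset({0})

    def test_pentane_chain_distances(self):
        g = chem.parse_smiles("CCCCC")
        nb = chem.atom_neighborhood(g, 0, radius=3)
        assert nb.members == frozenset({0, 1, 2, 3})

    def test_benzene_ball_is_whole_ring(self):
        g = chem.parse_smiles("c1ccccc1")
        for center in range(6):
            nb = chem.atom_neighborhood(g, center, radius=3)
            assert nb.members == frozenset(range(6))
            assert nb.fragment_smiles == "c1ccccc1"

    def test_out_of_range_center_raises(self):
        with pytest.raises(IndexError):
            chem.atom_neighborhood(chem.parse_smiles("CC"), 5)

    def test_members_match_bfs_oracle_exhaustively(self, tiny_molecules):
        for smiles in tiny_molecules:
            g = chem.parse_smiles(smiles)
            edges = [(i, j) for i, j, _ in g.bonds]
            for center in range(g.n_atom):
                for radius in (1, 2, 3):
                    expected = bfs_ball(g.n_atom, edges, center, radius)
                    got = chem.atom_neighborhood(g, center, radius).members
                    assert got == frozenset(expected)

    def test_members_equal_bond_distance_ball(self, tiny_molecules):
        for smiles in tiny_molecules:
            g = chem.parse_smiles(smiles)
            for center in range(g.n_atom):
                ball = {
                    b
                    for b in range(g.n_atom)
                    if chem.bond_distance(g, center, b) <= 3
                }
                assert chem.atom_neighborhood(g, center, 3).members == frozenset(ball)


class TestBondDistance:
    def test_self_distance_zero(self):
        assert chem.bond_distance(chem.parse_smiles("CCO"), 1, 1) == 0

    def test_pentane_end_to_end(self):
        assert chem.bond_distance(chem.parse_smiles("CCCCC"), 0, 4) == 4

    def test_disconnected_fragments_are_infinite(self):
        g = chem.parse_smiles("CC.O")
        assert math.isinf(chem.bond_distance(g, 0, 2))

    def test_symmetry(self, tiny_molecules):
        for smiles in tiny_molecules:
            g = chem.parse_smiles(smiles)
            for i in range(g.n_atom):
                for j in range(g.n_atom):
                    assert chem.bond_distance(g, i, j) == chem.bond_distance(g, j, i)
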