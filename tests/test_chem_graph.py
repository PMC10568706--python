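"""Molecular graph model: parsing, valence, editing primitives."""

import pytest
from rdkit import Chem

from fragopt.chem_graph import (
    AtomVocab,
    AttachmentSite,
    DEFAULT_VOCAB,
    InvalidSmilesError,
    MolGraph,
    OutOfVocabError,
    ValenceError,
    attach_fragment,
    bfs_order,
    canonical_smiles,
    enumerate_removals,
    free_valence,
    parse_smiles,
    write_smiles,
)


class TestParseWrite:
    @pytest.mark.parametrize("smiles,n_atoms,n_bonds", [
        ("C", 1, 0),
        ("c1ccccc1", 6, 6),
        ("C1=CC=CC=C1N", 7, 7),
        ("CCO", 3, 2),
        ("N#N", 2, 1),
    ])
    def test_atom_and_bond_counts(self, smiles, n_atoms, n_bonds):
        g = parse_smiles(smiles)
        assert g.n_atoms == n_atoms
        assert len(g.bonds) == n_bonds

    def test_benzene_is_kekulized(self):
        g = parse_smiles("c1ccccc1")
        orders = sorted(g.bonds.values())
        assert orders == [1, 1, 1, 2, 2, 2]

    def test_single_atom_round_trip(self):
        assert write_smiles(parse_smiles("C")) == "C"

    def test_write_matches_rdkit_canonicalizer(self):
        expected = Chem.MolToSmiles(Chem.MolFromSmiles("c1ccccc1"))
        assert write_smiles(parse_smiles("C1=CC=CC=C1")) == expected

    def test_round_trip_is_isomorphism_stable(self, random_molecules):
        for s in random_molecules[:100]:
            g = parse_smiles(s)
            assert parse_smiles(write_smiles(g)) == g

    def test_invalid_smiles_rejected(self):
        with pytest.raises(InvalidSmilesError, match="c1ccc"):
            parse_smiles("c1ccc")  # unclosed ring

    def test_out_of_vocab_element_named_in_error(self):
        with pytest.raises(OutOfVocabError, match="Se"):
            parse_smiles("[Se]")

    def test_charges_and_stereo_are_stripped(self):
        g = parse_smiles("C[NH3+].[Cl-]".split(".")[0])
        assert g.is_valence_valid()
        g2 = parse_smiles("C/C=C/C")
        assert "/" not in write_smiles(g2)

    def test_disconnected_input_rejected(self):
        with pytest.raises(InvalidSmilesError):
            parse_smiles("CC.CC")


class TestValence:
    def test_lone_carbon_has_four(self):
        assert free_valence(parse_smiles("C"), 0) == 4

    def test_benzene_carbon_has_one(self):
        g = parse_smiles("c1ccccc1")
        assert all(free_valence(g, i) == 1 for i in range(6))

    def test_nitrile_nitrogen_is_saturated(self):
        g = parse_smiles("C#N")
        n_idx = next(i for i in range(2) if g.symbol(i) == "N")
        assert free_valence(g, n_idx) == 0

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            free_valence(parse_smiles("C"), 5)

    def test_add_bond_refuses_valence_violation(self):
        g = parse_smiles("C")
        i = g.add_atom(g.vocab.index("F"))
        g.add_bond(0, i, 1)
        j = g.add_atom(g.vocab.index("O"))
        with pytest.raises(ValenceError):
            g.add_bond(i, j, 1)  # F already has its single bond

    def test_custom_vocab_rejects_missing_valence(self):
        with pytest.raises(ValueError):
            AtomVocab(("C", "N"), (4,))


class TestEnumerateRemovals:
    def test_ring_only_molecule_has_none(self):
        assert enumerate_removals(parse_smiles("c1ccccc1")) == []

    def test_ethylbenzene_children(self):
        children = {c.canonical() for c in enumerate_removals(parse_smiles("CCc1ccccc1"))}
        assert children == {canonical_smiles("Cc1ccccc1"),
                            canonical_smiles("c1ccccc1")}

    def test_ethane_tie_keeps_lexicographically_first(self):
        children = enumerate_removals(parse_smiles("CC"))
        assert [c.canonical() for c in children] == ["C"]

    def test_double_bonds_never_cut(self):
        # C=C is the only disconnecting bond but is not single
        assert enumerate_removals(parse_smiles("C=C")) == []

    def _oracle(self, smiles):
        """Brute force with RDKit only: delete each single acyclic bond.

        Works on the kekulized molecule and refills cut sites with implicit
        hydrogens (the package's hydrogen convention).
        """
        mol = Chem.MolFromSmiles(smiles)
        Chem.Kekulize(mol, clearAromaticFlags=True)
        out = set()
        for bond in mol.GetBonds():
            if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
                continue
            em = Chem.RWMol(mol)
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            em.RemoveBond(i, j)
            for idx in (i, j):
                atom = em.GetAtomWithIdx(idx)
                atom.SetNumExplicitHs(0)
                atom.SetNoImplicit(False)
            frags = Chem.GetMolFrags(em.GetMol(), asMols=True,
                                     sanitizeFrags=True)
            if len(frags) != 2:
                continue
            a, b = frags
            if a.GetNumAtoms() != b.GetNumAtoms():
                keep = a if a.GetNumAtoms() > b.GetNumAtoms() else b
                out.add(Chem.MolToSmiles(keep))
            else:
                out.add(min(Chem.MolToSmiles(a), Chem.MolToSmiles(b)))
        return out

    def test_matches_brute_force_oracle(self, random_molecules):
        for s in random_molecules:
            got = {c.canonical() for c in enumerate_removals(parse_smiles(s))}
            assert got == self._oracle(s), s


class TestAttachFragment:
    def test_methyl_onto_benzene(self):
        parent = parse_smiles("c1ccccc1")
        frag = parse_smiles("C")
        out = attach_fragment(parent, frag, AttachmentSite(0, 0))
        assert out.canonical() == canonical_smiles("Cc1ccccc1")

    def test_carbon_plus_carbon(self):
        out = attach_fragment(parse_smiles("C"), parse_smiles("C"),
                              AttachmentSite(0, 0))
        assert out.canonical() == "CC"

    def test_saturated_site_raises(self):
        parent = parse_smiles("C#N")
        n_idx = next(i for i in range(2) if parent.symbol(i) == "N")
        with pytest.raises(ValenceError):
            attach_fragment(parent, parse_smiles("C"),
                            AttachmentSite(n_idx, 0))

    def test_results_are_valid_over_random_attachments(self, random_molecules):
        import numpy as np
        rng = np.random.default_rng(0)
        frag = parse_smiles("CO")
        for s in random_molecules[:50]:
            parent = parse_smiles(s)
            sites = [i for i in range(parent.n_atoms)
                     if free_valence(parent, i) >= 1]
            if not sites:
                continue
            out = attach_fragment(parent, frag,
                                  AttachmentSite(int(rng.choice(sites)), 0))
            assert out.is_connected() and out.is_valence_valid()
            assert out.n_atoms == parent.n_atoms + 2


class TestBfsOrder:
    def test_single_atom(self):
        assert bfs_order(parse_smiles("C"), 0) == [0]

    def test_path_from_end(self):
        g = MolGraph([0, 0, 0], {(0, 1): 1, (1, 2): 1})
        assert bfs_order(g, 0) == [0, 1, 2]
        assert bfs_order(g, 2) == [2, 1, 0]

    def test_star_ties_break_by_index(self):
        g = MolGraph([0, 0, 0, 0], {(0, 1): 1, (0, 2): 1, (0, 3): 1})
        assert bfs_order(g, 0) == [0, 1, 2, 3]

    def test_root_out_of_range(self):
        with pytest.raises(IndexError):
            bfs_order(parse_smiles("CC"), 7)


def test_every_operation_preserves_valence(random_molecules):
    """Removal children of random molecules are valid connected graphs."""
    for s in random_molecules[:80]:
        for child in enumerate_removals(parse_smiles(s)):
            assert child.is_connected()
            assert child.is_valence_valid()
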