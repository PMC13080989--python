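"""Fragmentation, canonical keys and side-chain substitution."""

import numpy as np
import pytest
from rdkit import Chem

from fragmops.fragment_core import (
    Fragment,
    FragmentLibrary,
    FragmentationError,
    canonical_key,
    fragment_cbu,
    is_cleavage_stable,
    make_asymmetric_linkers,
    substitute_linker,
)


def keyset(frags):
    return sorted(f.smiles for f in frags)


class TestFragmentCBU:
    def test_terephthalate_splits_into_binding_groups_and_phenylene(self):
        frags = fragment_cbu("[O-]C(=O)c1ccc(C(=O)[O-])cc1")
        assert keyset(frags) == ["*C(=O)[O-]", "*C(=O)[O-]", "*c1ccc(*)cc1"]
        types = {f.smiles: f.frag_type for f in frags}
        assert types["*C(=O)[O-]"] == "binding_group"
        assert types["*c1ccc(*)cc1"] == "linker"

    def test_methyl_side_chain_is_extracted_and_parent_reverted_to_h(self):
        frags = fragment_cbu("Cc1cc(C(=O)[O-])ccc1C(=O)[O-]")
        types = {}
        for f in frags:
            types.setdefault(f.frag_type, []).append(f.smiles)
        assert types["side_chain"] == ["*C"]
        # the parent ring fragment gets its H back: plain 1,4-phenylene
        assert types["linker"] == ["*c1ccc(*)cc1"]
        assert sorted(types["binding_group"]) == ["*C(=O)[O-]", "*C(=O)[O-]"]

    def test_molecule_without_cleavable_bond_is_returned_untyped(self):
        frags = fragment_cbu("c1ccccc1")
        assert len(frags) == 1
        assert frags[0].frag_type == "untyped"
        assert frags[0].n_sites == 0
        assert frags[0].smiles == "c1ccccc1"

    def test_disconnected_input_raises(self):
        with pytest.raises(FragmentationError):
            fragment_cbu("CC.CC")

    def test_every_fragment_has_exactly_one_type(self):
        frags = fragment_cbu("Cc1cc(C(=O)[O-])ccc1C(=O)[O-]")
        for f in frags:
            assert f.frag_type in (
                "binding_group", "linker", "node", "side_chain", "untyped"
            )

    def test_pyrazolate_binding_group_is_recognized(self):
        frags = fragment_cbu("c1cc(-c2cn[n-]c2)ccc1-c2cn[n-]c2")
        bg = [f for f in frags if f.frag_type == "binding_group"]
        assert len(bg) == 2
        assert all(f.smiles == canonical_key("*c1cn[n-]c1") for f in bg)

    def test_dummy_count_equals_sites_and_geometry_entries(self):
        for f in fragment_cbu("[O-]C(=O)c1ccc(C(=O)[O-])cc1"):
            n_dummy_graph = f.smiles.count("*")
            n_dummy_geom = sum(1 for row in f.geometry if row[0] == "X")
            assert f.n_sites == n_dummy_graph == n_dummy_geom

    def test_fragmenting_copies_dedups_to_one_library(self):
        lib = FragmentLibrary()
        for _ in range(3):
            lib.update(fragment_cbu("[O-]C(=O)c1ccc(C(=O)[O-])cc1"))
        assert len(lib) == 2  # carboxylate + phenylene
        assert lib.counts_by_type["binding_group"] == 1
        assert lib.counts_by_type["linker"] == 1


class TestCanonicalKey:
    def test_atom_order_invariance(self):
        mol = Chem.MolFromSmiles("*c1ccc(*)cc1")
        renum = Chem.RenumberAtoms(mol, list(reversed(range(mol.GetNumAtoms()))))
        assert canonical_key(mol) == canonical_key(renum)

    def test_distinct_graphs_distinct_keys(self):
        assert canonical_key("*c1ccc(*)cc1") != canonical_key("*c1cccc(*)c1")

    def test_idempotence(self):
        k = canonical_key("*c1ccc(*)cc1")
        assert canonical_key(k) == k

    def test_unparseable_raises(self):
        with pytest.raises(ValueError):
            canonical_key("not-a-smiles((")


class TestSubstituteLinker:
    @staticmethod
    def _graph_substitution_oracle(linker_smiles, side_smiles):
        """Brute-force oracle: graph-edit every ring C-H position and count
        distinct canonical products (independent of the geometric join)."""
        linker = Chem.AddHs(Chem.MolFromSmiles(linker_smiles))
        side = Chem.MolFromSmiles(side_smiles)
        s_dummy = next(
            a.GetIdx() for a in side.GetAtoms() if a.GetAtomicNum() == 0
        )
        s_nbr = side.GetAtomWithIdx(s_dummy).GetNeighbors()[0].GetIdx()
        products = set()
        for atom in linker.GetAtoms():
            if atom.GetAtomicNum() != 6:
                continue
            hs = [nb.GetIdx() for nb in atom.GetNeighbors() if nb.GetAtomicNum() == 1]
            if not hs:
                continue
            combo = Chem.RWMol(Chem.CombineMols(linker, side))
            off = linker.GetNumAtoms()
            combo.AddBond(atom.GetIdx(), s_nbr + off, Chem.BondType.SINGLE)
            for idx in sorted([hs[0], s_dummy + off], reverse=True):
                combo.RemoveAtom(idx)
            prod = combo.GetMol()
            Chem.SanitizeMol(prod)
            products.add(Chem.MolToSmiles(Chem.RemoveHs(prod)))
        return products

    def test_benzene_plus_methyl_gives_single_product(self, library):
        prods = substitute_linker(library["*c1ccc(*)cc1"], library["*C"])
        oracle = self._graph_substitution_oracle("*c1ccc(*)cc1", "*C")
        assert len(prods) == len(oracle) == 1
        assert {p.smiles for p in prods} == oracle

    def test_each_product_count_matches_graph_oracle(self, library):
        linker = library["*c1ccc(*)cc1"]
        for sc in library.by_type("side_chain")[:6]:
            prods = substitute_linker(linker, sc)
            oracle = self._graph_substitution_oracle(linker.smiles, sc.smiles)
            assert {p.smiles for p in prods} == oracle

    def test_24_side_chains_give_24_unique_asymmetric_linkers(self, library):
        side_chains = library.by_type("side_chain")
        assert len(side_chains) == 24
        asym = make_asymmetric_linkers(library["*c1ccc(*)cc1"], side_chains)
        assert len(asym) == 24
        assert all(a.n_sites == 2 for a in asym)
        assert all(not a.flags["symmetric"] for a in asym)
        assert all(len(a.side_chain_keys) == 1 for a in asym)

    def test_degenerate_empty_side_chain_rejected(self, library):
        bare = Fragment.from_smiles("*[H]", embed=False)
        with pytest.raises(ValueError):
            substitute_linker(library["*c1ccc(*)cc1"], bare)

    def test_site_count_preconditions(self, library):
        with pytest.raises(ValueError):
            substitute_linker(library["*C"], library["*C"])
        with pytest.raises(ValueError):
            substitute_linker(library["*c1ccc(*)cc1"], library["*c1ccc(*)cc1"])


class TestRoundTrip:
    def test_assemble_then_fragment_recovers_input_keys(self, templates, library):
        """Fragmenting a CBU assembled from cleavage-stable fragments
        returns exactly the input fragment key multiset."""
        from fragmops.cbu_assembler import assemble_smiles
        from fragmops.cbu_templates import expand_orientations

        tmpl = templates["linear-2"]
        carb = library["*C(=O)[O-]"]
        stable_linkers = [
            f for f in library.by_type("linker")
            if is_cleavage_stable(f) and f.flags["cyclic"]
        ]
        assert len(stable_linkers) >= 3
        for lk1, lk2 in [(stable_linkers[0], stable_linkers[1]),
                         (stable_linkers[2], stable_linkers[2])]:
            asg = {0: carb, 1: lk1, 2: lk2, 3: carb}
            ori = expand_orientations(tmpl, asg, symmetric=True)[0]
            smi = assemble_smiles(tmpl, asg, ori)
            recovered = sorted(f.smiles for f in fragment_cbu(smi))
            expected = sorted([carb.smiles, carb.smiles, lk1.smiles, lk2.smiles])
            assert recovered == expected


class TestSymmetryDetection:
    def test_phenylene_symmetric_methylphenylene_not(self, library):
        assert library["*c1ccc(*)cc1"].flags["symmetric"]
        prod = substitute_linker(library["*c1ccc(*)cc1"], library["*C"])[0]
        assert not prod.flags["symmetric"]

    def test_linearity_flags(self, library):
        assert library["*C#C*"].flags["linear"]
        assert not library["*O*"].flags["linear"]
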