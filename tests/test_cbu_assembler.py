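"""SMILES-level and geometry-level CBU assembly and enumeration."""

import itertools

import numpy as np
import pytest
from rdkit import Chem

from fragmops import chem
from fragmops.cbu_assembler import (
    AssemblyError,
    admissible_fragments,
    assemble_geometry,
    assemble_smiles,
    enumerate_cbus,
    join_geometry,
)
from fragmops.cbu_templates import OrientationVector, expand_orientations
from fragmops.fragment_core import Fragment, FragmentLibrary
from tests.conftest import two_arm_assignment


class TestAssembleSmiles:
    def test_terephthalate(self, templates, carboxylate, phenylene):
        asg = two_arm_assignment(templates["linear-1"], carboxylate, [phenylene])
        smi = assemble_smiles(templates["linear-1"], asg, OrientationVector((0,)))
        assert smi == Chem.CanonSmiles("[O-]C(=O)c1ccc(C(=O)[O-])cc1")

    def test_node_template_gives_trimesate(self, templates, library, carboxylate):
        node = library["*c1cc(*)cc(*)c1"]
        asg = {0: carboxylate, 1: node}
        smi = assemble_smiles(templates["planar-0"], asg, OrientationVector(()))
        assert smi == Chem.CanonSmiles("[O-]C(=O)c1cc(C(=O)[O-])cc(C(=O)[O-])c1")

    def test_orientation_bit_irrelevant_for_symmetric_linker(
        self, templates, carboxylate, phenylene
    ):
        asg = two_arm_assignment(templates["linear-1"], carboxylate, [phenylene])
        s0 = assemble_smiles(templates["linear-1"], asg, OrientationVector((0,)))
        s1 = assemble_smiles(templates["linear-1"], asg, OrientationVector((1,)))
        assert s0 == s1

    def test_orientation_bit_matters_for_asymmetric_linker(
        self, templates, library, carboxylate
    ):
        # ene-yne linker: the two termini differ, so flipping the bit in a
        # mixed two-linker context changes the product
        eneyne = library["*C#C/C=C/*"]
        phen = library["*c1ccc(*)cc1"]
        tmpl = templates["linear-2"]
        asg = two_arm_assignment(tmpl, carboxylate, [eneyne, phen])
        s0 = assemble_smiles(tmpl, asg, OrientationVector((0, 0)))
        s1 = assemble_smiles(tmpl, asg, OrientationVector((1, 0)))
        assert s0 != s1

    def test_invalid_assignment_raises(self, templates, library, carboxylate):
        node = library.by_type("node")[0]
        asg = two_arm_assignment(templates["linear-1"], carboxylate, [node])
        with pytest.raises(AssemblyError):
            assemble_smiles(templates["linear-1"], asg, OrientationVector((0,)))


class TestJoinGeometry:
    def _pair(self, host_smi, guest_smi):
        host = Fragment.from_smiles(host_smi)
        guest = Fragment.from_smiles(guest_smi)
        return host, guest

    def test_clash_free_join_reproduces_mapped_bond_length(self):
        host, guest = self._pair("*c1ccc(*)cc1", "*C(=O)[O-]")
        hsite = host.sites()[0]
        pos = chem.coords_of(host.mol)
        nh = host.mol.GetAtomWithIdx(hsite).GetNeighbors()[0].GetIdx()
        expected = float(np.linalg.norm(pos[hsite] - pos[nh]))
        joined = join_geometry(host.mol, hsite, guest.mol, guest.sites()[0])
        assert joined is not None
        assert not any(a.GetAtomicNum() == 0 and a.GetDegree() == 0
                       for a in joined.GetAtoms())
        # the new bond is the unique bond between the two former site-neighbors
        jpos = chem.coords_of(joined)
        lengths = [
            float(np.linalg.norm(jpos[b.GetBeginAtomIdx()] - jpos[b.GetEndAtomIdx()]))
            for b in joined.GetBonds()
        ]
        assert any(abs(l - expected) < 1e-6 for l in lengths)

    def test_eclipsing_fixture_resolved_by_torsion_scan(self):
        """Initial pose of a tert-butyl onto a tetramethylethylene backbone
        clashes; the scan must find a rotated clash-free pose."""
        host, guest = self._pair("*C(C)(C)C(C)(C)*", "*C(C)(C)C")
        joined = join_geometry(host.mol, host.sites()[0], guest.mol, guest.sites()[0])
        assert joined is not None
        # verify the initial (unrotated) pose really clashed, i.e. the
        # accepted pose required at least one torsion increment
        blocked = join_geometry(
            host.mol, host.sites()[0], guest.mol, guest.sites()[0],
            torsion_step=360.0,  # only the initial pose is tried
        )
        assert blocked is None

    def test_fully_blocked_fixture_fails(self):
        host, guest = self._pair("*C(C(C)C)C(C(C)C)*", "*C(C)(C)C")
        joined = join_geometry(host.mol, host.sites()[0], guest.mol, guest.sites()[0])
        assert joined is None


class TestAssembleGeometry:
    @pytest.mark.parametrize("template_name,linker_keys", [
        ("linear-1", ["*c1ccc(*)cc1"]),
        ("linear-2", ["*c1ccc(*)cc1", "*C#C*"]),
        ("linear-1", ["*/C=C/C=C/*"]),
    ])
    def test_geometry_contracts(self, templates, library, carboxylate,
                                template_name, linker_keys):
        tmpl = templates[template_name]
        linkers = [library[k] for k in linker_keys]
        asg = two_arm_assignment(tmpl, carboxylate, linkers)
        ori = expand_orientations(tmpl, asg, symmetric=True)[0]
        cbu = assemble_geometry(tmpl, asg, ori)
        # no dummies remain
        assert all(a.GetAtomicNum() != 0 for a in cbu.mol.GetAtoms())
        # SMILES- and geometry-level assembly agree on composition
        assert cbu.smiles == assemble_smiles(tmpl, asg, ori)
        # binding-site count equals arrangement degree
        assert len(cbu.binding_sites) == 2
        # no nonbonded pair below the clash threshold
        assert min_nonbonded_margin(cbu.mol) >= 0.0

    def test_node_geometry(self, templates, library, carboxylate):
        asg = {0: carboxylate, 1: library["*c1cc(*)cc(*)c1"]}
        cbu = assemble_geometry(templates["planar-0"], asg, OrientationVector(()))
        assert len(cbu.binding_sites) == 3
        assert cbu.smiles == Chem.CanonSmiles(
            "[O-]C(=O)c1cc(C(=O)[O-])cc(C(=O)[O-])c1"
        )
        assert min_nonbonded_margin(cbu.mol) >= 0.0

    def test_missing_geometry_raises(self, templates, carboxylate):
        bare = Fragment.from_smiles("*c1ccc(*)cc1", frag_type="linker", embed=False)
        asg = two_arm_assignment(templates["linear-1"], carboxylate, [bare])
        with pytest.raises(AssemblyError, match="geometry"):
            assemble_geometry(
                templates["linear-1"], asg, OrientationVector((0,))
            )


def min_nonbonded_margin(mol):
    """Min over nonbonded pairs (1-2 and 1-3 excluded) of
    distance - clash_factor * vdW sum."""
    pos = chem.coords_of(mol)
    radii = chem.vdw_array(chem.symbols_of(mol))
    n = mol.GetNumAtoms()
    dmat = Chem.GetDistanceMatrix(mol)
    worst = np.inf
    for i in range(n):
        for j in range(i + 1, n):
            if dmat[i, j] <= 2:
                continue
            d = np.linalg.norm(pos[i] - pos[j])
            worst = min(worst, d - chem.CLASH_FACTOR * (radii[i] + radii[j]))
    return worst


def _zip_pair(host, host_site, guest, guest_site):
    """Fuse one dummy pair with RDKit molzip (exactly one labelled pair
    per call: multi-pair zips proved order-unstable for directional
    bonds)."""
    h = Chem.Mol(host)
    g = Chem.Mol(guest)
    h.GetAtomWithIdx(host_site).SetAtomMapNum(1)
    g.GetAtomWithIdx(guest_site).SetAtomMapNum(1)
    out = Chem.molzip(Chem.CombineMols(h, g))
    Chem.SanitizeMol(out)
    return out


def molzip_oracle(template, assignment, bits):
    """Independent SMILES assembly for two-arm templates: chain the
    binding group and linkers with sequential molzip fusions (a different
    join mechanism than the package's own direction-transfer join)."""
    from fragmops.fragment_core import bonding_sites

    assert template.arrangement in ("two_linear", "two_bent")
    positions = [s.position for s in template.slots]
    linker_positions = [s.position for s in template.linker_slots]
    bg0 = assignment[positions[0]]
    cur = Chem.Mol(bg0.mol)
    open_site = bonding_sites(cur)[0]
    for k, p in enumerate(linker_positions):
        frag = assignment[p]
        guest = Chem.Mol(frag.mol)
        sites = bonding_sites(guest)
        first, second = sites[bits[k]], sites[1 - bits[k]]
        guest.GetAtomWithIdx(second).SetIsotope(99)
        cur = _zip_pair(cur, open_site, guest, first)
        open_site = next(
            a.GetIdx() for a in cur.GetAtoms()
            if a.GetAtomicNum() == 0 and a.GetIsotope() == 99
        )
        cur.GetAtomWithIdx(open_site).SetIsotope(0)
    bg1 = assignment[positions[-1]]
    cur = _zip_pair(cur, open_site, Chem.Mol(bg1.mol), bonding_sites(bg1.mol)[0])
    return Chem.MolToSmiles(Chem.RemoveHs(cur))


class TestEnumerate:
    def test_toy_two_symmetric_linkers_two_products(self, templates, carboxylate,
                                                    library):
        lib = FragmentLibrary([carboxylate, library["*c1ccc(*)cc1"], library["*C#C*"]])
        cbus = enumerate_cbus(templates["linear-1"], lib)
        assert len(cbus) == 2

    def test_count_matches_bruteforce_molzip_oracle(self, templates, library,
                                                    carboxylate):
        """Randomized toy libraries: enumeration equals the brute-force
        cartesian-product + canonical-dedup oracle (20 trials)."""
        from fragmops.fragment_core import substitute_linker

        rng = np.random.default_rng(42)
        tmpl = templates["linear-2"]
        all_linkers = library.by_type("linker")
        asym_pool = substitute_linker(library["*c1ccc(*)cc1"], library["*C"]) + \
            substitute_linker(library["*c1ccc(*)cc1"], library["*F"])
        bgs = library.by_type("binding_group")
        for _ in range(20):
            n_sym = int(rng.integers(1, 4))
            pick = rng.choice(len(all_linkers), size=n_sym, replace=False)
            linkers = [all_linkers[i] for i in pick]
            if rng.random() < 0.7:
                linkers.append(asym_pool[int(rng.integers(len(asym_pool)))])
            n_bg = int(rng.integers(1, 3))
            lib = FragmentLibrary(bgs[:n_bg] + linkers)

            cbus = enumerate_cbus(tmpl, lib, symmetric=False, mode="smiles")

            oracle = set()
            bg_list = lib.by_type("binding_group")
            lk_list = lib.by_type("linker")
            for bg in bg_list:  # single binding-group species per CBU
                for lk1, lk2 in itertools.product(lk_list, repeat=2):
                    for bits in itertools.product((0, 1), repeat=2):
                        asg = {0: bg, 1: lk1, 2: lk2, 3: bg}
                        oracle.add(molzip_oracle(tmpl, asg, bits))
            assert {c.smiles for c in cbus} == oracle

    def test_enumeration_invariant_to_library_order(self, templates, library,
                                                    carboxylate):
        frags = [carboxylate, library["*c1ccc(*)cc1"], library["*C#C*"],
                 library["*C#C/C=C/*"]]
        lib1 = FragmentLibrary(frags)
        lib2 = FragmentLibrary(reversed(frags))
        c1 = enumerate_cbus(templates["linear-1"], lib1)
        c2 = enumerate_cbus(templates["linear-1"], lib2)
        assert [c.smiles for c in c1] == [c.smiles for c in c2]

    def test_symmetric_flag_irrelevant_for_all_symmetric_library(
        self, templates, library, carboxylate
    ):
        lib = FragmentLibrary(
            [carboxylate, library["*c1ccc(*)cc1"], library["*C#C*"]]
        )
        a = enumerate_cbus(templates["linear-2"], lib, symmetric=False)
        b = enumerate_cbus(templates["linear-2"], lib, symmetric=True)
        assert {c.smiles for c in a} == {c.smiles for c in b}

    def test_empty_slot_pool_raises_naming_slot(self, templates, carboxylate):
        lib = FragmentLibrary([carboxylate])
        with pytest.raises(AssemblyError, match="slot"):
            enumerate_cbus(templates["linear-1"], lib)
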