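"""Geometric MOP assembly: scaling, docking, stoichiometry, clashes."""

import numpy as np
import pytest

from fragmops import chem
from fragmops.cbu_assembler import BindingSite, ChemBuildingUnit
from fragmops.mop_assembler import (
    AssemblyFailure,
    AssemblyModel,
    assemble_mop,
    count_configurations,
    default_models,
    get_model,
)


def unit_counts(mop):
    metal = len({u for u, r, _ in mop.unit_provenance if r == "metal"})
    organic = len({u for u, r, _ in mop.unit_provenance if r == "organic"})
    return metal, organic


def toy_units_for(model, metal_reach=2.0, organic_reach=3.0):
    """Point-like units built exactly on the model's site frames, so the
    docking is exact by construction."""
    m_pos = np.asarray(model.metal_positions, dtype=float)
    o_pos = np.asarray(model.organic_positions, dtype=float)

    # metal: an apex atom at the cone origin plus one atom per binding
    # site, along the directions to the site's partners
    partners = model.metal_partners(0)
    dirs = []
    for o in partners:
        v = o_pos[o] - m_pos[0]
        dirs.append(v / np.linalg.norm(v))
    coords = np.vstack([[0.0, 0.0, 0.0], [metal_reach * d for d in dirs]])
    metal = ChemBuildingUnit(
        _elements=["V"] * 4,
        _coords=coords,
        binding_sites=[
            BindingSite((i + 1,), coords[i + 1], dirs[i]) for i in range(3)
        ],
        arrangement="3-pyramidal",
        label="toy-metal",
    )

    o_partners = model.organic_partners(0)
    odirs = []
    for m in o_partners:
        v = m_pos[m] - o_pos[0]
        odirs.append(v / np.linalg.norm(v))
    ocoords = np.array([organic_reach * d for d in odirs])
    arrangement = {"2-linear": "two_linear", "2-bent": "two_bent",
                   "3-planar": "three_planar"}[model.organic_class]
    organic = ChemBuildingUnit(
        _elements=["C"] * len(ocoords),
        _coords=ocoords,
        binding_sites=[
            BindingSite((i,), ocoords[i], odirs[i]) for i in range(len(ocoords))
        ],
        arrangement=arrangement,
        label="toy-organic",
        side_chain_keys={},
    )
    return metal, organic


class TestToyConstruction:
    def test_point_units_land_on_scaled_polyhedron(self):
        model = get_model("(3-pyramidal)4(2-linear)6")
        metal, organic = toy_units_for(model)
        mop = assemble_mop(model, metal, organic)
        # metal apex atoms sit on scaled tetrahedron vertices
        for m in range(4):
            atoms = mop.atoms_of_unit(m)
            apex = mop.coords[atoms[0]]
            expected = mop.scale * np.asarray(model.metal_positions[m])
            assert np.linalg.norm(apex - expected) < 1e-6
        # organic centroids on scaled edge midpoints
        for o in range(6):
            atoms = mop.atoms_of_unit(4 + o)
            centroid = mop.coords[atoms].mean(axis=0)
            expected = mop.scale * np.asarray(model.organic_positions[o])
            assert np.linalg.norm(centroid - expected) < 1e-6

    def test_scale_matches_reach_sum(self):
        model = get_model("(3-pyramidal)4(2-linear)6")
        metal, organic = toy_units_for(model, metal_reach=2.0, organic_reach=3.0)
        mop = assemble_mop(model, metal, organic)
        edge_len = np.linalg.norm(
            np.asarray(model.metal_positions[0]) - np.asarray(model.organic_positions[0])
        )
        expected_scale = (2.0 + 3.0 + chem.COORDINATION_GAP) / edge_len
        assert mop.scale == pytest.approx(expected_scale, rel=1e-9)


class TestStoichiometry:
    def test_lantern_has_2_metals_3_organics(self, metals, slim_cbu):
        model = get_model("(3-pyramidal)2(2-linear)3")
        mop = assemble_mop(model, metals[1], slim_cbu)
        assert unit_counts(mop) == (2, 3)
        assert mop.n_atoms == 2 * metals[1].n_atoms + 3 * slim_cbu.n_atoms

    def test_tetrahedron_has_4_metals_6_organics(self, metals, terephthalate_cbu):
        model = get_model("(3-pyramidal)4(2-linear)6")
        mop = assemble_mop(model, metals[1], terephthalate_cbu)
        assert unit_counts(mop) == (4, 6)
        assert mop.n_atoms == 4 * metals[1].n_atoms + 6 * terephthalate_cbu.n_atoms


class TestInvariances:
    def test_assembly_is_deterministic(self, metals, terephthalate_cbu):
        model = get_model("(3-pyramidal)4(2-linear)6")
        a = assemble_mop(model, metals[1], terephthalate_cbu)
        b = assemble_mop(model, metals[1], terephthalate_cbu)
        assert np.array_equal(a.coords, b.coords)

    def test_rigid_motion_of_inputs_leaves_output_invariant(
        self, metals, terephthalate_cbu
    ):
        model = get_model("(3-pyramidal)4(2-linear)6")
        ref = assemble_mop(model, metals[1], terephthalate_cbu)

        rot = chem.rotation_about_axis(np.array([1.0, 2.0, 3.0]), 1.1)
        shift = np.array([5.0, -3.0, 2.0])
        moved = ChemBuildingUnit(
            smiles=terephthalate_cbu.smiles,
            _elements=list(terephthalate_cbu.elements),
            _coords=terephthalate_cbu.coords @ rot.T + shift,
            binding_sites=[
                BindingSite(bs.atoms, bs.anchor @ rot.T + shift, bs.direction @ rot.T)
                for bs in terephthalate_cbu.binding_sites
            ],
            arrangement=terephthalate_cbu.arrangement,
            side_chain_keys=terephthalate_cbu.side_chain_keys,
        )
        out = assemble_mop(model, metals[1], moved)
        assert np.abs(out.coords - ref.coords).max() < 1e-6

    def test_longer_linker_strictly_increases_scale(
        self, templates, library, carboxylate, metals
    ):
        from fragmops.cbu_assembler import assemble_geometry
        from fragmops.cbu_templates import expand_orientations
        from tests.conftest import two_arm_assignment

        model = get_model("(3-pyramidal)4(2-linear)6")
        scales = []
        for linkers in (["*c1ccc(*)cc1"], ["*c1ccc(*)cc1", "*C#C*"]):
            tmpl = templates[f"linear-{len(linkers)}"]
            asg = two_arm_assignment(tmpl, carboxylate, [library[k] for k in linkers])
            ori = expand_orientations(tmpl, asg, symmetric=True)[0]
            cbu = assemble_geometry(tmpl, asg, ori)
            scales.append(assemble_mop(model, metals[1], cbu).scale)
        assert scales[1] > scales[0]


class TestFailures:
    def test_arity_mismatch_raises(self, metals, terephthalate_cbu):
        model = get_model("(3-pyramidal)4(3-planar)4")
        with pytest.raises(AssemblyFailure):
            assemble_mop(model, metals[1], terephthalate_cbu)

    def test_undersized_model_clashes_at_all_spins(self, metals, terephthalate_cbu):
        """A deliberately undersized lantern (organic sites crowded onto a
        tiny equatorial ring) cannot host a phenylene CBU at any allowed
        axial spin: neighboring organic units always overlap."""
        base = get_model("(3-pyramidal)2(2-linear)3")
        tiny = AssemblyModel(
            name="undersized-lantern",
            metal_class=base.metal_class,
            organic_class=base.organic_class,
            metal_positions=base.metal_positions,
            organic_positions=0.3 * np.asarray(base.organic_positions),
            edges=base.edges,
        )
        with pytest.raises(AssemblyFailure) as err:
            assemble_mop(tiny, metals[1], terephthalate_cbu)
        assert err.value.unit_pair is not None

    def test_no_interunit_pair_below_threshold_on_success(self, metals, slim_cbu):
        model = get_model("(3-pyramidal)2(2-linear)3")
        mop = assemble_mop(model, metals[1], slim_cbu)
        # re-check the clash invariant from the raw output, excluding
        # coordinating binding-group/metal contacts
        n_units = 5
        for i in range(n_units):
            for j in range(i + 1, n_units):
                ai, aj = mop.atoms_of_unit(i), mop.atoms_of_unit(j)
                ri = chem.vdw_array([mop.elements[k] for k in ai])
                rj = chem.vdw_array([mop.elements[k] for k in aj])
                gap = chem.pairwise_min_gap(
                    mop.coords[ai], chem.CLASH_FACTOR * ri,
                    mop.coords[aj], chem.CLASH_FACTOR * rj,
                )
                roles = {mop.unit_provenance[ai[0]][1], mop.unit_provenance[aj[0]][1]}
                if roles == {"metal", "organic"}:
                    continue  # coordination contact allowed
                assert gap >= 0.0


class TestCountConfigurations:
    def test_zero_organics_gives_zero(self):
        models = default_models()[:1]
        assert count_configurations({"2-linear": []}, models, ["m"] * 7) == 0

    def test_product_rule(self):
        models = [get_model("(3-pyramidal)4(2-linear)6")]
        sets = {"2-linear": ["c"] * 5}
        assert count_configurations(sets, models, ["m"] * 7) == 35

    def test_sums_over_models(self):
        models = default_models()
        sets = {"2-linear": ["a", "b"], "2-bent": ["c"], "3-planar": ["d", "e", "f"]}
        # two 2-linear models, one 2-bent, one 3-planar; 2 metals
        expected = (2 * 2 + 2 * 2 + 1 * 2 + 3 * 2)
        assert count_configurations(sets, models, ["m1", "m2"]) == expected
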