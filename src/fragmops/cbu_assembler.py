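"""Join fragments into complete organic CBUs and enumerate design spaces.

Two join protocols are provided.  The SMILES-level protocol operates on the
molecular graph only and is used for fast enumeration of a template's
design space.  The geometry-level protocol builds 3D structures from the
rigid per-fragment geometries: for each junction a local coordinate system
(site-neighbor atom, dummy direction, nearest other neighbor) is computed
on both fragments, the incoming fragment is rigidly transformed so that its
dummy maps onto the host's site-neighbor atom and vice versa, the dummies
are removed and a single bond is created.  If the resulting pose has
nonbonded overlaps the torsion about the new bond is incremented in fixed
steps until the overlaps are gone or a full turn has been scanned, in which
case the assembly fails.

Because each dummy sits at the position of the atom it replaced, the new
bond reproduces the original bond length by construction; no bond-length
correction is applied unless MMFF94 relaxation is requested.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from fragmops import chem
from fragmops.chem import CLASH_FACTOR, TORSION_STEP_DEG
from fragmops.cbu_templates import (
    CBUTemplate,
    OrientationVector,
    expand_orientations,
    validate_assignment,
)
from fragmops.fragment_core import Fragment, FragmentLibrary

_BG_PROP = "fragmops_bg"
_OPEN_PROP = "fragmops_open"


class AssemblyError(RuntimeError):
    """Raised when fragments cannot be joined (invalid assignment, valence
    violation, or an unresolvable steric clash)."""


@dataclass(frozen=True, eq=False)
class BindingSite:
    """Heavy atoms of one binding group plus its outward unit vector."""

    atoms: tuple[int, ...]
    anchor: np.ndarray
    direction: np.ndarray


@dataclass(eq=False)
class ChemBuildingUnit:
    """An assembled building unit.

    For organic CBUs ``mol`` carries the structure (and the conformer in
    geometry mode); metal units may instead supply raw ``elements`` and
    ``coords``.  ``fragment_keys`` and ``side_chain_keys`` record fragment
    provenance per template slot.
    """

    smiles: str | None = None
    mol: Chem.Mol | None = None
    template_name: str = ""
    fragment_keys: dict | None = None
    side_chain_keys: dict | None = None
    orientation: OrientationVector | None = None
    binding_sites: list[BindingSite] = field(default_factory=list)
    arrangement: str = ""
    label: str = ""
    _elements: list[str] | None = None
    _coords: np.ndarray | None = None

    @property
    def elements(self) -> list[str]:
        if self._elements is not None:
            return self._elements
        return [a.GetSymbol() for a in self.mol.GetAtoms()]

    @property
    def coords(self) -> np.ndarray:
        if self._coords is not None:
            return np.asarray(self._coords, dtype=float)
        return chem.coords_of(self.mol)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def center(self) -> np.ndarray:
        """Assembly reference point of the unit: the least-squares
        intersection of the binding-site axes (the lines through each
        anchor along its outward vector).  For a 2-linear unit this is the
        anchor midpoint; for a pyramidal metal unit it is the cone apex
        from which the binding vectors radiate.  A small regularization
        toward the anchor centroid resolves the rank deficiency of
        parallel axes."""
        anchors = np.array([bs.anchor for bs in self.binding_sites])
        if len(anchors) <= 2:
            # near-antiparallel axes make the line intersection ill
            # conditioned; the anchor midpoint is the natural reference
            return anchors.mean(axis=0)
        dirs = np.array([bs.direction for bs in self.binding_sites])
        eps = 1e-9
        a_mat = eps * np.eye(3)
        b_vec = eps * anchors.mean(axis=0)
        for a, d in zip(anchors, dirs):
            proj = np.eye(3) - np.outer(d, d)
            a_mat += proj
            b_vec += proj @ a
        return np.linalg.solve(a_mat, b_vec)

    @property
    def reach(self) -> float:
        """Mean distance from the unit center to its binding anchors."""
        c = self.center
        return float(np.mean([np.linalg.norm(bs.anchor - c) for bs in self.binding_sites]))


def _neighbors(mol: Chem.Mol, idx: int) -> list[int]:
    return [nb.GetIdx() for nb in mol.GetAtomWithIdx(idx).GetNeighbors()]


def _local_frame(mol: Chem.Mol, site_idx: int) -> tuple[int, np.ndarray, np.ndarray]:
    """Local frame at a bonding site: (neighbor index, x-axis toward the
    site atom, y-axis orthogonalized toward the nearest other neighbor)."""
    pos = chem.coords_of(mol)
    nbrs = _neighbors(mol, site_idx)
    if len(nbrs) != 1:
        raise AssemblyError(f"site atom {site_idx} must have exactly one neighbor")
    nh = nbrs[0]
    x = pos[site_idx] - pos[nh]
    x = x / np.linalg.norm(x)
    others = [i for i in _neighbors(mol, nh) if i != site_idx]
    if others:
        others.sort(key=lambda i: np.linalg.norm(pos[i] - pos[nh]))
        y = pos[others[0]] - pos[nh]
    else:
        y = np.array([0.0, 0.0, 1.0])
    y = y - np.dot(y, x) * x
    if np.linalg.norm(y) < 1e-6:
        y = np.array([1.0, 0.0, 0.0])
        y = y - np.dot(y, x) * x
        if np.linalg.norm(y) < 1e-6:
            y = np.array([0.0, 1.0, 0.0])
            y = y - np.dot(y, x) * x
    y = y / np.linalg.norm(y)
    return nh, x, y


def _junction_gap(host: Chem.Mol, guest: Chem.Mol, host_site: int, guest_site: int,
                  nh: int, nf: int, guest_pos: np.ndarray,
                  clash_factor: float, vdw_overrides=None) -> float:
    """Worst nonbonded clearance (dist - factor*vdW-sum) between host and
    placed guest, excluding the consumed site atoms and 1-2/1-3 pairs
    across the new bond."""
    host_pos = chem.coords_of(host)
    hsym = chem.symbols_of(host)
    gsym = chem.symbols_of(guest)
    h_keep = [i for i in range(host.GetNumAtoms()) if i != host_site]
    g_keep = [j for j in range(guest.GetNumAtoms()) if j != guest_site]
    h_excl = {nh, *(_neighbors(host, nh))}
    g_excl = {nf, *(_neighbors(guest, nf))}
    best = np.inf
    hr = chem.vdw_array(hsym, vdw_overrides)
    gr = chem.vdw_array(gsym, vdw_overrides)
    for i in h_keep:
        for j in g_keep:
            if i in h_excl and j in g_excl:
                continue
            d = np.linalg.norm(host_pos[i] - guest_pos[j])
            best = min(best, d - clash_factor * (hr[i] + gr[j]))
    return best


def join_geometry(
    host: Chem.Mol,
    host_site: int,
    guest: Chem.Mol,
    guest_site: int,
    bond_length: float | None = None,
    clash_factor: float = CLASH_FACTOR,
    torsion_step: float = TORSION_STEP_DEG,
    vdw_overrides: dict | None = None,
) -> Chem.Mol | None:
    """Geometric bonding-site join of ``guest`` onto ``host``.

    ``host_site`` may be a dummy atom or a hydrogen (side-chain grafting);
    ``guest_site`` must be a dummy.  Returns the joined molecule or ``None``
    if no clash-free torsion exists within a full turn.
    """
    nh, xh, yh = _local_frame(host, host_site)
    nf, xg, yg = _local_frame(guest, guest_site)
    zh = np.cross(xh, yh)
    zg = np.cross(xg, yg)
    basis_g = np.column_stack([xg, yg, zg])
    target = np.column_stack([-xh, yh, -zh])
    rot = target @ basis_g.T

    host_pos = chem.coords_of(host)
    guest_pos = chem.coords_of(guest)
    if bond_length is None:
        bond_length = float(np.linalg.norm(host_pos[host_site] - host_pos[nh]))
    nf_image = host_pos[nh] + xh * bond_length
    placed = (guest_pos - guest_pos[nf]) @ rot.T + nf_image

    chosen = None
    n_steps = max(1, int(round(360.0 / torsion_step)))
    for k in range(n_steps):
        angle = np.radians(k * torsion_step)
        rotk = chem.rotation_about_axis(xh, angle)
        cand = (placed - nf_image) @ rotk.T + nf_image
        gap = _junction_gap(host, guest, host_site, guest_site, nh, nf, cand,
                            clash_factor, vdw_overrides)
        if gap >= 0.0:
            chosen = cand
            break
    if chosen is None:
        return None

    guest2 = Chem.Mol(guest)
    chem.set_coords(guest2, chosen)
    off = host.GetNumAtoms()
    combo = Chem.RWMol(Chem.CombineMols(host, guest2))
    combo.AddBond(nh, nf + off, Chem.BondType.SINGLE)
    for idx in sorted([host_site, guest_site + off], reverse=True):
        combo.RemoveAtom(idx)
    out = combo.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception as exc:  # valence violation at the junction
        raise AssemblyError(f"valence violation at junction: {exc}") from exc
    return out


_DIR_INV = {
    Chem.BondDir.ENDUPRIGHT: Chem.BondDir.ENDDOWNRIGHT,
    Chem.BondDir.ENDDOWNRIGHT: Chem.BondDir.ENDUPRIGHT,
}


def _site_bond_dir(mol: Chem.Mol, dummy: int, nbr: int):
    """Direction of the dummy bond expressed as if it began at ``nbr``;
    ``None`` when undirected."""
    bond = mol.GetBondBetweenAtoms(dummy, nbr)
    d = bond.GetBondDir()
    if d not in _DIR_INV:
        return None
    return d if bond.GetBeginAtomIdx() == nbr else _DIR_INV[d]


def join_graph(host: Chem.Mol, host_site: int, guest: Chem.Mol,
               guest_site: int) -> Chem.Mol:
    """Graph-only bonding-site join (no coordinates required).

    The new single bond inherits the direction flags of the consumed dummy
    bonds so double-bond stereo adjacent to the junction survives; when
    the two sides disagree, every directional bond of the guest is flipped
    (a global flip leaves the guest's internal stereo unchanged).
    """
    nh = _neighbors(host, host_site)[0]
    nf = _neighbors(guest, guest_site)[0]
    dir_h = _site_bond_dir(host, host_site, nh)
    dir_g = _site_bond_dir(guest, guest_site, nf)
    off = host.GetNumAtoms()
    combo = Chem.RWMol(Chem.CombineMols(host, guest))
    if dir_h is not None and dir_g is not None and dir_g != _DIR_INV[dir_h]:
        for b in combo.GetBonds():
            if (b.GetBeginAtomIdx() >= off and b.GetEndAtomIdx() >= off
                    and b.GetBondDir() in _DIR_INV):
                b.SetBondDir(_DIR_INV[b.GetBondDir()])
        dir_g = _DIR_INV[dir_g]
    bond_idx = combo.AddBond(nh, nf + off, Chem.BondType.SINGLE) - 1
    new_bond = combo.GetBondWithIdx(bond_idx)
    final = dir_h if dir_h is not None else (
        _DIR_INV[dir_g] if dir_g is not None else None
    )
    if final is not None:
        if new_bond.GetBeginAtomIdx() != nh:
            final = _DIR_INV[final]
        new_bond.SetBondDir(final)
    for idx in sorted([host_site, guest_site + off], reverse=True):
        combo.RemoveAtom(idx)
    out = combo.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception as exc:
        raise AssemblyError(f"valence violation at junction: {exc}") from exc
    Chem.AssignStereochemistry(out, cleanIt=True, force=True)
    return out


def _tag(mol: Chem.Mol, prop: str, value: int, atoms=None) -> Chem.Mol:
    out = Chem.Mol(mol)
    idxs = range(out.GetNumAtoms()) if atoms is None else atoms
    for i in idxs:
        out.GetAtomWithIdx(i).SetIntProp(prop, value)
    return out


def _find_open(mol: Chem.Mol) -> int:
    for a in mol.GetAtoms():
        if a.HasProp(_OPEN_PROP):
            return a.GetIdx()
    raise AssemblyError("no open bonding site")


def _clear_open(mol: Chem.Mol, idx: int) -> None:
    mol.GetAtomWithIdx(idx).ClearProp(_OPEN_PROP)


def _build(template: CBUTemplate, assignment: dict, orientation: OrientationVector,
           geometric: bool, clash_factor: float = CLASH_FACTOR,
           torsion_step: float = TORSION_STEP_DEG) -> Chem.Mol:
    """Shared orchestration: grow the arm from the binding group, append
    linkers in sequence, then close with a second binding group or replicate
    the arm onto a node fragment."""

    def join(host, hsite, guest, gsite, what):
        if geometric:
            out = join_geometry(host, hsite, guest, gsite,
                                clash_factor=clash_factor,
                                torsion_step=torsion_step)
            if out is None:
                raise AssemblyError(f"unresolvable clash joining {what}")
            return out
        return join_graph(host, hsite, guest, gsite)

    linker_slots = template.linker_slots
    if len(orientation) != len(linker_slots):
        raise AssemblyError("orientation length mismatch")

    from fragmops.fragment_core import bonding_sites

    bg0 = assignment[template.slots[0].position]
    current = _tag(bg0.mol, _BG_PROP, 0)
    open_site = bonding_sites(current)[0]

    for k, slot in enumerate(linker_slots):
        frag = assignment[slot.position]
        sites = frag.sites()
        consume, keep = sites[orientation.bits[k]], sites[1 - orientation.bits[k]]
        guest = _tag(frag.mol, _OPEN_PROP, 1, atoms=[keep])
        current = join(current, open_site, guest, consume,
                       f"slot {slot.position} ({frag.smiles})")
        open_site = _find_open(current)
        _clear_open(current, open_site)

    last = template.slots[-1]
    if template.arrangement in ("two_linear", "two_bent"):
        bg1 = assignment[last.position]
        guest = _tag(bg1.mol, _BG_PROP, 1)
        gsite = bonding_sites(guest)[0]
        current = join(current, open_site, guest, gsite, "terminal binding group")
        return current

    # three_planar: replicate the arm over each node bonding site
    node_frag = assignment[last.position]
    arm = _tag(current, _OPEN_PROP, 1, atoms=[open_site])
    result = Chem.Mol(node_frag.mol)
    for copy_id in range(node_frag.n_sites):
        # recompute the node's remaining dummy sites each round
        remaining = [a.GetIdx() for a in result.GetAtoms()
                     if a.GetAtomicNum() == 0 and not a.HasProp(_OPEN_PROP)]
        if not remaining:
            break
        node_site = remaining[0]
        arm_copy = Chem.Mol(arm)
        for a in arm_copy.GetAtoms():
            if a.HasProp(_BG_PROP):
                a.SetIntProp(_BG_PROP, copy_id)
        asite = _find_open(arm_copy)
        result = join(result, node_site, arm_copy, asite, f"node arm {copy_id}")
        opened = [a.GetIdx() for a in result.GetAtoms() if a.HasProp(_OPEN_PROP)]
        for i in opened:
            _clear_open(result, i)
    return result


def _binding_groups_of(mol: Chem.Mol) -> dict[int, list[int]]:
    groups: dict[int, list[int]] = {}
    for a in mol.GetAtoms():
        if a.HasProp(_BG_PROP):
            groups.setdefault(a.GetIntProp(_BG_PROP), []).append(a.GetIdx())
    return groups


def _binding_sites_of(mol: Chem.Mol) -> list[BindingSite]:
    pos = chem.coords_of(mol)
    groups = _binding_groups_of(mol)
    sites = []
    for gid in sorted(groups):
        atoms = groups[gid]
        heavy = [i for i in atoms if mol.GetAtomWithIdx(i).GetAtomicNum() > 1]
        anchor = pos[heavy].mean(axis=0)
        junction = None
        for i in atoms:
            for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                if not nb.HasProp(_BG_PROP):
                    junction = nb.GetIdx()
        if junction is None:
            direction = anchor - pos.mean(axis=0)
        else:
            direction = anchor - pos[junction]
        n = np.linalg.norm(direction)
        direction = direction / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])
        sites.append(BindingSite(tuple(sorted(heavy)), anchor, direction))
    return sites


def _plane_fit(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - center)
    return center, vt[-1]


def _align_binding_groups(mol: Chem.Mol, clash_factor: float = CLASH_FACTOR,
                          scan_step: float = 5.0, rounds: int = 2) -> None:
    """Rotate each binding group about its junction bond so the groups end
    up coplanar: for 2-arm CBUs this makes the two groups mutually
    coplanar/antiparallel, otherwise they rotate onto the common plane
    through the group atoms.  Rotations that would introduce a clash with
    the rest of the molecule are rejected."""
    groups = _binding_groups_of(mol)
    if len(groups) < 2:
        return
    radii = chem.vdw_array(chem.symbols_of(mol))
    for _ in range(rounds):
        pos = chem.coords_of(mol)
        all_bg = sorted(i for atoms in groups.values() for i in atoms)
        plane_pt, normal = _plane_fit(pos[all_bg])
        for gid in sorted(groups):
            atoms = groups[gid]
            attach = junction = None
            for i in atoms:
                for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                    if not nb.HasProp(_BG_PROP):
                        attach, junction = i, nb.GetIdx()
            if junction is None:
                continue
            pos = chem.coords_of(mol)
            axis = pos[attach] - pos[junction]
            if np.linalg.norm(axis) < 1e-8:
                continue
            axis = axis / np.linalg.norm(axis)
            others = [i for i in range(mol.GetNumAtoms()) if i not in atoms]
            group = np.array(atoms)

            def ssd(p):
                return float((((p[group] - plane_pt) @ normal) ** 2).sum())

            def min_gap(p):
                diff = p[group][:, None, :] - p[others][None, :, :]
                dist = np.sqrt((diff**2).sum(-1))
                rsum = radii[group][:, None] + radii[others][None, :]
                # ignore the junction bond itself and its 1-3 contacts
                mask = np.ones_like(dist, dtype=bool)
                near = {junction, *_neighbors(mol, junction)}
                for col, j in enumerate(others):
                    if j in near:
                        mask[:, col] = False
                if not mask.any():
                    return np.inf
                return float((dist - clash_factor * rsum)[mask].min())

            base_gap = min_gap(pos)
            best = (ssd(pos), 0.0)
            for ang in np.arange(scan_step, 360.0, scan_step):
                rot = chem.rotation_about_axis(axis, np.radians(ang))
                trial = pos.copy()
                trial[group] = (pos[group] - pos[junction]) @ rot.T + pos[junction]
                if min_gap(trial) < min(base_gap, 0.0) - 1e-9:
                    continue
                if min_gap(trial) < 0.0 <= base_gap:
                    continue
                s = ssd(trial)
                if s < best[0] - 1e-12:
                    best = (s, ang)
            if best[1] != 0.0:
                rot = chem.rotation_about_axis(axis, np.radians(best[1]))
                newpos = pos.copy()
                newpos[group] = (pos[group] - pos[junction]) @ rot.T + pos[junction]
                chem.set_coords(mol, newpos)


def _finalize_smiles(mol: Chem.Mol, from_3d: bool = False) -> str:
    clean = Chem.Mol(mol)
    if from_3d and clean.GetNumConformers() > 0:
        Chem.AssignStereochemistryFrom3D(clean)
    return Chem.MolToSmiles(Chem.RemoveHs(clean))


def assemble_smiles(template: CBUTemplate, assignment: dict,
                    orientation: OrientationVector) -> str:
    """SMILES-level assembly: canonical, dummy-free product SMILES."""
    ok, reasons = validate_assignment(template, assignment)
    if not ok:
        raise AssemblyError("invalid assignment: " + "; ".join(reasons))
    mol = _build(template, assignment, orientation, geometric=False)
    if any(a.GetAtomicNum() == 0 for a in mol.GetAtoms()):
        raise AssemblyError("dummy atoms remain after assembly")
    return _finalize_smiles(mol)


def assemble_geometry(template: CBUTemplate, assignment: dict,
                      orientation: OrientationVector, minimize: bool = False,
                      clash_factor: float = CLASH_FACTOR,
                      torsion_step: float = TORSION_STEP_DEG,
                      align: bool = True) -> ChemBuildingUnit:
    """Geometry-level assembly into a :class:`ChemBuildingUnit`.

    Raises :class:`AssemblyError` when a junction clash cannot be resolved
    by the torsion scan or a fragment lacks geometry.
    """
    ok, reasons = validate_assignment(template, assignment)
    if not ok:
        raise AssemblyError("invalid assignment: " + "; ".join(reasons))
    for slot in template.slots:
        if assignment[slot.position].mol.GetNumConformers() == 0:
            raise AssemblyError(f"fragment at position {slot.position} has no geometry")
    mol = _build(template, assignment, orientation, geometric=True,
                 clash_factor=clash_factor, torsion_step=torsion_step)
    if any(a.GetAtomicNum() == 0 for a in mol.GetAtoms()):
        raise AssemblyError("dummy atoms remain after assembly")
    if minimize:
        try:
            AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
        except Exception:
            pass
    if align:
        _align_binding_groups(mol, clash_factor=clash_factor)
    return ChemBuildingUnit(
        smiles=_finalize_smiles(mol, from_3d=True),
        mol=mol,
        template_name=template.name,
        fragment_keys={s.position: assignment[s.position].key for s in template.slots},
        side_chain_keys={
            s.position: assignment[s.position].side_chain_keys for s in template.slots
        },
        orientation=orientation,
        binding_sites=_binding_sites_of(mol),
        arrangement=template.arrangement,
    )


def admissible_fragments(template: CBUTemplate, library: FragmentLibrary
                         ) -> dict[int, list[Fragment]]:
    """Per-slot admissible fragments, in canonical-key order."""
    out: dict[int, list[Fragment]] = {}
    for slot in template.slots:
        frags = [f for f in library.fragments if slot.admits(f)[0]]
        if not frags:
            raise AssemblyError(
                f"no admissible fragment for slot position {slot.position} "
                f"(accepts {slot.accepts})"
            )
        out[slot.position] = frags
    return out


def enumerate_cbus(template: CBUTemplate, library: FragmentLibrary,
                   symmetric: bool = False, mode: str = "smiles",
                   on_failure=None) -> list[ChemBuildingUnit]:
    """Enumerate the template's design space.

    Iterates the cartesian product of admissible fragments per slot crossed
    with the allowed linker orientations, assembles each candidate and
    deduplicates by canonical product SMILES.  Results are returned in
    deterministic (SMILES-sorted) order.  In geometry mode candidates whose
    assembly fails sterically are skipped (reported via ``on_failure``).
    """
    if mode not in ("smiles", "geometry"):
        raise ValueError("mode must be 'smiles' or 'geometry'")
    symmetric = symmetric or template.symmetric_required
    per_slot = admissible_fragments(template, library)
    positions = [s.position for s in template.slots]
    seen: dict[str, ChemBuildingUnit] = {}
    for combo in itertools.product(*(per_slot[p] for p in positions)):
        assignment = dict(zip(positions, combo))
        ok, _ = validate_assignment(template, assignment)
        if not ok:
            continue
        for orientation in expand_orientations(template, assignment, symmetric):
            try:
                if mode == "smiles":
                    smi = assemble_smiles(template, assignment, orientation)
                    cbu = ChemBuildingUnit(
                        smiles=smi,
                        template_name=template.name,
                        fragment_keys={p: assignment[p].key for p in positions},
                        side_chain_keys={
                            p: assignment[p].side_chain_keys for p in positions
                        },
                        orientation=orientation,
                        arrangement=template.arrangement,
                    )
                else:
                    cbu = assemble_geometry(template, assignment, orientation)
                    smi = cbu.smiles
            except AssemblyError as exc:
                if on_failure is not None:
                    on_failure(assignment, orientation, str(exc))
                continue
            seen.setdefault(smi, cbu)
    return [seen[k] for k in sorted(seen)]
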