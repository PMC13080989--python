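"""Purely geometric assembly of MOPs from metal and organic building units.

An assembly model names a polyhedral topology of geometric building unit
(GBU) classes, e.g. ``(3-pyramidal)4(2-linear)6``: four three-connected
metal vertices bridged by six linear two-connected organic units on the
edges of a tetrahedron.  Assembly proceeds in three steps:

1. the reference polyhedron is uniformly scaled so that the separation of
   each connected site pair matches the binding reach of the metal unit
   plus that of the organic unit plus a fixed coordination gap;
2. each building unit is rigidly docked onto its site by least-squares
   (Kabsch) superposition of its binding-site anchors and outward vectors
   onto the site's connection directions;
3. inter-unit nonbonded distances are checked; units in clashing pairs may
   spin about their site axis in fixed increments to escape, otherwise the
   assembly fails.

No force field is involved and metal centers are treated as rigid bodies;
the protocol is deterministic, so identical inputs give identical
coordinates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from fragmops import chem
from fragmops.chem import CLASH_FACTOR, COORDINATION_GAP, SPIN_STEP_DEG
from fragmops.cbu_assembler import ChemBuildingUnit

GBU_CLASSES = ("3-pyramidal", "2-linear", "2-bent", "3-planar")

#: organic template arrangement -> GBU class
ARRANGEMENT_TO_GBU = {
    "two_linear": "2-linear",
    "two_bent": "2-bent",
    "three_planar": "3-planar",
}


class AssemblyFailure(RuntimeError):
    """Unresolvable inter-unit clash (or unit/model mismatch)."""

    def __init__(self, message: str, unit_pair: tuple[int, int] | None = None):
        super().__init__(message)
        self.unit_pair = unit_pair


@dataclass(frozen=True, eq=False)
class AssemblyModel:
    """Polyhedral site frames plus stoichiometry for one MOP topology."""

    name: str
    metal_class: str
    organic_class: str
    metal_positions: np.ndarray      # (n_m, 3) reference coordinates
    organic_positions: np.ndarray    # (n_o, 3)
    edges: tuple[tuple[int, int], ...]  # (metal index, organic index)

    @property
    def stoichiometry(self) -> dict[str, int]:
        return {
            self.metal_class: len(self.metal_positions),
            self.organic_class: len(self.organic_positions),
        }

    @property
    def organic_degree(self) -> int:
        return int(self.organic_class[0])

    def metal_partners(self, m: int) -> list[int]:
        return [o for mm, o in self.edges if mm == m]

    def organic_partners(self, o: int) -> list[int]:
        return [m for m, oo in self.edges if oo == o]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "metal_class": self.metal_class,
            "organic_class": self.organic_class,
            "metal_positions": np.asarray(self.metal_positions).tolist(),
            "organic_positions": np.asarray(self.organic_positions).tolist(),
            "edges": [list(e) for e in self.edges],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AssemblyModel":
        return cls(
            name=d["name"],
            metal_class=d["metal_class"],
            organic_class=d["organic_class"],
            metal_positions=np.asarray(d["metal_positions"], dtype=float),
            organic_positions=np.asarray(d["organic_positions"], dtype=float),
            edges=tuple(tuple(e) for e in d["edges"]),
        )


def _tetrahedron() -> np.ndarray:
    v = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    )
    return v / np.sqrt(3.0)


def default_models() -> list[AssemblyModel]:
    """The four shipped topologies.

    * ``(3-pyramidal)4(2-linear)6`` - metals on tetrahedron vertices,
      linear linkers on the six edges;
    * ``(3-pyramidal)4(3-planar)4`` - tetrahedron vertices plus face
      centers;
    * ``(3-pyramidal)2(2-bent)3`` and ``(3-pyramidal)2(2-linear)3`` -
      trigonal lanterns: metals on the +-z axis, three organics spaced
      120 degrees about z (a deliberately narrow cage for the linear
      variant).
    """
    tet = _tetrahedron()
    edges_lin = []
    mids = []
    for a, b in itertools.combinations(range(4), 2):
        mids.append((tet[a] + tet[b]) / 2.0)
        o = len(mids) - 1
        edges_lin += [(a, o), (b, o)]
    m1 = AssemblyModel(
        "(3-pyramidal)4(2-linear)6", "3-pyramidal", "2-linear",
        tet, np.array(mids), tuple(edges_lin),
    )

    faces = []
    edges_pl = []
    for combo in itertools.combinations(range(4), 3):
        faces.append(tet[list(combo)].mean(axis=0))
        o = len(faces) - 1
        edges_pl += [(m, o) for m in combo]
    m2 = AssemblyModel(
        "(3-pyramidal)4(3-planar)4", "3-pyramidal", "3-planar",
        tet, np.array(faces), tuple(edges_pl),
    )

    apex = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])
    theta = np.radians([0.0, 120.0, 240.0])

    ring_bent = np.stack([np.cos(theta), np.sin(theta), np.zeros(3)], axis=1)
    edges_lant = tuple((m, o) for o in range(3) for m in range(2))
    m3 = AssemblyModel(
        "(3-pyramidal)2(2-bent)3", "3-pyramidal", "2-bent",
        apex, ring_bent, edges_lant,
    )

    ring_lin = 0.5 * ring_bent
    m4 = AssemblyModel(
        "(3-pyramidal)2(2-linear)3", "3-pyramidal", "2-linear",
        apex, ring_lin, edges_lant,
    )
    return [m1, m2, m3, m4]


def get_model(name: str) -> AssemblyModel:
    for m in default_models():
        if m.name == name:
            return m
    raise KeyError(f"unknown assembly model {name!r}")


@dataclass(eq=False)
class MOPStructure:
    """Assembled cage: coordinates plus per-atom unit provenance."""

    elements: list[str]
    coords: np.ndarray
    unit_provenance: list[tuple[int, str, str]]  # (unit index, role, cbu label)
    model_name: str
    scale: float
    unit_slices: list[slice] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def atoms_of_unit(self, unit: int) -> np.ndarray:
        return np.array(
            [i for i, (u, _, _) in enumerate(self.unit_provenance) if u == unit]
        )


def _site_targets(q: np.ndarray, partners_q: list[np.ndarray],
                  reaches: list[float]) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Target anchor points and outward directions for one model site."""
    targets, dirs = [], []
    for pq, reach in zip(partners_q, reaches):
        u = pq - q
        u = u / np.linalg.norm(u)
        targets.append(q + reach * u)
        dirs.append(u)
    return targets, dirs


def _spin_reference(unit: ChemBuildingUnit, center: np.ndarray,
                    axis: np.ndarray) -> np.ndarray | None:
    """Deterministic unit-internal direction perpendicular to the site
    axis, used to resolve the free axial spin of 2-linear units.  Returns
    the perpendicular component of the farthest-off-axis atom (rigid-motion
    covariant); ``None`` when every atom lies on the axis."""
    rel = unit.coords - center
    perp = rel - np.outer(rel @ axis, axis)
    # atom-index weighting breaks the symmetry of equivalent atom pairs in
    # a way that is invariant under rigid motions of the input coordinates
    weights = np.arange(1, len(perp) + 1, dtype=float)
    m = (perp * weights[:, None]).sum(axis=0)
    if np.linalg.norm(m) < 1e-6:
        norms = np.linalg.norm(perp, axis=1)
        best = int(np.argmax(norms))
        if norms[best] < 1e-6:
            return None
        m = perp[best]
    return m / np.linalg.norm(m)


def _dock(unit: ChemBuildingUnit, q: np.ndarray, partners_q: list[np.ndarray]
          ) -> tuple[np.ndarray, list[int]]:
    """Rigidly place a unit at model site ``q`` facing its partners.

    Returns transformed coordinates and the permutation mapping partner
    index -> binding-site index (the one minimizing the superposition
    residual).  When the superposition is axially degenerate (2-linear
    units: anchors and outward vectors collinear) the spin is fixed
    deterministically by rotating the farthest-off-axis atom toward the
    outward radial direction of the site.
    """
    anchors = [bs.anchor for bs in unit.binding_sites]
    dirs = [bs.direction for bs in unit.binding_sites]
    center = unit.center
    k = len(anchors)
    if k != len(partners_q):
        raise AssemblyFailure(
            f"unit has {k} binding sites but site expects {len(partners_q)}"
        )
    best = None
    for perm in itertools.permutations(range(k)):
        reaches = [float(np.linalg.norm(anchors[i] - center)) for i in perm]
        targets, tdirs = _site_targets(q, [partners_q[j] for j in range(k)], reaches)
        src = np.array(
            [anchors[i] for i in perm]
            + [anchors[i] + dirs[i] for i in perm]
            + [center]
        )
        tgt = np.array(targets + [t + d for t, d in zip(targets, tdirs)] + [q])
        src, tgt = _augment_frame(unit, center, q, perm, anchors, src, tgt)
        rot, trans = chem.kabsch(src, tgt)
        resid = float(((src @ rot.T + trans - tgt) ** 2).sum())
        # strict-improvement threshold: permutation ties (symmetric units)
        # resolve to the first permutation regardless of input orientation
        if best is None or resid < best[0] - 1e-9:
            best = (resid, rot, trans, list(perm))
    _, rot, trans, perm = best
    return unit.coords @ rot.T + trans, perm


def _augment_frame(unit, center, q, perm, anchors, src, tgt):
    """Append orientation-completing pseudo-point pairs so the rigid fit is
    full rank: a near-collinear 2-site constraint set leaves the axial spin
    (and the reflection branch of the superposition) numerically free, and
    a planar 3-site set leaves the reflection free.  The added pairs are
    covariant with rigid motions of the unit, so docking stays exactly
    invariant to the input frame."""
    k = len(anchors)
    src = np.asarray(src, dtype=float)
    tgt = np.asarray(tgt, dtype=float)
    if k == 2:
        axis_l = anchors[perm[1]] - anchors[perm[0]]
        na = np.linalg.norm(axis_l)
        axis_t = tgt[1] - tgt[0]
        nt = np.linalg.norm(axis_t)
        if na < 1e-9 or nt < 1e-9:
            return src, tgt
        axis_l, axis_t = axis_l / na, axis_t / nt
        m_ref = _spin_reference(unit, center, axis_l)
        if m_ref is None:
            return src, tgt
        n_ref = None
        for cand in (q, np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0])):
            rej = cand - (cand @ axis_t) * axis_t
            if np.linalg.norm(rej) > 1e-6:
                n_ref = rej / np.linalg.norm(rej)
                break
        extra_src = [center + m_ref, center + np.cross(axis_l, m_ref)]
        extra_tgt = [q + n_ref, q + np.cross(axis_t, n_ref)]
        return np.vstack([src, extra_src]), np.vstack([tgt, extra_tgt])
    if k == 3:
        nu_s = np.cross(anchors[perm[1]] - anchors[perm[0]],
                        anchors[perm[2]] - anchors[perm[0]])
        nu_t = np.cross(tgt[1] - tgt[0], tgt[2] - tgt[0])
        ns, ntn = np.linalg.norm(nu_s), np.linalg.norm(nu_t)
        if ns < 1e-9 or ntn < 1e-9:
            return src, tgt
        return (
            np.vstack([src, center + nu_s / ns]),
            np.vstack([tgt, q + nu_t / ntn]),
        )
    return src, tgt


def _fit_scale(model: AssemblyModel, reach_m: float, reach_o: float,
               gap: float) -> float:
    num = den = 0.0
    for m, o in model.edges:
        length = float(
            np.linalg.norm(model.metal_positions[m] - model.organic_positions[o])
        )
        num += length * (reach_m + reach_o + gap)
        den += length * length
    return num / den


def _clash_pairs(units, clash_factor, exclusions):
    """Indices of unit pairs with a nonbonded contact below threshold."""
    bad = []
    for (i, (ci, ri)), (j, (cj, rj)) in itertools.combinations(enumerate(units), 2):
        mask_i = exclusions.get((i, j))
        mask_j = exclusions.get((j, i))
        sel_i = np.ones(len(ci), dtype=bool)
        sel_j = np.ones(len(cj), dtype=bool)
        if mask_i is not None:
            sel_i[mask_i] = False
        if mask_j is not None:
            sel_j[mask_j] = False
        gap = chem.pairwise_min_gap(
            ci[sel_i], clash_factor * ri[sel_i], cj[sel_j], clash_factor * rj[sel_j]
        )
        if gap < 0.0:
            bad.append((i, j))
    return bad


def assemble_mop(
    model: AssemblyModel,
    metal: ChemBuildingUnit,
    organic: ChemBuildingUnit,
    clash_factor: float = CLASH_FACTOR,
    spin_step: float = SPIN_STEP_DEG,
    coordination_gap: float = COORDINATION_GAP,
) -> MOPStructure:
    """Assemble one MOP from a metal unit, an organic unit and a model.

    Raises :class:`AssemblyFailure` on arity mismatch or when inter-unit
    clashes survive the axial-spin scan of the 2-class organic units.
    """
    if len(metal.binding_sites) != 3:
        raise AssemblyFailure(
            f"metal unit must expose 3 binding sites for class {model.metal_class}"
        )
    want = ARRANGEMENT_TO_GBU.get(organic.arrangement, organic.arrangement)
    if want != model.organic_class:
        raise AssemblyFailure(
            f"organic unit class {want} does not match model class "
            f"{model.organic_class}"
        )
    if len(organic.binding_sites) != model.organic_degree:
        raise AssemblyFailure(
            f"organic unit exposes {len(organic.binding_sites)} sites, "
            f"model expects {model.organic_degree}"
        )

    scale = _fit_scale(model, metal.reach, organic.reach, coordination_gap)
    qm = scale * np.asarray(model.metal_positions, dtype=float)
    qo = scale * np.asarray(model.organic_positions, dtype=float)

    placed: list[np.ndarray] = []
    radii: list[np.ndarray] = []
    roles: list[str] = []
    site_perms: list[list[int]] = []
    n_m = len(qm)

    for m in range(n_m):
        coords, perm = _dock(metal, qm[m], [qo[o] for o in model.metal_partners(m)])
        placed.append(coords)
        radii.append(chem.vdw_array(metal.elements))
        roles.append("metal")
        site_perms.append(perm)
    for o in range(len(qo)):
        coords, perm = _dock(organic, qo[o], [qm[m] for m in model.organic_partners(o)])
        placed.append(coords)
        radii.append(chem.vdw_array(organic.elements))
        roles.append("organic")
        site_perms.append(perm)

    # clash exclusions: the binding group of an organic unit may approach
    # the metal unit it coordinates to
    exclusions: dict[tuple[int, int], list[int]] = {}
    for o in range(len(qo)):
        u_o = n_m + o
        partners = model.organic_partners(o)
        perm = site_perms[u_o]  # perm[k] = binding-site index docked to partner k
        for k, site_idx in enumerate(perm):
            u_m = partners[k]
            exclusions[(u_o, u_m)] = list(organic.binding_sites[site_idx].atoms)

    units = list(zip(placed, radii))
    bad = _clash_pairs(units, clash_factor, exclusions)

    if bad and organic.arrangement in ("two_linear", "two_bent"):
        involved = sorted(
            {u for pair in bad for u in pair if roles[u] == "organic"}
        )
        for u in involved:
            coords0 = units[u][0]
            bs = organic.binding_sites
            a0 = coords0[list(bs[0].atoms)].mean(axis=0)
            a1 = coords0[list(bs[1].atoms)].mean(axis=0)
            axis = a1 - a0
            if np.linalg.norm(axis) < 1e-8:
                continue
            axis = axis / np.linalg.norm(axis)
            for step in range(1, int(round(360.0 / spin_step))):
                rot = chem.rotation_about_axis(axis, np.radians(step * spin_step))
                trial = (coords0 - a0) @ rot.T + a0
                units[u] = (trial, units[u][1])
                if not any(u in pair for pair in _clash_pairs(
                        units, clash_factor, exclusions)):
                    break
            else:
                units[u] = (coords0, units[u][1])
        bad = _clash_pairs(units, clash_factor, exclusions)

    if bad:
        raise AssemblyFailure(
            f"inter-unit clash between units {bad[0][0]} and {bad[0][1]}",
            unit_pair=bad[0],
        )

    elements: list[str] = []
    coords_all: list[np.ndarray] = []
    provenance: list[tuple[int, str, str]] = []
    slices: list[slice] = []
    for u, (coords, _) in enumerate(units):
        unit_elems = metal.elements if roles[u] == "metal" else organic.elements
        label = (metal.label or metal.smiles or "metal") if roles[u] == "metal" \
            else (organic.label or organic.smiles or "organic")
        start = len(elements)
        elements.extend(unit_elems)
        coords_all.append(coords)
        provenance.extend((u, roles[u], label) for _ in unit_elems)
        slices.append(slice(start, len(elements)))
    return MOPStructure(
        elements=elements,
        coords=np.vstack(coords_all),
        unit_provenance=provenance,
        model_name=model.name,
        scale=float(scale),
        unit_slices=slices,
    )


def count_configurations(cbu_sets: dict, models, metals) -> int:
    """Total number of MOP configurations: sum over models of the count of
    compatible organic CBUs times the count of metal units (pure
    combinatorics, no assembly attempted)."""
    total = 0
    for model in models:
        organics = cbu_sets.get(model.organic_class, ())
        total += len(organics) * len(metals)
    return total
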