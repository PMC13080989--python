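"""Fragmentation of organic CBUs into typed molecular fragments.

An organic chemical building unit (CBU) is decomposed by cleaving every
exocyclic, non-hydrogen single bond and capping each cut with a dummy atom
(``*``) on either side; the dummy is placed at the position of the removed
neighbor, so the recorded geometry can later reproduce the original bond on
reassembly.  Fragments are typed by bonding-site count: one site -> side
chain, two -> linker, three or more -> node.  Binding groups (carboxylate,
pyrazolate, ...) are recognized by substructure patterns before any other
typing and are exempt from the site-count rule.  One-site fragments that are
*not* binding groups are treated as decorations: they are emitted as side
chains and their attachment point on the parent fragment is reverted to a
hydrogen, which keeps the parent a clean backbone fragment that can be
re-functionalized in a controlled way later.

Deduplication across a library is by canonical SMILES of the dummy-bearing
fragment graph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdmolops
from rdkit.Geometry import Point3D

from fragmops import chem
from fragmops.chem import LINEAR_TOL_DEG

FRAG_TYPES = ("binding_group", "linker", "node", "side_chain", "untyped")

#: default binding-group substructure patterns (SMARTS), matched against the
#: heavy-atom graph of a fragment
DEFAULT_BINDING_GROUP_SMARTS: tuple[str, ...] = (
    "[CX3](=O)[OX1-]",          # carboxylate
    "c1c[n-]nc1",               # pyrazolate
)

_PAIR_PROP = "fragmops_cut"


class FragmentationError(ValueError):
    pass


def _strip_site_labels(mol: Chem.Mol) -> Chem.Mol:
    out = Chem.Mol(mol)
    for atom in out.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomMapNum(0)
            atom.SetIsotope(0)
    return out


def canonical_key(frag: "Fragment | Chem.Mol | str") -> str:
    """Canonical SMILES key identifying a fragment graph (dummies included).

    Equal molecular graphs, including dummy placement, map to equal keys
    regardless of atom order; bookkeeping labels on dummies are ignored.
    """
    if isinstance(frag, Fragment):
        mol = frag.mol
    elif isinstance(frag, str):
        mol = chem.mol_from_smiles(frag)
    else:
        mol = frag
    clean = _strip_site_labels(mol)
    clean = Chem.RemoveHs(clean, sanitize=False)
    Chem.SanitizeMol(clean)
    return Chem.MolToSmiles(clean)


def bonding_sites(mol: Chem.Mol) -> list[int]:
    """Dummy-atom indices in deterministic (canonical-rank) order."""
    ranks = list(Chem.CanonicalRankAtoms(_strip_site_labels(mol), breakTies=True))
    sites = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    return sorted(sites, key=lambda i: ranks[i])


def _is_two_site_symmetric(mol: Chem.Mol) -> bool:
    """A 2-site fragment is symmetric iff its two sites are exchangeable."""
    sites = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(sites) != 2:
        return False
    smis = []
    for order in ((1, 2), (2, 1)):
        tagged = _strip_site_labels(mol)
        for idx, iso in zip(sites, order):
            tagged.GetAtomWithIdx(idx).SetIsotope(iso)
        smis.append(Chem.MolToSmiles(Chem.RemoveHs(tagged, sanitize=False)))
    return smis[0] == smis[1]


def _linear_flag(mol: Chem.Mol, tol_deg: float = LINEAR_TOL_DEG) -> bool:
    """True when the two (site-neighbor -> dummy) vectors are antiparallel
    within ``tol_deg`` after projection; False for fragments without exactly
    two sites or without coordinates."""
    sites = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(sites) != 2 or mol.GetNumConformers() == 0:
        return False
    pos = chem.coords_of(mol)
    vecs = []
    for atom in sites:
        nb = atom.GetNeighbors()[0]
        v = pos[atom.GetIdx()] - pos[nb.GetIdx()]
        n = np.linalg.norm(v)
        if n < 1e-8:
            return False
        vecs.append(v / n)
    cosang = float(np.clip(np.dot(vecs[0], vecs[1]), -1.0, 1.0))
    return bool(np.degrees(np.arccos(cosang)) >= 180.0 - tol_deg)


@dataclass(frozen=True)
class Fragment:
    """A molecular fragment with dummy-atom bonding sites and rigid geometry.

    ``mol`` is the authoritative representation (explicit hydrogens where
    known, one conformer when geometry is available); ``smiles`` is its
    canonical key.  ``side_chain_keys`` records side chains grafted onto the
    fragment by :func:`substitute_linker`, which downstream synthesizability
    terms query.
    """

    mol: Chem.Mol
    frag_type: str = "untyped"
    side_chain_keys: tuple[str, ...] = ()
    smiles: str = field(init=False)
    flags: dict = field(init=False)

    def __post_init__(self):
        if self.frag_type not in FRAG_TYPES:
            raise ValueError(f"unknown frag_type {self.frag_type!r}")
        object.__setattr__(self, "smiles", canonical_key(self.mol))
        object.__setattr__(
            self,
            "flags",
            {
                "cyclic": any(a.IsInRing() for a in self.mol.GetAtoms()),
                "linear": _linear_flag(self.mol),
                "symmetric": _is_two_site_symmetric(self.mol),
            },
        )

    @classmethod
    def from_smiles(cls, smiles: str, frag_type: str = "untyped",
                    embed: bool = True, seed: int = 2024,
                    side_chain_keys: tuple[str, ...] = ()) -> "Fragment":
        mol = chem.mol_from_smiles(smiles)
        if embed:
            mol = chem.embed_with_dummies(mol, seed=seed)
        return cls(mol=mol, frag_type=frag_type, side_chain_keys=side_chain_keys)

    @property
    def n_sites(self) -> int:
        return sum(1 for a in self.mol.GetAtoms() if a.GetAtomicNum() == 0)

    @property
    def key(self) -> str:
        return self.smiles

    @property
    def geometry(self) -> list[tuple[str, float, float, float]]:
        """(element, x, y, z) rows; dummies appear as ``X``."""
        if self.mol.GetNumConformers() == 0:
            return []
        pos = chem.coords_of(self.mol)
        out = []
        for atom, p in zip(self.mol.GetAtoms(), pos):
            sym = "X" if atom.GetAtomicNum() == 0 else atom.GetSymbol()
            out.append((sym, float(p[0]), float(p[1]), float(p[2])))
        return out

    @property
    def n_heavy(self) -> int:
        return sum(1 for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1)

    def sites(self) -> list[int]:
        return bonding_sites(self.mol)

    def __hash__(self):
        return hash((self.smiles, self.frag_type))

    def __eq__(self, other):
        return (
            isinstance(other, Fragment)
            and self.smiles == other.smiles
            and self.frag_type == other.frag_type
        )


class FragmentLibrary:
    """Fragments keyed by canonical SMILES; insertion is idempotent."""

    def __init__(self, fragments=()):
        self._by_key: dict[str, Fragment] = {}
        for f in fragments:
            self.add(f)

    def add(self, frag: Fragment) -> bool:
        """Add a fragment; returns False when its key was already present."""
        if frag.key in self._by_key:
            return False
        self._by_key[frag.key] = frag
        return True

    def update(self, frags) -> None:
        for f in frags:
            self.add(f)

    def __len__(self):
        return len(self._by_key)

    def __contains__(self, key: str):
        return key in self._by_key

    def __getitem__(self, key: str) -> Fragment:
        return self._by_key[key]

    def __iter__(self):
        return iter(self.fragments)

    @property
    def fragments(self) -> list[Fragment]:
        """Fragments in deterministic (canonical key) order."""
        return [self._by_key[k] for k in sorted(self._by_key)]

    def by_type(self, frag_type: str) -> list[Fragment]:
        return [f for f in self.fragments if f.frag_type == frag_type]

    @property
    def counts_by_type(self) -> dict[str, int]:
        counts = {t: 0 for t in FRAG_TYPES}
        for f in self.fragments:
            counts[f.frag_type] += 1
        return counts


def _compile_patterns(patterns) -> list[Chem.Mol]:
    compiled = []
    for p in patterns:
        q = Chem.MolFromSmarts(p) if isinstance(p, str) else p
        if q is None:
            raise ValueError(f"bad binding-group SMARTS: {p!r}")
        compiled.append(q)
    return compiled


def _matches_binding_group(mol: Chem.Mol, patterns: list[Chem.Mol]) -> bool:
    """True when a pattern match covers every heavy non-dummy atom."""
    heavy = {a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1}
    for patt in patterns:
        for match in mol.GetSubstructMatches(patt):
            if heavy <= set(match):
                return True
    return False


def _cleavable_bonds(mol: Chem.Mol, patterns: list[Chem.Mol]) -> list[int]:
    """Exocyclic, non-hydrogen single bonds outside binding-group matches."""
    protected: set[int] = set()
    for patt in patterns:
        for match in mol.GetSubstructMatches(patt):
            ms = set(match)
            for bond in mol.GetBonds():
                if bond.GetBeginAtomIdx() in ms and bond.GetEndAtomIdx() in ms:
                    protected.add(bond.GetIdx())
    out = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.GetIsAromatic():
            continue
        if bond.IsInRing() or bond.GetIdx() in protected:
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
            continue
        out.append(bond.GetIdx())
    return out


def _cleave(mol: Chem.Mol, bond_ids: list[int]) -> Chem.Mol:
    """Break the listed bonds, capping each end with a labeled dummy placed
    at the former neighbor position (labels pair the two new dummies)."""
    has_conf = mol.GetNumConformers() > 0
    pos = list(chem.coords_of(mol)) if has_conf else None
    rw = Chem.RWMol(mol)
    cuts = [
        (rw.GetBondWithIdx(b).GetBeginAtomIdx(), rw.GetBondWithIdx(b).GetEndAtomIdx())
        for b in bond_ids
    ]
    for label, (i, j) in enumerate(cuts, start=1):
        rw.RemoveBond(i, j)
        for here, there in ((i, j), (j, i)):
            d = Chem.Atom(0)
            d.SetAtomMapNum(label)
            d.SetNoImplicit(True)
            idx = rw.AddAtom(d)
            rw.AddBond(here, idx, Chem.BondType.SINGLE)
            if has_conf:
                pos.append(np.array(pos[there], dtype=float))
    out = rw.GetMol()
    if has_conf:
        conf = Chem.Conformer(out.GetNumAtoms())
        for k, p in enumerate(pos):
            conf.SetAtomPosition(k, Point3D(*[float(x) for x in p]))
        out.RemoveAllConformers()
        out.AddConformer(conf, assignId=True)
    Chem.SanitizeMol(out)
    return out


def _revert_dummy_to_h(mol: Chem.Mol, dummy_idx: int) -> Chem.Mol:
    """Replace one dummy by a hydrogen at a standard X-H bond length."""
    rw = Chem.RWMol(mol)
    atom = rw.GetAtomWithIdx(dummy_idx)
    nb = atom.GetNeighbors()[0]
    atom.SetAtomicNum(1)
    atom.SetAtomMapNum(0)
    atom.SetNoImplicit(True)
    out = rw.GetMol()
    if out.GetNumConformers() > 0:
        pos = chem.coords_of(out)
        v = pos[dummy_idx] - pos[nb.GetIdx()]
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            length = {"C": 1.09, "N": 1.01, "O": 0.96, "S": 1.34}.get(nb.GetSymbol(), 1.09)
            newp = pos[nb.GetIdx()] + v / norm * length
            out.GetConformer().SetAtomPosition(dummy_idx, Point3D(*map(float, newp)))
    Chem.SanitizeMol(out)
    return out


def fragment_cbu(
    cbu: "Chem.Mol | str",
    binding_group_patterns=DEFAULT_BINDING_GROUP_SMARTS,
    embed_seed: int = 2024,
) -> list[Fragment]:
    """Fragment an organic CBU into typed fragments.

    Every exocyclic non-hydrogen single bond is cleaved and both ends are
    capped with dummy atoms.  Bonds interior to a binding-group pattern
    match are protected so the group survives as one unit.  One-site
    fragments that are not binding groups become side chains and their
    attachment point on the (non-side-chain) parent is reverted to H.

    Parameters
    ----------
    cbu : rdkit Mol or SMILES
        Single-component molecular graph.  If no conformer is present one
        is generated so fragments carry extraction geometry.
    binding_group_patterns : sequence of SMARTS
        Patterns whose full-fragment matches are typed ``binding_group``.
    """
    mol = chem.mol_from_smiles(cbu) if isinstance(cbu, str) else Chem.Mol(cbu)
    if len(rdmolops.GetMolFrags(mol)) != 1:
        raise FragmentationError("input molecule is disconnected")
    patterns = _compile_patterns(binding_group_patterns)

    if mol.GetNumConformers() == 0:
        mol = chem.embed_with_dummies(mol, seed=embed_seed)
    else:
        mol = Chem.AddHs(mol, addCoords=True)

    bonds = _cleavable_bonds(mol, patterns)
    if not bonds:
        return [Fragment(mol=mol, frag_type="untyped")]

    cut = _cleave(mol, bonds)
    frag_idx_groups = rdmolops.GetMolFrags(cut)
    frag_mols = list(rdmolops.GetMolFrags(cut, asMols=True, sanitizeFrags=False))
    for fm in frag_mols:
        Chem.SanitizeMol(fm)

    n_sites = [
        sum(1 for a in fm.GetAtoms() if a.GetAtomicNum() == 0) for fm in frag_mols
    ]
    is_bg = [_matches_binding_group(fm, patterns) for fm in frag_mols]
    is_side = [
        (not bg) and ns == 1 for bg, ns in zip(is_bg, n_sites)
    ]

    # labels of cuts whose one-site end is a side chain -> revert the twin
    # dummy on the parent fragment to hydrogen
    side_labels: set[int] = set()
    for fm, side in zip(frag_mols, is_side):
        if side:
            for a in fm.GetAtoms():
                if a.GetAtomicNum() == 0:
                    side_labels.add(a.GetAtomMapNum())

    results: list[Fragment] = []
    for fm, bg, side in zip(frag_mols, is_bg, is_side):
        if bg:
            results.append(Fragment(mol=_strip_site_labels(fm), frag_type="binding_group"))
            continue
        if side:
            results.append(Fragment(mol=_strip_site_labels(fm), frag_type="side_chain"))
            continue
        # parent fragment: revert attachment points of side chains to H
        work = fm
        while True:
            target = next(
                (
                    a.GetIdx()
                    for a in work.GetAtoms()
                    if a.GetAtomicNum() == 0 and a.GetAtomMapNum() in side_labels
                ),
                None,
            )
            if target is None:
                break
            work = _revert_dummy_to_h(work, target)
        ns = sum(1 for a in work.GetAtoms() if a.GetAtomicNum() == 0)
        if ns >= 3:
            ftype = "node"
        elif ns == 2:
            ftype = "linker"
        elif ns == 1:
            ftype = "side_chain"
        else:
            ftype = "untyped"
        results.append(Fragment(mol=_strip_site_labels(work), frag_type=ftype))
    return results


def fragment_to_library(
    cbus, binding_group_patterns=DEFAULT_BINDING_GROUP_SMARTS
) -> FragmentLibrary:
    """Fragment many CBUs and collect unique fragments into a library."""
    lib = FragmentLibrary()
    for cbu in cbus:
        lib.update(fragment_cbu(cbu, binding_group_patterns))
    return lib


def is_cleavage_stable(frag: Fragment,
                       binding_group_patterns=DEFAULT_BINDING_GROUP_SMARTS) -> bool:
    """True when the fragment is a fixed point of the cleavage rule, i.e.
    contains no cleavable bond itself (bonds to dummies excluded).
    Fragments produced by exhaustive fragmentation have this property by
    construction."""
    patterns = _compile_patterns(binding_group_patterns)
    for b in _cleavable_bonds(frag.mol, patterns):
        bond = frag.mol.GetBondWithIdx(b)
        if (bond.GetBeginAtom().GetAtomicNum() == 0
                or bond.GetEndAtom().GetAtomicNum() == 0):
            continue
        return False
    return True


def substitute_linker(linker: Fragment, side_chain: Fragment) -> list[Fragment]:
    """Graft a one-site side chain onto each symmetry-distinct C-H position
    of a two-site linker, returning the unique asymmetric linker products.

    The graft uses the same local-frame bonding-site join as the geometric
    CBU assembler (the replaced hydrogen plays the role of the host dummy),
    so products carry consistent 3D geometry.  Products are deduplicated by
    canonical key and returned in key order.
    """
    from fragmops.cbu_assembler import join_geometry  # local: avoids cycle

    if linker.n_sites != 2:
        raise ValueError("linker must have exactly 2 bonding sites")
    if side_chain.n_sites != 1:
        raise ValueError("side chain must have exactly 1 bonding site")
    if side_chain.n_heavy == 0:
        raise ValueError("degenerate (empty) side chain is not substitutable")

    host = linker.mol
    sc_site = side_chain.sites()[0]
    seen: dict[str, Fragment] = {}
    for atom in host.GetAtoms():
        if atom.GetAtomicNum() != 6:
            continue
        h_idx = next(
            (nb.GetIdx() for nb in atom.GetNeighbors() if nb.GetAtomicNum() == 1),
            None,
        )
        if h_idx is None:
            continue
        joined = join_geometry(host, h_idx, side_chain.mol, sc_site)
        if joined is None:
            continue
        frag = Fragment(
            mol=joined,
            frag_type="linker",
            side_chain_keys=linker.side_chain_keys + (side_chain.key,),
        )
        seen.setdefault(frag.key, frag)
    return [seen[k] for k in sorted(seen)]


def make_asymmetric_linkers(linker: Fragment, side_chains) -> list[Fragment]:
    """Single C-H substitution of one linker with each of several side
    chains; the union is deduplicated by canonical key."""
    out: dict[str, Fragment] = {}
    for sc in side_chains:
        for prod in substitute_linker(linker, sc):
            out.setdefault(prod.key, prod)
    return [out[k] for k in sorted(out)]
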