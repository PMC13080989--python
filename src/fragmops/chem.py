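"""Shared cheminformatics helpers and numerical constants.

All geometry is in angstroms.  Dummy atoms (atomic number 0, SMILES ``*``)
mark bonding sites throughout the package; a fragment's dummy atom sits at
the position formerly occupied by the neighbor it was cleaved from, so a
dummy <-> neighbor mapping between two fragments reproduces the original
bond length by construction.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.warning")
RDLogger.DisableLog("rdApp.error")

# Bondi van der Waals radii (A) with a few extensions for metals; the
# fallback covers elements not in the table.  Dummy atoms have zero radius
# so they never participate in clash checks.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
    "Se": 1.90, "Zn": 2.01, "Cu": 1.96, "Zr": 2.36, "V": 2.10, "Fe": 2.05,
    "Cr": 2.06, "Mo": 2.17, "*": 0.0, "X": 0.0,
}
VDW_DEFAULT = 1.70

# Pyykko-style single-bond covalent radii (A), used when a new bond must be
# given a chemically sensible length (e.g. replacing an H by a side chain).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
    "Se": 1.20, "Zn": 1.18, "Zr": 1.54, "V": 1.34,
}
COVALENT_DEFAULT = 0.76

#: nonbonded pair counts as a clash when closer than this factor times the
#: sum of the two vdW radii
CLASH_FACTOR = 0.7
#: torsion-scan increment about a freshly created junction bond (degrees)
TORSION_STEP_DEG = 10.0
#: axial-spin increment for 2-class units during MOP assembly (degrees)
SPIN_STEP_DEG = 15.0
#: a 2-site fragment is "linear" when its two site vectors are within this
#: many degrees of antiparallel
LINEAR_TOL_DEG = 15.0
#: assumed binding-group-to-metal coordination gap during MOP scale fitting (A)
COORDINATION_GAP = 2.2


def vdw_radius(symbol: str, overrides: dict[str, float] | None = None) -> float:
    if overrides and symbol in overrides:
        return overrides[symbol]
    return VDW_RADII.get(symbol, VDW_DEFAULT)


def covalent_radius(symbol: str) -> float:
    return COVALENT_RADII.get(symbol, COVALENT_DEFAULT)


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse SMILES, raising ``ValueError`` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def coords_of(mol: Chem.Mol) -> np.ndarray:
    """(N, 3) array of conformer coordinates."""
    conf = mol.GetConformer()
    return np.array(conf.GetPositions(), dtype=float)


def set_coords(mol: Chem.Mol, coords: np.ndarray) -> None:
    conf = mol.GetConformer()
    for i, p in enumerate(coords):
        conf.SetAtomPosition(i, tuple(float(x) for x in p))


def symbols_of(mol: Chem.Mol) -> list[str]:
    return [a.GetSymbol() for a in mol.GetAtoms()]


def vdw_array(symbols, overrides=None) -> np.ndarray:
    return np.array([vdw_radius(s, overrides) for s in symbols], dtype=float)


def embed_with_dummies(mol: Chem.Mol, seed: int = 2024) -> Chem.Mol:
    """Generate 3D coordinates for a molecule that may contain dummy atoms.

    Dummies are temporarily promoted to carbon so distance-geometry embedding
    and the UFF relaxation see a chemically sensible cap; the cap position is
    retained as the dummy position, which is exactly the "dummy at the former
    neighbor position" convention used for fragment joining.  Hydrogens are
    made explicit and kept.
    """
    work = Chem.RWMol(mol)
    dummy_idx = [a.GetIdx() for a in work.GetAtoms() if a.GetAtomicNum() == 0]
    for i in dummy_idx:
        work.GetAtomWithIdx(i).SetAtomicNum(6)
    capped = work.GetMol()
    Chem.SanitizeMol(capped)
    capped = Chem.AddHs(capped)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    if AllChem.EmbedMolecule(capped, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(capped, params) != 0:
            raise ValueError(f"embedding failed for {Chem.MolToSmiles(mol)}")
    try:
        AllChem.UFFOptimizeMolecule(capped, maxIters=500)
    except Exception:  # pragma: no cover - relaxation is best-effort
        pass
    out = Chem.RWMol(capped)
    # demote caps back to dummies and strip the hydrogens that AddHs put on them
    cap_h = []
    for i in dummy_idx:
        atom = out.GetAtomWithIdx(i)
        atom.SetAtomicNum(0)
        atom.SetNoImplicit(True)
        atom.SetNumExplicitHs(0)
        for nb in atom.GetNeighbors():
            if nb.GetAtomicNum() == 1:
                cap_h.append(nb.GetIdx())
    for i in sorted(cap_h, reverse=True):
        out.RemoveAtom(i)
    final = out.GetMol()
    Chem.SanitizeMol(final, Chem.SANITIZE_ALL ^ Chem.SANITIZE_ADJUSTHS)
    return final


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (normalized) axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + np.sin(angle_rad) * k + (1.0 - np.cos(angle_rad)) * (k @ k)


def kabsch(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition mapping ``source`` onto ``target``.

    Returns ``(R, t)`` with ``target ~ source @ R.T + t``.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    sc = src.mean(axis=0)
    tc = tgt.mean(axis=0)
    h = (src - sc).T @ (tgt - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return rot, tc - rot @ sc


def pairwise_min_gap(
    coords_a: np.ndarray,
    radii_a: np.ndarray,
    coords_b: np.ndarray,
    radii_b: np.ndarray,
) -> float:
    """Minimum of distance minus vdW-sum over all cross pairs (negative = overlap)."""
    if len(coords_a) == 0 or len(coords_b) == 0:
        return np.inf
    diff = coords_a[:, None, :] - coords_b[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    return float((dist - (radii_a[:, None] + radii_b[None, :])).min())
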