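"""Cavity and synthesizability descriptors.

The inner sphere is the largest sphere centered at the cage centroid that
touches no atom's van der Waals surface; its diameter and volume are the
primary cavity descriptors.  Window diameter is estimated by casting rays
from the centroid over a Fibonacci sphere, clustering the escaping rays
into windows by angular adjacency and reporting twice the best clearance
per window.  Synthesizability is quantified with the Ertl-Schuffenhauer
synthetic accessibility score (fragment-contribution plus complexity
penalty, 1 = easy to 10 = hard) and the number of side-chain fragments a
CBU carries, read from its fragment provenance.
"""

from __future__ import annotations

import importlib.util
import math
import os
import sys
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, RDConfig

from fragmops import chem
from fragmops.cbu_assembler import ChemBuildingUnit
from fragmops.mop_assembler import MOPStructure


@dataclass(frozen=True)
class CavityReport:
    inner_sphere_diameter: float  # A
    inner_sphere_volume: float    # A^3
    window_diameter: float        # A
    centroid: np.ndarray


@dataclass(frozen=True)
class SynthReport:
    sa_score: float
    side_chain_count: int
    mol_weight: float  # g/mol


def _as_coords(mop) -> tuple[list[str], np.ndarray]:
    if isinstance(mop, MOPStructure):
        return mop.elements, np.asarray(mop.coords, dtype=float)
    elements, coords = mop
    return list(elements), np.asarray(coords, dtype=float)


def inner_sphere(mop, vdw_overrides: dict | None = None) -> tuple[float, float]:
    """Diameter (A) and volume (A^3) of the largest centroid-centered
    sphere touching no vdW surface.

    ``diameter = 2 * max(0, min_i(|r_i - c| - vdW_i))`` with ``c`` the
    unweighted centroid; a centroid inside an atom gives diameter 0.
    """
    elements, coords = _as_coords(mop)
    if len(coords) == 0:
        raise ValueError("empty structure")
    c = coords.mean(axis=0)
    radii = chem.vdw_array(elements, vdw_overrides)
    clearance = np.linalg.norm(coords - c, axis=1) - radii
    diameter = 2.0 * max(0.0, float(clearance.min()))
    volume = math.pi / 6.0 * diameter**3
    return diameter, volume


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    phi = (1.0 + 5.0**0.5) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = 2.0 * math.pi * i / phi
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def window_diameter(
    mop,
    n_rays: int = 2048,
    cluster_deg: float = 12.0,
    vdw_overrides: dict | None = None,
) -> float:
    """Largest probe diameter (A) that escapes the cage through a window.

    For each ray from the centroid the bottleneck clearance is the minimum
    over atoms of (distance from the atom to the ray) minus the vdW radius;
    escaping rays (positive clearance) are clustered into windows by
    angular adjacency and the maximum clearance per cluster defines that
    window's radius.  Returns 0 when no ray escapes.
    """
    elements, coords = _as_coords(mop)
    if len(coords) == 0:
        raise ValueError("empty structure")
    c = coords.mean(axis=0)
    radii = chem.vdw_array(elements, vdw_overrides)
    rel = coords - c
    dirs = _fibonacci_sphere(n_rays)

    # distance from each atom to each ray (a half line from the centroid)
    proj = rel @ dirs.T                      # (atoms, rays)
    perp = np.sqrt(
        np.maximum(0.0, (rel**2).sum(axis=1)[:, None] - np.maximum(proj, 0.0) ** 2)
    )
    dist_to_ray = np.where(
        proj > 0.0, perp, np.linalg.norm(rel, axis=1)[:, None]
    )
    clearance = (dist_to_ray - radii[:, None]).min(axis=0)   # per ray

    escape = clearance > 0.0
    if not escape.any():
        return 0.0

    idx = np.where(escape)[0]
    cos_thr = math.cos(math.radians(cluster_deg))
    # union-find over angularly adjacent escape rays
    parent = {int(i): int(i) for i in idx}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    dsub = dirs[idx]
    cosm = dsub @ dsub.T
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            if cosm[a, b] >= cos_thr:
                ra, rb = find(int(idx[a])), find(int(idx[b]))
                if ra != rb:
                    parent[ra] = rb

    best_per_cluster: dict[int, float] = {}
    for i in idx:
        root = find(int(i))
        best_per_cluster[root] = max(
            best_per_cluster.get(root, 0.0), float(clearance[i])
        )
    return 2.0 * max(best_per_cluster.values())


def cavity_report(mop, **kwargs) -> CavityReport:
    d, v = inner_sphere(mop, vdw_overrides=kwargs.get("vdw_overrides"))
    w = window_diameter(mop, **kwargs)
    _, coords = _as_coords(mop)
    return CavityReport(d, v, w, coords.mean(axis=0))


_sascorer = None


def _load_sascorer():
    global _sascorer
    if _sascorer is None:
        path = os.path.join(RDConfig.RDContribDir, "SA_Score", "sascorer.py")
        spec = importlib.util.spec_from_file_location("sascorer", path)
        mod = importlib.util.module_from_spec(spec)
        sys.modules["sascorer"] = mod
        spec.loader.exec_module(mod)
        _sascorer = mod
    return _sascorer


def sa_score(smiles: "str | Chem.Mol") -> float:
    """Ertl-Schuffenhauer synthetic accessibility score on [1, 10]."""
    mol = chem.mol_from_smiles(smiles) if isinstance(smiles, str) else smiles
    if any(a.GetAtomicNum() == 0 for a in mol.GetAtoms()):
        raise ValueError("sa_score is undefined for molecules with dummy atoms")
    return float(_load_sascorer().calculateScore(mol))


def side_chain_count(cbu: ChemBuildingUnit) -> int:
    """Number of side-chain fragments in a CBU, from slot provenance."""
    if cbu.side_chain_keys is None:
        raise ValueError("CBU carries no fragment provenance")
    return sum(len(keys) for keys in cbu.side_chain_keys.values())


def synth_report(cbu: ChemBuildingUnit) -> SynthReport:
    mol = cbu.mol if cbu.mol is not None else chem.mol_from_smiles(cbu.smiles)
    return SynthReport(
        sa_score=sa_score(Chem.RemoveHs(Chem.Mol(mol))),
        side_chain_count=side_chain_count(cbu),
        mol_weight=float(Descriptors.MolWt(mol)),
    )
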