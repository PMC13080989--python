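"""Synthetic fixture libraries, file I/O and structured logging.

The fixture generator reproduces the *category structure* of a curated MOP
fragment library - binding groups (carboxylate and pyrazolate), three-site
node fragments, linear cyclic linkers, linear acyclic linkers, nonlinear
acyclic linkers and one-site side chains - from a hand-written pool of
simple, chemically valid motifs.  It does not reproduce any particular
curated set; it exists so that every operation in the package can be
exercised end-to-end without external data.  Geometries are produced by
distance-geometry embedding plus a UFF relaxation, with dummies embedded
as carbon caps so they sit at realistic neighbor positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from fragmops import chem
from fragmops.cbu_assembler import BindingSite, ChemBuildingUnit
from fragmops.fragment_core import Fragment, FragmentLibrary

#: default category counts of the synthetic library (2+2+5+24+20+18 = 71)
DEFAULT_COUNTS = {
    "binding_group": 2,
    "node": 2,
    "nonlinear_acyclic_linker": 5,
    "side_chain": 24,
    "linear_cyclic_linker": 20,
    "linear_acyclic_linker": 18,
}

_CATEGORY_TO_TYPE = {
    "binding_group": "binding_group",
    "node": "node",
    "nonlinear_acyclic_linker": "linker",
    "side_chain": "side_chain",
    "linear_cyclic_linker": "linker",
    "linear_acyclic_linker": "linker",
}

# ordered motif pools; the first entries are the canonical choices (the two
# binding groups are always carboxylate then pyrazolate)
POOLS: dict[str, tuple[str, ...]] = {
    "binding_group": (
        "*C(=O)[O-]",            # carboxylate
        "*c1cn[n-]c1",           # pyrazolate (4-substituted)
    ),
    "node": (
        "*c1cc(*)cc(*)c1",       # benzene-1,3,5-triyl
        "*c1nc(*)nc(*)n1",       # 1,3,5-triazine-2,4,6-triyl
        "*c1cc(*)nc(*)c1",       # pyridine-2,4,6-triyl
    ),
    "nonlinear_acyclic_linker": (
        "*O*",                   # ether
        "*S*",                   # thioether
        "*N*",                   # secondary amine
        "*C*",                   # methylene
        "*C(=O)*",               # carbonyl
        "*S(=O)(=O)*",           # sulfonyl
    ),
    "side_chain": (
        "*F", "*Cl", "*Br", "*I",
        "*C",                    # methyl
        "*O",                    # hydroxy
        "*N",                    # amino
        "*S",                    # thiol
        "*P",                    # phosphino
        "*[SiH3]",               # silyl
        "*[SeH]",                # selenol
        "*C#N",                  # cyano
        "*[N+]#[C-]",            # isocyano
        "*C=O",                  # formyl
        "*C=S",                  # thioformyl
        "*C=C",                  # vinyl
        "*C#C",                  # ethynyl
        "*C=N",                  # iminomethyl
        "*N=O",                  # nitroso
        "*[N+](=O)[O-]",         # nitro
        "*N=[N+]=[N-]",          # azido
        "*N=N",                  # diazenyl
        "*N=C=O",                # isocyanato
        "*N=C=S",                # isothiocyanato
        "*C(F)(F)F",             # trifluoromethyl
        "*OC",                   # methoxy
        "*N(C)C",                # dimethylamino
        "*C(C)=O",               # acetyl
    ),
    "linear_cyclic_linker": (
        "*c1ccc(*)cc1",          # 1,4-phenylene
        "*c1ccc(*)cn1",          # pyridine-2,5-diyl
        "*c1cnc(*)cn1",          # pyrazine-2,5-diyl
        "*c1cnc(*)nc1",          # pyrimidine-2,5-diyl
        "*c1ccc(*)nn1",          # pyridazine-3,6-diyl
        "*c1nnc(*)nn1",          # 1,2,4,5-tetrazine-3,6-diyl
        "*c1ccc(*)s1",           # thiophene-2,5-diyl
        "*c1ccc(*)o1",           # furan-2,5-diyl
        "*c1ccc(*)[nH]1",        # pyrrole-2,5-diyl
        "*c1ncc(*)s1",           # thiazole-2,5-diyl
        "*c1ncc(*)o1",           # oxazole-2,5-diyl
        "*c1nnc(*)s1",           # 1,3,4-thiadiazole-2,5-diyl
        "*c1nnc(*)o1",           # 1,3,4-oxadiazole-2,5-diyl
        "*c1ncc(*)[nH]1",        # imidazole-2,5-diyl
        "*c1ccc(*)[se]1",        # selenophene-2,5-diyl
        "*c1ccc2cc(*)ccc2c1",    # naphthalene-2,6-diyl
        "*c1ccc(*)c2ccccc12",    # naphthalene-1,4-diyl
        "*c1cccc2c(*)cccc12",    # naphthalene-1,5-diyl
        "*c1ccc2nc(*)ccc2c1",    # quinoline-2,6-diyl
        "*c1cnc2cc(*)ccc2n1",    # quinoxaline-2,6-diyl
        "*c1ccc2cc3cc(*)ccc3cc2c1",  # anthracene-2,6-diyl
        "*c1ccc2[nH]c3ccc(*)cc3c2c1",  # carbazole-2,7-diyl
    ),
    "linear_acyclic_linker": (
        "*C#C*",                 # ethynylene
        "*/C=C/*",               # trans-vinylene
        "*/C=N/*",               # trans-imine
        "*/N=N/*",               # trans-azo
        "*C=C=C*",               # allene-1,3-diyl
        "*C#CC#C*",              # butadiynylene
        "*C#CC#CC#C*",           # hexatriynylene
        "*/C=C/C=C/*",           # trans,trans-butadienylene
        "*/C=C/C=C/C=C/*",       # all-trans-hexatrienylene
        "*C(=O)N*",              # amide
        "*C(=O)O*",              # ester
        "*C(=O)C(=O)*",          # oxalyl
        "*/C=N/N=C/*",           # azine
        "*C(=O)NNC(=O)*",        # diacylhydrazine
        "*C(=O)NC(=O)*",         # imide
        "*CC*",                  # ethylene
        "*CCCC*",                # butane-1,4-diyl
        "*C#C/C=C/C#C*",         # trans-enediyne
        "*/C=C/C#C*",            # ene-yne (asymmetric)
        "*CC#CC*",               # but-2-yne-1,4-diyl
    ),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Requested category counts plus the seed for deterministic selection."""

    counts: dict = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    seed: int = 0


_library_cache: dict = {}


def generate_fixture_library(spec: FixtureSpec | None = None) -> FragmentLibrary:
    """Build the synthetic fragment library.

    Deterministic for a given seed; the binding groups are always
    carboxylate and pyrazolate, the remaining categories are drawn from
    the motif pools by seeded permutation.  Raises when a requested count
    exceeds its pool.
    """
    spec = spec or FixtureSpec()
    cache_key = (tuple(sorted(spec.counts.items())), spec.seed)
    if cache_key in _library_cache:
        return _library_cache[cache_key]
    rng = np.random.default_rng(spec.seed)
    lib = FragmentLibrary()
    for category in sorted(spec.counts):
        count = spec.counts[category]
        if count < 0:
            raise ValueError(f"negative count for {category}")
        pool = POOLS.get(category)
        if pool is None:
            raise ValueError(f"unknown category {category!r}")
        if count > len(pool):
            raise ValueError(
                f"requested {count} {category} fragments, pool has {len(pool)}"
            )
        if category == "binding_group":
            chosen = list(pool[:count])
        else:
            # the first pool entry is the category's canonical representative
            # (1,4-phenylene, ethynylene, ...) and is always included; the
            # rest of the draw varies with the seed
            order = [i for i in rng.permutation(len(pool)) if i != 0]
            chosen = [pool[0]] + [pool[i] for i in sorted(order[: count - 1])]
            chosen = chosen[:count]
        for k, smi in enumerate(chosen):
            frag = Fragment.from_smiles(
                smi,
                frag_type=_CATEGORY_TO_TYPE[category],
                seed=(spec.seed * 1009 + k * 97 + 13) % (2**31 - 1),
            )
            lib.add(frag)
    _library_cache[cache_key] = lib
    return lib


def _metal_unit(symbol: str, radius: float, label: str,
                tilt_deg: float = 35.0) -> ChemBuildingUnit:
    """Synthetic trinuclear 3-pyramidal metal unit (fixture stand-in).

    Three metal atoms on a triangle of the given circumradius, a capping
    oxo above the plane and three bridging oxygens below; binding sites
    anchor on the metals and point radially outward with a downward tilt,
    giving the pyramidal site arrangement of a MOP vertex.
    """
    theta = np.radians([90.0, 210.0, 330.0])
    metal_pos = np.stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.zeros(3)], axis=1
    )
    cap = np.array([[0.0, 0.0, 0.9]])
    bridge_theta = np.radians([150.0, 270.0, 30.0])
    bridges = np.stack(
        [
            0.6 * radius * np.cos(bridge_theta),
            0.6 * radius * np.sin(bridge_theta),
            -0.4 * np.ones(3),
        ],
        axis=1,
    )
    coords = np.vstack([metal_pos, cap, bridges])
    elements = [symbol] * 3 + ["O"] * 4
    tilt = np.tan(np.radians(tilt_deg))
    sites = []
    for i in range(3):
        d = np.array([np.cos(theta[i]), np.sin(theta[i]), -tilt])
        sites.append(
            BindingSite(atoms=(i,), anchor=metal_pos[i], direction=d / np.linalg.norm(d))
        )
    return ChemBuildingUnit(
        smiles=None,
        mol=None,
        _elements=elements,
        _coords=coords,
        binding_sites=sites,
        arrangement="3-pyramidal",
        label=label,
    )


def generate_fixture_metals() -> list[ChemBuildingUnit]:
    """Three synthetic metal CBUs of increasing size (small, medium, large)."""
    return [
        _metal_unit("V", 1.6, "V3-oxo-small"),
        _metal_unit("Zr", 2.0, "Zr3-oxo-medium"),
        _metal_unit("V", 2.6, "V3-oxo-large"),
    ]


# ---------------------------------------------------------------------------
# file I/O

def write_xyz(path, elements, coords, comment: str = "") -> None:
    """XYZ with 8-decimal coordinates; dummy atoms use the symbol ``X``."""
    lines = [str(len(elements)), comment.replace("\n", " ")]
    for el, p in zip(elements, np.asarray(coords, dtype=float)):
        sym = "X" if el in ("*", "X") else el
        lines.append(f"{sym} {p[0]:.8f} {p[1]:.8f} {p[2]:.8f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path) -> tuple[list[str], np.ndarray, str]:
    text = Path(path).read_text().strip().splitlines()
    try:
        n = int(text[0].strip())
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed XYZ file {path}: bad atom count") from exc
    comment = text[1] if len(text) > 1 else ""
    rows = text[2 : 2 + n]
    if len(rows) != n:
        raise ValueError(f"malformed XYZ file {path}: expected {n} atom rows")
    elements, coords = [], []
    for row in rows:
        parts = row.split()
        if len(parts) < 4:
            raise ValueError(f"malformed XYZ row: {row!r}")
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return elements, np.array(coords), comment


def write_smiles_list(path, smiles, names=None) -> None:
    lines = []
    for i, smi in enumerate(smiles):
        name = names[i] if names else f"cbu-{i}"
        lines.append(f"{smi}\t{name}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_smiles_list(path) -> list[str]:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.append(line.split()[0])
    return out


def _fragment_to_record(frag: Fragment) -> dict:
    rec = {
        "smiles": frag.smiles,
        "frag_type": frag.frag_type,
        "flags": dict(frag.flags),
        "side_chain_keys": list(frag.side_chain_keys),
        "molblock": Chem.MolToMolBlock(frag.mol, includeStereo=True),
    }
    if frag.mol.GetNumConformers() > 0:
        rec["geometry"] = [
            [el, x, y, z] for el, x, y, z in frag.geometry
        ]
    return rec


def _fragment_from_record(rec: dict) -> Fragment:
    mol = Chem.MolFromMolBlock(rec["molblock"], removeHs=False, sanitize=True)
    if mol is None:
        raise ValueError("unreadable fragment molblock")
    if "geometry" in rec and mol.GetNumConformers() > 0:
        coords = np.array([[x, y, z] for _, x, y, z in rec["geometry"]])
        chem.set_coords(mol, coords)
    return Fragment(
        mol=mol,
        frag_type=rec["frag_type"],
        side_chain_keys=tuple(rec.get("side_chain_keys", ())),
    )


def write_library(path, lib: FragmentLibrary, meta: dict | None = None) -> None:
    """Fragment library as JSON (full-precision geometry alongside the
    molblock), in deterministic canonical-key order."""
    data = {
        "meta": meta or {},
        "counts_by_type": lib.counts_by_type,
        "fragments": [_fragment_to_record(f) for f in lib.fragments],
    }
    Path(path).write_text(json.dumps(data, indent=1))


def read_library(path) -> FragmentLibrary:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed library file {path}: {exc}") from exc
    return FragmentLibrary(_fragment_from_record(r) for r in data["fragments"])


def write_manifest(path, **fields) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "bits"):
            return list(o.bits)
        return str(o)

    Path(path).write_text(json.dumps(fields, indent=1, default=default))


class JsonlLogger:
    """Append-only JSON-lines event log (assembly failures and friends)."""

    def __init__(self, path):
        self.path = Path(path)

    def log(self, event: str, **fields) -> None:
        rec = {"event": event, **fields}
        with self.path.open("a") as fh:
            fh.write(json.dumps(rec, default=str) + "\n")
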