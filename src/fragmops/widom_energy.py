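"""Widom-insertion estimate of the mean CO2 interaction energy of a rigid MOP.

A rigid three-site CO2 probe is inserted at uniformly random positions in
the host bounding box (plus a margin) with uniformly random orientation.
Insertions whose probe atoms penetrate the hard core of a host atom are
rejected as inaccessible; for the accessible ones the interaction energy is

    U_int = U(host + probe) - U(host) - U(probe)

evaluated with a pluggable energy backend, and the unweighted arithmetic
mean over accessible insertions gives <U_int>.  A Boltzmann-weighted
average (the conventional Widom estimator numerator) is available as an
option.  The default backend is a Lennard-Jones + point-charge model with
TraPPE CO2 parameters against per-element host LJ parameters; any callable
satisfying the :class:`EnergyBackend` contract (machine-learned potentials
included) can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np

from fragmops import chem
from fragmops.chem import CLASH_FACTOR

K_B_EV = 8.617333262e-5  # eV/K

# TraPPE-style rigid CO2: C-O bond 1.16 A, linear; LJ eps in K, sigma in A,
# charges in e
CO2_SITES = (
    ("C", 0.0, 27.0, 2.80, 0.70),
    ("O", 1.16, 79.0, 3.05, -0.35),
    ("O", -1.16, 79.0, 3.05, -0.35),
)

# generic per-element host LJ parameters (UFF-like), eps in K, sigma in A
DEFAULT_HOST_LJ: dict[str, tuple[float, float]] = {
    "H": (22.1, 2.57), "C": (52.8, 3.43), "N": (34.7, 3.26),
    "O": (30.2, 3.12), "F": (25.2, 3.00), "S": (137.9, 3.59),
    "Cl": (114.2, 3.52), "Br": (126.3, 3.73), "I": (170.6, 4.01),
    "P": (153.5, 3.69), "Si": (202.3, 3.83), "Se": (146.4, 3.75),
    "Zr": (34.7, 2.78), "V": (8.1, 2.80), "Zn": (62.4, 2.46),
    "Cu": (2.5, 3.11), "Fe": (6.5, 2.59),
}
DEFAULT_HOST_LJ_FALLBACK = (30.0, 3.2)


class EnergyBackend(Protocol):
    """Deterministic total-energy model: coordinates (A) -> energy (eV)."""

    cutoff: float

    def evaluate(self, coords: np.ndarray, elements: list[str]) -> float: ...


class ZeroBackend:
    """Null potential: every configuration has zero energy."""

    cutoff = 0.0

    def evaluate(self, coords, elements) -> float:
        return 0.0


class LennardJonesBackend:
    """Pairwise 12-6 Lennard-Jones plus Coulomb point charges.

    Parameters are per element: ``lj[element] = (eps_K, sigma_A)`` with
    Lorentz-Berthelot mixing; ``charges[element]`` in elementary charges
    (defaults to zero for the host; the CO2 probe's charges are set per
    atom by the insertion machinery through ``charge_override``).  Energies
    are size-consistent: far-separated groups contribute nothing beyond
    the cutoff.
    """

    def __init__(self, lj: dict | None = None, charges: dict | None = None,
                 cutoff: float = 14.0):
        self.lj = dict(DEFAULT_HOST_LJ)
        if lj:
            self.lj.update(lj)
        self.charges = dict(charges or {})
        self.cutoff = float(cutoff)

    def _params(self, elements, charge_override=None):
        eps = np.array(
            [self.lj.get(e, DEFAULT_HOST_LJ_FALLBACK)[0] for e in elements]
        ) * K_B_EV
        sig = np.array(
            [self.lj.get(e, DEFAULT_HOST_LJ_FALLBACK)[1] for e in elements]
        )
        if charge_override is not None:
            q = np.asarray(charge_override, dtype=float)
        else:
            q = np.array([self.charges.get(e, 0.0) for e in elements])
        return eps, sig, q

    def evaluate(self, coords, elements, charge_override=None) -> float:
        coords = np.asarray(coords, dtype=float)
        n = len(coords)
        if n < 2:
            return 0.0
        eps, sig, q = self._params(elements, charge_override)
        iu, ju = np.triu_indices(n, k=1)
        d = np.linalg.norm(coords[iu] - coords[ju], axis=1)
        mask = d <= self.cutoff
        d = d[mask]
        if len(d) == 0:
            return 0.0
        e_mix = np.sqrt(eps[iu][mask] * eps[ju][mask])
        s_mix = 0.5 * (sig[iu][mask] + sig[ju][mask])
        sr6 = (s_mix / d) ** 6
        u_lj = 4.0 * e_mix * (sr6 * sr6 - sr6)
        # Coulomb constant e^2/(4 pi eps0) in eV*A
        u_c = 14.399645 * q[iu][mask] * q[ju][mask] / d
        return float(u_lj.sum() + u_c.sum())


@dataclass(frozen=True)
class EnergyBreakdown:
    u_complex: float  # eV
    u_host: float
    u_probe: float

    @property
    def u_int(self) -> float:
        return self.u_complex - self.u_host - self.u_probe


@dataclass(frozen=True)
class WidomResult:
    mean_u_int: float      # eV
    n_insertions: int
    n_accessible: int
    std_error: float       # eV
    seed: int

    def to_dict(self) -> dict:
        return {
            "mean_u_int_eV": self.mean_u_int,
            "n_insertions": self.n_insertions,
            "n_accessible": self.n_accessible,
            "std_error_eV": self.std_error,
            "seed": self.seed,
        }


def _probe_geometry() -> tuple[list[str], np.ndarray, np.ndarray]:
    elements = [s[0] for s in CO2_SITES]
    coords = np.array([[s[1], 0.0, 0.0] for s in CO2_SITES])
    charges = np.array([s[4] for s in CO2_SITES])
    return elements, coords, charges


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    quat = rng.normal(size=4)
    quat /= np.linalg.norm(quat)
    w, x, y, z = quat
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _host_arrays(mop):
    from fragmops.mop_assembler import MOPStructure
    from fragmops.cbu_assembler import ChemBuildingUnit

    if isinstance(mop, MOPStructure):
        return mop.elements, np.asarray(mop.coords, dtype=float)
    if isinstance(mop, ChemBuildingUnit):
        return mop.elements, mop.coords
    elements, coords = mop
    return list(elements), np.asarray(coords, dtype=float)


def insert_probe(mop, rng: np.random.Generator, margin: float = 5.0,
                 hardcore_factor: float = CLASH_FACTOR,
                 vdw_overrides: dict | None = None):
    """Draw one rigid CO2 pose and report accessibility.

    The center is uniform in the host's axis-aligned bounding box grown by
    ``margin`` A, the orientation uniform over rotations.  The pose is
    accessible iff no probe atom is within ``hardcore_factor`` times the
    vdW sum of any host atom.  Returns ``(elements, coords, charges,
    accessible)``.
    """
    elements, host_coords = _host_arrays(mop)
    p_elems, p_coords, p_charges = _probe_geometry()
    lo = host_coords.min(axis=0) - margin if len(host_coords) else -margin * np.ones(3)
    hi = host_coords.max(axis=0) + margin if len(host_coords) else margin * np.ones(3)
    center = lo + rng.random(3) * (hi - lo)
    rot = _random_rotation(rng)
    pose = p_coords @ rot.T + center
    if len(host_coords):
        host_r = chem.vdw_array(elements, vdw_overrides)
        probe_r = chem.vdw_array(p_elems, vdw_overrides)
        gap = chem.pairwise_min_gap(
            host_coords, hardcore_factor * host_r, pose, hardcore_factor * probe_r
        )
        accessible = bool(gap >= 0.0)
    else:
        accessible = True
    return p_elems, pose, p_charges, accessible


def interaction_energy(mop, probe_coords, backend,
                       probe_charges=None) -> EnergyBreakdown:
    """U_int = U(host+probe) - U(host) - U(probe) for one pose."""
    elements, host_coords = _host_arrays(mop)
    p_elems, p_ref, p_charges = _probe_geometry()
    if probe_charges is None:
        probe_charges = p_charges
    all_coords = np.vstack([host_coords, probe_coords]) if len(host_coords) \
        else np.asarray(probe_coords)
    all_elems = list(elements) + p_elems

    if isinstance(backend, LennardJonesBackend):
        host_q = np.array([backend.charges.get(e, 0.0) for e in elements])
        u_complex = backend.evaluate(
            all_coords, all_elems,
            charge_override=np.concatenate([host_q, probe_charges]),
        )
        u_host = backend.evaluate(host_coords, elements, charge_override=host_q)
        u_probe = backend.evaluate(probe_coords, p_elems,
                                   charge_override=probe_charges)
    else:
        u_complex = backend.evaluate(all_coords, all_elems)
        u_host = backend.evaluate(host_coords, elements)
        u_probe = backend.evaluate(probe_coords, p_elems)
    return EnergyBreakdown(u_complex, u_host, u_probe)


def widom_average(
    mop,
    backend,
    n_insertions: int = 10_000,
    seed: int = 0,
    margin: float = 5.0,
    hardcore_factor: float = CLASH_FACTOR,
    temperature: float | None = None,
    vdw_overrides: dict | None = None,
) -> WidomResult:
    """Ensemble-average interaction energy over accessible insertions.

    By default the unweighted arithmetic mean of U_int over accessible
    poses; with ``temperature`` (K) set, the Boltzmann-weighted average
    ``<U e^(-bU)>/<e^(-bU)>`` is reported instead.  Deterministic for a
    given seed.
    """
    if n_insertions < 1:
        raise ValueError("n_insertions must be >= 1")
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(int(n_insertions)):
        p_elems, pose, p_charges, ok = insert_probe(
            mop, rng, margin=margin, hardcore_factor=hardcore_factor,
            vdw_overrides=vdw_overrides,
        )
        if not ok:
            continue
        bd = interaction_energy(mop, pose, backend, probe_charges=p_charges)
        values.append(bd.u_int)
    if not values:
        raise RuntimeError(
            "no accessible insertion; enlarge the sampling margin or loosen "
            "the hard-core factor"
        )
    arr = np.array(values)
    if temperature is not None:
        beta = 1.0 / (K_B_EV * temperature)
        w = np.exp(-beta * (arr - arr.min()))
        mean = float((arr * w).sum() / w.sum())
    else:
        mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return WidomResult(
        mean_u_int=mean,
        n_insertions=int(n_insertions),
        n_accessible=len(arr),
        std_error=sem,
        seed=int(seed),
    )
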