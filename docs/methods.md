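# Methods

`fragmops` builds and searches a fragment-based design space for
metal–organic polyhedra (MOPs).  This note records the models and
procedures the package implements, the parameters that matter, the
numerical choices made where the design was genuinely open, and what the
synthetic fixtures do and do not show about real data.

## Fragmentation model

An organic chemical building unit (CBU) is fragmented by cleaving **every
exocyclic, non-hydrogen single bond** and capping each cut with a dummy
atom (`*`) on both sides.  "Exocyclic" means the bond belongs to no ring
of the smallest set of smallest rings, so biaryl bonds between two ring
systems are cleaved.  Each dummy is placed at the 3D position of the
neighbor it replaced; this convention makes a later dummy↔neighbor mapping
between two fragments reproduce the original bond length exactly.

Typing is by bonding-site count: one site → side chain, two → linker,
three or more → node.  Two exceptions:

* **Binding groups** (carboxylate `*C(=O)[O-]`, pyrazolate `*c1cn[n-]c1`
  by default; SMARTS-configurable) are recognized before any other rule:
  a fragment whose heavy atoms are exactly covered by a pattern match is a
  binding group regardless of site count, and bonds *interior* to a match
  are protected from cleavage.  Without that protection the C–O(−) single
  bond of a carboxylate would itself be cleaved, destroying the group;
  the protection is how "manually defined, excluded from categorization"
  binding groups are realized operationally.  Charged groups stay anionic
  throughout.
* **Side-chain reversion**: fragments with one site at cleavage time that
  are not binding groups are emitted as side chains, and their attachment
  point on the (non-side-chain) parent is replaced by a hydrogen at a
  standard X–H bond length.  Parents are then re-typed by their
  *post-reversion* site count — a ring that carried one binding group and
  one methyl ends up a clean 2-site linker, not a 1-site oddity.

Deduplication uses canonical SMILES of the dummy-bearing graph (dummy
bookkeeping labels stripped, hydrogens implicit).  A two-site fragment is
*symmetric* iff exchanging isotope labels on its two dummies leaves the
canonical SMILES unchanged; it is *linear* iff its two site-neighbor→dummy
vectors are within 15° of antiparallel (`LINEAR_TOL_DEG`, configurable).

A fragment is a **fixed point** of this cleavage rule when it contains no
cleavable bond itself.  Libraries produced by exhaustive fragmentation
consist of fixed points by construction, and only for CBUs assembled from
fixed points does the round trip (assemble → fragment → same key multiset)
hold exactly.  The fixture pools deliberately include a few non-fixed-point
motifs (amide, ester linkers) because such groups occur in real linker
chemistry; the round-trip property test therefore restricts itself to
cleavage-stable fragments (`is_cleavage_stable`).

## Templates and orientations

A CBU template is an ordered slot list: binding group, linkers at explicit
sequence positions, and either a closing binding group (2-arm templates)
or a node fragment whose every site receives a copy of the assembled arm
(3-arm templates).  Slot constraints (`max_atoms` on heavy atoms,
`cyclic`, `linear`) only filter candidates.  Validation additionally
enforces a single binding-group species per CBU, so mixed-terminus CBUs
are never generated.

Asymmetric linkers carry one orientation bit per slot (which bonding site
joins the growing chain first).  Exhaustive enumeration attempts both bits
per asymmetric linker (2^k vectors); under the *symmetric constraint* an
asymmetric linker occupying more than one slot receives alternating bits
(`bit = linker index mod 2` — the phase is irrelevant when the termini are
equivalent, and a phase had to be chosen), and exactly one vector is
produced.  Eight templates ship as data (four 2-linear with one to three
linker slots, two 2-bent, two 3-planar); their slot constraints are this
package's own approximations of common MOP topologies, not a reproduction
of any published template table.

## CBU assembly

**SMILES level.**  Fragments are chained by fusing dummy pairs into single
bonds.  The fusion transfers the RDKit bond-direction flags of the
consumed dummy bonds onto the new bond (flipping all of the guest's
directional bonds when the two sides disagree — a global flip leaves the
guest's internal stereochemistry unchanged), so trans markers on vinylene,
azo or polyene linkers survive assembly.  This fusion is hand-written
because `Chem.molzip`, the obvious off-the-shelf choice, proved
order-unstable for multi-pair zips with directional bonds in the installed
RDKit build; the test suite still uses sequential single-pair `molzip`
fusions as an independent cross-check of the join.

**Geometry level.**  For each junction a local frame is built on both
sides (origin at the site-neighbor atom, x toward the dummy, y
orthogonalized toward the nearest other neighbor, right-handed z); the
incoming fragment is rigidly transformed so its dummy maps onto the host's
site-neighbor and vice versa, which reproduces the original bond length by
construction — no bond-length correction is applied unless MMFF94
relaxation is requested (`minimize=True`; default off).  Nonbonded
host–guest pairs (excluding 1-2 and 1-3 across the new bond) are checked
against the clash rule *distance < 0.7 × (vdW_i + vdW_j)* (Bondi radii,
both factor and table configurable); on a clash the torsion about the new
bond is scanned in 10° steps, and the assembly fails if a full turn finds
no clash-free pose.  Finally each binding group is rotated about its
junction bond (5° scan, two refinement rounds) onto the least-squares
plane through all binding-group atoms — coplanar/antiparallel groups for
2-linear CBUs, a common plane otherwise — rejecting rotations that would
introduce a clash.  The product SMILES of a 3D assembly is derived with
stereochemistry perceived from the final coordinates, which keeps the
SMILES-level and geometry-level routes consistent on the fixtures.

## MOP assembly

Purely geometric, no force field, deterministic.  An assembly model fixes
a reference polyhedron: `(3-pyramidal)4(2-linear)6` is a tetrahedron with
metals at vertices and linear linkers on edges; `(3-pyramidal)4(3-planar)4`
adds face centers; the two lantern models place two metals on ±z and three
organics 120° apart on the equator (ring radius 0.5 of the apex distance
for the 2-linear lantern — deliberately narrow, so bulky organics fail
there by clash, and 1.0 for the 2-bent lantern).

1. **Scale fit.**  One global scalar *s* minimizes the weighted squared
   mismatch between each connected site pair's separation and
   `reach_metal + reach_organic + 2.2 Å`, where a unit's *reach* is the
   mean distance from its reference point to its binding anchors and
   2.2 Å is the assumed coordination gap (configurable).  A unit's
   reference point is the anchor midpoint for 2-site units and the
   least-squares intersection of the binding-site axes (the cone apex)
   for ≥3-site units; the intersection is ill-conditioned for
   near-antiparallel axes, which is why 2-site units use the midpoint.
2. **Docking.**  Each unit is placed by Kabsch superposition of its
   binding anchors, anchor+outward pseudo-atoms and reference point onto
   the site's target geometry, minimizing over the ≤6 anchor-to-partner
   permutations with a strict-improvement threshold so symmetric-unit
   ties resolve identically in any input frame.  Because a 2-linear
   unit's constraint points are collinear, the axial spin (and, for
   near-planar sets, the reflection branch of the superposition) is
   numerically free; the correspondence is therefore augmented with
   rigid-motion-covariant pseudo-points — an index-weighted off-axis spin
   reference plus a handedness partner for 2-site units, the anchor-plane
   normal for 3-site units.  The spin convention points the unit's
   off-axis bulk outward (along the site's radial direction).  With these
   choices assembly is bit-deterministic and exactly invariant (≲1e-12 Å)
   to rigid motions of the input coordinates.
3. **Clash handling.**  All inter-unit atom pairs are checked with the
   same 0.7×vdW rule, except pairs between an organic unit's binding
   group and the metal unit it coordinates to.  Organic 2-class units in
   clashing pairs may spin about their own axis in 15° steps (greedily,
   one unit at a time); if clashes survive, assembly fails with the
   offending unit pair.

## Cavity and synthesizability descriptors

*Inner sphere*: `d = 2·max(0, min_i(|r_i − c| − vdW_i))` with `c` the
unweighted atom centroid; volume is the sphere volume.  *Window diameter*:
2048 rays from the centroid over a Fibonacci sphere; a ray's bottleneck is
the smallest (atom-to-ray distance − vdW) over all atoms ahead of the
centroid; escaping rays are clustered by angular adjacency (12°,
union-find) and twice the best clearance per cluster is a window; the
maximum over windows is reported, 0 when nothing escapes.  On a planar
6-ring fixture this agrees with a brute-force 2D grid oracle to within the
grid resolution.  Note that deleting atoms from a structure moves the
centroid, so "removing an obstruction increases the window" is only
guaranteed when the centroid stays put (the tests use a punched spherical
shell for this reason).

*SA score* is the Ertl–Schuffenhauer fragment-contribution/complexity
score on [1, 10], computed by the reference implementation shipped with
RDKit (`Contrib/SA_Score`); molecules with dummy atoms are rejected.
*Side-chain count* is read from the CBU's slot provenance (each grafted
side chain records its canonical key on the linker that carries it), so
no re-fragmentation is needed.

## Genetic algorithm

Chromosome: `[model index, metal index, fragment index per slot...,
orientation bit per linker slot...]`, all categorical; the template is
fixed per run and candidate lists are filtered per template beforehand, so
runs over different templates are independent.  Defaults follow the
reference protocol: population 30, 30 generations, mutation probability
0.15 per gene (resampling excludes the current value), uniform per-gene
crossover with probability 0.9 (uniform chosen where "gene crossover" was
underdetermined; configurable), elitism proportion 0.05 (at least one
elite), tournament size 3 (unstated in the source protocol; configurable),
optional replacement of duplicate chromosomes by random ones.  Fitness
evaluations are cached by gene tuple; failed assemblies receive a sentinel
fitness one unit below the worst evaluated candidate at ranking time,
keeping the population size fixed.  Same seed → bit-identical trajectory.

Two fitness functions: `cavity_fitness = −(w_vol·|V − 625| + 10·SA +
10·n_side)` with weights 1:10:10 and **no unit normalization** — the Å³
deviation and the dimensionless scores are combined as printed, which is a
deliberate reproduction of the reference weighting, and
`energy_fitness = −⟨U_int⟩` for CO₂ affinity (more negative mean
interaction energy ranks higher).  The 625 Å³ default target is 1.05× the
van der Waals volume of C₆₀.

## Widom insertion

A rigid 3-site CO₂ probe (TraPPE-style: C–O 1.16 Å linear; ε/k_B = 27 K /
79 K, σ = 2.80 / 3.05 Å, q = +0.70/−0.35 e) is inserted with center
uniform in the host bounding box + 5 Å margin and orientation uniform on
SO(3) (normalized-quaternion sampling).  A pose is accessible iff no probe
atom is within 0.7× the vdW sum of any host atom (the same hard-core
factor as the assemblers, for consistency).  For accessible poses
`U_int = U(host+probe) − U(host) − U(probe)`, each term evaluated by the
backend, and the reported ⟨U_int⟩ is the **unweighted arithmetic mean**
over accessible insertions; a Boltzmann-weighted variant is available via
a temperature argument.  The default backend is pairwise 12-6
Lennard-Jones (Lorentz–Berthelot mixing, UFF-like per-element host
parameters, 14 Å cutoff) plus Coulomb point charges (host charges default
to zero), which is exactly size-consistent beyond the cutoff.  Any object
with a deterministic `evaluate(coords, elements) → eV` satisfies the
backend contract, so machine-learned potentials can be plugged in without
being packaged here.  Default 10⁴ insertions; the standard error is the
sample SEM over accessible poses.

## Synthetic fixtures

`generate_fixture_library` emulates the *category structure* of a curated
MOP fragment library — 2 binding groups (always carboxylate and
pyrazolate), 2 three-site nodes, 20 linear cyclic linkers, 18 linear
acyclic linkers, 5 nonlinear acyclic linkers, 24 one-site side chains
(71 fragments total by default) — drawn deterministically from hand-written
pools of simple valid motifs (azine/azole diyls, polyene/polyyne chains,
halide/nitro/amine side chains, ...).  The first entry of each pool
(1,4-phenylene, ethynylene, ...) is always included; the rest of the draw
varies with the seed.  Geometries come from ETKDG embedding plus UFF
relaxation with dummies embedded as carbon caps.  Three synthetic
trinuclear oxo-bridged metal units (small/medium/large, V/Zr/V) stand in
for experimentally derived metal CBUs.

What passing tests show: the fragmentation/assembly/search machinery is
exact and self-consistent on chemically valid inputs spanning the same
category structure as real libraries.  What they do not show: agreement
with any published CBU counts, cavity-diameter distributions or absolute
⟨U_int⟩ values, all of which depend on the authors' curated fragment set,
template constraints, experimental metal units and a machine-learned
potential, none of which ship here.  Problem sizes in the test suite
(toy spaces ≤ 1000 configurations, 10⁵ Monte Carlo insertions on one-atom
hosts, 2×10³ insertions on full cages) were chosen as the smallest sizes
at which the checked statistics are stable.

## Known limitations

* Fragments are rigid; CBU conformation does not adapt inside the MOP,
  and no whole-MOP geometry optimization or metal force-field treatment
  is performed.
* The clash factor 0.7 is a heuristic; assembly success/failure counts
  are sensitive to it, so reproduction of any particular success rate is
  approximate by nature.
* The window algorithm reports the largest per-ray clearance per angular
  cluster; it does not trace curved escape paths, so very tortuous
  windows are underestimated.
* Widom sampling of a box around an isolated cage means most insertions
  probe the outside surface; for interior-only statistics the margin and
  accessibility rule would need retargeting.
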