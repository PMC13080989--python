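# fragmops

Fragment-based inverse design of metal–organic polyhedra (MOPs).

MOPs are discrete cage molecules built from metal clusters and organic
linkers — molecular cousins of MOFs — with applications in host–guest
chemistry and gas capture.  Designing new ones means searching an
enormous combinatorial space of organic building blocks.  `fragmops`
makes that space explicit and searchable:

* **Fragmentation** — organic chemical building units (CBUs) are cleaved
  at every exocyclic non-hydrogen single bond into typed fragments
  (binding groups such as carboxylate and pyrazolate, linkers, nodes,
  side chains), each carrying dummy-atom bonding sites and rigid 3D
  geometry.
* **Template reassembly** — slot-based CBU templates recombine fragments
  into new building blocks, at SMILES level for fast enumeration and at
  geometry level (local-frame alignment, torsion-scan clash resolution)
  for 3D structures.
* **Cage assembly** — a purely geometric protocol scales a reference
  polyhedron (tetrahedral `(3-pyramidal)4(2-linear)6`, lantern
  `(3-pyramidal)2(2-linear)3`, ...), docks metal and organic units onto
  its sites by least-squares superposition and rejects clashing
  candidates.
* **Descriptors** — inner-sphere diameter/volume, ray-cast window
  diameter, Ertl–Schuffenhauer synthetic accessibility, side-chain
  counts.
* **Widom insertion** — ensemble-average CO₂ interaction energy
  ⟨U_int⟩ = ⟨U(host+CO₂) − U(host) − U(CO₂)⟩ over accessible random
  insertions of a rigid 3-site probe, with a pluggable energy backend
  (a Lennard-Jones + point-charge model ships as default).
* **Genetic algorithm** — chromosomes encode assembly model, metal,
  per-slot fragments and linker orientations; tournament selection,
  uniform crossover, mutation and elitism optimize either cavity volume
  toward a target (625 Å³ for a C₆₀ guest, fitness
  `−(|V−625| + 10·SA + 10·n_side)`) or ⟨U_int⟩.

A deterministic synthetic fragment library (71 fragments in the standard
category structure, plus three synthetic metal units) ships with the
package so everything runs end-to-end with no external data.

## Worked example

```python
from fragmops import *
from fragmops.cbu_templates import default_templates, expand_orientations
from fragmops.mop_assembler import get_model
from fragmops.workbench_io import generate_fixture_library, generate_fixture_metals
from fragmops.descriptors import cavity_report, synth_report

lib = generate_fixture_library()                      # 71 fragments
tmpl = {t.name: t for t in default_templates()}["linear-1"]
asg = {0: lib["*C(=O)[O-]"], 1: lib["*c1ccc(*)cc1"], 2: lib["*C(=O)[O-]"]}
ori = expand_orientations(tmpl, asg, symmetric=True)[0]

cbu = assemble_geometry(tmpl, asg, ori)               # terephthalate, 3D
mop = assemble_mop(get_model("(3-pyramidal)4(2-linear)6"),
                   generate_fixture_metals()[1], cbu)
print(cbu.smiles)
print(mop.n_atoms, round(mop.scale, 2))

rep = cavity_report(mop)
print(round(rep.inner_sphere_diameter, 2), round(rep.inner_sphere_volume, 1),
      round(rep.window_diameter, 2))

res = widom_average(mop, LennardJonesBackend(), n_insertions=2000, seed=1)
print(round(res.mean_u_int, 4), res.n_accessible)
```

prints

```
O=C([O-])c1ccc(C(=O)[O-])cc1
124 9.78
5.0 65.5 3.77
0.0149 1706
```

— the carboxylate + 1,4-phenylene + carboxylate assignment canonicalizes
to terephthalate; six copies of it bridge four trinuclear metal vertices
into a 124-atom tetrahedral cage whose reference polyhedron was scaled to
9.78 Å.  The largest centroid-centered sphere clearing every van der
Waals surface is 5.0 Å across (65.5 Å³ — far below the 625 Å³ C₆₀
target, so this candidate would score poorly in the cavity GA), the
widest escape window passes a 3.77 Å probe, and 2000 CO₂ insertions
(1706 accessible) give a mean Lennard-Jones interaction energy of
+0.015 eV — dominated by near-contact poses outside this small cage.

The same pipeline is scriptable from the shell:

```bash
fragmops fixture --seed 0 --out lib.json
fragmops enumerate --template linear-1 --library lib.json --mode smiles --out cbus.smi
fragmops assemble-cbu --template linear-1 --library lib.json \
    --fragments "*C(=O)[O-],*c1ccc(*)cc1,*C(=O)[O-]" --out cbu.sdf
fragmops assemble-mop --model "(3-pyramidal)4(2-linear)6" \
    --organic cbu.sdf --metal medium --library lib.json --out mop.xyz
fragmops descriptors --mop mop.xyz
fragmops widom --mop mop.xyz --backend lj --n 10000 --seed 1
fragmops optimize --template linear-1 --library lib.json --fitness cavity \
    --target-volume 625 --pop 30 --gens 30 --seed 1 --out run/
```

See `docs/methods.md` for the models, parameter choices and limitations.

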