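"""Genetic algorithm over the fragment-encoded MOP design space.

Each candidate MOP is a chromosome of categorical genes: assembly-model
index, metal index, one fragment index per template slot, and one
orientation bit per linker slot.  The CBU template is fixed per run (runs
parallelize over templates), so candidate lists are filtered per template
beforehand.  Evolution uses elitism, tournament selection, uniform
per-gene crossover, per-gene mutation and optional replacement of
duplicate chromosomes by random ones.  Default hyperparameters: population
30 evolved for 30 generations, mutation probability 0.15, crossover
probability 0.9, elitism proportion 0.05.

Two fitness functions are provided.  ``cavity_fitness`` combines three
weighted penalty terms - deviation of the inner-sphere volume from a
target (625 A^3 by default, sized for a C60 guest), the synthetic
accessibility score, and the side-chain count - with weight ratio 1:10:10
and no unit normalization.  ``energy_fitness`` is simply the negated
ensemble-average guest interaction energy, so stronger (more negative)
binding ranks higher.  Candidates whose MOP assembly fails receive a
sentinel fitness one unit below the worst evaluated candidate, keeping the
population size fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from fragmops.cbu_templates import CBUTemplate, OrientationVector
from fragmops.fragment_core import Fragment

FAILED = object()  # sentinel cache entry for configurations that do not assemble


@dataclass(frozen=True)
class Chromosome:
    genes: tuple[int, ...]

    def __len__(self):
        return len(self.genes)


@dataclass(frozen=True)
class GAParams:
    pop_size: int = 30
    n_generations: int = 30
    p_mut: float = 0.15
    p_cross: float = 0.9
    elitism_frac: float = 0.05
    tournament_size: int = 3
    replace_duplicates: bool = True
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_mut, self.p_cross, self.elitism_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def n_elite(self) -> int:
        return max(1, round(self.elitism_frac * self.pop_size))


@dataclass(frozen=True)
class FitnessSpec:
    mode: str = "cavity_target"          # or "interaction_energy"
    target_volume: float = 625.0         # A^3
    weights: tuple[float, float, float] = (1.0, 10.0, 10.0)

    def __post_init__(self):
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be nonnegative")


@dataclass
class SearchSpace:
    """Template-filtered candidate lists defining the gene ranges."""

    template: CBUTemplate
    assembly_models: list
    metals: list
    slot_fragments: dict[int, list[Fragment]]  # position -> admissible fragments

    def __post_init__(self):
        if not self.assembly_models or not self.metals:
            raise ValueError("assembly model and metal lists must be nonempty")
        for pos, frags in self.slot_fragments.items():
            if not frags:
                raise ValueError(f"empty fragment list for slot position {pos}")

    @property
    def positions(self) -> list[int]:
        return [s.position for s in self.template.slots]

    @property
    def n_linker_slots(self) -> int:
        return len(self.template.linker_slots)

    @property
    def gene_sizes(self) -> list[int]:
        sizes = [len(self.assembly_models), len(self.metals)]
        sizes += [len(self.slot_fragments[p]) for p in self.positions]
        sizes += [2] * self.n_linker_slots
        return sizes

    @property
    def n_genes(self) -> int:
        return 2 + len(self.positions) + self.n_linker_slots

    @property
    def n_configurations(self) -> int:
        return int(np.prod(self.gene_sizes, dtype=np.int64))

    def random_chromosome(self, rng: np.random.Generator) -> Chromosome:
        return Chromosome(tuple(int(rng.integers(s)) for s in self.gene_sizes))

    def all_chromosomes(self):
        import itertools
        for genes in itertools.product(*(range(s) for s in self.gene_sizes)):
            yield Chromosome(genes)


def decode(chrom: Chromosome, space: SearchSpace):
    """Chromosome -> (assembly model, metal, slot assignment, orientation)."""
    sizes = space.gene_sizes
    if len(chrom.genes) != len(sizes):
        raise ValueError(
            f"chromosome length {len(chrom.genes)} != expected {len(sizes)}"
        )
    for g, s in zip(chrom.genes, sizes):
        if not 0 <= g < s:
            raise ValueError(f"gene value {g} out of range [0, {s})")
    model = space.assembly_models[chrom.genes[0]]
    metal = space.metals[chrom.genes[1]]
    positions = space.positions
    assignment = {
        p: space.slot_fragments[p][chrom.genes[2 + i]]
        for i, p in enumerate(positions)
    }
    bits = chrom.genes[2 + len(positions):]
    return model, metal, assignment, OrientationVector(tuple(bits))


def encode(model_idx: int, metal_idx: int, frag_idxs, bits, space: SearchSpace
           ) -> Chromosome:
    genes = (model_idx, metal_idx, *frag_idxs, *bits)
    chrom = Chromosome(tuple(int(g) for g in genes))
    decode(chrom, space)  # validates ranges
    return chrom


def cavity_fitness(cavity, synth, spec: FitnessSpec = FitnessSpec()) -> float:
    """Negative weighted penalty; 0 is a perfect score.

    ``fitness = -(w_vol * |V - target| + w_sa * SA + w_side * n_side)``
    with the terms combined as printed (A^3 against dimensionless scores,
    ratio 1:10:10 by default).
    """
    w_vol, w_sa, w_side = spec.weights
    volume = getattr(cavity, "inner_sphere_volume", cavity)
    sa = getattr(synth, "sa_score", None)
    n_side = getattr(synth, "side_chain_count", None)
    if sa is None:
        sa, n_side = synth
    return -(
        w_vol * abs(volume - spec.target_volume) + w_sa * sa + w_side * n_side
    )


def energy_fitness(mean_u_int: float) -> float:
    """Fitness for minimizing the ensemble-average interaction energy:
    more negative <U_int> gives higher fitness."""
    mean = getattr(mean_u_int, "mean_u_int", mean_u_int)
    return -float(mean)


@dataclass
class GenerationRecord:
    generation: int
    best_chromosome: Chromosome
    best_fitness: float
    mean_fitness: float


@dataclass
class Trajectory:
    generations: list[GenerationRecord] = field(default_factory=list)
    evaluations: dict[tuple, float] = field(default_factory=dict)
    n_failed: int = 0

    @property
    def best(self) -> GenerationRecord:
        return max(self.generations, key=lambda g: g.best_fitness)

    @property
    def n_evaluated(self) -> int:
        return len(self.evaluations) + self.n_failed

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "generation": [g.generation for g in self.generations],
                "best_fitness": [g.best_fitness for g in self.generations],
                "mean_fitness": [g.mean_fitness for g in self.generations],
                "best_genes": [list(g.best_chromosome.genes) for g in self.generations],
            }
        )


def evolve(space: SearchSpace, fitness, params: GAParams = GAParams()) -> Trajectory:
    """Run the GA.

    ``fitness`` is a callable taking ``(chromosome, space)`` and returning
    a float, or ``None``/``raise`` :class:`fragmops.AssemblyError` for
    candidates that fail to assemble; failures receive a sentinel one unit
    below the worst evaluated fitness.  Evaluations are cached by gene
    tuple, and the same seed reproduces the trajectory bit for bit.
    """
    from fragmops.cbu_assembler import AssemblyError
    from fragmops.mop_assembler import AssemblyFailure

    rng = np.random.default_rng(params.seed)
    cache: dict[tuple, object] = {}
    traj = Trajectory()

    def raw_eval(chrom: Chromosome):
        key = chrom.genes
        if key not in cache:
            try:
                val = fitness(chrom, space)
            except (AssemblyError, AssemblyFailure):
                val = None
            cache[key] = FAILED if val is None or (
                isinstance(val, float) and math.isnan(val)
            ) else float(val)
        return cache[key]

    def effective(values):
        finite = [v for v in values if v is not FAILED]
        sentinel = (min(finite) - 1.0) if finite else -1.0
        return [sentinel if v is FAILED else v for v in values]

    pop = [space.random_chromosome(rng) for _ in range(params.pop_size)]

    for gen in range(params.n_generations):
        raw = [raw_eval(c) for c in pop]
        fit = effective(raw)
        order = sorted(range(len(pop)), key=lambda i: fit[i], reverse=True)
        best_i = order[0]
        traj.generations.append(
            GenerationRecord(
                generation=gen,
                best_chromosome=pop[best_i],
                best_fitness=fit[best_i],
                mean_fitness=float(np.mean(fit)),
            )
        )
        if gen == params.n_generations - 1:
            break

        elites = [pop[i] for i in order[: params.n_elite]]
        children: list[Chromosome] = list(elites)

        def tournament() -> Chromosome:
            idx = rng.integers(0, len(pop), size=params.tournament_size)
            best = max(idx, key=lambda i: fit[int(i)])
            return pop[int(best)]

        while len(children) < params.pop_size:
            p1, p2 = tournament(), tournament()
            if rng.random() < params.p_cross:
                mask = rng.integers(0, 2, size=space.n_genes)
                genes = tuple(
                    g1 if m == 0 else g2
                    for g1, g2, m in zip(p1.genes, p2.genes, mask)
                )
            else:
                genes = p1.genes
            genes = list(genes)
            for k, size in enumerate(space.gene_sizes):
                if size > 1 and rng.random() < params.p_mut:
                    new = int(rng.integers(size - 1))
                    if new >= genes[k]:
                        new += 1
                    genes[k] = new
            children.append(Chromosome(tuple(genes)))

        if params.replace_duplicates:
            seen = set()
            for i, c in enumerate(children):
                if c.genes in seen:
                    children[i] = space.random_chromosome(rng)
                seen.add(children[i].genes)
        pop = children

    traj.evaluations = {
        k: v for k, v in cache.items() if v is not FAILED
    }
    traj.n_failed = sum(1 for v in cache.values() if v is FAILED)
    return traj
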