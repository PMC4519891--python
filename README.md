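# fccfold

Ab initio protein structure prediction on the 3-D face-centered cubic
(FCC) lattice, treating folding as a **multi-objective** optimisation
problem: a contact-based free-energy term *and* an empirical backbone
angle-preference term are minimised together with NSGA / NSGA-II, and
compared against single-objective genetic-algorithm baselines.

## Who this is for

Researchers studying simplified (lattice) protein folding models and
multi-objective evolutionary search: the package provides the lattice
geometry, the energy and angle objectives, the bespoke variation
operators, and a reproducible search engine — all scriptable from Python
or a small CLI.

## The model

A protein of sequence s = s₁…sₙ is a self-avoiding walk c = p₁…pₙ on the
FCC lattice, whose 12 neighbour directions (labelled 1–12) are the integer
vectors with two ±1 components and one zero. Objectives (all minimised):

- **E<sup>HP</sup>(c) = −|{(i,j) : j ≥ i+2, pᵢ, pⱼ lattice neighbours, sᵢ and sⱼ hydrophobic}|** —
  the HP model; hydrophobic = {C,F,I,L,M,V,W,Y}.
- **E<sup>CP</sup>(c) = −Σ M[sᵢ][sⱼ]** over the same contacts, for any
  user-supplied symmetric 20×20 contact potential M (Berrera,
  Miyazawa–Jernigan, …).
- **K<sup>KA</sup>(c) = −Σᵢ pref(κᵢ, αᵢ)** — the backbone angle-preference
  objective. κᵢ is the virtual bend angle at Cα atoms i−2, i, i+2; αᵢ the
  signed virtual dihedral of i−1…i+2. A packaged 13×6 empirical preference
  matrix (κ bins 30°–150° × six α spaces) scores each pair; pairs binning
  to zero-preference cells, or geometrically degenerate fragments, violate
  the angle constraint and such conformations are discarded during the
  multi-objective search.

Search uses binary-tournament selection, rotation-based one-point
crossover (the tail fragment is re-attached under the 9 square-based plus
8 triangle-hexagon-based lattice rotations — at most 17 offspring),
generalized pull-move local search, K-site mutation (K = 3), and either
elitist (GA), dominance-rank (NSGA) or rank-plus-crowding (NSGA-II)
survival. Defaults: population = sequence length, generations = 2 ×
length, crossover rate 0.85, mutation rate 1/length.

Predicted and reference Cα traces are compared by distance-matrix RMSD

RMSD = √( Σ_{i<j} (c⁽ᵐᵒᵈᵉˡ⁾ᵢⱼ − c⁽ʳᵉᵃˡ⁾ᵢⱼ)² / C(n,2) ),

with the lattice step scaled to the mean Cα–Cα distance of 3.8 Å.

## Worked example

```bash
$ printf '>demo\nMKVFLAGYEWCPHNDTSIRQ\n' > demo.fasta
$ fccfold predict --fasta demo.fasta --mode nsga2 --seed 1 --out demo_out
demo: 8 solution(s), best energy -10
```

The run writes, per input sequence, the final Pareto front as a
move-string table (`demo.moves.tsv`), one Cα-only PDB per front member in
Å (`demo_0.ca.pdb`, …), a generation log (`demo.log.tsv`) and the resolved
configuration (`demo.config.json`). For this 20-residue sequence with
seed 1 the front holds 8 trade-off conformations; its best contact energy
is E<sup>HP</sup> = −10 (ten H–H contacts) and the log's last line shows
the population's best angle score K<sup>KA</sup> = −218.06. Comparing two
front members:

```bash
$ fccfold evaluate --model demo_out/demo_0.ca.pdb --ref demo_out/demo_1.ca.pdb
5.2542
```

i.e. their internal Cα–Cα distance matrices differ by 5.25 Å RMS — the
same metric you would use against an experimental Cα trace
(`--ref native.pdb`). `fccfold enumerate-angles` prints every (κ, α) pair
realizable on the lattice, and `fccfold fixtures` emits random
self-avoiding walks for testing.

The same machinery is available as a library:

```python
from fccfold import EvolutionConfig, run_multiobjective
result = run_multiobjective("MKVFLAGYEWCPHNDTSIRQ", EvolutionConfig(mode="nsga2", seed=1))
for ind in result.front:
    print(ind.objectives)   # (E_HP, K_KA) per Pareto-front member
```

## Data

- `src/fccfold/data/ka_preferences.tsv` — the 13×6 (κ, α) preference
  matrix (empirical frequencies from a non-redundant, <30 % identity,
  high-resolution PDB survey).
- `src/fccfold/data/cb513_benchmark_ids.txt` — the 75 CB513-derived
  benchmark identifiers (22–88 residues). Sequences and native structures
  are not bundled; supply them as FASTA/PDB files.

See `docs/methods.md` for modelling assumptions, parameter rationale and
limitations.
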