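# Methods

## Lattice model

Residues are Cα centroids on the face-centered cubic lattice: the sites
reachable from the origin by steps with two components in {−1,+1} and one
zero. Each site has 12 neighbours at squared distance 2, giving the
densest regular packing available to a backbone-only model and much better
Cα-trace fidelity than cubic or square lattices. Chains are encoded as
absolute move strings over the labels 1–12 (FL, FR, FU, FD, BL, BR, BU,
BD, LU, LD, RU, RD); the published direction table lists BL and BR with
the same vector, an evident misprint, so BR is taken as (+1,0,−1) — the
unique assignment making the 12 vectors distinct and closed under
negation. Conformations are canonicalized to start at the origin; no
rotational canonicalization is applied because the variation operators
work on raw coordinates. Lattice units convert to Å by 3.8/√2, mapping
the step length onto the mean Cα–Cα virtual bond (3.8 Å).

## Objectives

**Contact energies.** A contact is a residue pair (i, j), j ≥ i+2, on
neighbouring sites. E_HP counts hydrophobic–hydrophobic contacts
(hydrophobic class C,F,I,L,M,V,W,Y; histidine is treated as polar),
negated so lower is better. E_CP generalizes to any symmetric 20×20
potential supplied as TSV; no published matrix is bundled, since variants
of the Berrera and Miyazawa–Jernigan tables differ in provenance and
normalisation, and the choice is the user's.

**Angle preferences.** κ at residue i is the bend angle of Cα(i−2), Cα(i),
Cα(i+2); α is the signed dihedral of Cα(i−1)…Cα(i+2) in the standard
(DSSP/IUPAC) sign convention. A chain of n residues defines n−4 (κ, α)
pairs (positions 2 ≤ i ≤ n−3, 0-based). Exhaustive enumeration of all
self-avoiding 5-point fragments (first move fixed; the lattice rotation
group is transitive on directions, so this only removes a 12-fold
multiplicity) shows that non-degenerate κ spans exactly 30°–150° and that
the realizable α values are {0°, ±54.74°, ±70.53°, ±109.47°, ±125.26°,
180°} — six magnitudes, mirror-symmetric in sign. Colinearity is decided
with exact integer cross products, not a float tolerance; a floating-point
test misclassifies some exactly-straight fragments as ≈179.999998°.

The preference matrix is 13 κ bins (30°–150°, 10° steps) × six α bins
labelled 60°, 80°, 180°, −130°, −110°, −10°. The labels are names of
dihedral ranges inherited from the survey that produced the matrix, not
lattice values; lattice α values are assigned to the nearest label by
circular distance, which maps the six realizable magnitudes onto exactly
the six bins and is unambiguous because the realized values cluster far
from bin boundaries. κ is rounded half-to-even to the nearest 10° center;
values rounding outside 30–150 score zero. K_KA is minus the summed
preference over defined, non-degenerate pairs (≤ 0; lower = more
native-like backbone geometry). The angle constraint used by the
multi-objective modes rejects any conformation with a degenerate fragment
or a zero-preference pair.

## Search

All four engines share one generational loop driven by a single seeded
PCG64 generator, so identical configuration + seed reproduces runs
bit-for-bit.

* **Initialization.** Single-objective runs start from uniform random
  self-avoiding walks (restart on dead ends). Multi-objective runs need
  angle-legal starts, and rejection sampling is hopeless beyond ~15
  residues (per-pair acceptance compounds over n−4 pairs), so initial
  conformations are grown by a randomized backtracking search that rejects
  a step as soon as the (κ, α) pair it completes is illegal; if the search
  exhausts its node budget the individual falls back to an unconstrained
  walk carrying an infeasibility flag and is ranked after every feasible
  front.
* **Variation.** Binary tournament (feasible beats infeasible, then
  energy / rank / rank-plus-crowding). With probability 0.85 a
  rotation-based crossover splits at a random point G: the head comes from
  parent 1, the tail moves from parent 2, and the tail is re-attached
  rigidly under each of 17 lattice rotations about G — 9 square-based
  (axes x, y, z; 90°, 180°, 270°) and 8 triangle-hexagon-based (the four
  body-diagonal 3-fold axes; 120°, 240°). All self-avoiding (and, in
  constrained modes, angle-legal) results enter the offspring pool;
  survival prunes. A failed crossover is retried up to 3 times, then the
  parent survives (liveness). Each offspring then gets one generalized
  pull-move trial, accepted only if it strictly improves the primary
  energy while staying legal, and a K-site mutation (K = 3, probability
  1/length) that resamples K consecutive moves and is discarded if the
  result is illegal.
* **Survival.** GA: elitist truncation on energy over parents+offspring
  (the best value is therefore monotone). NSGA: dominance-rank truncation.
  NSGA-II: rank then crowding distance (boundary members infinite) over
  the merged pool. Ties are broken by a seeded shuffle applied before
  ranking, keeping runs deterministic.
* **Termination.** A fixed number of generations (default 2 × length);
  the GA returns the best survivor, the multi-objective modes the final
  feasible first front (duplicates removed).

The original rank-based algorithm is implemented with pure dominance-rank
survival, without fitness sharing; a niche radius would add a parameter
the rest of the protocol never specifies.

## Evaluation

Structural similarity is the distance-matrix RMSD over all C(n,2) Cα–Cα
pairs, in Å. It needs no superposition and is invariant under rigid motion
and reflection; it is intentionally the only metric exposed (no Kabsch
RMSD) to avoid mixing incomparable numbers. References are compared as
raw Cα coordinates; no lattice fitting of the native is performed.

## Synthetic data

Test fixtures are generated, never downloaded: uniform random
self-avoiding walks, random 20-letter sequences with a 40 % hydrophobic
fraction (typical of globular proteins under the 8-letter hydrophobic
class), and random H/P strings. These emulate chain connectivity,
excluded volume and composition, but not real contact topology, secondary
structure or evolutionary sequence correlations — so passing tests
demonstrate algorithmic correctness (legality of every operator product,
Pareto machinery against brute-force oracles, determinism, monotone
elitism, and that the bi-objective search reaches better angle scores
than the energy-only GA on paired seeds), not predictive accuracy on real
proteins.

## Numerical choices

* Degeneracy of κ/α decided by integer cross products (exact); degenerate
  α returns NaN and is excluded from scoring.
* κ binning: round-half-to-even; α binning: nearest center, circular.
* dRMSD via `scipy.spatial.distance.pdist`; contact detection via a
  hash-map neighbourhood lookup verified against an all-pairs oracle.
* Angle computation over a whole chain is vectorized (one numpy pass);
  the scalar per-position functions are kept as the reference
  implementation and the two are cross-checked in the tests.
* Contact-potential sums iterate contacts in sorted order so float
  accumulation is reproducible.

## Problem sizes

Library defaults follow the published protocol (population = length,
generations = 2 × length). The test suite exercises the engines at 12–20
residues with 10 paired seeds — sizes chosen so the full suite documents
the behavioural claims in about a minute while still using the default
protocol at n = 20. Benchmark-scale runs (22–88 residues, 30 repeats)
are a straightforward loop over `load_benchmark_list()` with user-supplied
FASTA/PDB files.

## Limitations

* Backbone-only, single chain; no side chains, hydrogen bonds,
  electrostatics or solvation.
* The preference matrix is shipped as data; re-deriving it from a current
  PDB snapshot would require a DSSP pipeline that is out of scope.
* The α bin labels inherit a non-contiguous range convention from the
  original survey (recorded in the data file's provenance, unused by the
  lattice-side binning).
* Lattice discretisation bounds attainable accuracy: even a perfect
  search cannot beat the best lattice fit of the native fold.
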