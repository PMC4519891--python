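"""Evolutionary search engines for lattice protein folding.

Four modes share one generational loop and the same variation operators:

* ``ga-hp`` / ``ga-cp`` — single-objective genetic algorithms minimizing
  the HP or contact-potential energy, with elitist survival.
* ``nsga`` / ``nsga2`` — bi-objective search minimizing (E_HP, K_KA),
  i.e. contact energy together with the backbone angle-preference
  objective, under the angle-legality constraint: offspring containing a
  degenerate or zero-preference (κ, α) pair are discarded.  NSGA survives
  by dominance rank alone; NSGA-II by rank then crowding distance over the
  merged parent+offspring pool.

Variation operators:

* rotation-based crossover — one-point crossover in which the tail
  fragment (taken from the second parent) is re-attached to the first
  parent's head under each of 17 lattice rotations about the crossover
  point: 9 square-based (coordinate axes x, y, z at 90°, 180°, 270°) and 8
  triangle-hexagon-based (the four body-diagonal 3-fold axes at 120° and
  240°).  Rotating the junction searches collision-free re-attachments,
  which is what raises the crossover success rate on a crowded lattice.
* generalized pull move — local search: one residue hops to a free
  neighbour of its predecessor and the tail is pulled along, each pulled
  point taking its predecessor's former position, until the chain
  reconnects.
* K-site mutation — resamples K consecutive move symbols (K = 3 by
  default), perturbing the walk locally without destroying the global
  fold.

Default parameters follow the published protocol: population size equal
to the sequence length, 2 x length generations, crossover rate 0.85,
mutation rate 1/length, tournament size 2.  All randomness flows from one
seeded generator, so runs are reproducible bit-for-bit.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from . import angles as _angles
from . import energy as _energy
from .angles import PreferenceMatrix, check_angle_constraint, load_preference_matrix
from .energy import ContactMatrix
from .lattice import (
    DIRECTION_ARRAY,
    Conformation,
    conformation_from_coords,
    is_self_avoiding,
    moves_from_coords,
    neighbors,
    random_saw,
)

__all__ = [
    "Individual",
    "EvolutionConfig",
    "GAResult",
    "ParetoResult",
    "rotation_matrices",
    "rotation_crossover",
    "generalized_pull_move",
    "k_site_mutation",
    "tournament_select",
    "nondominated_sort",
    "crowding_distance",
    "random_feasible_conformation",
    "run_single_objective",
    "run_multiobjective",
]

Mode = Literal["ga-hp", "ga-cp", "nsga", "nsga2"]


# ---------------------------------------------------------------------------
# rotations


def _square_rotations() -> list[np.ndarray]:
    mats = []
    for axis in np.eye(3):
        for angle in (0.5 * math.pi, math.pi, 1.5 * math.pi):
            mats.append(Rotation.from_rotvec(axis * angle).as_matrix())
    return mats


def _diagonal_rotations() -> list[np.ndarray]:
    mats = []
    for axis in ([1, 1, 1], [1, 1, -1], [1, -1, 1], [-1, 1, 1]):
        u = np.asarray(axis, dtype=float) / math.sqrt(3.0)
        for angle in (2.0 * math.pi / 3.0, 4.0 * math.pi / 3.0):
            mats.append(Rotation.from_rotvec(u * angle).as_matrix())
    return mats


def _as_int(mats: list[np.ndarray]) -> list[np.ndarray]:
    out = []
    for m in mats:
        r = np.rint(m).astype(np.int64)
        assert np.allclose(m, r, atol=1e-9), "lattice rotation must be integral"
        out.append(r)
    return out


def rotation_matrices() -> dict[str, list[np.ndarray]]:
    """The 17 crossover rotations, grouped by family.

    ``square``: 9 matrices (3 coordinate axes x 3 angles); ``diagonal``: 8
    matrices (4 body-diagonal axes x 2 angles).  All are integer matrices
    that permute the 12 FCC directions.
    """
    return {
        "square": _as_int(_square_rotations()),
        "diagonal": _as_int(_diagonal_rotations()),
    }


_ROTATIONS: list[np.ndarray] = (
    rotation_matrices()["square"] + rotation_matrices()["diagonal"]
)


# ---------------------------------------------------------------------------
# variation operators


def rotation_crossover(
    parent1: Conformation,
    parent2: Conformation,
    rng: np.random.Generator,
    point: int | None = None,
) -> list[Conformation]:
    """One-point crossover with rotational re-attachment.

    Splits at a random move index G in 1..n-2: the head (moves before G)
    comes from ``parent1``, the tail (moves from G on) from ``parent2``.
    The tail is treated as a rigid body and attached under each of the 17
    lattice rotations; only offspring that remain self-avoiding walks are
    kept, so at most 17 are returned (possibly none).
    """
    if parent1.sequence != parent2.sequence:
        raise ValueError("parents must share the same sequence")
    n = parent1.n
    if n < 3:
        return []
    g = int(rng.integers(1, n - 1)) if point is None else point
    if not 1 <= g <= n - 2:
        raise ValueError(f"crossover point {g} outside 1..{n - 2}")
    head = parent1.coords[: g + 1]
    tail_steps = DIRECTION_ARRAY[np.array(parent2.moves[g:]) - 1]
    offspring = []
    for rot in _ROTATIONS:
        steps = tail_steps @ rot.T
        coords = np.vstack([head, head[-1] + np.cumsum(steps, axis=0)])
        if is_self_avoiding(coords):
            offspring.append(
                Conformation(parent1.sequence, moves_from_coords(coords), coords)
            )
    return offspring


def generalized_pull_move(
    conformation: Conformation, rng: np.random.Generator
) -> Conformation:
    """One generalized pull move; returns the input if no legal move exists.

    A random bonded pair (P_i, P_{i+1}) is chosen; P_{i+1} hops to a free
    lattice neighbour of P_i, and the downstream points are pulled along —
    each moving to its predecessor's former position — until the chain is
    reconnected.  Candidates are tried in random order and the first
    resulting valid self-avoiding walk is returned.
    """
    coords = conformation.coords
    n = len(coords)
    if n < 2:
        return conformation
    occupied = {tuple(p) for p in coords.tolist()}
    i = int(rng.integers(0, n - 1))
    candidates = [q for q in neighbors(coords[i]) if q not in occupied]
    for k in rng.permutation(len(candidates)):
        new = coords.copy()
        new[i + 1] = candidates[int(k)]
        for j in range(i + 2, n):
            if int(np.sum((new[j] - new[j - 1]) ** 2)) == 2:
                break
            new[j] = coords[j - 1]
        if _valid_walk(new):
            return Conformation(conformation.sequence, moves_from_coords(new), new)
    return conformation


def _valid_walk(coords: np.ndarray) -> bool:
    steps = np.diff(coords, axis=0)
    if not (np.sum(steps**2, axis=1) == 2).all():
        return False
    if (steps == 0).all(axis=1).any() or np.abs(steps).max() > 1:
        return False
    return is_self_avoiding(coords)


def k_site_mutation(
    conformation: Conformation,
    k: int,
    rng: np.random.Generator,
    max_attempts: int = 50,
) -> Conformation:
    """Resample K consecutive move symbols; retry until self-avoiding.

    The window start is uniform over the move string; downstream
    coordinates are rebuilt from the mutated moves (absolute encoding).
    After ``max_attempts`` failed draws the input is returned unchanged.
    """
    n = conformation.n
    if not 1 <= k < n:
        raise ValueError(f"mutation window {k} outside 1..{n - 1}")
    moves = np.array(conformation.moves)
    for _ in range(max_attempts):
        start = int(rng.integers(0, n - k))
        mutated = moves.copy()
        mutated[start : start + k] = rng.integers(1, 13, size=k)
        coords = np.zeros((n, 3), dtype=np.int64)
        coords[1:] = np.cumsum(DIRECTION_ARRAY[mutated - 1], axis=0)
        if is_self_avoiding(coords):
            return Conformation(conformation.sequence, tuple(mutated.tolist()), coords)
    return conformation


# ---------------------------------------------------------------------------
# population machinery


@dataclass
class Individual:
    conformation: Conformation
    objectives: tuple[float, ...]
    rank: int | None = None
    crowding: float | None = None
    feasible: bool = True


@dataclass
class EvolutionConfig:
    """Search parameters; unset fields resolve to the published defaults.

    population_size = sequence length, generations = 2 x length,
    crossover_rate = 0.85, mutation_rate = 1/length, K = 3, tournament 2.
    """

    mode: Mode = "nsga2"
    seed: int = 0
    population_size: int | None = None
    generations: int | None = None
    crossover_rate: float = 0.85
    mutation_rate: float | None = None
    k: int = 3
    tournament_size: int = 2
    contact_matrix: ContactMatrix | None = None
    preference_matrix: PreferenceMatrix | None = None

    def resolved(self, sequence: str) -> "EvolutionConfig":
        n = len(sequence)
        cfg = replace(
            self,
            mode=self.mode.lower(),
            population_size=self.population_size or n,
            generations=self.generations if self.generations is not None else 2 * n,
            mutation_rate=self.mutation_rate
            if self.mutation_rate is not None
            else 1.0 / n,
            k=min(self.k, n - 1),
        )
        if cfg.mode not in ("ga-hp", "ga-cp", "nsga", "nsga2"):
            raise ValueError(f"unknown mode {cfg.mode!r}")
        if cfg.mode == "ga-cp" and cfg.contact_matrix is None:
            raise ValueError("ga-cp mode requires a contact matrix")
        if cfg.mode in ("nsga", "nsga2") and cfg.preference_matrix is None:
            cfg = replace(cfg, preference_matrix=load_preference_matrix())
        return cfg

    @property
    def multiobjective(self) -> bool:
        return self.mode in ("nsga", "nsga2")


def dominates(a: Sequence[float], b: Sequence[float]) -> bool:
    """Pareto dominance for minimization: no worse everywhere, better once."""
    return all(x <= y for x, y in zip(a, b)) and any(x < y for x, y in zip(a, b))


def nondominated_sort(population: list[Individual]) -> list[list[Individual]]:
    """Fast non-dominated sort; assigns 1-based ranks and returns fronts."""
    n = len(population)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    counts = [0] * n
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(population[i].objectives, population[j].objectives):
                dominated_by[i].append(j)
                counts[j] += 1
            elif dominates(population[j].objectives, population[i].objectives):
                dominated_by[j].append(i)
                counts[i] += 1
    fronts: list[list[Individual]] = []
    current = [i for i in range(n) if counts[i] == 0]
    rank = 1
    while current:
        for i in current:
            population[i].rank = rank
        fronts.append([population[i] for i in current])
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                counts[j] -= 1
                if counts[j] == 0:
                    nxt.append(j)
        current = nxt
        rank += 1
    return fronts


def crowding_distance(front: list[Individual]) -> list[float]:
    """Standard NSGA-II crowding distance; boundary members get infinity."""
    n = len(front)
    if n == 0:
        return []
    if n <= 2:
        for ind in front:
            ind.crowding = math.inf
        return [math.inf] * n
    m = len(front[0].objectives)
    dist = [0.0] * n
    for obj in range(m):
        order = sorted(range(n), key=lambda i: front[i].objectives[obj])
        lo = front[order[0]].objectives[obj]
        hi = front[order[-1]].objectives[obj]
        dist[order[0]] = dist[order[-1]] = math.inf
        if hi == lo:
            continue
        for pos in range(1, n - 1):
            gap = (
                front[order[pos + 1]].objectives[obj]
                - front[order[pos - 1]].objectives[obj]
            )
            if not math.isinf(dist[order[pos]]):
                dist[order[pos]] += gap / (hi - lo)
    for ind, d in zip(front, dist):
        ind.crowding = d
    return dist


def _better(a: Individual, b: Individual, mode: str) -> Individual:
    """Binary-tournament comparison; ties go to the first argument."""
    if a.feasible != b.feasible:
        return a if a.feasible else b
    if mode in ("ga-hp", "ga-cp"):
        return a if a.objectives[0] <= b.objectives[0] else b
    if (a.rank or 1) != (b.rank or 1):
        return a if (a.rank or 1) < (b.rank or 1) else b
    if mode == "nsga2":
        ac = a.crowding if a.crowding is not None else 0.0
        bc = b.crowding if b.crowding is not None else 0.0
        if ac != bc:
            return a if ac > bc else b
    return a


def tournament_select(
    population: list[Individual], rng: np.random.Generator, mode: str = "ga-hp"
) -> Individual:
    """Binary tournament: the better of two uniformly drawn individuals."""
    if not population:
        raise ValueError("cannot select from an empty population")
    if len(population) == 1:
        return population[0]
    i, j = rng.choice(len(population), size=2, replace=False)
    return _better(population[int(i)], population[int(j)], mode)


# ---------------------------------------------------------------------------
# constrained initialization


def random_feasible_conformation(
    sequence: str,
    matrix: PreferenceMatrix,
    rng: np.random.Generator,
    max_nodes: int = 200_000,
    max_restarts: int = 50,
) -> Conformation:
    """Sample a SAW satisfying the angle constraint, by backtracking growth.

    The chain is grown step by step in a randomized depth-first search; a
    step is rejected as soon as the (κ, α) pair it completes (at position
    j-2 once point j exists) is degenerate or falls in a zero-preference
    bin.  Dead branches backtrack; ``max_nodes`` expansions trigger a
    restart.  This makes angle-legal initial populations practical at any
    chain length, where rejection sampling of plain SAWs is hopeless.
    """
    n = len(sequence)
    if n < 2:
        raise ValueError("need at least 2 residues")
    dirs = DIRECTION_ARRAY.tolist()
    for _ in range(max_restarts):
        pts: list[tuple[int, int, int]] = [(0, 0, 0)]
        occupied = {pts[0]}
        stack: list[list[int]] = [list(rng.permutation(12))]
        nodes = 0
        while stack and nodes < max_nodes:
            if len(pts) == n:
                return conformation_from_coords(sequence, np.array(pts))
            options = stack[-1]
            if not options:
                stack.pop()
                if len(pts) > 1:
                    occupied.discard(pts.pop())
                continue
            k = options.pop()
            dx, dy, dz = dirs[int(k)]
            x, y, z = pts[-1]
            q = (x + dx, y + dy, z + dz)
            if q in occupied:
                continue
            nodes += 1
            pts.append(q)
            j = len(pts) - 1
            if j >= 4:
                coords = np.array(pts[j - 4 :], dtype=np.int64)
                if not _angles._pair_is_feasible(coords, 2, matrix):
                    pts.pop()
                    continue
            occupied.add(q)
            stack.append(list(rng.permutation(12)))
        # fell through: restart with a fresh random branch order
    raise RuntimeError(
        f"no angle-feasible walk of length {n} found in {max_restarts} restarts"
    )


# ---------------------------------------------------------------------------
# engines


@dataclass
class GAResult:
    best: Individual
    history: list[dict]
    population: list[Individual] = field(default_factory=list)


@dataclass
class ParetoResult:
    front: list[Individual]
    history: list[dict]
    population: list[Individual] = field(default_factory=list)


class _Problem:
    """Objective evaluation and feasibility for one sequence + mode."""

    def __init__(self, sequence: str, config: EvolutionConfig):
        self.sequence = sequence
        self.config = config
        self.mode = config.mode

    def evaluate(self, conformation: Conformation) -> tuple[float, ...]:
        if self.mode == "ga-cp":
            return (_energy.cp_energy(conformation, self.config.contact_matrix),)
        e_hp = float(_energy.hp_energy(conformation))
        if self.mode == "ga-hp":
            return (e_hp,)
        return (e_hp, _angles.ka_energy(conformation, self.config.preference_matrix))

    def feasible(self, conformation: Conformation) -> bool:
        if not self.config.multiobjective:
            return True
        return check_angle_constraint(conformation, self.config.preference_matrix)

    def individual(self, conformation: Conformation, feasible=None) -> Individual:
        return Individual(
            conformation,
            self.evaluate(conformation),
            feasible=self.feasible(conformation) if feasible is None else feasible,
        )


def _initial_population(
    problem: _Problem, config: EvolutionConfig, rng: np.random.Generator
) -> list[Individual]:
    pop = []
    for _ in range(config.population_size):
        if config.multiobjective:
            try:
                conf = random_feasible_conformation(
                    problem.sequence, config.preference_matrix, rng
                )
            except RuntimeError:
                conf = random_saw(len(problem.sequence), rng, problem.sequence)
        else:
            conf = random_saw(len(problem.sequence), rng, problem.sequence)
        pop.append(problem.individual(conf))
    return pop


def _local_search(
    ind_conf: Conformation, problem: _Problem, rng: np.random.Generator
) -> Conformation:
    """One pull-move trial, accepted only if it strictly improves the
    primary energy (and, in constrained modes, stays angle-legal)."""
    trial = generalized_pull_move(ind_conf, rng)
    if trial is ind_conf:
        return ind_conf
    if not problem.feasible(trial):
        return ind_conf
    if problem.evaluate(trial)[0] < problem.evaluate(ind_conf)[0]:
        return trial
    return ind_conf


def _make_offspring(
    population: list[Individual],
    problem: _Problem,
    config: EvolutionConfig,
    rng: np.random.Generator,
) -> list[Individual]:
    offspring: list[Individual] = []
    for _ in range(max(1, config.population_size // 2)):
        pa = tournament_select(population, rng, config.mode)
        pb = tournament_select(population, rng, config.mode)
        if rng.random() < config.crossover_rate:
            confs: list[Conformation] = []
            for _attempt in range(3):
                kids = rotation_crossover(pa.conformation, pb.conformation, rng)
                confs = [c for c in kids if problem.feasible(c)]
                if confs:
                    break
            if not confs:
                confs = [pa.conformation]  # failed crossover: parent survives
        else:
            confs = [pa.conformation, pb.conformation]
        for conf in confs:
            conf = _local_search(conf, problem, rng)
            if rng.random() < config.mutation_rate:
                mutant = k_site_mutation(conf, config.k, rng)
                if problem.feasible(mutant):
                    conf = mutant
            offspring.append(problem.individual(conf))
    return offspring


def _rank_population(population: list[Individual], mode: str) -> None:
    if mode in ("ga-hp", "ga-cp"):
        for r, ind in enumerate(
            sorted(population, key=lambda x: x.objectives[0]), start=1
        ):
            ind.rank = r
        return
    feas = [ind for ind in population if ind.feasible]
    infeas = [ind for ind in population if not ind.feasible]
    fronts = nondominated_sort(feas) if feas else []
    for front in fronts:
        crowding_distance(front)
    worst = len(fronts) + 1
    for ind in infeas:  # penalized rank: after every feasible front
        ind.rank = worst
        ind.crowding = 0.0


def _survival(
    merged: list[Individual], config: EvolutionConfig, rng: np.random.Generator
) -> list[Individual]:
    size = config.population_size
    if not config.multiobjective:
        merged.sort(key=lambda x: x.objectives[0])
        return merged[:size]
    # rng-shuffled stable order breaks ties reproducibly
    merged = [merged[int(i)] for i in rng.permutation(len(merged))]
    _rank_population(merged, config.mode)
    feas = [ind for ind in merged if ind.feasible]
    infeas = [ind for ind in merged if not ind.feasible]
    fronts = _group_fronts(feas)
    survivors: list[Individual] = []
    for front in fronts:
        if len(survivors) + len(front) <= size:
            survivors.extend(front)
        else:
            need = size - len(survivors)
            if config.mode == "nsga2":
                front = sorted(
                    front, key=lambda x: -(x.crowding if x.crowding else 0.0)
                )
            survivors.extend(front[:need])
        if len(survivors) >= size:
            return survivors
    survivors.extend(infeas[: size - len(survivors)])
    return survivors


def _group_fronts(feasible: list[Individual]) -> list[list[Individual]]:
    by_rank: dict[int, list[Individual]] = {}
    for ind in feasible:
        by_rank.setdefault(ind.rank or 1, []).append(ind)
    return [by_rank[r] for r in sorted(by_rank)]


def _history_row(gen: int, population: list[Individual], mode: str) -> dict:
    primary = [ind.objectives[0] for ind in population]
    row = {
        "generation": gen,
        "best_energy": min(primary),
        "median_energy": statistics.median(primary),
    }
    if mode in ("nsga", "nsga2"):
        ka = [ind.objectives[1] for ind in population]
        row["best_ka"] = min(ka)
        row["median_ka"] = statistics.median(ka)
        row["front_size"] = sum(1 for ind in population if ind.rank == 1)
    return row


def _run(sequence: str, config: EvolutionConfig):
    sequence = sequence.upper()
    _energy.classify_hp(sequence)  # validates the alphabet
    config = config.resolved(sequence)
    rng = np.random.default_rng(config.seed)
    problem = _Problem(sequence, config)
    population = _initial_population(problem, config, rng)
    _rank_population(population, config.mode)
    history = [_history_row(0, population, config.mode)]
    for gen in range(1, config.generations + 1):
        offspring = _make_offspring(population, problem, config, rng)
        population = _survival(population + offspring, config, rng)
        _rank_population(population, config.mode)
        history.append(_history_row(gen, population, config.mode))
    return population, history, config


def run_single_objective(sequence: str, config: EvolutionConfig) -> GAResult:
    """Minimize one contact energy by an elitist GA; returns the best
    individual remaining in the final population plus the run history."""
    if config.mode not in ("ga-hp", "ga-cp"):
        raise ValueError("run_single_objective requires mode ga-hp or ga-cp")
    population, history, _ = _run(sequence, config)
    best = min(population, key=lambda x: x.objectives[0])
    return GAResult(best=best, history=history, population=population)


def run_multiobjective(sequence: str, config: EvolutionConfig) -> ParetoResult:
    """Minimize (E_HP, K_KA) under the angle constraint; returns the final
    first (non-dominated, feasible) front plus the run history."""
    if config.mode not in ("nsga", "nsga2"):
        raise ValueError("run_multiobjective requires mode nsga or nsga2")
    population, history, _ = _run(sequence, config)
    feas = [ind for ind in population if ind.feasible]
    front = nondominated_sort(feas)[0] if feas else []
    # drop duplicate conformations for a clean front
    seen: set[tuple[int, ...]] = set()
    unique = []
    for ind in front:
        key = ind.conformation.moves
        if key not in seen:
            seen.add(key)
            unique.append(ind)
    return ParetoResult(front=unique, history=history, population=population)
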