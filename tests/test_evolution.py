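"""Variation operators, Pareto machinery and the search engines."""

import itertools
import math

import numpy as np
import pytest

from fccfold.angles import check_angle_constraint
from fccfold.energy import hp_energy
from fccfold.evolution import (
    EvolutionConfig,
    Individual,
    crowding_distance,
    dominates,
    generalized_pull_move,
    k_site_mutation,
    nondominated_sort,
    random_feasible_conformation,
    rotation_crossover,
    rotation_matrices,
    run_multiobjective,
    run_single_objective,
    tournament_select,
)
from fccfold.fixtures import random_sequence
from fccfold.lattice import DIRECTION_ARRAY, random_saw


def make_pop(objectives):
    return [Individual(None, tuple(obj)) for obj in objectives]


class TestRotations:
    def test_family_sizes(self):
        rots = rotation_matrices()
        assert len(rots["square"]) == 9
        assert len(rots["diagonal"]) == 8

    def test_all_seventeen_distinct_lattice_symmetries(self):
        mats = rotation_matrices()["square"] + rotation_matrices()["diagonal"]
        keys = {tuple(m.ravel()) for m in mats}
        assert len(keys) == 17
        dir_set = {tuple(v) for v in DIRECTION_ARRAY.tolist()}
        for m in mats:
            assert round(float(np.linalg.det(m))) == 1  # proper rotation
            rotated = {tuple(v) for v in (DIRECTION_ARRAY @ m.T).tolist()}
            assert rotated == dir_set  # permutes the FCC neighbourhood


class TestCrossover:
    def test_at_most_seventeen_valid_offspring(self, rng):
        for _ in range(20):
            seq = random_sequence(15, rng)
            p1 = random_saw(15, rng, seq)
            p2 = random_saw(15, rng, seq)
            kids = rotation_crossover(p1, p2, rng)
            assert len(kids) <= 17
            for kid in kids:
                kid.validate()
                assert kid.sequence == seq

    def test_head_comes_from_first_parent(self, rng):
        seq = "A" * 12
        p1 = random_saw(12, rng, seq)
        p2 = random_saw(12, rng, seq)
        g = 5
        kids = rotation_crossover(p1, p2, rng, point=g)
        for kid in kids:
            assert np.array_equal(kid.coords[: g + 1], p1.coords[: g + 1])
            assert kid.moves[:g] == p1.moves[:g]

    def test_sequence_mismatch_rejected(self, rng):
        p1 = random_saw(10, rng, "A" * 10)
        p2 = random_saw(10, rng, "G" * 10)
        with pytest.raises(ValueError):
            rotation_crossover(p1, p2, rng)

    def test_tail_is_rigidly_rotated(self, rng):
        # each offspring's tail internal distance matrix equals the donor's
        seq = "A" * 10
        p1 = random_saw(10, rng, seq)
        p2 = random_saw(10, rng, seq)
        g = 4
        tail_ref = np.diff(p2.coords[g:], axis=0)
        for kid in rotation_crossover(p1, p2, rng, point=g):
            tail = np.diff(kid.coords[g:], axis=0)
            assert np.array_equal(
                np.einsum("ij,ij->i", tail, tail),
                np.einsum("ij,ij->i", tail_ref, tail_ref),
            )


class TestPullMove:
    def test_always_returns_valid_walk(self, rng):
        for _ in range(1000):
            conf = random_saw(20, rng)
            moved = generalized_pull_move(conf, rng)
            moved.validate()
            assert moved.sequence == conf.sequence

    def test_two_residue_chain(self, rng):
        conf = random_saw(2, rng)
        moved = generalized_pull_move(conf, rng)
        moved.validate()

    def test_often_changes_the_conformation(self, rng):
        changed = 0
        for _ in range(20):
            conf = random_saw(20, rng)
            moved = generalized_pull_move(conf, rng)
            changed += moved.moves != conf.moves
        assert changed > 0


class TestMutation:
    def test_valid_and_local(self, rng):
        for _ in range(200):
            conf = random_saw(20, rng)
            mut = k_site_mutation(conf, 3, rng)
            mut.validate()
            differing = sum(a != b for a, b in zip(conf.moves, mut.moves))
            assert differing <= 3

    def test_full_window_resamples_whole_chain(self, rng):
        conf = random_saw(8, rng)
        mut = k_site_mutation(conf, 7, rng)
        mut.validate()

    def test_window_bounds(self, rng):
        conf = random_saw(8, rng)
        with pytest.raises(ValueError):
            k_site_mutation(conf, 8, rng)


class TestDominance:
    def test_example_fronts(self):
        pop = make_pop([(1, 2), (2, 1), (2, 2)])
        fronts = nondominated_sort(pop)
        assert [sorted(i.objectives for i in f) for f in fronts] == [
            [(1, 2), (2, 1)],
            [(2, 2)],
        ]
        assert [i.rank for i in pop] == [1, 1, 2]

    def test_identical_vectors_share_a_front(self):
        pop = make_pop([(1, 1), (1, 1), (1, 1)])
        assert len(nondominated_sort(pop)) == 1

    def test_single_individual(self):
        assert len(nondominated_sort(make_pop([(0, 0)]))) == 1

    def test_matches_peeling_oracle(self, rng):
        def oracle_ranks(objs):
            remaining = list(range(len(objs)))
            rank = {}
            r = 1
            while remaining:
                front = [
                    i
                    for i in remaining
                    if not any(
                        dominates(objs[j], objs[i]) for j in remaining if j != i
                    )
                ]
                for i in front:
                    rank[i] = r
                remaining = [i for i in remaining if i not in front]
                r += 1
            return [rank[i] for i in range(len(objs))]

        for n in (5, 20, 50):
            objs = [tuple(v) for v in rng.integers(0, 8, size=(n, 2)).tolist()]
            pop = make_pop(objs)
            nondominated_sort(pop)
            assert [i.rank for i in pop] == oracle_ranks(objs)


class TestCrowding:
    def test_small_fronts_all_infinite(self):
        pop = make_pop([(0, 1), (1, 0)])
        assert crowding_distance(pop) == [math.inf, math.inf]

    def test_evenly_spaced_interior(self):
        pop = make_pop([(0.0, 2.0), (1.0, 1.0), (2.0, 0.0)])
        dist = crowding_distance(pop)
        assert dist[0] == math.inf and dist[2] == math.inf
        assert dist[1] == pytest.approx(2.0)

    def test_permutation_invariance(self, rng):
        objs = [(0.0, 3.0), (1.0, 2.5), (2.0, 1.0), (4.0, 0.0)]
        base = dict(zip(objs, crowding_distance(make_pop(objs))))
        for perm in itertools.permutations(objs):
            got = dict(zip(perm, crowding_distance(make_pop(list(perm)))))
            assert got == base


class TestTournament:
    def test_single_member_population(self, rng):
        pop = make_pop([(-1.0,)])
        assert tournament_select(pop, rng, "ga-hp") is pop[0]

    def test_lower_energy_wins(self, rng):
        pop = make_pop([(-5.0,), (-3.0,)])
        for _ in range(10):
            assert tournament_select(pop, rng, "ga-hp").objectives == (-5.0,)

    def test_crowded_comparison(self):
        a = Individual(None, (0, 0), rank=1, crowding=math.inf)
        b = Individual(None, (0, 0), rank=1, crowding=0.2)
        from fccfold.evolution import _better

        assert _better(a, b, "nsga2") is a
        assert _better(b, a, "nsga2") is a
        c = Individual(None, (0, 0), rank=2, crowding=math.inf)
        assert _better(a, c, "nsga") is a


class TestFeasibleSampler:
    def test_feasible_and_deterministic(self, pref):
        a = random_feasible_conformation("A" * 25, pref, np.random.default_rng(11))
        b = random_feasible_conformation("A" * 25, pref, np.random.default_rng(11))
        a.validate()
        assert check_angle_constraint(a, pref)
        assert a.moves == b.moves


class TestSingleObjective:
    def test_zero_generations_returns_best_of_init(self):
        seq = random_sequence(12, 3)
        cfg = EvolutionConfig(mode="ga-hp", seed=3, generations=0)
        res = run_single_objective(seq, cfg)
        assert len(res.history) == 1
        assert res.best.objectives[0] == res.history[0]["best_energy"]

    @pytest.mark.parametrize("seed", range(5))
    def test_elitism_makes_best_energy_monotone(self, seed):
        seq = random_sequence(14, seed)
        cfg = EvolutionConfig(mode="ga-hp", seed=seed, generations=12)
        res = run_single_objective(seq, cfg)
        bests = [row["best_energy"] for row in res.history]
        assert all(b2 <= b1 for b1, b2 in zip(bests, bests[1:]))
        assert res.best.objectives[0] == bests[-1]

    def test_all_polar_sequence_stays_at_zero(self):
        cfg = EvolutionConfig(mode="ga-hp", seed=1, generations=5)
        res = run_single_objective("GSTN" * 4, cfg)
        assert res.best.objectives[0] == 0.0

    def test_contact_potential_mode_requires_matrix(self):
        with pytest.raises(ValueError):
            run_single_objective("ACDE", EvolutionConfig(mode="ga-cp", seed=0))

    def test_contact_potential_mode_runs(self, rng):
        from fccfold.energy import ContactMatrix

        cfg = EvolutionConfig(
            mode="ga-cp",
            seed=2,
            generations=4,
            contact_matrix=ContactMatrix.hp_indicator(),
        )
        res = run_single_objective(random_sequence(10, 5), cfg)
        assert res.best.objectives[0] <= 0.0


@pytest.fixture(scope="module")
def small_run():
    seq = random_sequence(12, 7)
    cfg = EvolutionConfig(mode="nsga2", seed=7, generations=8)
    return seq, cfg, run_multiobjective(seq, cfg)


class TestMultiObjective:
    def test_front_is_mutually_nondominated(self, small_run):
        _, _, res = small_run
        objs = [ind.objectives for ind in res.front]
        for a in objs:
            for b in objs:
                assert not dominates(a, b)

    def test_front_satisfies_angle_constraint(self, small_run, pref):
        _, _, res = small_run
        assert res.front
        for ind in res.front:
            ind.conformation.validate()
            assert check_angle_constraint(ind.conformation, pref)
            assert ind.objectives[0] == hp_energy(ind.conformation)

    def test_seed_determinism(self, small_run):
        seq, cfg, res = small_run
        again = run_multiobjective(seq, cfg)
        assert [i.conformation.moves for i in res.population] == [
            i.conformation.moves for i in again.population
        ]
        assert [i.objectives for i in res.front] == [i.objectives for i in again.front]

    def test_nsga_mode_runs_with_rank_only_survival(self):
        seq = random_sequence(10, 9)
        cfg = EvolutionConfig(mode="nsga", seed=9, generations=6)
        res = run_multiobjective(seq, cfg)
        assert res.front
        for ind in res.front:
            ind.conformation.validate()
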