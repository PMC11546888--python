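"""Seed sets, random walk with restart, and boosted-set extraction.

The walk's fixed point has a closed form, u* = p (I - (1-p) A)^-1 u0, which
serves as an independent oracle for the power iteration throughout.
"""

import numpy as np
import pytest

from mirboost.identifiers import GeneId
from mirboost.ppi_network import build_transition_matrix
from mirboost.propagation import (
    classify_connectivity,
    construct_seed_set,
    make_restart_vector,
    rwr,
    select_boosted,
)

from conftest import gid, make_net, random_net


def solve_rwr(A, u0, p):
    """Closed-form stationary solution (dangling mass sent to u0)."""
    M = A.matrix.copy()
    if A.dangling.any():
        # teleporting from dangling columns == replacing them with u0
        M[:, A.dangling] = u0[:, None]
    n = M.shape[0]
    return np.linalg.solve(np.eye(n) - (1 - p) * M, p * u0)


def seeds_on(net, entrez):
    genes = {gid(e) for e in entrez}
    return construct_seed_set(genes, genes, net, mode="intersection")


class TestConstructSeedSet:
    def test_intersection_and_union(self):
        net = make_net([(1, 2), (2, 3), (3, 4)])
        degs = {gid(1), gid(2), gid(3)}
        targets = {gid(2), gid(3), gid(4)}
        inter = construct_seed_set(degs, targets, net, "intersection")
        assert inter.entrez == {2, 3}
        union = construct_seed_set(degs, targets, net, "union")
        assert union.entrez == {1, 2, 3, 4}

    def test_provenance_flags(self):
        net = make_net([(1, 2), (2, 3)])
        seeds = construct_seed_set({gid(1), gid(2)}, {gid(2), gid(3)}, net, "union")
        assert seeds.provenance[1] == {"is_DEG": True, "is_DER_target": False}
        assert seeds.provenance[2] == {"is_DEG": True, "is_DER_target": True}
        # every intersection seed carries both flags
        inter = construct_seed_set({gid(1), gid(2)}, {gid(2), gid(3)}, net, "intersection")
        assert all(
            flags["is_DEG"] and flags["is_DER_target"]
            for flags in inter.provenance.values()
        )

    def test_empty_seed_set_is_hard_error(self):
        net = make_net([(1, 2)])
        with pytest.raises(ValueError, match="empty"):
            construct_seed_set({gid(99)}, {gid(99)}, net, "intersection")


class TestRestartVector:
    def test_uniform_over_seeds(self):
        net = make_net([(1, 2), (2, 3), (3, 4)])
        u0 = make_restart_vector(seeds_on(net, {1, 2}), net)
        np.testing.assert_allclose(u0, [0.5, 0.5, 0.0, 0.0])

    def test_single_seed_indicator(self):
        net = make_net([(1, 2), (2, 3)])
        u0 = make_restart_vector(seeds_on(net, {3}), net)
        np.testing.assert_array_equal(u0, [0, 0, 1])

    @pytest.mark.parametrize("seed_ids", [{1}, {1, 3}, {1, 2, 3, 4}])
    def test_always_a_distribution(self, seed_ids):
        net = make_net([(1, 2), (2, 3), (3, 4)])
        assert make_restart_vector(seeds_on(net, seed_ids), net).sum() == pytest.approx(1.0)


class TestRWR:
    def test_restart_one_returns_u0_exactly(self, path_abc):
        A = build_transition_matrix(path_abc)
        u0 = make_restart_vector(seeds_on(path_abc, {1}), path_abc)
        res = rwr(A, u0, restart_p=1.0)
        np.testing.assert_array_equal(res.scores, u0)
        assert res.iterations == 1

    def test_single_node_network(self):
        net = make_net([], extra_nodes=[1])
        A = build_transition_matrix(net)
        res = rwr(A, np.array([1.0]), restart_p=0.5)
        np.testing.assert_allclose(res.scores, [1.0])

    def test_path_matches_direct_solve(self, path_abc):
        A = build_transition_matrix(path_abc)
        u0 = make_restart_vector(seeds_on(path_abc, {1}), path_abc)
        res = rwr(A, u0, restart_p=0.5, tol=1e-14)
        expected = solve_rwr(A, u0, 0.5)
        np.testing.assert_allclose(res.scores, expected, atol=1e-10)

    def test_oracle_equivalence_on_random_graphs(self):
        """Power iteration equals the linear-system solution (20 graphs)."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            net = random_net(rng, n_max=50)
            A = build_transition_matrix(net)
            n_seeds = int(rng.integers(1, net.n_nodes // 2 + 1))
            seed_ids = {net.nodes[i].entrez for i in rng.choice(net.n_nodes, n_seeds, replace=False)}
            u0 = make_restart_vector(seeds_on(net, seed_ids), net)
            p = float(rng.uniform(0.1, 0.9))
            res = rwr(A, u0, restart_p=p, tol=1e-12)
            assert res.converged
            np.testing.assert_allclose(res.scores, solve_rwr(A, u0, p), atol=1e-8)

    def test_mass_conserved_every_iteration_with_isolated_nodes(self):
        net = make_net([(1, 2), (2, 3)], extra_nodes=[99])
        A = build_transition_matrix(net)
        seeds = seeds_on(net, {1, 99})  # a seed ON the isolated node
        u0 = make_restart_vector(seeds, net)
        for k in range(1, 12):  # truncate the iteration at every prefix
            res = rwr(A, u0, restart_p=0.3, tol=1e-300, max_iter=k)
            assert abs(res.scores.sum() - 1.0) < 1e-9

    def test_every_seed_scores_positive(self):
        rng = np.random.default_rng(5)
        net = random_net(rng, n_max=30)
        seed_ids = {net.nodes[0].entrez, net.nodes[-1].entrez}
        A = build_transition_matrix(net)
        res = rwr(A, make_restart_vector(seeds_on(net, seed_ids), net), restart_p=0.7)
        by = res.by_entrez()
        assert all(by[e] > 0 for e in seed_ids)

    def test_seed_dominance_as_restart_approaches_one(self):
        rng = np.random.default_rng(11)
        net = random_net(rng, n_max=25)
        seed_ids = {net.nodes[i].entrez for i in (0, 1)}
        A = build_transition_matrix(net)
        res = rwr(A, make_restart_vector(seeds_on(net, seed_ids), net), restart_p=0.99)
        by = res.by_entrez()
        worst_seed = min(by[e] for e in seed_ids)
        best_other = max(v for e, v in by.items() if e not in seed_ids)
        assert worst_seed > best_other

    def test_non_convergence_flagged(self, path_abc):
        A = build_transition_matrix(path_abc)
        u0 = make_restart_vector(seeds_on(path_abc, {1}), path_abc)
        res = rwr(A, u0, restart_p=0.5, tol=1e-300, max_iter=3)
        assert not res.converged

    def test_invalid_parameters_rejected(self, path_abc):
        A = build_transition_matrix(path_abc)
        u0 = make_restart_vector(seeds_on(path_abc, {1}), path_abc)
        with pytest.raises(ValueError):
            rwr(A, u0, restart_p=0.0)
        with pytest.raises(ValueError):
            rwr(A, u0, tol=0.0)
        with pytest.raises(ValueError):
            rwr(A, np.ones(3), restart_p=0.5)  # not a distribution


def _scored_fixture():
    """Star around seed 1 plus a pendant path, 11 nodes total."""
    edges = [(1, k) for k in range(2, 10)] + [(9, 10), (10, 11)]
    net = make_net(edges)
    seeds = seeds_on(net, {1})
    A = build_transition_matrix(net)
    scores = rwr(A, make_restart_vector(seeds, net), restart_p=0.7, tol=1e-12)
    return net, seeds, scores


class TestSelectBoosted:
    def test_level_zero_is_seeds_only(self):
        net, seeds, scores = _scored_fixture()
        out = select_boosted(scores, seeds, 0.0, net)
        assert out.entrez == seeds.entrez

    def test_level_one_is_whole_network(self):
        net, seeds, scores = _scored_fixture()
        out = select_boosted(scores, seeds, 1.0, net)
        assert out.entrez == {g.entrez for g in net.nodes}
        assert set(out.classification) == out.entrez - seeds.entrez

    def test_level_picks_top_scoring_nonseeds(self):
        net, seeds, scores = _scored_fixture()
        out = select_boosted(scores, seeds, 0.2, net)  # ceil(0.2 * 10) = 2 non-seeds
        assert len(out) == len(seeds) + 2
        by = scores.by_entrez()
        chosen = out.entrez - seeds.entrez
        best_left_out = max(
            v for e, v in by.items() if e not in out.entrez
        )
        assert min(by[e] for e in chosen) >= best_left_out

    def test_count_arithmetic(self):
        net, seeds, scores = _scored_fixture()
        n_nonseed = net.n_nodes - len(seeds)
        for level in (0.0, 0.01, 0.1, 0.2, 0.5, 1.0):
            out = select_boosted(scores, seeds, level, net)
            assert len(out) == len(seeds) + int(np.ceil(level * n_nonseed))

    def test_monotone_nesting_across_levels(self):
        net, seeds, scores = _scored_fixture()
        prev: set = set()
        for level in (0.0, 0.01, 0.1, 0.2, 1.0):
            current = select_boosted(scores, seeds, level, net).entrez
            assert prev <= current
            prev = current

    def test_tie_break_by_ascending_entrez(self):
        # all leaves of the star tie; ascending entrez decides
        net = make_net([(1, k) for k in (5, 3, 9, 7)])
        seeds = seeds_on(net, {1})
        A = build_transition_matrix(net)
        scores = rwr(A, make_restart_vector(seeds, net), restart_p=0.7)
        out = select_boosted(scores, seeds, 0.5, net)
        assert out.entrez - {1} == {3, 5}

    def test_level_out_of_bounds(self):
        net, seeds, scores = _scored_fixture()
        with pytest.raises(ValueError):
            select_boosted(scores, seeds, 1.5, net)


class TestClassifyConnectivity:
    def test_star_all_direct(self, star6):
        seeds = seeds_on(star6, {1})
        A = build_transition_matrix(star6)
        scores = rwr(A, make_restart_vector(seeds, star6), restart_p=0.7)
        boosted = select_boosted(scores, seeds, 1.0, star6)
        assert classify_connectivity(boosted, seeds, star6) == (5, 0)

    def test_path_direct_then_indirect(self, path_abc):
        seeds = seeds_on(path_abc, {1})
        A = build_transition_matrix(path_abc)
        scores = rwr(A, make_restart_vector(seeds, path_abc), restart_p=0.7)
        boosted = select_boosted(scores, seeds, 1.0, path_abc)
        assert classify_connectivity(boosted, seeds, path_abc) == (1, 1)
        assert boosted.classification == {2: "direct", 3: "indirect"}

    def test_boosted_equals_seeds_gives_zero(self, path_abc):
        seeds = seeds_on(path_abc, {1})
        A = build_transition_matrix(path_abc)
        scores = rwr(A, make_restart_vector(seeds, path_abc), restart_p=0.7)
        boosted = select_boosted(scores, seeds, 0.0, path_abc)
        assert classify_connectivity(boosted, seeds, path_abc) == (0, 0)

    def test_counts_partition_nonseeds(self):
        net, seeds, scores = _scored_fixture()
        boosted = select_boosted(scores, seeds, 0.7, net)
        d, i = classify_connectivity(boosted, seeds, net)
        assert d + i == len(boosted) - len(seeds)
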