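import numpy as np
import pytest
from scipy.stats import chisquare
from hypothesis import given, settings
from hypothesis import strategies as st

import networkx as nx

from netenrich import (
    DegreeSequence,
    Network,
    RandomizationError,
    RankedGeneList,
    null_ensemble,
    randomize_edge_swap,
    randomize_sequential,
    sample_uniform_rejection,
)
from netenrich.randomize import (
    enumerate_labeled_graphs,
    graphical_sequences,
    is_graphical,
    replicate_rng,
)
from .oracles import sequential_exact_distribution


def edge_key(net: Network):
    return frozenset(net.edges())


class TestDegreeSequence:
    def test_orders_nonincreasing(self):
        ds = DegreeSequence([("a", 1), ("b", 3), ("c", 2)])
        assert ds.degrees == [3, 2, 1]

    def test_rejects_nonpositive_degree(self):
        with pytest.raises(ValueError):
            DegreeSequence([("a", 0), ("b", 2)])

    def test_rejects_odd_sum(self):
        with pytest.raises(ValueError):
            DegreeSequence([("a", 1), ("b", 2)])


@pytest.mark.parametrize(
    "seq,expected",
    [((1, 1), True), ((2, 2, 2), True), ((3, 1), False), ((3, 3, 1, 1), False),
     ((2, 2, 1, 1), True)],
)
def test_erdos_gallai(seq, expected):
    assert is_graphical(seq) is expected


class TestSequential:
    def test_single_edge_unique_realization(self):
        net = Network([("A", "B")])
        for seed in range(5):
            assert randomize_sequential(net, seed) == net

    def test_star_unique_realization(self, star):
        for seed in range(5):
            assert randomize_sequential(star, seed) == star

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_degrees_preserved_and_simple(self, seed):
        g = nx.barabasi_albert_graph(80, 2, seed=seed)
        net = Network((f"n{u}", f"n{v}") for u, v in g.edges())
        rnd = randomize_sequential(net, seed)
        assert rnd.degrees == net.degrees
        rnd.check_invariants()

    def test_deterministic_under_seed(self, star):
        g = nx.barabasi_albert_graph(60, 2, seed=3)
        net = Network((f"n{u}", f"n{v}") for u, v in g.edges())
        assert randomize_sequential(net, 11) == randomize_sequential(net, 11)
        # different seeds should (overwhelmingly) differ on a graph this size
        assert randomize_sequential(net, 11) != randomize_sequential(net, 12)

    def test_isolated_nodes_survive(self):
        net = Network([("A", "B"), ("B", "C"), ("A", "C")], nodes=["Z"])
        rnd = randomize_sequential(net, 0)
        assert rnd.has_node("Z") and rnd.degree("Z") == 0

    def test_matches_exact_choice_tree_distribution(self):
        """The sampler's empirical law agrees with the exact recursion over
        the algorithm's choice tree (tie-breaks and weighted draws)."""
        deg = (2, 2, 2, 1, 1)
        exact = sequential_exact_distribution(deg)
        counts = {}
        n_draws = 4000
        rng = np.random.default_rng(2024)
        base = Network(
            [("n0", "n1"), ("n0", "n2"), ("n1", "n2"), ("n3", "n4")]
        )  # any realization of the degree sequence
        for _ in range(n_draws):
            rnd = randomize_sequential(base, rng)
            key = frozenset(
                (int(u[1:]), int(v[1:])) for u, v in rnd.edges()
            )
            counts[key] = counts.get(key, 0) + 1
        graphs = sorted(exact, key=sorted)
        observed = np.array([counts.get(g, 0) for g in graphs])
        expected = np.array([float(exact[g]) * n_draws for g in graphs])
        stat, p = chisquare(observed, expected)
        assert p > 1e-3

    def test_marginal_link_probability_on_matchings(self):
        """On a perfect-matching degree sequence (all degrees 1) the chance
        that two given nodes end up linked is 1/(N-1), the same pairwise
        probability as uniform neighbor choice."""
        net = Network([("a", "b"), ("c", "d"), ("e", "f")])
        n_draws = 6000
        rng = np.random.default_rng(99)
        hits = sum(
            randomize_sequential(net, rng).has_edge("a", "b")
            for _ in range(n_draws)
        )
        p_hat = hits / n_draws
        expect = 1 / 5
        assert abs(p_hat - expect) < 4 * np.sqrt(expect * (1 - expect) / n_draws)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(5, 30))
    def test_degree_preservation_property(self, seed, n):
        g = nx.gnm_random_graph(n, min(2 * n, n * (n - 1) // 2), seed=seed)
        net = Network(
            ((f"n{u}", f"n{v}") for u, v in g.edges()),
            nodes=(f"n{i}" for i in g.nodes()),
        )
        rnd = randomize_sequential(net, seed)
        assert rnd.degrees == net.degrees
        rnd.check_invariants()


class TestEdgeSwap:
    def test_zero_swaps_is_identity(self, triangle):
        assert randomize_edge_swap(triangle, 0, seed=0) == triangle

    def test_path_has_no_valid_swap(self, path3):
        # the single edge pair shares node B: every proposal aborts
        assert randomize_edge_swap(path3, 500, seed=0) == path3

    def test_four_cycle_reaches_all_three_realizations(self):
        cycle = Network([("A", "B"), ("B", "C"), ("C", "D"), ("A", "D")])
        seen = set()
        rng = np.random.default_rng(5)
        current = cycle
        for _ in range(200):
            current = randomize_edge_swap(current, 1, rng)
            seen.add(edge_key(current))
        assert len(seen) == 3  # the 3 labeled 4-cycles on 4 nodes

    @pytest.mark.parametrize("seed", [0, 7])
    def test_degrees_preserved_and_simple(self, seed):
        g = nx.barabasi_albert_graph(60, 2, seed=seed)
        net = Network((f"n{u}", f"n{v}") for u, v in g.edges())
        rnd = randomize_edge_swap(net, 500, seed=seed)
        assert rnd.degrees == net.degrees
        rnd.check_invariants()

    def test_requires_two_edges(self):
        with pytest.raises(ValueError):
            randomize_edge_swap(Network([("A", "B")]), 1, seed=0)


class TestRejectionSampler:
    def test_single_edge(self):
        net = sample_uniform_rejection(DegreeSequence.from_degrees([1, 1]), 0)
        assert net.n_edges == 1

    def test_triangle_unique(self):
        ds = DegreeSequence.from_degrees([2, 2, 2])
        net = sample_uniform_rejection(ds, 0)
        assert net.n_edges == 3
        assert all(d == 2 for d in net.degrees.values())

    def test_paths_drawn_uniformly(self):
        """Degrees (2,2,1,1) realize exactly the 2 labeled paths with the
        degree-2 nodes in the middle; draws split evenly between them."""
        ds = DegreeSequence.from_degrees([2, 2, 1, 1])
        rng = np.random.default_rng(0)
        counts = {}
        n_draws = 2000
        for _ in range(n_draws):
            net = sample_uniform_rejection(ds, rng)
            counts[edge_key(net)] = counts.get(edge_key(net), 0) + 1
        assert len(counts) == 2
        stat, p = chisquare(list(counts.values()))
        assert p > 1e-3

    def test_max_tries_exhausted(self):
        ds = DegreeSequence.from_degrees([2, 2, 1, 1])
        with pytest.raises(RandomizationError):
            sample_uniform_rejection(ds, 0, max_tries=1)


class TestNullEnsemble:
    def test_absent_fgs_gives_zero_curves(self, triangle, abc_ranked):
        ens = null_ensemble(triangle, abc_ranked, {"Z"}, 3, B=5, seed=0)
        assert not ens.curves.any()

    def test_single_replicate_mean_is_the_curve(self, triangle, abc_ranked):
        ens = null_ensemble(triangle, abc_ranked, {"C"}, 3, B=1, seed=0)
        assert np.array_equal(ens.mean_curve(), ens.curves[0])

    def test_curves_nondecreasing(self):
        g = nx.barabasi_albert_graph(40, 2, seed=1)
        net = Network((f"n{u}", f"n{v}") for u, v in g.edges())
        ags = RankedGeneList("a", [f"n{i}" for i in range(10)])
        ens = null_ensemble(net, ags, {f"n{i}" for i in range(20, 30)}, 10,
                            B=10, seed=3)
        assert (np.diff(ens.curves, axis=1) >= 0).all()

    def test_fixed_k_matches_last_curve_point(self):
        g = nx.barabasi_albert_graph(40, 2, seed=2)
        net = Network((f"n{u}", f"n{v}") for u, v in g.edges())
        ags = RankedGeneList("a", [f"n{i}" for i in range(10)])
        F = {f"n{i}" for i in range(15, 30)}
        full = null_ensemble(net, ags, F, 10, B=8, seed=5)
        fixed = null_ensemble(net, ags, F, 10, B=8, seed=5, fixed_k=True)
        assert np.array_equal(fixed.curves, full.curves[:, -1])

    def test_replicate_seeds_independent_of_ensemble_size(self):
        g = nx.barabasi_albert_graph(40, 2, seed=4)
        net = Network((f"n{u}", f"n{v}") for u, v in g.edges())
        ags = RankedGeneList("a", [f"n{i}" for i in range(8)])
        F = {f"n{i}" for i in range(20, 30)}
        small = null_ensemble(net, ags, F, 8, B=3, seed=7)
        large = null_ensemble(net, ags, F, 8, B=6, seed=7)
        assert np.array_equal(small.curves, large.curves[:3])


def test_enumeration_counts_match_rejection_support():
    """Exhaustive enumeration and the rejection sampler agree on which
    labeled graphs realize a degree sequence."""
    ds = DegreeSequence.from_degrees([2, 2, 2, 1, 1])
    graphs = enumerate_labeled_graphs([2, 2, 2, 1, 1])
    assert len(graphs) == 7
    rng = np.random.default_rng(1)
    seen = set()
    for _ in range(300):
        net = sample_uniform_rejection(ds, rng)
        seen.add(
            frozenset((int(u[1:]), int(v[1:])) for u, v in net.edges())
        )
    assert seen <= set(graphs)


def test_graphical_sequences_enumeration():
    seqs = graphical_sequences(4)
    assert (1, 1) in seqs
    assert (2, 2, 2) in seqs
    assert (3, 3, 3, 3) in seqs  # K4
    assert all(is_graphical(s) for s in seqs)
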