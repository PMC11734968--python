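"""Clique percolation, intensity thresholds, entropy, null band, selection."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgmnet import (
    CommunitySolution,
    clique_intensity,
    partition_entropy,
    percolate,
    permute_entropy_null,
    select_solution,
    threshold_grid,
)
from mgmnet.communities import ThresholdGrid, EntropyNull
from mgmnet.mgm import WeightedNetwork


def _network(p, edges, nodes=None):
    """Build a WeightedNetwork from an {(i, j): magnitude} dict."""
    nodes = tuple(nodes or (f"n{i}" for i in range(p)))
    mag = np.zeros((p, p))
    for (i, j), w in edges.items():
        mag[i, j] = mag[j, i] = w
    return WeightedNetwork(
        nodes=nodes,
        magnitude=mag,
        sign=np.zeros((p, p)),
        involves_categorical=np.zeros((p, p), dtype=bool),
    )


def _random_network(rng, p, density=0.4):
    edges = {}
    for i, j in combinations(range(p), 2):
        if rng.random() < density:
            edges[(i, j)] = float(rng.uniform(0.05, 0.5))
    return _network(p, edges)


def brute_force_percolate(network, k, I):
    """Oracle: enumerate all k-subsets, test cliquehood + intensity, then
    join cliques sharing k−1 nodes by breadth-first search."""
    p = network.p
    mag = network.magnitude
    cliques = []
    for sub in combinations(range(p), k):
        mags = [mag[a, b] for a, b in combinations(sub, 2)]
        if all(m > 0 for m in mags):
            intensity = np.prod(mags) ** (1.0 / len(mags))
            if intensity >= I:
                cliques.append(frozenset(sub))
    unvisited = set(range(len(cliques)))
    communities = []
    while unvisited:
        stack = [unvisited.pop()]
        group = set()
        while stack:
            a = stack.pop()
            group |= cliques[a]
            joined = [
                b for b in unvisited if len(cliques[a] & cliques[b]) == k - 1
            ]
            for b in joined:
                unvisited.remove(b)
            stack.extend(joined)
        communities.append(frozenset(network.nodes[i] for i in group))
    return set(communities)


class TestCliqueIntensity:
    def test_closed_form_cube_root(self):
        assert clique_intensity([0.1, 0.2, 0.4]) == pytest.approx(0.2)

    def test_equal_magnitudes_identity(self):
        assert clique_intensity([0.3] * 6) == pytest.approx(0.3)  # k = 4

    def test_zero_magnitude_rejected(self):
        with pytest.raises(ValueError, match="not a clique"):
            clique_intensity([0.1, 0.0, 0.4])

    def test_invalid_length_rejected(self):
        with pytest.raises(ValueError, match="k-clique"):
            clique_intensity([0.1, 0.2])

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.01, max_value=1.0), min_size=3, max_size=3
        )
    )
    def test_never_exceeds_arithmetic_mean(self, mags):
        assert clique_intensity(mags) <= np.mean(mags) + 1e-12


class TestPercolate:
    def test_two_triangles_sharing_one_node(self):
        # triangles {0,1,2} and {2,3,4} share only node 2; node 5 dangling
        edges = {
            (0, 1): 0.3, (0, 2): 0.3, (1, 2): 0.3,
            (2, 3): 0.3, (2, 4): 0.3, (3, 4): 0.3,
            (4, 5): 0.01,
        }
        net = _network(6, edges)
        sol = percolate(net, k=3, I=0.2)
        assert set(sol.communities) == {
            frozenset({"n0", "n1", "n2"}),
            frozenset({"n2", "n3", "n4"}),
        }
        assert sol.isolated == {"n5"}
        assert sol.ratio == pytest.approx(1.0)

    def test_complete_graph_single_community(self):
        edges = {(i, j): 0.5 for i, j in combinations(range(4), 2)}
        sol = percolate(_network(4, edges), k=3, I=0.4)
        assert sol.communities == (frozenset({"n0", "n1", "n2", "n3"}),)

    def test_threshold_above_max_intensity_empties(self):
        edges = {(i, j): 0.5 for i, j in combinations(range(4), 2)}
        sol = percolate(_network(4, edges), k=3, I=0.6)
        assert sol.n_communities == 0
        assert len(sol.isolated) == 4
        assert np.isnan(sol.ratio)

    def test_k_below_three_rejected(self):
        with pytest.raises(ValueError, match="k must be"):
            percolate(_network(3, {(0, 1): 0.2}), k=2, I=0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        net = _random_network(rng, p=int(rng.integers(5, 11)))
        for k in (3, 4):
            for I in (0.0, 0.15, 0.3):
                sol = percolate(net, k, I)
                assert set(sol.communities) == brute_force_percolate(net, k, I)

    @pytest.mark.parametrize("seed", [3, 17])
    def test_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        net = _random_network(rng, p=9)
        lo = percolate(net, 3, 0.1)
        hi = percolate(net, 3, 0.25)
        cover_lo = set().union(*lo.communities) if lo.communities else set()
        for comm in hi.communities:
            # every high-threshold community sits inside one low-threshold one
            assert any(comm <= low for low in lo.communities)
        assert (set().union(*hi.communities) if hi.communities else set()) <= cover_lo


def _manual_solution(communities, isolated, p_total, k=3, I=0.1):
    sol = CommunitySolution(
        k=k,
        I=I,
        communities=tuple(frozenset(c) for c in communities),
        isolated=frozenset(isolated),
        ratio=float("nan"),
        entropy_bits=0.0,
    )
    h = partition_entropy(sol, p_total)
    return CommunitySolution(
        k=k, I=I, communities=sol.communities, isolated=sol.isolated,
        ratio=sol.ratio, entropy_bits=h,
    )


class TestPartitionEntropy:
    def test_equal_bipartition_one_bit(self):
        comms = [[f"a{i}" for i in range(15)], [f"b{i}" for i in range(15)]]
        assert _manual_solution(comms, [], 30).entropy_bits == pytest.approx(1.0)

    def test_shared_node_split_equally(self):
        sol = _manual_solution([list("ABC"), list("CDE")], [], 5)
        assert sol.entropy_bits == pytest.approx(1.0)

    def test_isolated_pseudo_community(self):
        sol = _manual_solution([list("abc")], ["d"], 4)
        expected = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
        assert sol.entropy_bits == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.8113, abs=1e-4)

    def test_equal_sizes_reach_log2_of_count(self):
        comms = [[f"c{i}_{j}" for j in range(5)] for i in range(4)]
        assert _manual_solution(comms, [], 20).entropy_bits == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_effective_sizes_conserved(self, seed):
        rng = np.random.default_rng(seed)
        net = _random_network(rng, p=10)
        sol = percolate(net, 3, 0.12)
        counts = sol.membership_counts()
        eff = sum(
            sum(1.0 / counts[n] for n in comm) for comm in sol.communities
        )
        assert eff + len(sol.isolated) == pytest.approx(net.p)


class TestThresholdGrid:
    def test_rows_ordered_and_complete(self, rng):
        net = _random_network(rng, p=8)
        grid = threshold_grid(net, k_values=(3, 4), I_step=0.1)
        frame = grid.frame
        for k in (3, 4):
            I_vals = frame[frame["k"] == k]["I"].to_numpy()
            assert np.all(np.diff(I_vals) > 0)
        assert frame["I"].max() <= net.magnitude.max()

    def test_empty_network_all_rows_empty(self):
        net = _network(4, {})
        grid = threshold_grid(net)
        assert (grid.frame["n_communities"] == 0).all()


class TestEntropyNull:
    def test_equal_weight_network_within_band(self):
        # every edge identical -> shuffling magnitudes is a graph-law symmetry
        rng = np.random.default_rng(5)
        edges = {
            (i, j): 0.3
            for i, j in combinations(range(9), 2)
            if rng.random() < 0.35
        }
        net = _network(9, edges)
        null = permute_entropy_null(net, k_values=(3,), I_step=0.05, n_perm=60, seed=6)
        grid = threshold_grid(net, k_values=(3,), I_step=0.05)
        observed_max = grid.frame["entropy_bits"].max()
        assert not null.exceeds(3, observed_max)

    def test_determinism(self):
        rng = np.random.default_rng(8)
        net = _random_network(rng, p=8)
        a = permute_entropy_null(net, n_perm=10, seed=3)
        b = permute_entropy_null(net, n_perm=10, seed=3)
        assert a.upper == b.upper


def _grid_from_solutions(solutions, p_total):
    rows = [
        {
            "k": sol.k,
            "I": sol.I,
            "n_communities": sol.n_communities,
            "n_isolated": len(sol.isolated),
            "ratio": sol.ratio,
            "entropy_bits": sol.entropy_bits,
        }
        for sol in solutions
    ]
    return ThresholdGrid(
        frame=pd.DataFrame(rows),
        solutions={(s.k, s.I): s for s in solutions},
        p_total=p_total,
    )


def _sized_solution(sizes, isolated_count, k, I, start=0):
    comms = []
    node = start
    for s in sizes:
        comms.append([f"x{node + i}" for i in range(s)])
        node += s
    isolated = [f"iso{i}" for i in range(isolated_count)]
    p_total = sum(sizes) + isolated_count
    sol = _manual_solution(comms, isolated, p_total, k=k, I=I)
    return CommunitySolution(
        k=k, I=I, communities=sol.communities, isolated=sol.isolated,
        ratio=_ratio(sizes), entropy_bits=sol.entropy_bits,
    )


def _ratio(sizes):
    ordered = sorted(sizes, reverse=True)
    if not ordered:
        return float("nan")
    if len(ordered) == 1:
        return float("inf")
    return ordered[0] / ordered[1]


class TestSelectSolution:
    null = EntropyNull(n_perm=100, upper={3: 10.0, 4: 10.0}, maxima={})

    def test_template_sizes_ratio_crosses_two(self):
        sol = _sized_solution([12, 6, 6, 4, 4], 0, k=3, I=0.11)
        assert sol.ratio == pytest.approx(2.0)
        grid = _grid_from_solutions([sol], p_total=32)
        result = select_solution(grid, self.null)
        assert result.ratio_candidate is sol

    def test_fewer_isolated_candidate_wins(self):
        # entropy optimum isolates 13 nodes, ratio optimum only 10
        ratio_sol = _sized_solution([8, 4, 4, 4], 10, k=3, I=0.11)
        entropy_sol = _sized_solution([6, 4, 4, 3], 13, k=4, I=0.08)
        entropy_sol = CommunitySolution(
            k=4, I=0.08, communities=entropy_sol.communities,
            isolated=entropy_sol.isolated, ratio=entropy_sol.ratio,
            entropy_bits=entropy_sol.entropy_bits + 1.0,  # force entropy optimum
        )
        grid = _grid_from_solutions([ratio_sol, entropy_sol], p_total=30)
        result = select_solution(grid, self.null)
        assert result.chosen is ratio_sol
        assert "isolated" in result.rationale

    def test_single_community_rejected_as_giant(self):
        giant = _sized_solution([20], 5, k=3, I=0.2)
        multi = _sized_solution([5, 4, 4], 12, k=3, I=0.3)
        assert np.isinf(giant.ratio)
        grid = _grid_from_solutions([giant, multi], p_total=25)
        result = select_solution(grid, self.null)
        assert result.chosen is multi

    def test_no_candidate_raises_with_advice(self):
        empty = _sized_solution([], 10, k=3, I=0.0)
        grid = _grid_from_solutions([empty], p_total=10)
        with pytest.raises(ValueError, match="finer I grid"):
            select_solution(grid, self.null)
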