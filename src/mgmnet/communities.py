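"""Overlapping community detection by weighted clique percolation.

A *k-clique* is a fully connected subgraph on k nodes; its *intensity* is
the geometric mean of its edge magnitudes.  Communities are the node unions
of connected components of the clique adjacency graph (two k-cliques
adjacent when they share k−1 nodes), restricted to cliques whose intensity
reaches the threshold I — so nodes may belong to several communities and
some belong to none (isolated).

Two indicators guide the (k, I) choice: the *ratio* of the largest to the
second-largest community (the value 2 marks the emergence of a giant
component) and the Shannon *entropy* of the partition (isolated nodes
pooled as one pseudo-community, shared nodes split equally among their
communities), compared against a permutation null that shuffles the edge
magnitudes over node pairs.  A deterministic four-step rule codifies the
final visual-inspection choice between the two candidate solutions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .mgm import WeightedNetwork

__all__ = [
    "CommunitySolution",
    "ThresholdGrid",
    "EntropyNull",
    "SelectionResult",
    "clique_intensity",
    "percolate",
    "threshold_grid",
    "partition_entropy",
    "permute_entropy_null",
    "select_solution",
]


def clique_intensity(edge_magnitudes: Sequence[float]) -> float:
    """Geometric mean of a clique's edge magnitudes.

    The sequence length must equal k·(k−1)/2 for some clique size k ≥ 3; a
    zero magnitude means the subgraph is not a clique and is an error.
    """
    mags = np.asarray(edge_magnitudes, dtype=float)
    m = mags.size
    k = (1.0 + np.sqrt(1.0 + 8.0 * m)) / 2.0
    if m < 3 or abs(k - round(k)) > 1e-9 or round(k) < 3:
        raise ValueError(f"{m} magnitudes do not form a k-clique edge set (k >= 3)")
    if np.any(mags <= 0):
        raise ValueError("zero or negative magnitude: not a clique")
    return float(np.exp(np.mean(np.log(mags))))


@dataclass(frozen=True)
class CommunitySolution:
    """Communities (overlap allowed) found at one (k, I) pair."""

    k: int
    I: float
    communities: tuple[frozenset[str], ...]
    isolated: frozenset[str]
    ratio: float            # inf with one community, nan with none
    entropy_bits: float

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.communities)

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    def membership_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for comm in self.communities:
            for node in comm:
                counts[node] = counts.get(node, 0) + 1
        return counts

    def to_text(self) -> str:
        lines = [f"k: {self.k}", f"I: {self.I:.6g}"]
        for idx, comm in enumerate(self.communities):
            lines.append(f"community {idx + 1}: {', '.join(sorted(comm))}")
        lines.append(f"isolated: {', '.join(sorted(self.isolated)) or '(none)'}")
        ratio = "inf" if np.isinf(self.ratio) else (
            "nan" if np.isnan(self.ratio) else f"{self.ratio:.6g}"
        )
        lines.append(f"ratio: {ratio}")
        lines.append(f"entropy_bits: {self.entropy_bits:.6g}")
        return "\n".join(lines) + "\n"


def _sizes_ratio(sizes: Sequence[int]) -> float:
    if len(sizes) == 0:
        return float("nan")
    if len(sizes) == 1:
        return float("inf")
    ordered = sorted(sizes, reverse=True)
    return ordered[0] / ordered[1]


def partition_entropy(solution: CommunitySolution, p_total: int) -> float:
    """Shannon entropy (bits) of the effective community-size distribution.

    Each shared node contributes 1/(number of its communities) to each of
    them; isolated nodes are pooled as one pseudo-community of their full
    count.  H = −Σ_c (size_c/p_total)·log2(size_c/p_total) over positive
    sizes.
    """
    counts = solution.membership_counts()
    member_total = len(counts) + len(solution.isolated)
    if member_total > p_total:
        raise ValueError("solution references more nodes than p_total")
    sizes = [
        sum(1.0 / counts[node] for node in comm) for comm in solution.communities
    ]
    if solution.isolated:
        sizes.append(float(len(solution.isolated)))
    h = 0.0
    for s in sizes:
        if s > 0:
            frac = s / p_total
            h -= frac * np.log2(frac)
    return float(h)


# ---------------------------------------------------------------------------
# percolation


def _k_cliques(
    graph: nx.Graph, k: int, magnitude: Mapping[tuple[str, str], float]
) -> list[tuple[frozenset[str], float]]:
    """All k-cliques with their intensities (via k-subsets of maximal cliques)."""
    seen: dict[frozenset[str], float] = {}
    for maximal in nx.find_cliques(graph):
        if len(maximal) < k:
            continue
        for sub in combinations(sorted(maximal), k):
            key = frozenset(sub)
            if key in seen:
                continue
            mags = [graph[u][v]["magnitude"] for u, v in combinations(sub, 2)]
            seen[key] = float(np.exp(np.mean(np.log(mags))))
    return list(seen.items())


def _percolate_cliques(
    cliques: Sequence[frozenset[str]], k: int
) -> list[set[str]]:
    """Union the node sets of clique-adjacency components (share k−1 nodes)."""
    parent = list(range(len(cliques)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    by_subset: dict[frozenset[str], int] = {}
    for idx, clique in enumerate(cliques):
        for drop in clique:
            sub = clique - {drop}
            if sub in by_subset:
                union(by_subset[sub], idx)
            else:
                by_subset[sub] = idx
    groups: dict[int, set[str]] = {}
    for idx, clique in enumerate(cliques):
        groups.setdefault(find(idx), set()).update(clique)
    return list(groups.values())


def _network_graph(network: WeightedNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    p = network.p
    for i in range(p):
        for j in range(i + 1, p):
            if network.magnitude[i, j] > 0:
                g.add_edge(
                    network.nodes[i],
                    network.nodes[j],
                    magnitude=float(network.magnitude[i, j]),
                )
    return g


def _solution_from_cliques(
    network_nodes: Sequence[str],
    cliques: Sequence[tuple[frozenset[str], float]],
    k: int,
    I: float,
) -> CommunitySolution:
    admitted = [c for c, intensity in cliques if intensity >= I]
    comms = _percolate_cliques(admitted, k)
    comms_sorted = tuple(
        frozenset(c)
        for c in sorted(comms, key=lambda c: (-len(c), tuple(sorted(c))))
    )
    covered = set().union(*comms_sorted) if comms_sorted else set()
    isolated = frozenset(set(network_nodes) - covered)
    solution = CommunitySolution(
        k=k,
        I=float(I),
        communities=comms_sorted,
        isolated=isolated,
        ratio=_sizes_ratio([len(c) for c in comms_sorted]),
        entropy_bits=0.0,
    )
    entropy = partition_entropy(solution, p_total=len(network_nodes))
    return CommunitySolution(
        k=solution.k,
        I=solution.I,
        communities=solution.communities,
        isolated=solution.isolated,
        ratio=solution.ratio,
        entropy_bits=entropy,
    )


def percolate(network: WeightedNetwork, k: int, I: float) -> CommunitySolution:
    """Clique percolation of the unsigned magnitude graph at one (k, I)."""
    if k < 3:
        raise ValueError("k must be >= 3")
    graph = _network_graph(network)
    cliques = _k_cliques(graph, k, {})
    return _solution_from_cliques(network.nodes, cliques, k, I)


# ---------------------------------------------------------------------------
# threshold optimisation


@dataclass(frozen=True)
class ThresholdGrid:
    """Percolation summary over every (k, I) combination on the grid."""

    frame: pd.DataFrame
    solutions: Mapping[tuple[int, float], CommunitySolution]
    p_total: int


def _intensity_grid(max_magnitude: float, I_step: float) -> np.ndarray:
    if max_magnitude <= 0:
        return np.array([0.0])
    n_steps = int(np.floor(max_magnitude / I_step + 1e-9))
    return np.arange(n_steps + 1) * I_step


def threshold_grid(
    network: WeightedNetwork,
    k_values: Sequence[int] = (3, 4),
    I_step: float = 0.005,
) -> ThresholdGrid:
    """Evaluate percolation at every k in ``k_values`` and I ∈ {0, step, …}."""
    if any(k < 3 for k in k_values):
        raise ValueError("all k values must be >= 3")
    if I_step <= 0:
        raise ValueError("I_step must be positive")
    graph = _network_graph(network)
    max_mag = float(network.magnitude.max()) if network.p else 0.0
    I_values = _intensity_grid(max_mag, I_step)
    rows = []
    solutions: dict[tuple[int, float], CommunitySolution] = {}
    for k in sorted(k_values):
        cliques = _k_cliques(graph, k, {})
        for I in I_values:
            sol = _solution_from_cliques(network.nodes, cliques, k, float(I))
            solutions[(k, float(I))] = sol
            rows.append(
                {
                    "k": k,
                    "I": float(I),
                    "n_communities": sol.n_communities,
                    "n_isolated": len(sol.isolated),
                    "ratio": sol.ratio,
                    "entropy_bits": sol.entropy_bits,
                }
            )
    frame = pd.DataFrame(
        rows, columns=["k", "I", "n_communities", "n_isolated", "ratio", "entropy_bits"]
    )
    return ThresholdGrid(frame=frame, solutions=solutions, p_total=network.p)


@dataclass(frozen=True)
class EntropyNull:
    """Permutation null of the maximal partition entropy, per clique size k."""

    n_perm: int
    upper: Mapping[int, float]          # 97.5th percentile of per-perm maxima
    maxima: Mapping[int, np.ndarray]

    def exceeds(self, k: int, entropy_bits: float) -> bool:
        """Is an observed entropy higher than expected by chance at this k?"""
        return entropy_bits > self.upper[k]


def permute_entropy_null(
    network: WeightedNetwork,
    k_values: Sequence[int] = (3, 4),
    I_step: float = 0.005,
    n_perm: int = 100,
    seed: int = 0,
) -> EntropyNull:
    """Null distribution of the maximal entropy under edge-magnitude shuffling.

    Each permutation keeps the multiset of edge magnitudes and the edge
    count but reassigns them to a uniformly random set of node pairs (degree
    structure is not preserved).  For each permutation and k the maximal
    entropy over the I grid is recorded; the upper bound of the 95%
    confidence band is the 97.5th percentile of those maxima.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    p = network.p
    iu = np.triu_indices(p, k=1)
    weights = network.magnitude[iu]
    nonzero = weights[weights > 0]
    n_pairs = len(weights)
    maxima = {k: np.zeros(n_perm) for k in k_values}
    for b in range(n_perm):
        mag = np.zeros((p, p))
        chosen = rng.choice(n_pairs, size=len(nonzero), replace=False)
        shuffled = rng.permutation(nonzero)
        mag[iu[0][chosen], iu[1][chosen]] = shuffled
        mag = mag + mag.T
        permuted = WeightedNetwork(
            nodes=network.nodes,
            magnitude=mag,
            sign=np.zeros((p, p)),
            involves_categorical=np.zeros((p, p), dtype=bool),
        )
        graph = _network_graph(permuted)
        I_values = _intensity_grid(float(mag.max()), I_step)
        for k in k_values:
            cliques = _k_cliques(graph, k, {})
            best = 0.0
            for I in I_values:
                sol = _solution_from_cliques(permuted.nodes, cliques, k, float(I))
                best = max(best, sol.entropy_bits)
            maxima[k][b] = best
    upper = {k: float(np.percentile(v, 97.5)) for k, v in maxima.items()}
    return EntropyNull(n_perm=n_perm, upper=upper, maxima=maxima)


# ---------------------------------------------------------------------------
# solution selection


@dataclass(frozen=True)
class SelectionResult:
    ratio_candidate: CommunitySolution | None
    entropy_candidate: CommunitySolution | None
    chosen: CommunitySolution
    rationale: str


def _passes_giant_rule(sol: CommunitySolution, p_total: int) -> bool:
    if not sol.communities:
        return False
    non_isolated = p_total - len(sol.isolated)
    return max(sol.sizes) <= 0.5 * non_isolated


def select_solution(
    grid: ThresholdGrid, null: EntropyNull, p_total: int | None = None
) -> SelectionResult:
    """Pick the final community solution from the two indicator candidates.

    The *ratio candidate* is, for the smallest k that has one, the largest I
    at which the largest/second-largest size ratio is ≥ 2 (at least two
    communities required — the crossing is undefined for a lone community).
    The *entropy candidate* maximizes the partition entropy over the grid
    and is flagged against the permutation null.  The final choice applies,
    in order: (1) no giant component (largest community ≤ 50% of
    non-isolated nodes), (2) fewer isolated nodes, (3) more communities,
    (4) higher entropy.
    """
    p_total = grid.p_total if p_total is None else p_total
    frame = grid.frame
    lines: list[str] = []

    ratio_candidate = None
    for k in sorted(frame["k"].unique()):
        sub = frame[
            (frame["k"] == k)
            & (frame["n_communities"] >= 2)
            & np.isfinite(frame["ratio"])
            & (frame["ratio"] >= 2.0)
        ]
        if len(sub):
            I = float(sub["I"].max())
            ratio_candidate = grid.solutions[(int(k), I)]
            lines.append(
                f"ratio rule: k={k}, largest I with ratio >= 2 is {I:.6g} "
                f"(ratio {ratio_candidate.ratio:.6g})"
            )
            break
    if ratio_candidate is None:
        lines.append("ratio rule: no (k, I) with >= 2 communities and ratio >= 2")

    entropy_candidate = None
    with_comm = frame[frame["n_communities"] >= 1]
    if len(with_comm):
        best = with_comm.loc[with_comm["entropy_bits"].idxmax()]
        entropy_candidate = grid.solutions[(int(best["k"]), float(best["I"]))]
        above = null.exceeds(entropy_candidate.k, entropy_candidate.entropy_bits)
        lines.append(
            f"entropy rule: max entropy {entropy_candidate.entropy_bits:.4g} bits at "
            f"k={entropy_candidate.k}, I={entropy_candidate.I:.6g}; "
            f"{'exceeds' if above else 'within'} the {null.n_perm}-permutation "
            f"95% bound ({null.upper[entropy_candidate.k]:.4g} bits)"
        )
    else:
        lines.append("entropy rule: no (k, I) yields any community")

    candidates = [
        ("ratio", ratio_candidate),
        ("entropy", entropy_candidate),
    ]
    candidates = [(name, c) for name, c in candidates if c is not None]
    if not candidates:
        raise ValueError(
            "no candidate solution on the grid; use a finer I grid (smaller I_step)"
        )

    passing = [
        (name, c) for name, c in candidates if _passes_giant_rule(c, p_total)
    ]
    for name, c in candidates:
        ok = _passes_giant_rule(c, p_total)
        lines.append(
            f"giant-component check ({name}): largest {max(c.sizes) if c.sizes else 0} "
            f"of {p_total - len(c.isolated)} non-isolated -> "
            f"{'pass' if ok else 'fail'}"
        )
    pool = passing if passing else candidates
    if len(pool) == 1:
        name, chosen = pool[0]
        lines.append(f"chosen: {name} candidate")
    else:
        (n1, c1), (n2, c2) = pool
        key1 = (len(c1.isolated), -c1.n_communities, -c1.entropy_bits)
        key2 = (len(c2.isolated), -c2.n_communities, -c2.entropy_bits)
        lines.append(
            f"comparison: isolated {len(c1.isolated)} vs {len(c2.isolated)}; "
            f"communities {c1.n_communities} vs {c2.n_communities}; "
            f"entropy {c1.entropy_bits:.4g} vs {c2.entropy_bits:.4g}"
        )
        if key1 <= key2:
            name, chosen = n1, c1
        else:
            name, chosen = n2, c2
        lines.append(f"chosen: {name} candidate")
    return SelectionResult(
        ratio_candidate=ratio_candidate,
        entropy_candidate=entropy_candidate,
        chosen=chosen,
        rationale="\n".join(lines) + "\n",
    )
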