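"""Per-(node, community) stabilizing/communicating indices and subscale models.

For a node v in community c, the *stabilizing index* sums the magnitudes of
v's edges to co-members of c; the *communicating index* sums its edges to
members of other communities.  Edges to community-less (isolated) nodes
count toward neither; their omitted strength share is logged.  A node in
several communities gets one row per community.

Subscale re-analysis re-estimates a community-restricted network after
replacing multi-dimensional constructs by their subscale columns, with a
display filter that suppresses (but does not delete) edges at or below a
threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .communities import CommunitySolution
from .data_io import MixedDataset
from .mgm import EstimatorConfig, NodewiseFit, WeightedNetwork, estimate_mgm

__all__ = ["LocalIndexTable", "local_indices", "subscale_network"]

log = logging.getLogger(__name__)

#: Tie window for flagging a third top-ranked node.
TOP_TIE_WINDOW = 0.05


@dataclass(frozen=True)
class LocalIndexTable:
    """Rows of (node, community, stabilizing, communicating) with top markers."""

    frame: pd.DataFrame

    def top_stabilizers(self, community: int) -> tuple[str, ...]:
        sub = self.frame[
            (self.frame["community"] == community) & self.frame["top_stabilizer"]
        ]
        return tuple(sub["node"])

    def top_communicators(self, community: int) -> tuple[str, ...]:
        sub = self.frame[
            (self.frame["community"] == community) & self.frame["top_communicator"]
        ]
        return tuple(sub["node"])


def _top_flags(values: pd.Series) -> pd.Series:
    """Flag the top two entries, or three when the 3rd is within the tie window."""
    order = values.sort_values(ascending=False)
    flagged = list(order.index[:2])
    if len(order) >= 3 and order.iloc[1] - order.iloc[2] <= TOP_TIE_WINDOW:
        flagged.append(order.index[2])
    return pd.Series(values.index.isin(flagged), index=values.index)


def local_indices(
    network: WeightedNetwork,
    solution: CommunitySolution,
    signed: bool = False,
) -> LocalIndexTable:
    """Stabilizing and communicating sums for every (node, community) pair.

    Magnitudes are summed in absolute value by default (``signed=True``
    applies the sign layer where defined).
    """
    unknown = set().union(*solution.communities, solution.isolated) - set(
        network.nodes
    ) if solution.communities or solution.isolated else set()
    if unknown:
        raise ValueError(f"solution references nodes absent from network: {unknown}")
    idx = {name: i for i, name in enumerate(network.nodes)}
    community_members = [set(c) for c in solution.communities]
    in_any = set().union(*community_members) if community_members else set()
    weight = network.magnitude.copy()
    if signed:
        weight = weight * np.where(network.sign != 0, network.sign, 1)

    rows = []
    omitted = 0.0
    total_strength = float(np.abs(network.magnitude).sum()) / 2.0
    for cid, members in enumerate(community_members):
        for node in sorted(members):
            vi = idx[node]
            stab = sum(weight[vi, idx[u]] for u in members if u != node)
            comm = sum(
                weight[vi, idx[u]]
                for u in in_any
                if u not in members and u != node
            )
            omitted += sum(
                network.magnitude[vi, idx[u]] for u in network.nodes
                if u not in in_any and u != node
            )
            rows.append(
                {
                    "node": node,
                    "community": cid,
                    "stabilizing": float(stab),
                    "communicating": float(comm),
                }
            )
    frame = pd.DataFrame(
        rows, columns=["node", "community", "stabilizing", "communicating"]
    )
    if len(frame):
        frame["top_stabilizer"] = frame.groupby("community")["stabilizing"].transform(
            _top_flags
        )
        frame["top_communicator"] = frame.groupby("community")[
            "communicating"
        ].transform(_top_flags)
    else:
        frame["top_stabilizer"] = pd.Series(dtype=bool)
        frame["top_communicator"] = pd.Series(dtype=bool)
    if total_strength > 0 and omitted > 0:
        log.info(
            "edges to isolated nodes omitted from indices: %.3g (%.1f%% of total strength)",
            omitted,
            100.0 * omitted / (2.0 * total_strength),
        )
    return LocalIndexTable(frame=frame)


def subscale_network(
    dataset: MixedDataset,
    community_nodes: set[str] | frozenset[str],
    subscale_map: dict[str, list[str]] | None = None,
    display_threshold: float = 0.05,
    config: EstimatorConfig | None = None,
) -> tuple[WeightedNetwork, WeightedNetwork, dict[str, NodewiseFit]]:
    """Re-estimate one community's network at subscale resolution.

    Constructs present in ``subscale_map`` are replaced by their subscale
    columns (which must exist in the dataset); the mixed graphical model is
    then re-estimated on that node set alone.  Returns the full network, a
    display view with edges of magnitude ≤ ``display_threshold`` suppressed,
    and the nodewise fits.
    """
    if not community_nodes:
        raise ValueError("empty community node set")
    subscale_map = subscale_map or {}
    wanted: set[str] = set()
    for node in community_nodes:
        for col in subscale_map.get(node, [node]):
            if col not in dataset.names and node in subscale_map:
                raise ValueError(f"subscale column {col!r} not in dataset")
            wanted.add(col)
    columns = [n for n in dataset.names if n in wanted]
    missing = {
        n for n in community_nodes if n not in dataset.names and n not in subscale_map
    }
    if missing:
        raise ValueError(f"community nodes absent from dataset: {sorted(missing)}")
    sub_specs = tuple(s for s in dataset.specs if s.name in columns)
    sub = MixedDataset(
        values=dataset.values[[s.name for s in sub_specs]].copy(), specs=sub_specs
    )
    full, fits = estimate_mgm(sub, config)
    return full, full.thresholded(display_threshold), fits
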