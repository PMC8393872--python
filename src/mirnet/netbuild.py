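"""Score-filtered protein-protein interaction subnetworks and hub ranking.

Interaction input is a STRING-style edge table with an integer combined
confidence score in [0, 1000]; edges below the conventional
medium-confidence threshold of 400 are dropped.  Networks are the subgraphs
induced by gene lists (edges kept only when both endpoints are in the list;
list members absent from the interactome stay as degree-0 nodes so mean
connectivity has a well-defined denominator), and hubs are the
highest-degree nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "NetworkStats",
    "read_interactions",
    "clean_interactions",
    "induced_subnetwork",
    "network_stats",
    "rank_hubs",
    "compare_networks",
]

_SCORE_ALIASES = ("combined_score", "combine_score", "score")


@dataclass(frozen=True)
class NetworkStats:
    nodes: int
    edges: int
    mean_neighbors: float  # 2E / V


def read_interactions(path, score_min: int = 400) -> pd.DataFrame:
    """Read a whitespace/tab-separated scored edge table and clean it.

    The first two columns are taken as the interactors; the score column may
    be named combined_score, combine_score (the STRING dump dialect) or
    score.  Edges with score < ``score_min`` are dropped (closed threshold),
    self-loops removed, duplicate undirected pairs collapsed keeping the
    maximum score.
    """
    df = pd.read_csv(path, sep=r"\s+")
    score_col = next((c for c in _SCORE_ALIASES if c in df.columns), None)
    if score_col is None:
        raise ValueError(
            f"no combined-score column found (expected one of {_SCORE_ALIASES})"
        )
    cols = [c for c in df.columns if c != score_col]
    if len(cols) < 2:
        raise ValueError("need two interactor columns and a score column")
    df = df.rename(
        columns={cols[0]: "protein_a", cols[1]: "protein_b", score_col: "combined_score"}
    )[["protein_a", "protein_b", "combined_score"]]
    return clean_interactions(df, score_min=score_min)


def clean_interactions(df: pd.DataFrame, score_min: int = 400) -> pd.DataFrame:
    """Apply the score filter, drop self-loops, collapse duplicate pairs."""
    if df.empty:
        return df.reset_index(drop=True)
    df = df.loc[df["combined_score"] >= score_min].copy()
    df = df.loc[df["protein_a"] != df["protein_b"]]
    a = df[["protein_a", "protein_b"]].min(axis=1)
    b = df[["protein_a", "protein_b"]].max(axis=1)
    df["protein_a"], df["protein_b"] = a, b
    df = (
        df.groupby(["protein_a", "protein_b"], sort=True, as_index=False)["combined_score"]
        .max()
    )
    return df.reset_index(drop=True)


def induced_subnetwork(interactions: pd.DataFrame, genes: Sequence[str]) -> nx.Graph:
    """Subgraph induced by ``genes``: every list member is a node (isolated if
    it has no retained interaction), edges need both endpoints in the list."""
    if len(genes) == 0:
        raise ValueError("gene list is empty")
    gset = set(genes)
    g = nx.Graph()
    g.add_nodes_from(sorted(gset))
    if len(interactions):
        mask = interactions["protein_a"].isin(gset) & interactions["protein_b"].isin(gset)
        sub = interactions.loc[mask]
        g.add_weighted_edges_from(
            zip(sub["protein_a"], sub["protein_b"], sub["combined_score"]),
            weight="combined_score",
        )
    return g


def network_stats(graph: nx.Graph) -> NetworkStats:
    v, e = graph.number_of_nodes(), graph.number_of_edges()
    if v == 0:
        warnings.warn("empty graph", stacklevel=2)
        return NetworkStats(0, 0, 0.0)
    return NetworkStats(v, e, 2.0 * e / v)


def rank_hubs(graph: nx.Graph, top_n: int = 30) -> pd.DataFrame:
    """All nodes ranked by degree (descending, ties by identifier ascending).

    Columns: gene, degree, rank (1..n), is_top (rank <= top_n).
    """
    rows = sorted(graph.degree(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(rows, columns=["gene", "degree"])
    df["rank"] = np.arange(1, len(df) + 1)
    df["is_top"] = df["rank"] <= top_n
    return df


def compare_networks(graphs: Mapping[str, nx.Graph]) -> pd.DataFrame:
    """Node/edge/mean-neighbor table for a family of induced networks."""
    if len(graphs) < 2:
        raise ValueError("need at least 2 networks to compare")
    rows = []
    for name, g in graphs.items():
        s = network_stats(g)
        rows.append((name, s.nodes, s.edges, round(s.mean_neighbors, 2)))
    return pd.DataFrame(rows, columns=["network", "nodes", "edges", "mean_neighbors"])
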