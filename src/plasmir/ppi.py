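"""Seed-based protein-protein interaction subnetworks and hub ranking.

Given a seed list (the merged miRNA-target genes) and an interactome edge
list, the first-order network is the induced subgraph on the seeds plus all
of their direct interactors; seeds absent from the interactome are kept as
isolated, flagged nodes. An optional tissue filter (e.g. ovary-expressed
genes) restricts the interactome — not the seeds — before expansion.

The *minimum network* is obtained by iteratively deleting non-seed nodes of
degree <= 1 until a fixed point: only interactors that actually connect seed
proteins survive. The rule is confluent, so the result is independent of
deletion order and idempotent. Hubs are nodes ranked by degree (ties by
betweenness, then id).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = [
    "TissueFilter",
    "read_interactome",
    "build_ppi",
    "minimum_network",
    "rank_hubs",
]


@dataclass
class TissueFilter:
    """Named set of tissue-expressed gene symbols."""

    tissue: str
    expressed: frozenset

    def __post_init__(self) -> None:
        self.expressed = frozenset(str(g).upper() for g in self.expressed)
        if not self.expressed:
            raise ValueError("tissue-expressed gene set must be non-empty")

    @classmethod
    def from_file(cls, tissue: str, path) -> "TissueFilter":
        with open(path) as fh:
            genes = {line.strip() for line in fh if line.strip()}
        return cls(tissue=tissue, expressed=frozenset(genes))


def read_interactome(path) -> pd.DataFrame:
    """Tab-delimited symbol-pair edge list (two columns, header optional)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("interactome table needs two symbol columns")
    df = df.iloc[:, :2]
    df.columns = ["gene_a", "gene_b"]
    return df


def build_ppi(seeds, interactome: pd.DataFrame, tissue: TissueFilter | None = None) -> nx.Graph:
    """First-order PPI network around ``seeds``.

    The tissue filter (if any) removes interactome edges whose endpoints are
    not both tissue-expressed *before* seeding. Self-loops and duplicate
    edges are dropped on ingest (counts recorded in ``G.graph``).
    """
    seeds = [str(s).upper() for s in seeds]
    if not seeds:
        raise ValueError("seed list must be non-empty")
    if interactome.empty:
        raise ValueError("interactome must be non-empty")
    edges = interactome.iloc[:, :2].astype(str).apply(lambda c: c.str.upper())
    edges.columns = ["gene_a", "gene_b"]
    n_self = int((edges["gene_a"] == edges["gene_b"]).sum())
    edges = edges[edges["gene_a"] != edges["gene_b"]]
    key = edges.apply(lambda r: tuple(sorted((r["gene_a"], r["gene_b"]))), axis=1)
    n_dup = int(key.duplicated().sum())
    edges = edges[~key.duplicated().to_numpy()]
    if tissue is not None:
        keep = edges["gene_a"].isin(tissue.expressed) & edges["gene_b"].isin(tissue.expressed)
        edges = edges[keep]

    full = nx.Graph()
    full.add_edges_from(edges.itertuples(index=False, name=None))
    seed_set = set(seeds)
    nodes = set()
    for s in seed_set:
        if s in full:
            nodes.add(s)
            nodes.update(full.neighbors(s))
    g = full.subgraph(nodes).copy()
    g.add_nodes_from(seed_set - set(g.nodes))  # absent seeds, isolated
    nx.set_node_attributes(g, {n: (n in seed_set) for n in g.nodes}, "seed")
    g.graph["n_self_loops_dropped"] = n_self
    g.graph["n_duplicate_edges_dropped"] = n_dup
    g.graph["n_seeds"] = len(seed_set)
    return g


def minimum_network(g: nx.Graph) -> nx.Graph:
    """Prune non-seed nodes of degree <= 1 to a fixed point (confluent)."""
    out = g.copy()
    while True:
        doomed = [
            n for n, d in out.nodes(data=True)
            if not d.get("seed", False) and out.degree(n) <= 1
        ]
        if not doomed:
            return out
        out.remove_nodes_from(doomed)


def rank_hubs(g: nx.Graph, top_k: int = 20) -> pd.DataFrame:
    """All nodes with degree/betweenness, top-``top_k`` flagged as hubs.

    Sorted by degree descending, ties broken by betweenness (unnormalized)
    then lexicographic id, so the ordering is deterministic.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot rank hubs of an empty graph")
    btw = nx.betweenness_centrality(g, normalized=False)
    rows = [
        {
            "gene": n,
            "degree": g.degree(n),
            "betweenness": btw[n],
            "seed": bool(g.nodes[n].get("seed", False)),
        }
        for n in g.nodes
    ]
    out = pd.DataFrame(rows).sort_values(
        by=["degree", "betweenness", "gene"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    out.index = out.index + 1
    out.index.name = "rank"
    out["hub"] = out.index <= top_k
    return out
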