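"""miRNA-target bipartite networks, centrality ranking and set intersections.

A :class:`TargetDB` is an evidence-graded edge table (miRNA, gene symbol,
evidence in {strong, weak}, source). From it one can

* build the bipartite miRNA-target network for a miRNA list, optionally
  filtered to strong-evidence edges;
* rank miRNAs by degree and (unnormalized shortest-path) betweenness
  centrality, with deterministic tie-breaking;
* extract the *core* network keeping only genes hit by at least two of the
  listed miRNAs (labeled ``mid`` at exactly two partners, ``high`` above);
* intersect per-group target sets into exclusive Venn regions.

Gene symbols are upper-cased on ingest; alias resolution is out of scope but
a symbol-map hook is provided.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = [
    "TargetDB",
    "build_network",
    "rank_centrality",
    "core_network",
    "intersect_target_sets",
    "total_shared",
]

_EVIDENCE_PRIORITY = {"strong": 0, "weak": 1}


@dataclass
class TargetDB:
    """Deduplicated miRNA→gene edge set with evidence grades."""

    edges: pd.DataFrame  # columns: mirna, gene, evidence, source

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, symbol_map: dict | None = None) -> "TargetDB":
        """Normalize symbols, optionally remap them, and merge duplicates.

        Duplicate (miRNA, gene) pairs keep the strongest evidence grade.
        """
        df = frame.copy()
        required = {"mirna", "gene", "evidence"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"target table lacks columns: {sorted(missing)}")
        if "source" not in df.columns:
            df["source"] = "unknown"
        df["gene"] = df["gene"].astype(str).str.strip().str.upper()
        if symbol_map:
            upper_map = {k.upper(): v.upper() for k, v in symbol_map.items()}
            df["gene"] = df["gene"].map(lambda g: upper_map.get(g, g))
        if (df["gene"] == "").any():
            raise ValueError("empty gene symbols in target table")
        bad = set(df["evidence"].unique()) - set(_EVIDENCE_PRIORITY)
        if bad:
            raise ValueError(f"unknown evidence grades: {sorted(bad)}")
        df["_prio"] = df["evidence"].map(_EVIDENCE_PRIORITY)
        df = (
            df.sort_values(["mirna", "gene", "_prio"], kind="stable")
            .drop_duplicates(subset=["mirna", "gene"], keep="first")
            .drop(columns="_prio")
            .reset_index(drop=True)
        )
        return cls(edges=df)

    @classmethod
    def from_tsv(cls, path, symbol_map: dict | None = None) -> "TargetDB":
        return cls.from_frame(pd.read_csv(path, sep="\t"), symbol_map=symbol_map)

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def targets_of(self, mirnas, evidence: str = "all") -> set[str]:
        """Union of target gene symbols of the given miRNAs."""
        sel = self.edges[self.edges["mirna"].isin(set(mirnas))]
        if evidence != "all":
            sel = sel[sel["evidence"] == evidence]
        return set(sel["gene"])


def build_network(mirnas, db: TargetDB, evidence: str = "all") -> nx.Graph:
    """Bipartite miRNA-target graph for the listed miRNAs.

    Edge set = db edges whose miRNA is listed and whose evidence passes the
    filter (``"all"``, ``"strong"`` or ``"weak"``). miRNAs with no passing
    edge stay in the graph as degree-0 nodes (with a warning).
    """
    mirnas = list(dict.fromkeys(mirnas))
    if not mirnas:
        raise ValueError("miRNA list must be non-empty")
    sel = db.edges[db.edges["mirna"].isin(set(mirnas))]
    if evidence != "all":
        sel = sel[sel["evidence"] == evidence]
    g = nx.Graph()
    g.add_nodes_from(mirnas, kind="mirna")
    for _, row in sel.iterrows():
        g.add_node(row["gene"], kind="gene")
        g.add_edge(row["mirna"], row["gene"], evidence=row["evidence"])
    isolated = [m for m in mirnas if g.degree(m) == 0]
    if isolated:
        warnings.warn(
            f"{len(isolated)} miRNA(s) have no passing target edges: "
            f"{isolated[:5]}",
            stacklevel=2,
        )
    return g


def rank_centrality(net: nx.Graph) -> pd.DataFrame:
    """miRNA table ranked by degree then betweenness then id.

    Betweenness is the classic unnormalized shortest-path count with
    endpoints excluded.
    """
    btw = nx.betweenness_centrality(net, normalized=False)
    rows = [
        {"mirna": n, "degree": net.degree(n), "betweenness": btw[n]}
        for n, d in net.nodes(data=True)
        if d.get("kind") == "mirna"
    ]
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out = out.sort_values(
        by=["degree", "betweenness", "mirna"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    out.index = out.index + 1
    out.index.name = "rank"
    return out


def core_network(net: nx.Graph, min_interactions: int = 2) -> nx.Graph:
    """Subgraph of genes targeted by >= ``min_interactions`` listed miRNAs.

    Kept genes are labeled ``high`` (more than two miRNA partners) or ``mid``
    (exactly two); their miRNA partners come along, and disconnected
    components are preserved. May be empty.
    """
    keep_genes = [
        n
        for n, d in net.nodes(data=True)
        if d.get("kind") == "gene" and net.degree(n) >= min_interactions
    ]
    partners = {m for g in keep_genes for m in net.neighbors(g)}
    sub = net.subgraph(set(keep_genes) | partners).copy()
    for g in keep_genes:
        sub.nodes[g]["label"] = "high" if net.degree(g) > 2 else "mid"
    return sub


def intersect_target_sets(sets_by_group: dict) -> pd.DataFrame:
    """Exclusive Venn regions of >=2 named gene sets.

    For k sets there are 2^k - 1 exclusive regions; each row reports the
    region (names joined by ``&``), its size and the sorted member list.
    Region sizes sum to the size of the overall union, and for three sets the
    four multi-set regions sum to the total number of shared targets.
    """
    names = list(sets_by_group)
    if len(names) < 2:
        raise ValueError("need >=2 named sets")
    sets = {n: {str(g).upper() for g in v} for n, v in sets_by_group.items()}
    rows = []
    for r in range(len(names), 0, -1):
        for inside in itertools.combinations(names, r):
            outside = [n for n in names if n not in inside]
            region = set.intersection(*(sets[n] for n in inside))
            for n in outside:
                region -= sets[n]
            rows.append(
                {
                    "region": "&".join(inside),
                    "n_sets": r,
                    "size": len(region),
                    "members": sorted(region),
                }
            )
    return pd.DataFrame(rows)


def total_shared(regions: pd.DataFrame) -> int:
    """Number of genes in any multi-set region (shared by >=2 groups)."""
    return int(regions.loc[regions["n_sets"] >= 2, "size"].sum())
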