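"""Hypergeometric over-representation analysis against GMT gene sets.

For a query gene list and a named collection of gene sets with universe
(background) of size N, the enrichment p of a set of size K overlapped in k
of the n query genes is the one-sided upper tail

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

(DAVID-style; the EASE variant, which scores k-1 successes, is selectable).
Raw p against an alpha of 0.05 is the primary significance criterion;
Benjamini-Hochberg q-values are reported alongside. Query genes outside the
universe are dropped (with a count kept in ``DataFrame.attrs``) rather than
inflating the background.

``compare_groups`` partitions the categories significant in at least one
miRNA group into shared (all groups, each pair) and group-unique buckets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "ora_test",
    "bh_adjust",
    "compare_groups",
]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the universe they are tested against.

    The universe defaults to the union of all set members; a user-supplied
    background overrides it. Every set must be non-empty and a subset of the
    universe.
    """

    sets: dict
    universe: frozenset

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(s) for name, s in self.sets.items()}
        self.universe = frozenset(self.universe)
        for name, s in self.sets.items():
            if not s:
                raise ValueError(f"gene set {name!r} is empty")
            if not s <= self.universe:
                raise ValueError(f"gene set {name!r} is not within the universe")

    @classmethod
    def from_sets(cls, sets: dict, background=None) -> "GeneSetCollection":
        sets = {n: frozenset(str(g).upper() for g in s) for n, s in sets.items()}
        if background is None:
            universe = frozenset().union(*sets.values()) if sets else frozenset()
        else:
            universe = frozenset(str(g).upper() for g in background)
        return cls(sets=sets, universe=universe)


def read_gmt(path, background=None) -> GeneSetCollection:
    """Read a GMT file (name <tab> description <tab> member symbols...)."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            name, _desc, *genes = fields
            sets[name] = {g for g in genes if g}
    return GeneSetCollection.from_sets(sets, background=background)


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora_test(
    query,
    collection: GeneSetCollection,
    background=None,
    method: str = "hypergeom",
) -> pd.DataFrame:
    """One-sided over-representation test of ``query`` against every set.

    Returns one row per set sorted by p ascending (ties by set name) with
    overlap count, sizes, raw p, BH q and the overlapping symbols. The number
    of query genes dropped for lying outside the universe is stored in
    ``result.attrs["n_dropped"]``.
    """
    if method not in ("hypergeom", "ease"):
        raise ValueError(f"unknown ORA method: {method!r}")
    universe = (
        frozenset(str(g).upper() for g in background)
        if background is not None
        else collection.universe
    )
    query = {str(g).upper() for g in query}
    effective = query & universe
    n_dropped = len(query) - len(effective)
    if not effective:
        raise ValueError("no query genes inside the universe")
    N, n = len(universe), len(effective)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & universe
        K = len(members)
        overlap = sorted(effective & members)
        k = len(overlap)
        score_k = max(k - 1, 0) if method == "ease" else k
        p = float(hypergeom.sf(score_k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "query_size": n,
                "set_size": K,
                "universe_size": N,
                "p": min(p, 1.0),
                "overlap_genes": overlap,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"])
    out = out.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)
    out = out[
        ["set_name", "overlap", "query_size", "set_size", "universe_size", "p", "q", "overlap_genes"]
    ]
    out.attrs["n_dropped"] = n_dropped
    return out


def compare_groups(results_by_group: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Shared-vs-unique layout of significant categories across groups.

    A category lands in the bucket named by the exact set of groups where its
    raw p < alpha: ``all`` when every group hits it, ``A&B`` for a pair,
    ``unique:A`` for one. Categories significant nowhere are absent.
    """
    if len(results_by_group) < 2:
        raise ValueError("need results for >=2 groups")
    groups = list(results_by_group)
    sig = {
        g: set(df.loc[df["p"] < alpha, "set_name"]) for g, df in results_by_group.items()
    }
    categories = sorted(set().union(*sig.values()))
    rows = []
    for cat in categories:
        hit = [g for g in groups if cat in sig[g]]
        if len(hit) == len(groups):
            bucket = "all"
        elif len(hit) == 1:
            bucket = f"unique:{hit[0]}"
        else:
            bucket = "&".join(hit)
        rows.append({"category": cat, "groups": "&".join(hit), "n_groups": len(hit), "bucket": bucket})
    return pd.DataFrame(rows)
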