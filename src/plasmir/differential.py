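"""Nonparametric differential expression across FIGO-staged cohorts.

Normalized counts are tested per miRNA with the tie-corrected Kruskal-Wallis
test (chi-square approximation by default, seeded permutation p optional),
followed by Dunn's pairwise post hoc z tests on pooled mid-ranks with a
Bonferroni-style adjustment. Fold change follows the plasma-profiling
convention ``(stage mean - control mean) / control mean`` — 0 means no
change and negative values mean downregulation.

Each miRNA is then stratified by an operational detection rule into

* **group 1** — detected in controls and in at least one patient cohort, with
  a significant Kruskal-Wallis difference (differential level);
* **group 2** — undetected in controls, detected only in the earliest stage;
* **group 3** — undetected in controls, detected in every patient stage;
* **none** otherwise.

The three groups are mutually exclusive by construction. The differential
subset can be hierarchically clustered (z-scored log2 counts, Euclidean
distance, average linkage) with a deterministic leaf order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st

from .countmatrix import CountMatrix

__all__ = [
    "DetectionRule",
    "kruskal_wallis",
    "dunn_posthoc",
    "fold_change",
    "detection_flags",
    "stratify",
    "de_analyze",
    "cluster_heatmap",
    "ClusterResult",
]

GROUPS = ("group1", "group2", "group3")


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def _validate_groups(groups) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need >=2 cohorts")
    for a in arrs:
        if a.size == 0:
            raise ValueError("every cohort needs >=1 observation")
    if sum(a.size for a in arrs) < 3:
        raise ValueError("need >=3 observations in total")
    return arrs


def _h_statistic(ranks: np.ndarray, sizes: np.ndarray, tie_term: float) -> float:
    """Tie-corrected H from pooled mid-ranks split per group.

    ``tie_term`` is sum(t^3 - t) over tie groups of the pooled sample.
    """
    n_total = int(sizes.sum())
    idx = np.concatenate([[0], np.cumsum(sizes)])
    h = 0.0
    for i, n_i in enumerate(sizes):
        r_mean = ranks[idx[i]: idx[i + 1]].mean()
        h += n_i * r_mean * r_mean
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    denom = 1.0 - tie_term / (n_total ** 3 - n_total)
    if denom <= 0:  # all observations tied
        return 0.0
    return h / denom


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float((counts ** 3 - counts).sum())


def kruskal_wallis(
    values_by_cohort,
    method: str = "chi2",
    n_permutations: int = 100_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and p-value.

    ``method="chi2"`` uses the upper-tail chi-square approximation with
    ``k - 1`` degrees of freedom (the convention even at six samples per
    cohort); ``method="permutation"`` estimates the p-value by Monte Carlo
    relabeling, which is preferable at very small n. Fully tied input returns
    ``(0.0, 1.0)``.
    """
    arrs = _validate_groups(values_by_cohort)
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    if method == "chi2":
        h, p = st.kruskal(*arrs)
        return float(h), float(p)
    if method != "permutation":
        raise ValueError(f"unknown method: {method!r}")
    sizes = np.array([a.size for a in arrs])
    ranks = st.rankdata(pooled)
    tie = _tie_term(pooled)
    h_obs = _h_statistic(ranks, sizes, tie)
    rng = np.random.default_rng(seed)
    n_total = pooled.size
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    denom = 1.0 - tie / (n_total ** 3 - n_total)
    hits = 0
    done = 0
    batch = 20_000
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        perms = rng.permuted(np.broadcast_to(ranks, (b, n_total)).copy(), axis=1)
        grp_sums = np.add.reduceat(perms, offsets, axis=1)
        h = (
            12.0 / (n_total * (n_total + 1))
            * ((grp_sums ** 2) / sizes[None, :]).sum(axis=1)
            - 3.0 * (n_total + 1)
        )
        if denom > 0:
            h /= denom
        hits += int((h >= h_obs - 1e-12).sum())
        done += b
    return float(h_obs), (hits + 1) / (n_permutations + 1)


def dunn_posthoc(values_by_cohort, adjust: str = "bonferroni", labels=None) -> pd.DataFrame:
    """Dunn's pairwise z tests on pooled mid-ranks.

    ``z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))``
    with ``T = sum(t^3 - t)`` over pooled tie groups; two-sided normal p,
    adjusted by multiplying by the number of pairs (capped at 1) by default,
    Holm step-down selectable.
    """
    arrs = _validate_groups(values_by_cohort)
    k = len(arrs)
    labels = list(labels) if labels is not None else [f"cohort{i+1}" for i in range(k)]
    pooled = np.concatenate(arrs)
    n_total = pooled.size
    ranks = st.rankdata(pooled)
    sizes = np.array([a.size for a in arrs])
    idx = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = [ranks[idx[i]: idx[i + 1]].mean() for i in range(k)]
    tie = _tie_term(pooled)
    var_core = n_total * (n_total + 1) / 12.0 - tie / (12.0 * (n_total - 1))
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        se2 = var_core * (1.0 / sizes[i] + 1.0 / sizes[j])
        if se2 <= 0:  # all observations tied
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(se2)
        p = 2.0 * st.norm.sf(abs(z))
        rows.append((labels[i], labels[j], z, p))
    out = pd.DataFrame(rows, columns=["cohort_a", "cohort_b", "z", "p"])
    m = len(out)
    if adjust == "bonferroni":
        out["p_adj"] = np.minimum(out["p"] * m, 1.0)
    elif adjust == "holm":
        from statsmodels.stats.multitest import multipletests

        out["p_adj"] = multipletests(out["p"], method="holm")[1]
    else:
        raise ValueError(f"unknown adjustment: {adjust!r}")
    return out


def fold_change(stage_mean: float, control_mean: float) -> float:
    """Signed relative change ``(stage - control) / control``.

    A zero (or negative) control mean makes the ratio undefined; NaN is
    returned as the "control-absent" sentinel rather than +/-inf.
    """
    if control_mean <= 0:
        return float("nan")
    return (stage_mean - control_mean) / control_mean


# ---------------------------------------------------------------------------
# Detection and stratification
# ---------------------------------------------------------------------------

@dataclass
class DetectionRule:
    """A miRNA counts as detected in a cohort when strictly more than
    ``threshold`` counts are seen in at least ``min_fraction`` of that
    cohort's samples (defaults: >0 after background correction, in >=50%)."""

    min_fraction: float = 0.5
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.min_fraction <= 1):
            raise ValueError("min_fraction must be in (0, 1]")


def detection_flags(m: CountMatrix, rule: DetectionRule | None = None) -> pd.DataFrame:
    """Probe x cohort boolean detection calls under ``rule``."""
    rule = rule or DetectionRule()
    out = {}
    for cohort in m.cohort_order:
        block = m.counts[m.samples_of(cohort)]
        frac = (block > rule.threshold).mean(axis=1)
        out[cohort] = frac >= rule.min_fraction
    return pd.DataFrame(out)


def stratify(
    detected: pd.DataFrame, kw_p: pd.Series, alpha: float = 0.05,
    cohort_order=None,
) -> pd.Series:
    """Assign each probe to group1/group2/group3 or none (total function).

    ``detected`` is the probe x cohort flag table whose first cohort is the
    control and second is the earliest patient stage.
    """
    cohorts = list(cohort_order) if cohort_order is not None else list(detected.columns)
    control, early, later = cohorts[0], cohorts[1], cohorts[2:]
    assignments = []
    for probe in detected.index:
        row = detected.loc[probe]
        in_control = bool(row[control])
        patient_hits = [c for c in cohorts[1:] if row[c]]
        if in_control and patient_hits and kw_p.get(probe, 1.0) < alpha:
            assignments.append("group1")
        elif not in_control and row[early] and not any(row[c] for c in later):
            assignments.append("group2")
        elif not in_control and all(row[c] for c in cohorts[1:]):
            assignments.append("group3")
        else:
            assignments.append("none")
    return pd.Series(assignments, index=detected.index, name="group")


def de_analyze(
    m: CountMatrix,
    alpha: float = 0.05,
    rule: DetectionRule | None = None,
    adjust: str = "bonferroni",
    kw_method: str = "chi2",
) -> pd.DataFrame:
    """Per-probe differential-expression table over the endogenous probes.

    Columns: per-cohort means, ``kw_h``, ``kw_p``, Dunn adjusted p per cohort
    pair, per-stage fold changes, per-cohort detection flags and the final
    ``group`` assignment.
    """
    rule = rule or DetectionRule()
    cohorts = m.cohort_order
    control = cohorts[0]
    endo = m.class_counts("endogenous")
    sample_sets = {c: list(m.samples_of(c)) for c in cohorts}
    detected = detection_flags(m, rule).loc[endo.index]

    records = []
    for probe, row in endo.iterrows():
        by_cohort = [row[sample_sets[c]].to_numpy() for c in cohorts]
        h, p = kruskal_wallis(by_cohort, method=kw_method)
        dunn = dunn_posthoc(by_cohort, adjust=adjust, labels=cohorts)
        rec = {"probe_id": probe, "kw_h": h, "kw_p": p}
        for c in cohorts:
            rec[f"mean_{c}"] = float(np.mean(by_cohort[cohorts.index(c)]))
        for c in cohorts[1:]:
            rec[f"fc_{c}"] = fold_change(rec[f"mean_{c}"], rec[f"mean_{control}"])
        for _, d in dunn.iterrows():
            rec[f"dunn_p_{d.cohort_a}_vs_{d.cohort_b}"] = d.p_adj
        for c in cohorts:
            rec[f"detected_{c}"] = bool(detected.loc[probe, c])
        records.append(rec)
    table = pd.DataFrame(records).set_index("probe_id")
    table["group"] = stratify(detected, table["kw_p"], alpha=alpha, cohort_order=cohorts)
    return table


# ---------------------------------------------------------------------------
# Hierarchical clustering of the differential set
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    ordered: pd.DataFrame
    newick: str
    linkage: np.ndarray
    constant_rows: list[str]


def _linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    tree = sch.to_tree(link)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = node.left, node.right
        lb = max(node.dist - left.dist, 0.0)
        rb = max(node.dist - right.dist, 0.0)
        return f"({walk(left)}:{lb:.6g},{walk(right)}:{rb:.6g})"

    return walk(tree) + ";"


def cluster_heatmap(
    sub: pd.DataFrame, log_transform: bool = True, scale: bool = True
) -> ClusterResult:
    """Cluster a probe x sample matrix for heatmap display.

    Rows are z-scored on log2(count + 1) (both transforms can be disabled);
    distance is Euclidean with average linkage. Rows are pre-sorted
    lexicographically by probe id so equal-distance merges resolve
    deterministically; constant rows (z-score undefined) are flagged and set
    to the zero vector.
    """
    if len(sub) < 2:
        raise ValueError("clustering needs >=2 rows")
    sub = sub.sort_index(kind="stable")
    x = np.log2(sub.to_numpy(dtype=float) + 1.0) if log_transform else sub.to_numpy(dtype=float)
    constant = np.zeros(len(sub), dtype=bool)
    if scale:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=0, keepdims=True)
        constant = (sd[:, 0] == 0)
        sd[sd == 0] = 1.0
        z = (x - mu) / sd
        z[constant, :] = 0.0
    else:
        z = x
    link = sch.linkage(z, method="average", metric="euclidean")
    order = sch.leaves_list(link)
    labels = list(sub.index)
    ordered = pd.DataFrame(z, index=sub.index, columns=sub.columns).iloc[order]
    return ClusterResult(
        ordered=ordered,
        newick=_linkage_to_newick(link, labels),
        linkage=link,
        constant_rows=[labels[i] for i in np.flatnonzero(constant)],
    )
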