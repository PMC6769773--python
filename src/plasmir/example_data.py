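"""Bundled worked-example data from a published plasma-miRNA profiling study
of serous epithelial ovarian cancer (FIGO-staged cohorts vs healthy
controls).

Two small curated tables are shipped:

* the three differential miRNA groups — 17 miRNAs at significantly
  different levels between controls and patients (group 1), 19 detected only
  in FIGO I patients (group 2) and 9 detected in all patient stages
  (group 3). As printed, hsa-miR-584-5p appears in *both* the group 1 and
  group 2 columns (45 listed entries, 44 unique ids); the stratification in
  :mod:`plasmir.differential` enforces disjoint groups, so this duplication
  is kept here purely as source bookkeeping.
* the shared-target regions of the three groups' experimentally validated
  target gene sets: 5 genes hit by all three groups, 18 / 21 / 10 genes in
  the exclusive pairwise overlaps, 54 shared targets in total.

These lists serve as deterministic fixtures for the set-algebra operations;
the per-group *exclusive* targets are not part of the published intersection
table and are not included.
"""

from __future__ import annotations

MIRNA_GROUPS: dict[str, list[str]] = {
    "group1": [
        "hsa-miR-1185-2-3p",
        "hsa-miR-553",
        "hsa-miR-144-3p",
        "hsa-miR-146b-5p",
        "hsa-miR-148b-3p",
        "hsa-miR-1976",
        "hsa-miR-19b-3p",
        "hsa-miR-526a",
        "hsa-miR-219a-2-3p",
        "hsa-miR-25-3p",
        "hsa-miR-26b-5p",
        "hsa-miR-301a-3p",
        "hsa-miR-513a-3p",
        "hsa-miR-552-3p",
        "hsa-miR-584-5p",
        "hsa-miR-613",
        "hsa-miR-615-5p",
    ],
    "group2": [
        "hsa-miR-1185-1-3p",
        "hsa-miR-1197",
        "hsa-miR-1266-5p",
        "hsa-miR-149-5p",
        "hsa-miR-23a-3p",
        "hsa-miR-3161",
        "hsa-miR-331-3p",
        "hsa-miR-331-5p",
        "hsa-miR-337-5p",
        "hsa-miR-3615",
        "hsa-miR-409-3p",
        "hsa-miR-4455",
        "hsa-miR-498",
        "hsa-miR-520g-3p",
        "hsa-miR-584-5p",
        "hsa-miR-590-5p",
        "hsa-miR-625-5p",
        "hsa-miR-628-5p",
        "hsa-miR-651-5p",
    ],
    "group3": [
        "hsa-miR-125a-3p",
        "hsa-miR-1281",
        "hsa-miR-128-2-5p",
        "hsa-miR-1305",
        "hsa-miR-223-3p",
        "hsa-miR-325",
        "hsa-miR-497-5p",
        "hsa-miR-500a-5p",
        "hsa-miR-548h-3p",
    ],
}

# Exclusive shared-target regions of the three group target sets.
SHARED_TARGET_REGIONS: dict[frozenset, list[str]] = {
    frozenset({"group1", "group2", "group3"}): [
        "MET", "SMAD7", "EZH2", "TERT", "IL6",
    ],
    frozenset({"group1", "group2"}): [
        "TLR4", "MTOR", "IGF1", "ZEB1", "SOX4", "PTBP2", "BIRC5", "CCNE1",
        "RHOB", "MMP16", "IGF1R", "MYC", "PXK", "SOCS1", "PBX3", "PRKAA1",
        "CFTR", "FBXW7",
    ],
    frozenset({"group1", "group3"}): [
        "ROCK1", "KCNJ6", "PTEN", "TGFBR2", "HOTAIR", "PLEKHA1", "ERBB2",
        "FGA", "CDH1", "PPP2R5E", "FGG", "IRS1", "RECK", "DDX3X", "FGB",
        "HLA-G", "WWP1", "RB1", "TCEAL1", "HSP90AA1", "ZFX",
    ],
    frozenset({"group2", "group3"}): [
        "GIT1", "NPM3", "BRCA1", "CHUK", "STAT3", "SP1", "FOXO3", "VEGFA",
        "E2F1", "MEF2C",
    ],
}


def mirna_groups() -> dict[str, list[str]]:
    """The three differential miRNA group columns as printed (17/19/9)."""
    return {g: list(v) for g, v in MIRNA_GROUPS.items()}


def shared_target_sets() -> dict[str, set[str]]:
    """Per-group target sets reassembled from the shared-region table.

    Each group's set is the union of every region it participates in; running
    these through :func:`plasmir.targets.intersect_target_sets` recovers the
    published region sizes (5 triple, 18/21/10 pairwise, 54 shared in total).
    """
    groups = ("group1", "group2", "group3")
    out: dict[str, set[str]] = {g: set() for g in groups}
    for region, genes in SHARED_TARGET_REGIONS.items():
        for g in region:
            out[g].update(genes)
    return out
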