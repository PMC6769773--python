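"""End-to-end orchestration: simulate → normalize → DE → qPCR → networks.

A :class:`RunConfig` (YAML-loadable) drives the stages in a fixed order with
per-stage seeds derived deterministically from one root seed, so re-running
an identical configuration reproduces identical outputs. Each stage writes
its tabular outputs under the run directory and contributes counts to a
machine-readable JSON run report; a stage failure leaves a ``FAILED`` marker
naming the stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .countmatrix import DEFAULT_COHORTS, CountMatrix
from .differential import DetectionRule, cluster_heatmap, de_analyze
from .enrichment import compare_groups, ora_test, write_gmt
from .normalization import normalize
from .ppi import build_ppi, minimum_network, rank_hubs
from .qpcr import ingest_ct, relative_expression_table, validate_against_panel
from .synthetic_data import (
    PanelDefinition,
    SimulationConfig,
    generate_counts,
    generate_genesets,
    generate_interactome,
    generate_qpcr_plate,
    generate_target_db,
)
from .targets import TargetDB, build_network, core_network, intersect_target_sets, rank_centrality, total_shared

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ("simulate", "normalize", "de", "qpcr", "net", "enrich", "ppi")

SHARED_CORE = ("MET", "SMAD7", "EZH2", "TERT", "IL6")


@dataclass
class RunConfig:
    """Configuration of a full synthetic-data pipeline run."""

    outdir: str = "plasmir_run"
    seed: int = 0
    alpha: float = 0.05
    samples_per_cohort: int = 6
    planted_per_group: int = 8
    planted_log2_effect: float = 2.0
    baseline_mean: float = 100.0
    dispersion: float = 10.0
    lane_scale_sd: float = 0.2
    background_mean: float = 2.0
    detection_min_fraction: float = 0.5
    detection_threshold: float = 0.0
    evidence: str = "strong"
    reference_assay: str = "hsa-miR-103-3p"
    hub_top_k: int = 20
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage toggle: {s!r}")
        self.stages = {s: bool(self.stages.get(s, True)) for s in STAGES}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        params = asdict(self)
        params.pop("outdir")
        blob = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seed(root: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2^31."""
    digest = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; return (and write) the report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {s: _stage_seed(config.seed, s) for s in STAGES}
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "root_seed": config.seed,
        "stage_seeds": seeds,
        "stages": {},
    }
    state: dict = {}
    current = None
    try:
        for stage in STAGES:
            if not config.stages[stage]:
                continue
            current = stage
            report["stages"][stage] = _STAGE_FUNCS[stage](config, seeds[stage], outdir, state)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {current} failed: {exc}\n")
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _panel_and_sim(config: RunConfig, seed: int) -> tuple[PanelDefinition, SimulationConfig]:
    panel = PanelDefinition()
    k, eff = config.planted_per_group, config.planted_log2_effect
    ids = panel.endogenous_ids
    sim = SimulationConfig(
        samples_per_cohort=config.samples_per_cohort,
        baseline_mean=config.baseline_mean,
        dispersion=config.dispersion,
        lane_scale_sd=config.lane_scale_sd,
        background_mean=config.background_mean,
        planted_group1=[(p, eff) for p in ids[:k]],
        planted_group2=[(p, eff) for p in ids[k: 2 * k]],
        planted_group3=[(p, eff) for p in ids[2 * k: 3 * k]],
        seed=seed,
    )
    return panel, sim


def _stage_simulate(config: RunConfig, seed: int, outdir: Path, state: dict) -> dict:
    panel, sim = _panel_and_sim(config, seed)
    cm, truth = generate_counts(sim, panel)
    cm.to_tsv(outdir / "counts.tsv", outdir / "cohorts.tsv")
    truth.to_tsv(outdir / "truth.tsv")
    state["counts"] = cm
    state["truth"] = truth
    return {
        "probes": int(cm.counts.shape[0]),
        "endogenous_probes": int(len(cm.probes_of("endogenous"))),
        "samples": int(cm.counts.shape[1]),
        "planted_per_group": config.planted_per_group,
    }


def _stage_normalize(config: RunConfig, seed: int, outdir: Path, state: dict) -> dict:
    if "counts" not in state:
        state["counts"] = CountMatrix.from_tsv(outdir / "counts.tsv", outdir / "cohorts.tsv")
    norm, rep = normalize(state["counts"])
    norm.to_tsv(outdir / "normalized.tsv", outdir / "cohorts.tsv")
    rep.to_tsv(outdir / "normalization_report.tsv")
    state["normalized"] = norm
    return {
        "probes_out": int(norm.counts.shape[0]),
        "mean_background_threshold": float(rep.background_threshold.mean()),
    }


def _stage_de(config: RunConfig, seed: int, outdir: Path, state: dict) -> dict:
    norm = state["normalized"]
    rule = DetectionRule(config.detection_min_fraction, config.detection_threshold)
    de = de_analyze(norm, alpha=config.alpha, rule=rule)
    de_out = de.copy()
    de.to_csv(outdir / "de.tsv", sep="\t")
    diff = de.index[de["group"] != "none"]
    if len(diff) >= 2:
        clust = cluster_heatmap(norm.counts.loc[diff])
        clust.ordered.to_csv(outdir / "heatmap_matrix.tsv", sep="\t")
        (outdir / "dendrogram.nwk").write_text(clust.newick + "\n")
    state["de"] = de_out
    counts = de["group"].value_counts().to_dict()
    return {
        "tested": int(len(de)),
        "differential": int(len(diff)),
        "per_group": {g: int(counts.get(g, 0)) for g in ("group1", "group2", "group3")},
    }


def _stage_qpcr(config: RunConfig, seed: int, outdir: Path, state: dict) -> dict:
    de = state["de"]
    truth = state.get("truth")
    group1 = [p for p in de.index if de.loc[p, "group"] == "group1"][:4]
    flat = [p for p in de.index if de.loc[p, "group"] == "none"][:1]
    assays = group1 + flat
    if not assays:
        return {"assays": 0, "note": "no assays selected"}
    levels: dict = {}
    eff = 2.0 ** config.planted_log2_effect
    for a in assays:
        true_group = truth.group.get(a, "none") if truth is not None else "none"
        up = eff if true_group != "none" else 1.0
        levels[a] = {c: (1.0 if c == DEFAULT_COHORTS[0] else up) for c in DEFAULT_COHORTS}
    raw = generate_qpcr_plate(
        n_samples_per_cohort=config.samples_per_cohort,
        assays=assays,
        true_relative_levels=levels,
        reference=config.reference_assay,
        seed=seed,
    )
    raw.to_csv(outdir / "ct.tsv", sep="\t", index=False)
    plate = ingest_ct(raw, reference=config.reference_assay)
    rq = relative_expression_table(plate)
    rq.to_csv(outdir / "qpcr_rq.tsv", sep="\t", index=False)
    concordance = validate_against_panel(rq, de, alpha=config.alpha)
    concordance.to_csv(outdir / "qpcr_concordance.tsv", sep="\t")
    verdicts = concordance["verdict"].value_counts().to_dict()
    return {"assays": len(assays), "verdicts": {k: int(v) for k, v in verdicts.items()}}


def _stage_net(config: RunConfig, seed: int, outdir: Path, state: dict) -> dict:
    de = state["de"]
    groups = {
        g: [p for p in de.index if de.loc[p, "group"] == g]
        for g in ("group1", "group2", "group3")
    }
    groups = {g: v for g, v in groups.items() if v}
    if len(groups) < 2:
        return {"note": "fewer than two non-empty miRNA groups; skipped"}
    db = generate_target_db(groups, shared_core=SHARED_CORE, seed=seed)
    db.to_tsv(outdir / "targets.tsv")
    state["target_db"] = db
    state["groups"] = groups
    rank_rows = {}
    target_sets = {}
    for g, mirnas in groups.items():
        net = build_network(mirnas, db, evidence=config.evidence)
        rank = rank_centrality(net)
        rank.to_csv(outdir / f"centrality_{g}.tsv", sep="\t")
        core = core_network(net)
        nx_edges = pd.DataFrame(core.edges, columns=["node_a", "node_b"])
        nx_edges.to_csv(outdir / f"core_{g}.tsv", sep="\t", index=False)
        rank_rows[g] = rank
        target_sets[g] = db.targets_of(mirnas, evidence=config.evidence)
    state["target_sets"] = target_sets
    regions = intersect_target_sets(target_sets)
    regions.assign(members=regions["members"].map(" ".join)).to_csv(
        outdir / "venn_regions.tsv", sep="\t", index=False
    )
    return {
        "groups": {g: len(v) for g, v in groups.items()},
        "region_sizes": dict(zip(regions["region"], regions["size"].astype(int))),
        "total_shared": total_shared(regions),
    }


def _stage_enrich(config: RunConfig, seed: int, outdir: Path, state: dict) -> dict:
    target_sets = state.get("target_sets")
    if not target_sets:
        return {"note": "no target sets; skipped"}
    db: TargetDB = state["target_db"]
    universe = sorted(set(db.edges["gene"]))
    planted = sorted(target_sets[next(iter(target_sets))])[: min(25, len(universe))]
    collection = generate_genesets(universe, enriched_set=planted, seed=seed)
    write_gmt(collection, outdir / "genesets.gmt")
    results = {}
    for g, genes in target_sets.items():
        res = ora_test(genes, collection)
        res.assign(overlap_genes=res["overlap_genes"].map(" ".join)).to_csv(
            outdir / f"enrichment_{g}.tsv", sep="\t", index=False
        )
        results[g] = res
    shared = compare_groups(results, alpha=config.alpha)
    shared.to_csv(outdir / "enrichment_shared.tsv", sep="\t", index=False)
    return {
        "sets": len(collection.sets),
        "significant_per_group": {
            g: int((r["p"] < config.alpha).sum()) for g, r in results.items()
        },
        "shared_categories": int((shared["n_groups"] == len(results)).sum()),
    }


def _stage_ppi(config: RunConfig, seed: int, outdir: Path, state: dict) -> dict:
    target_sets = state.get("target_sets")
    if not target_sets:
        return {"note": "no target sets; skipped"}
    seeds_list = sorted(set().union(*target_sets.values()))
    db: TargetDB = state["target_db"]
    universe = sorted(set(db.edges["gene"]) | {f"EXT{i:04d}" for i in range(1, 301)})
    interactome = generate_interactome(universe, n_edges=4 * len(universe), hub_bias=1.0, seed=seed)
    interactome.to_csv(outdir / "interactome.tsv", sep="\t", index=False)
    g = build_ppi(seeds_list, interactome)
    mini = minimum_network(g)
    hubs = rank_hubs(mini, top_k=config.hub_top_k)
    hubs.to_csv(outdir / "hubs.tsv", sep="\t")
    pd.DataFrame(mini.edges, columns=["gene_a", "gene_b"]).to_csv(
        outdir / "minimum_network.tsv", sep="\t", index=False
    )
    return {
        "seeds": len(seeds_list),
        "first_order_nodes": int(g.number_of_nodes()),
        "first_order_edges": int(g.number_of_edges()),
        "minimum_nodes": int(mini.number_of_nodes()),
        "minimum_edges": int(mini.number_of_edges()),
        "top_hub": hubs.iloc[0]["gene"] if len(hubs) else None,
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "normalize": _stage_normalize,
    "de": _stage_de,
    "qpcr": _stage_qpcr,
    "net": _stage_net,
    "enrich": _stage_enrich,
    "ppi": _stage_ppi,
}
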