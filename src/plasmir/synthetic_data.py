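"""Synthetic inputs for the plasma-miRNA pipeline.

Every input the analysis consumes can be simulated here with the statistical
structure the downstream methods assume, so the whole pipeline is testable
without access to proprietary panel scans or external target databases:

* hybridization-panel counts — negative-binomial counts with multiplicative
  lane (sample) scale effects, additive background, control-probe classes and
  cohort-specific planted expression patterns;
* qPCR Ct plates — triplicate cycle-threshold readings around
  ``-log2(level)`` with a detection ceiling;
* miRNA→target edge databases with evidence grades and a planted shared core;
* gene-set collections (GMT-writable) with a planted enriched set;
* random interactomes with an optional hub bias.

All generators are pure functions of (configuration, seed): the same seed
always yields byte-identical output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .countmatrix import DEFAULT_COHORTS, CountMatrix

__all__ = [
    "PanelDefinition",
    "SimulationConfig",
    "GroundTruth",
    "generate_counts",
    "generate_target_db",
    "generate_qpcr_plate",
    "generate_genesets",
    "generate_interactome",
]


# ---------------------------------------------------------------------------
# Panel and simulation configuration
# ---------------------------------------------------------------------------

def _default_endogenous() -> list[str]:
    return [f"hsa-miR-sim-{i:04d}" for i in range(1, 799)]


def _default_negative() -> list[str]:
    return [f"NEG_{c}" for c in "ABCDEF"]


def _default_positive() -> list[str]:
    return [f"POS_{c}" for c in "ABCDEF"]


def _default_housekeeping() -> list[str]:
    return [f"HK_{i:02d}" for i in range(1, 11)]


def _default_ladder() -> list[float]:
    # four-fold geometric dilution ladder, strictly decreasing
    return [128.0, 32.0, 8.0, 2.0, 0.5, 0.125]


@dataclass
class PanelDefinition:
    """Probe content of a digital-counting miRNA panel.

    Defaults mirror a 798-probe human miRNA code set with six negative
    controls (no target; estimate background), six positive controls spiked
    at a geometric concentration ladder (estimate lane scale), and ten
    housekeeping miRNAs (per-sample content normalization).
    """

    endogenous_ids: list[str] = field(default_factory=_default_endogenous)
    negative_ids: list[str] = field(default_factory=_default_negative)
    positive_ids: list[str] = field(default_factory=_default_positive)
    positive_ladder: list[float] = field(default_factory=_default_ladder)
    housekeeping_ids: list[str] = field(default_factory=_default_housekeeping)

    def __post_init__(self) -> None:
        groups = [
            self.endogenous_ids,
            self.negative_ids,
            self.positive_ids,
            self.housekeeping_ids,
        ]
        for g in groups:
            if not g:
                raise ValueError("every probe-class id list must be non-empty")
        all_ids = list(itertools.chain.from_iterable(groups))
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("probe id sets must be pairwise disjoint")
        if len(self.positive_ladder) != len(self.positive_ids):
            raise ValueError("ladder length must match positive probe count")
        ladder = np.asarray(self.positive_ladder, dtype=float)
        if not (np.diff(ladder) < 0).all():
            raise ValueError("positive ladder must be strictly decreasing")

    @property
    def all_ids(self) -> list[str]:
        return (
            list(self.endogenous_ids)
            + list(self.negative_ids)
            + list(self.positive_ids)
            + list(self.housekeeping_ids)
        )


@dataclass
class SimulationConfig:
    """Study design and noise model for a simulated panel run.

    ``planted_group1`` probes carry a per-cohort log2 effect over baseline and
    stay expressed everywhere (differential level). ``planted_group2`` probes
    are background-only except in the second cohort (early-stage-only
    expression). ``planted_group3`` probes are background-only in the first
    (control) cohort and expressed in every patient cohort. Effects are
    ``(probe_id, log2_effect)`` pairs; for group 1 the effect applies in every
    patient cohort relative to the control baseline.
    """

    samples_per_cohort: int = 6
    cohorts: tuple[str, ...] = DEFAULT_COHORTS
    baseline_mean: float = 100.0
    dispersion: float = 10.0
    lane_scale_sd: float = 0.2
    background_mean: float = 2.0
    positive_scale: float = 300.0
    planted_group1: list[tuple[str, float]] = field(default_factory=list)
    planted_group2: list[tuple[str, float]] = field(default_factory=list)
    planted_group3: list[tuple[str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples_per_cohort < 2:
            raise ValueError("samples_per_cohort must be >= 2")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be positive")
        if self.lane_scale_sd < 0 or self.background_mean < 0:
            raise ValueError("lane_scale_sd and background_mean must be >= 0")
        ids = [p for p, _ in self.planted_group1 + self.planted_group2 + self.planted_group3]
        if len(set(ids)) != len(ids):
            raise ValueError("planted probe lists must be disjoint across groups")


@dataclass
class GroundTruth:
    """Planted truth of a simulation: per-probe group label and cohort means.

    ``group`` maps every endogenous probe to ``group1``/``group2``/``group3``
    or ``none``; ``true_mean`` is the probe x cohort expected signal (before
    lane scaling and background).
    """

    group: pd.Series
    true_mean: pd.DataFrame

    def to_tsv(self, path) -> None:
        out = self.true_mean.copy()
        out.insert(0, "group", self.group)
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draw with var = mu + mu^2/dispersion.

    ``dispersion = inf`` degrades to Poisson; zero means yield zero counts.
    """
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if not pos.any():
        return out
    if np.isinf(dispersion):
        out[pos] = rng.poisson(mean[pos])
    else:
        p = dispersion / (dispersion + mean[pos])
        out[pos] = rng.negative_binomial(dispersion, p)
    return out


def generate_counts(
    config: SimulationConfig, panel: PanelDefinition | None = None
) -> tuple[CountMatrix, GroundTruth]:
    """Simulate a raw panel count matrix plus its planted ground truth.

    Endogenous counts are NB(baseline * cohort effect * lane scale +
    background); negative controls see background only; positive controls
    follow the concentration ladder times the lane scale (Poisson noise);
    housekeeping probes sit at fixed per-probe levels times the lane scale,
    so both control-based correction factors are identifiable.
    """
    panel = panel or PanelDefinition()
    endo = set(panel.endogenous_ids)
    planted = {
        "group1": dict(config.planted_group1),
        "group2": dict(config.planted_group2),
        "group3": dict(config.planted_group3),
    }
    for grp, eff in planted.items():
        unknown = set(eff) - endo
        if unknown:
            raise ValueError(f"{grp} plants unknown probe ids: {sorted(unknown)[:5]}")

    rng = np.random.default_rng(config.seed)
    n = config.samples_per_cohort
    cohorts = list(config.cohorts)
    control = cohorts[0]
    figo = cohorts[1:]
    early = figo[0] if figo else None

    samples = [f"{c}_s{i+1}" for c in cohorts for i in range(n)]
    sample_cohort = pd.Series(
        [c for c in cohorts for _ in range(n)], index=samples, name="cohort"
    )
    lane_scale = np.exp(rng.normal(0.0, config.lane_scale_sd, size=len(samples)))

    # expected signal per endogenous probe and cohort (before lane/background)
    true_mean = pd.DataFrame(
        config.baseline_mean,
        index=pd.Index(panel.endogenous_ids, name="probe_id"),
        columns=cohorts,
        dtype=float,
    )
    group = pd.Series("none", index=true_mean.index, name="group")
    for pid, eff in planted["group1"].items():
        group[pid] = "group1"
        for c in figo:
            true_mean.loc[pid, c] = config.baseline_mean * 2.0 ** eff
    for pid, eff in planted["group2"].items():
        group[pid] = "group2"
        true_mean.loc[pid, :] = 0.0
        if early is not None:
            true_mean.loc[pid, early] = config.baseline_mean * 2.0 ** eff
    for pid, eff in planted["group3"].items():
        group[pid] = "group3"
        true_mean.loc[pid, control] = 0.0
        for c in figo:
            true_mean.loc[pid, c] = config.baseline_mean * 2.0 ** eff

    mean_per_sample = true_mean[sample_cohort.values].to_numpy()
    endo_mu = mean_per_sample * lane_scale[None, :] + config.background_mean
    endo_counts = _nb_draw(rng, endo_mu, config.dispersion)

    neg_mu = np.full((len(panel.negative_ids), len(samples)), config.background_mean)
    neg_counts = _nb_draw(rng, neg_mu, config.dispersion)

    ladder = np.asarray(panel.positive_ladder, dtype=float)
    pos_mu = ladder[:, None] * config.positive_scale * lane_scale[None, :]
    pos_counts = rng.poisson(pos_mu)

    # fixed, spread-out housekeeping levels (geometric spacing) so the
    # per-sample geometric mean is well conditioned
    n_hk = len(panel.housekeeping_ids)
    hk_levels = config.baseline_mean * np.logspace(-0.5, 0.5, n_hk, base=10.0)
    hk_mu = hk_levels[:, None] * lane_scale[None, :] + config.background_mean
    hk_counts = _nb_draw(rng, hk_mu, config.dispersion)

    counts = pd.DataFrame(
        np.vstack([endo_counts, neg_counts, pos_counts, hk_counts]),
        index=pd.Index(panel.all_ids, name="probe_id"),
        columns=samples,
        dtype=float,
    )
    probe_class = pd.Series(
        ["endogenous"] * len(panel.endogenous_ids)
        + ["negative"] * len(panel.negative_ids)
        + ["positive"] * len(panel.positive_ids)
        + ["housekeeping"] * n_hk,
        index=counts.index,
        name="probe_class",
    )
    cm = CountMatrix(counts=counts, probe_class=probe_class, cohorts=sample_cohort)
    cm.lane_scale = pd.Series(lane_scale, index=samples, name="lane_scale")
    return cm, GroundTruth(group=group, true_mean=true_mean)


# ---------------------------------------------------------------------------
# Target database
# ---------------------------------------------------------------------------

def generate_target_db(
    mirna_ids,
    gene_universe_size: int = 500,
    edges_per_mirna_range: tuple[int, int] = (5, 30),
    shared_core=(),
    seed: int = 0,
    strong_fraction: float = 0.5,
):
    """Random evidence-graded miRNA→gene edge table.

    ``mirna_ids`` is either a flat list or a mapping group → miRNA list; with
    a mapping, every ``shared_core`` gene is guaranteed a strong edge from at
    least one miRNA of every group, so the core lands in the all-groups
    intersection of the group target sets.
    """
    from .targets import TargetDB

    if isinstance(mirna_ids, dict):
        groups = {g: list(v) for g, v in mirna_ids.items()}
    else:
        groups = {"all": list(mirna_ids)}
    flat = [m for v in groups.values() for m in v]
    if not flat:
        raise ValueError("miRNA list must be non-empty")
    lo, hi = edges_per_mirna_range
    if not (1 <= lo <= hi <= gene_universe_size):
        raise ValueError("edges_per_mirna_range out of bounds for the universe")

    # shared-core symbols join the universe if not already of the GENE#### form
    universe = np.array([f"GENE{i:04d}" for i in range(1, gene_universe_size + 1)])
    shared_core = [g.upper() for g in shared_core]
    rng = np.random.default_rng(seed)

    rows: list[tuple[str, str, str, str]] = []
    for mir in flat:
        k = int(rng.integers(lo, hi + 1))
        genes = rng.choice(universe, size=k, replace=False)
        for g in genes:
            ev = "strong" if rng.random() < strong_fraction else "weak"
            rows.append((mir, str(g), ev, "sim"))
    for gene in shared_core:
        for gname, members in groups.items():
            carrier = members[int(rng.integers(len(members)))]
            rows.append((carrier, gene, "strong", "sim-core"))

    edges = pd.DataFrame(rows, columns=["mirna", "gene", "evidence", "source"])
    return TargetDB.from_frame(edges)


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

def generate_qpcr_plate(
    n_samples_per_cohort: int,
    assays,
    true_relative_levels,
    replicate_sd: float = 0.25,
    ceiling: float = 45.0,
    reference: str = "hsa-miR-103-3p",
    cohorts: tuple[str, ...] = DEFAULT_COHORTS,
    base_ct: float = 30.0,
    sample_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a triplicate Ct table around ``base_ct - log2(level)``.

    ``true_relative_levels`` maps assay → (cohort → level relative to the
    reference assay, which is fixed at level 1). A per-sample additive offset
    (RNA input variation) shifts every assay of a lane equally, so it cancels
    in the ΔCt; draws past the detection ceiling are recorded as
    ``Undetermined``. Levels must be positive.
    """
    if ceiling <= 0:
        raise ValueError("ceiling must be positive")
    for assay, levels in true_relative_levels.items():
        for cohort, level in levels.items():
            if level <= 0:
                raise ValueError(f"non-positive level for {assay}/{cohort}")
    rng = np.random.default_rng(seed)
    rows = []
    for cohort in cohorts:
        for i in range(n_samples_per_cohort):
            sample = f"{cohort}_q{i+1}"
            offset = rng.normal(0.0, sample_sd)
            for assay in list(assays) + [reference]:
                if assay == reference:
                    level = 1.0
                else:
                    level = true_relative_levels.get(assay, {}).get(cohort, 1.0)
                center = base_ct - np.log2(level) + offset
                for rep in range(1, 4):
                    ct = center + rng.normal(0.0, replicate_sd)
                    value = "Undetermined" if ct > ceiling else f"{ct:.4f}"
                    rows.append((sample, cohort, assay, rep, value))
    return pd.DataFrame(rows, columns=["sample", "cohort", "assay", "replicate", "ct"])


# ---------------------------------------------------------------------------
# Gene sets and interactome
# ---------------------------------------------------------------------------

def generate_genesets(
    universe,
    n_sets: int = 20,
    set_size_range: tuple[int, int] = (10, 50),
    enriched_set=(),
    seed: int = 0,
):
    """Random GMT-writable gene-set collection over ``universe``.

    If ``enriched_set`` is given it is included verbatim as ``SET_PLANTED``,
    so a query overlapping it is over-represented by construction.
    """
    from .enrichment import GeneSetCollection

    universe = [g.upper() for g in universe]
    lo, hi = set_size_range
    if hi > len(universe):
        raise ValueError("set size range exceeds universe size")
    enriched = [g.upper() for g in enriched_set]
    if set(enriched) - set(universe):
        raise ValueError("enriched_set must be drawn from the universe")
    rng = np.random.default_rng(seed)
    arr = np.array(universe)
    sets: dict[str, frozenset] = {}
    for i in range(1, n_sets + 1):
        k = int(rng.integers(lo, hi + 1))
        sets[f"SET_{i:03d}"] = frozenset(rng.choice(arr, size=k, replace=False))
    if enriched:
        sets["SET_PLANTED"] = frozenset(enriched)
    return GeneSetCollection(sets=sets, universe=frozenset(universe))


def generate_interactome(
    universe,
    n_edges: int = 2000,
    hub_bias: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Random undirected interactome edge list over gene symbols.

    With ``hub_bias = 0`` endpoints are uniform over the universe, so node
    degrees are ~ Binomial(2 * n_edges, 1/|universe|); a positive bias draws
    endpoints with probability proportional to ``rank^-hub_bias``, producing
    heavy-tailed hub-dominated degrees. Self-loops and duplicate edges are
    rejected and resampled.
    """
    universe = [g.upper() for g in universe]
    n = len(universe)
    if n_edges > n * (n - 1) // 2:
        raise ValueError("more edges requested than simple-graph capacity")
    rng = np.random.default_rng(seed)
    if hub_bias == 0:
        weights = None
    else:
        w = (np.arange(1, n + 1, dtype=float)) ** (-float(hub_bias))
        weights = w / w.sum()
    seen: set[tuple[int, int]] = set()
    edges: list[tuple[str, str]] = []
    while len(edges) < n_edges:
        m = 2 * (n_edges - len(edges)) + 16
        a = rng.choice(n, size=m, p=weights)
        b = rng.choice(n, size=m, p=weights)
        for i, j in zip(a, b):
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            edges.append((universe[key[0]], universe[key[1]]))
            if len(edges) == n_edges:
                break
    return pd.DataFrame(edges, columns=["gene_a", "gene_b"])
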