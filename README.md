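# plasmir

Analysis pipeline for circulating miRNA profiles measured in blood plasma on
a digital hybridization-counting panel (NanoString nCounter-style), aimed at
ovarian-cancer biomarker studies that compare healthy controls with patients
stratified by FIGO stage.

Plasma miRNA counts from such panels are low, over-dispersed and subject to
per-lane technical scale effects, and many miRNAs are detectable only in
patients. `plasmir` implements the full analysis chain such a study needs,
plus a synthetic-data generator that emulates every input, so the whole
pipeline is testable end to end without access to raw panel scans or
proprietary databases:

1. **Normalization** — per-sample background threshold from negative
   controls (mean + 2 SD, floored at zero), lane correction from the
   geometric mean of the positive spike-in ladder, content normalization
   from the geometric mean of 10 housekeeping miRNAs.
2. **Differential expression** — tie-corrected Kruskal–Wallis H across the
   four cohorts (chi-square p by default, seeded permutation p for small n),
   Dunn's pairwise post hoc z on pooled mid-ranks with Bonferroni-style
   adjustment, fold change as (stage mean − control mean)/control mean, and
   stratification of each miRNA into: **group 1** (detected everywhere,
   significantly different), **group 2** (patient-only, earliest stage
   only), **group 3** (patient-only, all stages). Hierarchical clustering
   (z-scored log2 counts, Euclidean, average linkage) with Newick export.
3. **qPCR validation** — 2^−ΔCt relative expression from triplicate Ct
   plates against a reference miRNA (hsa-miR-103-3p), 45-cycle detection
   ceiling, and cross-platform concordance verdicts.
4. **Target networks** — bipartite miRNA–target graphs from evidence-graded
   edge tables, degree/betweenness ranking, strong-evidence core network,
   and exclusive Venn-region intersection of group target sets.
5. **Enrichment** — one-sided hypergeometric over-representation against
   GMT gene-set collections with BH q-values and shared-vs-unique category
   comparison across miRNA groups.
6. **PPI analysis** — seed-based first-order protein–protein interaction
   networks (optionally tissue-filtered), minimum-network pruning of
   non-seed leaves, and hub ranking.

## Worked example

Simulate the study design (4 cohorts × 6 samples, 798 endogenous probes,
8 planted miRNAs per group at a 4-fold effect), normalize, test, stratify:

```python
import plasmir as pm

panel = pm.PanelDefinition()                  # 798 endogenous + 6/6/10 controls
ids = panel.endogenous_ids
cfg = pm.SimulationConfig(
    planted_group1=[(p, 2.0) for p in ids[:8]],     # 4x up in every stage
    planted_group2=[(p, 2.0) for p in ids[8:16]],   # FIGO I only
    planted_group3=[(p, 2.0) for p in ids[16:24]],  # all stages, not control
    seed=7,
)
cm, truth = pm.generate_counts(cfg, panel)
norm, report = pm.normalize(cm)
de = pm.de_analyze(norm, alpha=0.05)
print(de["group"].value_counts().to_dict())
```

prints

```
{'none': 745, 'group1': 39, 'group2': 7, 'group3': 7}
```

The 8 planted group-1 miRNAs are all recovered (the extra group-1 calls are
the expected ~5% false positives of the α = 0.05 gate over 774 null probes);
7 of 8 planted probes are recovered in each of groups 2 and 3, for an
overall planted-label recovery of 0.917 at this seed. A single probe's
record shows the test output:

```
hsa-miR-sim-0001: mean_Control=85.9  mean_FIGO_I=324.3  fc_FIGO_I=2.77
                  kw_p=2.54e-03  group=group1
```

On the printed four-cohort ladder `{1,2,3},{4,5,6},{7,8,9},{10,11,12}` the
rank statistics evaluate to `H = 10.3846, p = 0.0156`, and Dunn's extreme
pair gives `|z| = 3.0571`.

The same chain runs from the shell:

```sh
plasmir run --seed 7 --outdir run/      # simulate → ... → ppi, report.json
plasmir simulate --seed 3 --outdir sim/
plasmir normalize sim/counts.tsv --cohorts sim/cohorts.tsv --out norm.tsv
plasmir de norm.tsv --cohorts sim/cohorts.tsv --out de.tsv
```

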