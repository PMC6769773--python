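# Methods

## Study design being modeled

The pipeline targets a plasma circulating-miRNA profiling design: four
cohorts (healthy controls and FIGO I / III / IV ovarian-cancer patients),
six plasma samples per cohort, profiled on a digital hybridization-counting
panel of 798 endogenous human miRNA probes plus control probes (6 negative,
6 positive spike-ins on a four-fold concentration ladder, 10 housekeeping
miRNAs). Counts are per-molecule tallies without amplification, so they are
low for most plasma miRNAs, over-dispersed relative to Poisson, and carry a
per-lane multiplicative technical scale.

## Synthetic-data generator

The generator is the package's substitute for raw panel scans and external
databases; all statistical claims the test suite makes are claims about
data with this structure.

**Counts.** Endogenous counts are negative binomial with
`var = μ + μ²/dispersion` and mean
`baseline · 2^(cohort effect) · lane_scale + background`. Lane scales are
log-normal (`lane_scale_sd` on the log scale) and shared by all probes of a
lane, which is what makes positive-control correction identifiable.
Background is additive and *not* lane-scaled; negative-control probes see
background only. Positive controls follow `ladder · positive_scale ·
lane_scale` with Poisson noise; housekeeping probes sit at fixed per-probe
levels (geometrically spaced over one decade around the baseline) times the
lane scale. "Absent" miRNAs are background-only rather than structurally
zero, so detection calls are actually exercised.

Planted signals mirror the three biological patterns of interest: group-1
probes are expressed everywhere with a per-cohort log2 effect over baseline;
group-2 probes are background-only except in FIGO I; group-3 probes are
background-only in controls and expressed in every patient stage.

Default parameters (chosen once for realism of the emulated platform):

| parameter | default | unit | rationale |
|---|---|---|---|
| `samples_per_cohort` | 6 | samples | the profiled study design |
| `baseline_mean` | 100 | counts | typical detectable plasma miRNA count |
| `dispersion` | 10 | NB size | moderate over-dispersion (CV ≈ 0.33 at μ=100); Poisson is the ∞ limit |
| `lane_scale_sd` | 0.2 | log-counts | ±20% lane-to-lane technical variation |
| `background_mean` | 2 | counts | negative-control magnitude of plasma panels |
| `positive_scale` | 300 | counts/fM | puts the spike-in ladder at ~37–38 000 counts; real ladders span ~10²–10⁵ and never fall below background |

Panel probe-class sizes other than the 798 endogenous and 10 housekeeping
probes are not dictated by the emulated study; 6 negative and 6 positive
controls follow platform convention.

**Other inputs.** The target-database generator draws 5–30 targets per
miRNA from a symbol universe, grades edges strong/weak, and can force a
shared core of genes to be targeted by at least one miRNA of every group
(so the core provably lands in the all-groups Venn region). The qPCR
generator draws triplicate Ct values around `base_ct − log2(level)` with a
per-sample offset (RNA input variation, cancels in ΔCt) and records draws
past the 45-cycle ceiling as `Undetermined`. Gene-set and interactome
generators produce GMT-writable collections (with an optional planted
enriched set) and simple random graphs (uniform endpoints at `hub_bias=0`,
power-law weighted endpoints otherwise). Every generator is a pure function
of its configuration and seed.

**What is not emulated:** fluorescence/scan-level artifacts, binding
density, probe-specific hybridization efficiency, amplification efficiency
in qPCR, correlated miRNA co-regulation, and realistic interactome topology
beyond a simple hub bias. Passing tests demonstrate correctness of the
analysis logic under the stated statistical structure, not performance on
any particular real cohort.

## Normalization

Stages run in the fixed order background → positive → housekeeping.

1. **Background**: per sample, threshold `t = mean(neg) + 2·sd(neg)`
   (sample SD, n−1), subtracted from every non-negative-control count and
   floored at 0. The one-sided upper bound is used because subtracting
   `mean − 2·sd` would under-correct. Zero after correction is "not
   detected". Requires ≥ 2 negative probes.
2. **Positive-control**: per lane, `g_s` = geometric mean of the positive
   spike-in counts (a per-lane median is selectable); the factor is
   `center(g)/g_s`, applied multiplicatively. `center` is the across-lane
   arithmetic mean by default (platform convention); with the geometric
   option the factors' geometric mean is exactly 1.
3. **Housekeeping**: identical arithmetic on the housekeeping geometric
   means; endogenous *and* housekeeping rows are scaled, which makes the
   stage idempotent in its factors (re-running returns factors of 1).

Zeros are replaced by 1 before log-averaging in geometric means — exact for
integer counts, keeps factors finite, and is applied uniformly.

A note on lane-doubling: multiplying one lane by a constant is absorbed by
its factor *up to a single global rescale*, because the factor numerator
(the across-lane mean of the `g_s`) also moves. The two normalized matrices
are exactly proportional (tested at 1e-9); element-wise equality would
require a data-independent reference level, which no across-lane convention
provides.

## Differential expression

The Kruskal–Wallis H uses pooled mid-ranks with the standard tie
correction; fully tied input returns (H=0, p=1). The p-value is upper-tail
chi-square with k−1 df by default. At the study design (k=4, n=6/cohort)
this approximation is conservative — its empirical size is ≈ 0.04 at
nominal 0.05 — so a seeded Monte Carlo permutation p (vectorized
relabeling) is available and is what the calibration suite uses; with it
the null rejection rate is 0.05 within Monte Carlo error. Dunn's post hoc z
uses the pooled-rank variance with tie term, two-sided normal p, multiplied
by the number of pairs and capped at 1 (Holm selectable). Fold change is
`(stage mean − control mean)/control mean` on cohort arithmetic means of
normalized counts; a zero control mean yields NaN (flagged
"control-absent"), never ±∞. Downregulation is negative by this convention.

Detection — which the stratification needs but which count panels do not
define intrinsically — is operationalized as: strictly positive
(post-background) counts in at least 50% of a cohort's samples; both knobs
are configurable. Group assignment is a total function and the three groups
are mutually exclusive by construction: group 1 requires control detection,
≥1 patient-cohort detection and KW p < α; group 2 requires no control
detection and detection in the earliest stage only; group 3 requires no
control detection and detection in all patient stages. (The bundled
published example lists contain one miRNA printed in two group columns;
the package documents rather than reproduces that bookkeeping.)

Clustering z-scores log2(count+1) rows (population SD; constant rows are
flagged and zeroed), uses Euclidean distance with average linkage, and
pre-sorts rows lexicographically so equal-distance merges are
deterministic. The dendrogram is exported as Newick with branch lengths as
merge-height differences.

## qPCR validation

ΔCt is the difference of replicate means (equivalent to per-replicate
ΔCt averaging for balanced triplicates); relative expression is 2^−ΔCt.
Readings `Undetermined` or above the 45-cycle ceiling are set to exactly
45 and flagged; an all-ceiling target keeps its arithmetic (the value is
the detection-floor sentinel) with the censored flag propagated, while an
all-ceiling *reference* is an error. Concordance verdicts per shared assay:
`both-significant-same-direction`, `discordant` (exactly one platform
significant, or directions conflict), `underpowered` (neither significant).
Patient-only panel groups count as upregulation for direction purposes.

## Networks and enrichment

Betweenness is the classic unnormalized shortest-path count with endpoints
excluded; rankings sort by degree, then betweenness, then id, so output
order is deterministic. The core network keeps genes with ≥ 2 miRNA
partners (`mid` = 2, `high` > 2) plus their partners, preserving
disconnected components. Venn intersection returns all 2^k − 1 exclusive
regions; their sizes sum to the union (a tested conservation law).

ORA is the one-sided upper-tail hypergeometric `P(X ≥ k)` with the
universe defaulting to all collection genes (user background overrides;
query genes outside the universe are dropped and counted, never added).
The EASE variant (k−1) is selectable. Raw p < 0.05 is the primary
criterion; BH q-values are reported alongside because no correction
convention is canonical for this analysis.

The PPI first-order network is the induced subgraph on seeds plus direct
interactors; tissue filters restrict the interactome (both endpoints
expressed) *before* expansion, never the seeds, since seeds are measured
targets regardless of annotation. The minimum network iteratively deletes
non-seed nodes of degree ≤ 1; the rule is confluent, hence order-independent
and idempotent (both property-tested). A Steiner-tree-style minimum
connector is out of scope.

## Numerical and degenerate-input conventions

- Seeds: every stochastic routine takes an explicit seed; the pipeline
  derives per-stage seeds from one root seed by SHA-256, keeping them
  below 2^31.
- All-tied rank tests return H=0/p=1 and z=0/p=1 rather than 0/0.
- Empty cohorts, missing housekeeping/reference assays, all-zero positive
  lanes, negative Ct values, and empty seed/miRNA lists raise errors that
  name the offender.
- Gene symbols are upper-cased on ingest everywhere; duplicate target
  edges keep the strongest evidence grade; interactome self-loops and
  duplicates are dropped with counts recorded.

## Problem sizes used by the test and acceptance runs

Simulated runs use the full 798-probe panel at the 4×6 study design.
Calibration uses three null simulations (2394 probes) with 2000
permutations per probe; recovery uses 20 seeded simulations with 8 planted
probes per group at a log2 effect of 2; the permutation cross-check of the
worked rank-test example uses 10^5 Monte Carlo draws against exhaustive
enumeration of all 369 600 assignments.

## Known limitations

- The chi-square Kruskal–Wallis p is conservative at n=6/cohort (documented
  above); results near the significance boundary depend on which p-variant
  is chosen.
- The detection rule is a pragmatic operationalization; real panels
  sometimes use negative-control-based per-probe thresholds instead.
- No alias resolution for gene symbols (a symbol-map hook exists), no GO
  term ancestry, no batch correction, no parametric count models, and no
  reproduction of database-dependent quantities (absolute degree values,
  interactome node/edge totals).
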