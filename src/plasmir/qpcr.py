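"""2^-ΔCt relative quantification from triplicate qPCR plates.

Cycle-threshold (Ct) readings are ingested with a detection ceiling
(default 45 cycles): values recorded as ``Undetermined`` or above the
ceiling are set to exactly the ceiling and flagged as censored. Relative
expression against a reference assay (default hsa-miR-103-3p, the panel's
internal control) is

    ΔCt = mean(replicate Ct of target) - mean(replicate Ct of reference)
    relative expression = 2^-ΔCt

Replicate means are taken before differencing. Adding any constant to every
Ct of a sample (RNA-input shift) leaves 2^-ΔCt unchanged, and lower target
Ct means strictly higher expression.

Cohort differences in 2^-ΔCt are re-tested with the same Kruskal-Wallis +
Dunn machinery used on the panel counts, and each shared assay gets a
cross-platform concordance verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential import dunn_posthoc, kruskal_wallis

__all__ = [
    "CtPlate",
    "ingest_ct",
    "relative_expression",
    "relative_expression_table",
    "validate_against_panel",
]

DEFAULT_REFERENCE = "hsa-miR-103-3p"
UNDETERMINED_TOKENS = {"undetermined", "undet", "na", ""}


@dataclass
class CtPlate:
    """Long-format Ct records with ceiling handling applied.

    ``data`` columns: sample, cohort, assay, replicate, ct (float, cycles),
    censored (bool — the reading was undetermined or above the ceiling).
    """

    data: pd.DataFrame
    ceiling: float = 45.0
    reference: str = DEFAULT_REFERENCE

    @property
    def assays(self) -> list[str]:
        return sorted(self.data["assay"].unique())

    def replicate_means(self) -> pd.DataFrame:
        """Per (sample, assay): mean Ct, all-censored flag, cohort."""
        grp = self.data.groupby(["sample", "assay"], sort=True)
        out = grp.agg(
            ct_mean=("ct", "mean"),
            all_censored=("censored", "all"),
            cohort=("cohort", "first"),
        ).reset_index()
        return out


def ingest_ct(table, ceiling: float = 45.0, reference: str = DEFAULT_REFERENCE) -> CtPlate:
    """Parse a raw Ct table (path or DataFrame) applying the ceiling rule.

    ``Undetermined`` tokens and readings above the ceiling become exactly the
    ceiling value with the censored flag set; negative Ct values are invalid.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    df = table.copy()
    required = {"sample", "assay", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    if "cohort" not in df.columns:
        df["cohort"] = "unknown"

    raw = df["ct"].astype(str).str.strip()
    is_token = raw.str.lower().isin(UNDETERMINED_TOKENS)
    ct = pd.to_numeric(raw.where(~is_token), errors="coerce")
    unparsable = ct.isna() & ~is_token
    if unparsable.any():
        raise ValueError(f"unparsable Ct values: {list(raw[unparsable].unique())[:5]}")
    if (ct.dropna() < 0).any():
        raise ValueError("negative Ct values are invalid")
    censored = is_token | (ct > ceiling)
    ct = ct.where(~censored, ceiling).astype(float)
    out = df[["sample", "cohort", "assay", "replicate"]].copy()
    out["ct"] = ct
    out["censored"] = censored.to_numpy()
    return CtPlate(data=out, ceiling=ceiling, reference=reference)


def _mean_ct(plate: CtPlate, sample: str, assay: str) -> tuple[float, bool]:
    sel = plate.data[(plate.data["sample"] == sample) & (plate.data["assay"] == assay)]
    if sel.empty:
        raise KeyError(f"no Ct records for sample {sample!r}, assay {assay!r}")
    return float(sel["ct"].mean()), bool(sel["censored"].all())


def relative_expression(plate: CtPlate, sample: str, assay: str) -> float:
    """2^-ΔCt of one assay in one sample against the plate's reference."""
    target, _ = _mean_ct(plate, sample, assay)
    try:
        ref, ref_censored = _mean_ct(plate, sample, plate.reference)
    except KeyError:
        raise ValueError(
            f"reference assay {plate.reference!r} not measured for sample {sample!r}"
        ) from None
    if ref_censored:
        raise ValueError(
            f"reference assay undetectable (all replicates censored) in {sample!r}"
        )
    return float(2.0 ** -(target - ref))


def relative_expression_table(plate: CtPlate) -> pd.DataFrame:
    """ΔCt, 2^-ΔCt and censoring flag for every (sample, assay) pair.

    Target assays with all replicates at the ceiling keep the arithmetic
    (their value is the detection-floor sentinel) and carry ``censored=True``.
    """
    means = plate.replicate_means()
    ref = means[means["assay"] == plate.reference].set_index("sample")
    if ref.empty:
        raise ValueError(f"reference assay {plate.reference!r} absent from plate")
    bad = ref.index[ref["all_censored"]]
    if len(bad):
        raise ValueError(f"reference assay undetectable in sample(s): {list(bad)}")
    rows = []
    for _, r in means.iterrows():
        if r["assay"] == plate.reference:
            continue
        if r["sample"] not in ref.index:
            raise ValueError(f"reference missing for sample {r['sample']!r}")
        delta = r["ct_mean"] - ref.loc[r["sample"], "ct_mean"]
        rows.append(
            {
                "sample": r["sample"],
                "cohort": r["cohort"],
                "assay": r["assay"],
                "delta_ct": delta,
                "rq": 2.0 ** -delta,
                "censored": bool(r["all_censored"]),
            }
        )
    return pd.DataFrame(rows)


def validate_against_panel(
    rq_table: pd.DataFrame,
    panel_de: pd.DataFrame,
    alpha: float = 0.05,
    cohort_order=None,
) -> pd.DataFrame:
    """Cross-platform concordance of qPCR 2^-ΔCt against panel DE calls.

    ``panel_de`` is the per-probe table from :func:`plasmir.differential.
    de_analyze` (needs ``group`` and the ``fc_*`` columns). For each assay
    shared between platforms, 2^-ΔCt values are re-tested across cohorts
    (Kruskal-Wallis + Dunn) and the verdict is one of
    ``both-significant-same-direction``, ``discordant`` or ``underpowered``.
    """
    shared = sorted(set(rq_table["assay"]) & set(panel_de.index))
    if not shared:
        raise ValueError("no shared assays between qPCR table and panel results")
    cohorts = (
        list(cohort_order)
        if cohort_order is not None
        else list(dict.fromkeys(rq_table["cohort"]))
    )
    control = cohorts[0]
    fc_cols = [c for c in panel_de.columns if c.startswith("fc_")]
    rows = []
    for assay in shared:
        sub = rq_table[rq_table["assay"] == assay]
        by_cohort = [sub.loc[sub["cohort"] == c, "rq"].to_numpy() for c in cohorts]
        h, p = kruskal_wallis(by_cohort)
        dunn = dunn_posthoc(by_cohort, labels=cohorts)
        qpcr_sig = p < alpha
        control_mean = float(np.mean(by_cohort[0]))
        patient_mean = float(np.mean(np.concatenate(by_cohort[1:])))
        qpcr_dir = np.sign(patient_mean - control_mean)

        panel_row = panel_de.loc[assay]
        panel_group = panel_row.get("group", "none")
        panel_sig = panel_group in ("group1", "group2", "group3")
        if panel_group in ("group2", "group3"):
            panel_dir = 1.0  # patient-only expression is upregulation
        else:
            fcs = panel_row[fc_cols].astype(float)
            panel_dir = np.sign(fcs.mean()) if len(fcs) else 0.0

        if panel_sig and qpcr_sig and panel_dir == qpcr_dir and panel_dir != 0:
            verdict = "both-significant-same-direction"
        elif not panel_sig and not qpcr_sig:
            verdict = "underpowered"
        else:
            verdict = "discordant"
        rec = {
            "assay": assay,
            "kw_h": h,
            "kw_p": p,
            "qpcr_direction": qpcr_dir,
            "panel_group": panel_group,
            "panel_direction": panel_dir,
            "censored_any": bool(sub["censored"].any()),
            "verdict": verdict,
        }
        for _, d in dunn.iterrows():
            rec[f"dunn_p_{d.cohort_a}_vs_{d.cohort_b}"] = d.p_adj
        rows.append(rec)
    return pd.DataFrame(rows).set_index("assay")
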