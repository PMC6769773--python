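"""Probe-by-sample count matrix with probe-class and cohort annotations.

The count matrix is the object every normalization stage transforms: rows are
panel probes (endogenous miRNAs plus negative, positive and housekeeping
control probes), columns are samples (one hybridization lane each), and each
sample carries a cohort label (e.g. ``Control``, ``FIGO_I``...).

On-disk dialect (tab-delimited):

* counts TSV — first two columns ``probe_id`` and ``probe_class``, remaining
  columns one per sample; header row holds sample ids.
* cohort map TSV — two columns ``sample`` and ``cohort``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

PROBE_CLASSES = ("endogenous", "negative", "positive", "housekeeping")

DEFAULT_COHORTS = ("Control", "FIGO_I", "FIGO_III", "FIGO_IV")


@dataclass
class CountMatrix:
    """Probe x sample counts plus per-probe class and per-sample cohort.

    Parameters
    ----------
    counts
        DataFrame, index = probe ids, columns = sample ids, values
        non-negative (raw counts are integers; normalized counts are reals).
    probe_class
        Series indexed like ``counts`` rows with values from
        :data:`PROBE_CLASSES`.
    cohorts
        Series indexed like ``counts`` columns giving each sample's cohort.
    """

    counts: pd.DataFrame
    probe_class: pd.Series
    cohorts: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        self.probe_class = self.probe_class.reindex(self.counts.index)
        self.cohorts = self.cohorts.reindex(self.counts.columns)
        if self.probe_class.isna().any():
            missing = list(self.probe_class.index[self.probe_class.isna()])
            raise ValueError(f"probes without a class annotation: {missing[:5]}")
        bad = set(self.probe_class.unique()) - set(PROBE_CLASSES)
        if bad:
            raise ValueError(f"unknown probe classes: {sorted(bad)}")
        if self.cohorts.isna().any():
            missing = list(self.cohorts.index[self.cohorts.isna()])
            raise ValueError(f"samples without a cohort label: {missing[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("count matrix contains negative entries")

    # -- convenience views -------------------------------------------------

    def probes_of(self, probe_class: str) -> pd.Index:
        """Ids of all probes of the given class, in matrix order."""
        return self.counts.index[self.probe_class == probe_class]

    def class_counts(self, probe_class: str) -> pd.DataFrame:
        """Sub-matrix of one probe class."""
        return self.counts.loc[self.probes_of(probe_class)]

    def samples_of(self, cohort: str) -> pd.Index:
        return self.counts.columns[self.cohorts == cohort]

    @property
    def cohort_order(self) -> list[str]:
        """Cohort labels in first-appearance (sample) order."""
        seen: list[str] = []
        for c in self.cohorts:
            if c not in seen:
                seen.append(c)
        return seen

    def with_counts(self, counts: pd.DataFrame) -> "CountMatrix":
        """New matrix with the same annotations restricted to ``counts``."""
        return CountMatrix(
            counts=counts,
            probe_class=self.probe_class.loc[counts.index].copy(),
            cohorts=self.cohorts.loc[counts.columns].copy(),
        )

    def drop_class(self, probe_class: str) -> "CountMatrix":
        keep = self.counts.index[self.probe_class != probe_class]
        return self.with_counts(self.counts.loc[keep])

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, counts_path, cohorts_path=None) -> None:
        out = self.counts.copy()
        out.insert(0, "probe_class", self.probe_class)
        out.index.name = "probe_id"
        out.to_csv(counts_path, sep="\t")
        if cohorts_path is not None:
            cm = self.cohorts.rename("cohort").to_frame()
            cm.index.name = "sample"
            cm.to_csv(cohorts_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, cohorts_path) -> "CountMatrix":
        tab = pd.read_csv(counts_path, sep="\t", index_col="probe_id")
        probe_class = tab.pop("probe_class")
        cohorts = pd.read_csv(cohorts_path, sep="\t", index_col="sample")["cohort"]
        return cls(counts=tab, probe_class=probe_class, cohorts=cohorts)
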