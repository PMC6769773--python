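"""Three-stage control-probe normalization of digital miRNA counts.

The procedure follows the standard workflow for hybridization-based digital
counting panels:

1. **Background correction** — per sample, subtract a threshold estimated
   from the negative-control probes (mean + 2 sample standard deviations),
   flooring at zero. Counts at zero afterwards are treated as "not detected".
2. **Positive-control (lane) correction** — each lane's technical scale is
   estimated as the geometric mean of its positive-control spike-in counts;
   each lane is rescaled so these agree across lanes.
3. **Housekeeping (content) normalization** — per-sample factors from the
   geometric mean of the housekeeping miRNA counts (default panel carries 10).

Both scaling stages compute ``factor_s = center(g_1..g_S) / g_s`` where
``g_s`` is the lane's control geometric mean and ``center`` is the
across-lane arithmetic mean by default (``geometric`` selectable, in which
case the geometric mean of the reported factors is exactly 1). Zeros are
replaced by 1 before log-averaging, which is exact for integer counts and
keeps the factors finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .countmatrix import CountMatrix

__all__ = [
    "NormalizationReport",
    "background_correct",
    "positive_control_normalize",
    "housekeeping_normalize",
    "normalize",
]


@dataclass
class NormalizationReport:
    """Per-sample diagnostics of the three stages.

    ``background_threshold`` is in counts; the two factors are dimensionless
    multipliers applied to each lane.
    """

    background_threshold: pd.Series
    positive_factor: pd.Series
    housekeeping_factor: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "background_threshold": self.background_threshold,
                "positive_factor": self.positive_factor,
                "housekeeping_factor": self.housekeeping_factor,
            }
        )
        out.index.name = "sample"
        return out

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _geomean_with_zero_rule(block: pd.DataFrame) -> pd.Series:
    """Per-column geometric mean, zeros replaced by 1 before log-averaging."""
    vals = block.to_numpy(dtype=float).copy()
    if (vals < 0).any():
        raise ValueError("negative control-probe counts")
    vals[vals == 0] = 1.0
    return pd.Series(np.exp(np.log(vals).mean(axis=0)), index=block.columns)


def _center(g: pd.Series, method: str) -> float:
    if method == "arithmetic":
        return float(g.mean())
    if method == "geometric":
        return float(np.exp(np.log(g).mean()))
    raise ValueError(f"unknown center method: {method!r}")


def background_correct(m: CountMatrix) -> tuple[CountMatrix, pd.Series]:
    """Subtract the per-sample negative-control threshold mean + 2*sd.

    The threshold is one-sided (upper bound of the background distribution,
    sample sd with n-1 denominator); corrected counts floor at zero and the
    negative-control rows are dropped from the output.
    """
    neg = m.class_counts("negative")
    if len(neg) < 2:
        raise ValueError(
            "background correction needs >=2 negative-control probes "
            f"(got {len(neg)})"
        )
    thresholds = neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1)
    thresholds.name = "background_threshold"
    corrected = (m.counts.sub(thresholds, axis=1)).clip(lower=0.0)
    out = m.with_counts(corrected).drop_class("negative")
    return out, thresholds


def positive_control_normalize(
    m: CountMatrix, center: str = "arithmetic", lane_statistic: str = "geomean"
) -> tuple[CountMatrix, pd.Series]:
    """Rescale lanes so their positive-control spike-in levels agree.

    ``lane_statistic`` chooses the per-lane summary of the positive code set:
    ``"geomean"`` (default, the platform convention) or ``"median"``.
    Positive-control rows are dropped from the output.
    """
    pos = m.class_counts("positive")
    if len(pos) < 1:
        raise ValueError("positive-control normalization needs >=1 positive probe")
    dead = pos.columns[(pos == 0).all(axis=0)]
    if len(dead):
        raise ValueError(
            f"all positive controls are zero in sample(s): {list(dead)}"
        )
    if lane_statistic == "geomean":
        g = _geomean_with_zero_rule(pos)
    elif lane_statistic == "median":
        g = pos.median(axis=0)
    else:
        raise ValueError(f"unknown lane statistic: {lane_statistic!r}")
    factors = _center(g, center) / g
    factors.name = "positive_factor"
    scaled = m.counts.mul(factors, axis=1)
    out = m.with_counts(scaled).drop_class("positive")
    return out, factors


def housekeeping_normalize(
    m: CountMatrix, hk_ids=None, center: str = "arithmetic"
) -> tuple[CountMatrix, pd.Series]:
    """Per-sample content normalization from housekeeping miRNA counts.

    The factor is ``center(h)/h_s`` with ``h_s`` the lane's housekeeping
    geometric mean. Endogenous and housekeeping rows are scaled (so the
    operation is idempotent in its factors); housekeeping rows stay in the
    matrix, still flagged by their probe class.
    """
    if hk_ids is None:
        hk_ids = list(m.probes_of("housekeeping"))
    missing = [h for h in hk_ids if h not in m.counts.index]
    if missing:
        raise ValueError(f"housekeeping probes missing from matrix: {missing}")
    if not hk_ids:
        raise ValueError("no housekeeping probes given")
    h = _geomean_with_zero_rule(m.counts.loc[hk_ids])
    factors = _center(h, center) / h
    factors.name = "housekeeping_factor"
    scaled = m.counts.mul(factors, axis=1)
    out = m.with_counts(scaled)
    return out, factors


def normalize(
    m: CountMatrix, center: str = "arithmetic", lane_statistic: str = "geomean"
) -> tuple[CountMatrix, NormalizationReport]:
    """Full chain in the fixed order background → positive → housekeeping."""
    m1, thresholds = background_correct(m)
    m2, pos_factors = positive_control_normalize(
        m1, center=center, lane_statistic=lane_statistic
    )
    m3, hk_factors = housekeeping_normalize(m2, center=center)
    report = NormalizationReport(
        background_threshold=thresholds,
        positive_factor=pos_factors,
        housekeeping_factor=hk_factors,
    )
    return m3, report
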