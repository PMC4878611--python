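"""Median-of-ratios size factors and tool-independent reference fold changes.

The size-factor estimator is the classic median-of-ratios: for sample *j*,

    sf_j = median_g counts[g, j] / geomean_g,

where the median runs over "reference" genes only — genes with a strictly
positive count in every sample (genes with any zero have no finite geometric
mean contribution and are excluded, the standard convention).

Reference log2 fold changes are the per-gene log2 ratio of mean normalized
counts between the two conditions, computed once on the full clean replicate
set and reused as the tool-independent yardstick when benchmarking
subselections against a fold-change threshold.  Sign convention:
``log2fc = log2(mean(condition2) / mean(condition1))`` with condition order
taken from the design (first condition = reference/denominator).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import NormalizationError
from .experiment_io import CountMatrix, ExperimentDesign

__all__ = ["SizeFactors", "ReferenceFoldChanges", "size_factors", "normalize",
           "reference_log2fc"]

SizeFactors = pd.Series  # sample_id -> positive scale factor


def size_factors(cm: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors, one positive factor per sample."""
    counts = cm.counts.astype(float)
    reference = (counts > 0).all(axis=1)
    if not reference.any():
        raise NormalizationError(
            "no reference gene: every gene has a zero count in some sample"
        )
    logc = np.log(counts[reference])
    log_ratios = logc - logc.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(sf, index=cm.sample_ids, name="size_factor")


def normalize(cm: CountMatrix, sf: SizeFactors) -> pd.DataFrame:
    """Divide each sample's counts by its size factor (real-valued result)."""
    missing = [s for s in cm.sample_ids if s not in sf.index]
    if missing:
        raise NormalizationError(f"missing size factor(s) for {missing}")
    factors = sf.loc[cm.sample_ids].to_numpy(dtype=float)
    if (factors <= 0).any() or not np.isfinite(factors).all():
        raise NormalizationError("size factors must be finite and > 0")
    return cm.data.astype(float) / factors


@dataclass(frozen=True)
class ReferenceFoldChanges:
    """Per-gene reference log2FC with the per-condition normalized means.

    ``log2fc`` may be +/-inf when exactly one condition's mean is zero; a gene
    with zero mean in both conditions carries log2fc 0.0 and is flagged in
    ``both_zero`` (such genes enter the benchmark universe only at T = 0).
    """

    table: pd.DataFrame  # columns: log2fc, mean_cond1, mean_cond2, both_zero
    conditions: tuple[str, str]

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]

    @property
    def both_zero(self) -> pd.Series:
        return self.table["both_zero"]

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# log2fc = log2(mean[{self.conditions[1]}] / "
                     f"mean[{self.conditions[0]}])\n")
            self.table.to_csv(fh, sep="\t")


def reference_log2fc(cm: CountMatrix, design: ExperimentDesign) -> ReferenceFoldChanges:
    """Reference log2 fold change per gene from mean normalized counts."""
    design.check_matches(cm)
    sf = size_factors(cm)
    norm = normalize(cm, sf)
    c1, c2 = design.conditions
    m1 = norm[design.samples_in(c1)].mean(axis=1)
    m2 = norm[design.samples_in(c2)].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(m2.to_numpy()) - np.log2(m1.to_numpy())
    both_zero = (m1.to_numpy() == 0) & (m2.to_numpy() == 0)
    lfc[both_zero] = 0.0
    table = pd.DataFrame(
        {"log2fc": lfc, "mean_cond1": m1, "mean_cond2": m2, "both_zero": both_zero},
        index=cm.data.index,
    )
    return ReferenceFoldChanges(table=table, conditions=(c1, c2))
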