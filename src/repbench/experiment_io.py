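"""Count-matrix and design-table IO plus basic replicate QC.

The canonical in-memory containers are thin wrappers around pandas objects:
a :class:`CountMatrix` is a genes x samples integer DataFrame with stable
row/column order, and an :class:`ExperimentDesign` maps each sample to one of
exactly two condition labels.  Gene order in the matrix defines vector order
for every downstream operation (reference fold changes, SDE vectors,
confusion counting), so it is never silently re-sorted.

Supported on-disk formats
-------------------------
* Matrix TSV: first column ``gene_id``, one column per sample, header row.
* Per-sample TSV: two columns ``gene_id TAB count``, no header (htseq-count
  output).  htseq-count summary rows beginning with ``__`` (``__no_feature``
  etc.) are dropped with a logged warning.
* Design TSV: ``sample_id TAB condition`` with a header row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, DesignError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "ExperimentDesign",
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "replicate_correlation",
]


def _validate_count_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Check integer, non-negative counts and unique identifiers; cast to int64.

    Fractional values are rejected, never rounded: a fractional "count" means
    something upstream already went wrong.
    """
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene_id(s): {dupes[:5]}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample_id(s): {dupes[:5]}")
    values = df.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        raise FormatError("non-numeric count values")
    if np.isnan(values.astype(float)).any():
        raise FormatError("missing count values")
    if (values < 0).any():
        raise FormatError("negative count values")
    if not np.issubdtype(values.dtype, np.integer):
        if values.size and np.any(values != np.floor(values)):
            raise FormatError("fractional count values (counts must be integers)")
    return df.astype(np.int64)


@dataclass(frozen=True)
class CountMatrix:
    """Gene x sample integer read-count matrix with stable ordering."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        object.__setattr__(self, "data", _validate_count_frame(self.data))
        self.data.index.name = "gene_id"

    @classmethod
    def from_arrays(
        cls,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        counts: np.ndarray | Sequence[Sequence[int]],
    ) -> "CountMatrix":
        frame = pd.DataFrame(np.asarray(counts), index=list(gene_ids), columns=list(sample_ids))
        return cls(frame)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ConsistencyError(f"sample(s) not in matrix: {missing}")
        return CountMatrix(self.data.loc[:, list(sample_ids)])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountMatrix) and self.data.equals(other.data)


@dataclass(frozen=True)
class ExperimentDesign:
    """Sample -> condition assignment for exactly two conditions.

    Condition order follows first appearance in the input; the first condition
    is the reference (denominator) condition for fold changes.
    """

    assignment: Mapping[str, str]
    conditions: tuple[str, str] = field(init=False)

    def __post_init__(self) -> None:
        items = dict(self.assignment)
        object.__setattr__(self, "assignment", items)
        seen: list[str] = []
        for cond in items.values():
            if cond not in seen:
                seen.append(cond)
        if len(seen) != 2:
            raise DesignError(f"need exactly 2 conditions, got {len(seen)}: {seen}")
        for cond in seen:
            n = sum(1 for c in items.values() if c == cond)
            if n < 2:
                raise DesignError(f"condition {cond!r} has {n} sample(s); need >= 2")
        object.__setattr__(self, "conditions", (seen[0], seen[1]))

    @property
    def samples(self) -> list[str]:
        return list(self.assignment)

    def samples_in(self, condition: str) -> list[str]:
        if condition not in self.conditions:
            raise DesignError(f"unknown condition {condition!r}")
        return [s for s, c in self.assignment.items() if c == condition]

    def condition_of(self, sample: str) -> str:
        try:
            return self.assignment[sample]
        except KeyError:
            raise DesignError(f"unknown sample {sample!r}") from None

    def check_matches(self, cm: CountMatrix) -> None:
        """Raise ConsistencyError unless design samples == matrix samples."""
        d, m = set(self.samples), set(cm.sample_ids)
        if d != m:
            raise ConsistencyError(
                f"design/matrix sample mismatch: only-in-design={sorted(d - m)[:5]}, "
                f"only-in-matrix={sorted(m - d)[:5]}"
            )

    def subset(self, sample_ids: Sequence[str]) -> "ExperimentDesign":
        return ExperimentDesign({s: self.condition_of(s) for s in sample_ids})


def read_counts(
    path: str | Path | Sequence[str | Path],
    layout: str = "matrix",
) -> CountMatrix:
    """Read a count matrix from a matrix TSV or a set of per-sample TSVs.

    Parameters
    ----------
    path
        For ``layout="matrix"`` a single TSV path.  For
        ``layout="per-sample"`` a sequence of two-column htseq-count-style
        files; the sample id is each file's stem and all files must share an
        identical gene universe.
    """
    if layout == "matrix":
        if isinstance(path, (list, tuple)):
            raise FormatError("matrix layout takes a single path")
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = _drop_htseq_special(df, str(path))
        return CountMatrix(df)
    if layout == "per-sample":
        paths = [path] if isinstance(path, (str, Path)) else list(path)
        if not paths:
            raise FormatError("no per-sample files given")
        columns: dict[str, pd.Series] = {}
        ref_index: pd.Index | None = None
        for p in paths:
            p = Path(p)
            tbl = pd.read_csv(p, sep="\t", header=None, names=["gene_id", "count"])
            tbl = tbl.set_index("gene_id")
            if tbl.index.has_duplicates:
                raise FormatError(f"duplicate gene_id in {p}")
            tbl = _drop_htseq_special(tbl, str(p))
            if ref_index is None:
                ref_index = tbl.index
            elif set(tbl.index) != set(ref_index):
                raise ConsistencyError(
                    f"gene universe of {p} differs from {paths[0]}"
                )
            columns[p.stem] = tbl["count"].reindex(ref_index)
        df = pd.DataFrame(columns, index=ref_index)
        return CountMatrix(df)
    raise FormatError(f"unknown layout {layout!r}")


def _drop_htseq_special(df: pd.DataFrame, source: str) -> pd.DataFrame:
    special = [g for g in df.index if str(g).startswith("__")]
    if special:
        logger.warning("dropping %d htseq-count summary row(s) from %s: %s",
                       len(special), source, special)
        df = df.drop(index=special)
    return df


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.data.to_csv(path, sep="\t")


def read_design(path: str | Path) -> ExperimentDesign:
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise FormatError("design table needs two columns: sample_id, condition")
    samples = df.iloc[:, 0].astype(str)
    conditions = df.iloc[:, 1].astype(str)
    if samples.duplicated().any():
        raise DesignError(f"duplicate sample(s) in design: "
                          f"{samples[samples.duplicated()].tolist()}")
    return ExperimentDesign(dict(zip(samples, conditions)))


def write_design(design: ExperimentDesign, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": design.samples,
         "condition": [design.condition_of(s) for s in design.samples]}
    ).to_csv(path, sep="\t", index=False)


def replicate_correlation(
    cm: CountMatrix, design: ExperimentDesign, condition: str
) -> pd.DataFrame:
    """Pairwise Pearson correlation of raw gene-count vectors within a condition.

    Returns a symmetric samples x samples table with unit diagonal.  Pairs
    involving a zero-variance (constant) count vector are undefined and
    reported as NaN.
    """
    samples = design.samples_in(condition)
    if len(samples) < 2:
        raise DesignError(f"condition {condition!r} has fewer than 2 samples")
    x = cm.data.loc[:, samples].to_numpy(dtype=float).T  # samples x genes
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centered @ centered.T) / np.outer(norms, norms)
    r[np.outer(norms == 0, np.ones(len(samples), dtype=bool))] = np.nan
    r[np.outer(np.ones(len(samples), dtype=bool), norms == 0)] = np.nan
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=samples, columns=samples)
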