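"""Concordance of SDE call vectors across callers: clustering with AU support.

Each caller's result is reduced to a binary vector over the gene universe
(1 = SDE), vectors are compared by correlation distance d = 1 - Pearson r
(range [0, 2]), hierarchically clustered with complete linkage, and every
branch of the dendrogram is annotated with two support percentages obtained
by resampling genes with replacement:

* BP% — the classical bootstrap proportion: the fraction of same-size
  resampled matrices whose clustering contains the branch's leaf set;
* AU% — the approximately unbiased support from multiscale bootstrap:
  BP is measured at several resampling sizes r*G (r in 0.5..1.4 by
  default), the probit transform z_r = Phi^-1(1 - BP_r) is fit by least
  squares to  z_r = v*sqrt(r) + c/sqrt(r),  and AU = (1 - Phi(v - c)) * 100.

A branch present in every replicate at every scale is saturated and clamped
to AU = 100; a branch absent everywhere is clamped to AU = 0.  z is clamped
to +/-8 before fitting so the regression stays finite at BP near 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .de_tests import DEResult
from .errors import ConsistencyError, ConstantRowError

__all__ = [
    "sde_matrix", "correlation_distance", "complete_linkage", "Dendrogram",
    "au_support", "fit_au", "DEFAULT_SCALES",
]

DEFAULT_SCALES: tuple[float, ...] = tuple(np.round(np.arange(0.5, 1.45, 0.1), 1))
_Z_CLAMP = 8.0


def sde_matrix(results: Mapping[str, DEResult]) -> pd.DataFrame:
    """Binary callers x genes matrix of SDE calls (gene order = input order)."""
    if len(results) < 2:
        raise ConsistencyError("need >= 2 result sets")
    names = list(results)
    universe = results[names[0]].gene_ids
    rows = {}
    for name in names:
        res = results[name]
        if res.gene_ids != universe:
            raise ConsistencyError(f"gene universe of {name!r} differs")
        rows[name] = res.sde.to_numpy(dtype=bool).astype(np.int8)
    return pd.DataFrame(rows, index=universe).T


def _corr_rows(x: np.ndarray, strict: bool, labels: Sequence[str] | None = None
               ) -> np.ndarray:
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    if strict and (norms == 0).any():
        bad = [labels[i] if labels is not None else str(i)
               for i in np.flatnonzero(norms == 0)]
        raise ConstantRowError(
            f"constant SDE vector(s) {bad}: correlation undefined; "
            "drop them explicitly before clustering"
        )
    safe = np.where(norms == 0, 1.0, norms)
    r = (centered @ centered.T) / np.outer(safe, safe)
    r[norms == 0, :] = 0.0   # tolerant mode: undefined correlation -> 0
    r[:, norms == 0] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def correlation_distance(m: pd.DataFrame) -> pd.DataFrame:
    """d(a, b) = 1 - Pearson r of the two rows; rejects constant rows."""
    r = _corr_rows(m.to_numpy(dtype=float), strict=True, labels=list(m.index))
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(np.maximum(d, 0.0), index=m.index, columns=m.index)


@dataclass(frozen=True)
class Dendrogram:
    """Complete-linkage merge tree over labelled items.

    ``merges`` is the scipy linkage matrix; ``labels`` maps leaf index to
    item name.  ``branches()`` yields every internal node's leaf set with its
    merge height (merge order follows scipy's deterministic tie handling).
    """

    merges: np.ndarray
    labels: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def branches(self) -> list[tuple[frozenset, float]]:
        n = self.n_leaves
        members: dict[int, frozenset] = {i: frozenset([self.labels[i]])
                                         for i in range(n)}
        out = []
        for k, (a, b, height, _) in enumerate(self.merges):
            leaves = members[int(a)] | members[int(b)]
            members[n + k] = leaves
            out.append((leaves, float(height)))
        return out

    def to_newick(self, branch_labels: Mapping[frozenset, str] | None = None
                  ) -> str:
        """Newick string; internal nodes optionally labelled (e.g. 'AU/BP')."""
        n = self.n_leaves
        members: dict[int, frozenset] = {i: frozenset([self.labels[i]])
                                         for i in range(n)}
        heights: dict[int, float] = {i: 0.0 for i in range(n)}
        text: dict[int, str] = {i: self.labels[i] for i in range(n)}
        for k, (a, b, height, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            node = n + k
            members[node] = members[a] | members[b]
            heights[node] = float(height)
            la = max(0.0, float(height) - heights[a])
            lb = max(0.0, float(height) - heights[b])
            label = ""
            if branch_labels is not None:
                label = branch_labels.get(members[node], "")
            text[node] = f"({text[a]}:{la:g},{text[b]}:{lb:g}){label}"
        root = n + len(self.merges) - 1
        return text[root] + ";"


def complete_linkage(d: pd.DataFrame) -> Dendrogram:
    """Agglomerative clustering with maximum inter-cluster distance."""
    mat = d.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1] or mat.shape[0] < 2:
        raise ConsistencyError("distance matrix must be square with >= 2 items")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ConsistencyError("distance matrix must be symmetric")
    Z = linkage(squareform(mat, checks=False), method="complete")
    return Dendrogram(merges=Z, labels=tuple(d.index))


def fit_au(bp_by_scale: Sequence[float], scales: Sequence[float]
           ) -> tuple[float, float, float]:
    """Fit the multiscale-bootstrap model to one branch's BP curve.

    Returns (v, c, AU) where z_r = Phi^-1(1 - BP_r) ~ v*sqrt(r) + c/sqrt(r)
    and AU = 1 - Phi(v - c), on the probability scale (0..1).  Saturated
    curves (BP = 1 or BP = 0 at every scale) clamp to AU = 1 or 0.
    """
    bp = np.asarray(bp_by_scale, dtype=float)
    r = np.asarray(scales, dtype=float)
    if bp.shape != r.shape or bp.ndim != 1:
        raise ValueError("bp and scales must be 1-D and the same length")
    if np.all(bp == 1.0):
        return float("nan"), float("nan"), 1.0
    if np.all(bp == 0.0):
        return float("nan"), float("nan"), 0.0
    z = np.clip(stats.norm.ppf(1.0 - bp), -_Z_CLAMP, _Z_CLAMP)
    X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    (v, c), *_ = np.linalg.lstsq(X, z, rcond=None)
    au = float(1.0 - stats.norm.cdf(v - c))
    return float(v), float(c), au


def au_support(
    m: pd.DataFrame,
    scales: Sequence[float] = DEFAULT_SCALES,
    B: int = 1000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-branch BP% and AU% for the complete-linkage tree of ``m``.

    Genes (columns) are resampled with replacement, size round(r * G) per
    scale r, B replicates per scale.  Rows that become constant in a
    replicate are tolerated (their correlations are treated as 0).
    Returns one row per internal branch of the reference dendrogram with
    columns ``leaves`` (sorted tuple), ``bp`` and ``au`` (percent), ``v``,
    ``c`` and ``saturated``.
    """
    if rng is None:
        rng = np.random.default_rng()
    if B < 1:
        raise ValueError("B must be >= 1")
    x = m.to_numpy(dtype=float)
    labels = list(m.index)
    G = x.shape[1]
    ref_tree = complete_linkage(correlation_distance(m))
    ref_branches = [leaves for leaves, _ in ref_tree.branches()]
    scales = [float(s) for s in scales]
    hits = np.zeros((len(ref_branches), len(scales)))
    for si, r in enumerate(scales):
        size = max(2, int(round(r * G)))
        for _ in range(B):
            idx = rng.integers(0, G, size=size)
            sub = x[:, idx]
            corr = _corr_rows(sub, strict=False)
            d = np.maximum(1.0 - corr, 0.0)
            np.fill_diagonal(d, 0.0)
            d = (d + d.T) / 2.0
            Z = linkage(squareform(d, checks=False), method="complete")
            boot = Dendrogram(merges=Z, labels=tuple(labels))
            boot_sets = {leaves for leaves, _ in boot.branches()}
            for bi, branch in enumerate(ref_branches):
                if branch in boot_sets:
                    hits[bi, si] += 1
    bp = hits / B
    rows = []
    scale1 = scales.index(1.0) if 1.0 in scales else int(np.argmin(
        np.abs(np.asarray(scales) - 1.0)))
    for bi, branch in enumerate(ref_branches):
        v, c, au = fit_au(bp[bi], scales)
        rows.append({
            "leaves": tuple(sorted(branch)),
            "bp": 100.0 * bp[bi, scale1],
            "au": 100.0 * au,
            "v": v, "c": c,
            "saturated": bool(np.all(bp[bi] == 1.0)),
            "absent": bool(np.all(bp[bi] == 0.0)),
        })
    return pd.DataFrame(rows)
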