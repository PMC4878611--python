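"""Replicate-subsampling benchmark: gold standards, bootstrap sweeps, rates.

The benchmark answers "how well does a DE caller with n_r replicates agree
with the same caller given all replicates?".  The workflow is:

1. ``compute_gold_standard`` — run the caller on the full clean matrix; SDE
   at adjusted p <= alpha defines that caller's reference truth; attach the
   tool-independent reference log2 fold changes from the same full matrix.
2. ``run_bootstrap`` — i independent subselections of n_r replicates per
   condition (without replacement), caller re-run on each submatrix with
   size factors recomputed per submatrix.
3. ``confusion``/``rates`` — per iteration, restricted to genes whose
   |reference log2FC| >= T, count TP/FP/TN/FN against the gold standard,
   then average across iterations:

       TPR = TP/(TP+FN)   FPR = FP/(FP+TN)
       TNR = TN/(TN+FP)   FNR = FN/(FN+TP)

   with SDs propagated from the count SDs by the first-order delta method
   (count covariances neglected).
4. ``null_fpr_distribution`` — two disjoint pseudo-condition groups drawn
   from a single condition, where every SDE call is a false positive by
   construction.
5. ``tpr_breakpoint`` — two-segment continuous piecewise-linear fit of the
   TPR-vs-threshold curve, locating the transition between the shallow
   high-threshold and steep low-threshold regimes.

Seeding: a master seed deterministically yields one child seed per
iteration (recorded in the run), so any single iteration can be reproduced
in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .de_tests import DEResult, TestConfig, run_caller
from .errors import BenchmarkError, ConsistencyError
from .experiment_io import CountMatrix, ExperimentDesign
from .normalization import ReferenceFoldChanges, reference_log2fc

logger = logging.getLogger(__name__)

__all__ = [
    "GoldStandard", "BootstrapRun", "ConfusionSummary", "RateCurve",
    "compute_gold_standard", "subselect", "run_bootstrap",
    "representative_stats", "fraction_sde", "confusion", "rates",
    "null_split", "null_fpr_distribution", "tpr_breakpoint",
    "distribution_summary",
]


@dataclass(frozen=True)
class GoldStandard:
    caller: str
    result: DEResult
    ref_fc: ReferenceFoldChanges
    alpha: float

    @property
    def sde(self) -> pd.Series:
        return self.result.sde


@dataclass(frozen=True)
class BootstrapRun:
    caller: str
    n_r: int
    iterations: tuple[DEResult, ...]
    selections: tuple[tuple[str, ...], ...]
    seeds: tuple[int, ...]
    master_seed: int | None
    n_failed: int = 0

    @property
    def i(self) -> int:
        return len(self.iterations)


@dataclass(frozen=True)
class ConfusionSummary:
    """Per-iteration TP/FP/TN/FN counts at one (n_r, T) cell plus summaries."""

    caller: str
    n_r: int
    T: float
    per_iteration: pd.DataFrame   # columns TP, FP, TN, FN, one row per iteration
    universe_size: int

    @property
    def means(self) -> pd.Series:
        return self.per_iteration.mean()

    @property
    def sds(self) -> pd.Series:
        if len(self.per_iteration) < 2:
            return pd.Series(0.0, index=self.per_iteration.columns)
        return self.per_iteration.std(ddof=1)


@dataclass(frozen=True)
class RateCurve:
    """TPR/FPR/TNR/FNR (from mean counts) with delta-method SDs."""

    caller: str
    n_r: int
    T: float
    values: dict[str, float]
    sds: dict[str, float]
    universe_size: int


def compute_gold_standard(
    cm_full: CountMatrix,
    design: ExperimentDesign,
    caller: str,
    cfg: TestConfig | None = None,
) -> GoldStandard:
    """Caller's SDE set on the full clean matrix plus reference fold changes."""
    if cfg is None:
        cfg = TestConfig()
    result = run_caller(caller, cm_full, design, cfg)
    ref = reference_log2fc(cm_full, design)
    return GoldStandard(caller=caller, result=result, ref_fc=ref, alpha=cfg.alpha)


def subselect(
    design: ExperimentDesign, n_r: int, rng: np.random.Generator
) -> list[str]:
    """n_r distinct samples per condition, drawn without replacement."""
    chosen: list[str] = []
    for cond in design.conditions:
        pool = design.samples_in(cond)
        if n_r > len(pool):
            raise BenchmarkError(
                f"n_r={n_r} exceeds condition {cond!r} size {len(pool)}"
            )
        idx = rng.choice(len(pool), size=n_r, replace=False)
        chosen.extend(pool[k] for k in idx)
    return chosen


def _child_seeds(master_seed: int | None, i: int) -> np.ndarray:
    rng = np.random.default_rng(master_seed)
    return rng.integers(0, 2**31 - 1, size=i)


def run_bootstrap(
    cm: CountMatrix,
    design: ExperimentDesign,
    caller: str,
    n_r: int,
    i: int,
    cfg: TestConfig | None = None,
    seed: int | None = None,
) -> BootstrapRun:
    """i independent subselections of n_r replicates per condition, caller
    re-run on each submatrix (size factors recomputed per submatrix)."""
    if cfg is None:
        cfg = TestConfig()
    seeds = _child_seeds(seed, i)
    iterations: list[DEResult] = []
    selections: list[tuple[str, ...]] = []
    used_seeds: list[int] = []
    n_failed = 0
    for k in range(i):
        child = int(seeds[k])
        rng = np.random.default_rng(child)
        samples = subselect(design, n_r, rng)
        sub_cm = cm.subset_samples(samples)
        sub_design = design.subset(samples)
        try:
            res = run_caller(caller, sub_cm, sub_design,
                             replace(cfg, seed=child))
        except Exception:  # caller failure: flag and exclude, keep going
            n_failed += 1
            logger.exception("caller %s failed on iteration %d (seed %d)",
                             caller, k, child)
            continue
        iterations.append(res)
        selections.append(tuple(samples))
        used_seeds.append(child)
    if n_failed:
        logger.warning("%d/%d iterations failed and were excluded", n_failed, i)
    return BootstrapRun(
        caller=caller, n_r=n_r, iterations=tuple(iterations),
        selections=tuple(selections), seeds=tuple(used_seeds),
        master_seed=seed, n_failed=n_failed,
    )


def representative_stats(run: BootstrapRun) -> pd.DataFrame:
    """Per-gene mean log2FC and median adjusted p across iterations.

    Infinite log2FC values are excluded from the mean (exclusion counted in
    ``n_inf_excluded``); missing p_adj are excluded from the median.  The
    even-count median is the midpoint of the two central values.
    """
    if not run.iterations:
        raise BenchmarkError("no valid iterations")
    lfc = pd.concat([r.table["log2fc"] for r in run.iterations], axis=1)
    padj = pd.concat([r.table["p_adj"] for r in run.iterations], axis=1)
    finite = lfc.replace([np.inf, -np.inf], np.nan)
    return pd.DataFrame({
        "mean_log2fc": finite.mean(axis=1),
        "n_inf_excluded": lfc.apply(np.isinf).sum(axis=1),
        "median_p_adj": padj.median(axis=1),
    })


def distribution_summary(values: np.ndarray) -> dict[str, float]:
    """Boxplot-style summary: median, quartiles and central 95% limits."""
    q = np.percentile(values, [2.5, 25, 50, 75, 97.5])
    return {"lo95": float(q[0]), "q1": float(q[1]), "median": float(q[2]),
            "q3": float(q[3]), "hi95": float(q[4])}


def fraction_sde(run: BootstrapRun) -> tuple[np.ndarray, dict[str, float]]:
    """Per-iteration fraction of genes called SDE plus its summary."""
    if not run.iterations:
        raise BenchmarkError("no valid iterations")
    fractions = np.array([r.sde.mean() for r in run.iterations])
    return fractions, distribution_summary(fractions)


def confusion(run: BootstrapRun, gold: GoldStandard, T: float) -> ConfusionSummary:
    """Confusion counts vs the gold standard, restricted per iteration to
    genes with |reference log2FC| >= T (infinite magnitudes always pass)."""
    if run.caller != gold.caller:
        raise ConsistencyError(
            f"run caller {run.caller!r} != gold caller {gold.caller!r}"
        )
    if not run.iterations:
        raise BenchmarkError("no valid iterations")
    gold_genes = gold.result.gene_ids
    universe = np.abs(gold.ref_fc.log2fc.to_numpy()) >= T
    n_universe = int(universe.sum())
    if n_universe == 0:
        raise BenchmarkError(f"no genes with |reference log2FC| >= {T}")
    gold_sde = gold.sde.to_numpy(dtype=bool)[universe]
    rows = []
    for res in run.iterations:
        if res.gene_ids != gold_genes:
            raise ConsistencyError("iteration gene universe differs from gold")
        run_sde = res.sde.to_numpy(dtype=bool)[universe]
        tp = int(np.sum(run_sde & gold_sde))
        fp = int(np.sum(run_sde & ~gold_sde))
        fn = int(np.sum(~run_sde & gold_sde))
        tn = int(np.sum(~run_sde & ~gold_sde))
        rows.append((tp, fp, tn, fn))
    per_iter = pd.DataFrame(rows, columns=["TP", "FP", "TN", "FN"])
    return ConfusionSummary(caller=run.caller, n_r=run.n_r, T=T,
                            per_iteration=per_iter, universe_size=n_universe)


def _delta_ratio_sd(a: float, b: float, sa: float, sb: float) -> float:
    """SD of a/(a+b) from SDs of a and b, first-order delta method,
    covariance neglected."""
    denom = (a + b) ** 2
    if denom == 0:
        return float("nan")
    return float(np.sqrt((b * sa) ** 2 + (a * sb) ** 2) / denom)


def rates(conf: ConfusionSummary) -> RateCurve:
    """TPR/FPR/TNR/FNR on mean counts with propagated SDs.

    A rate whose denominator is zero is NaN (undefined), never reported as 0.
    """
    m, s = conf.means, conf.sds
    pairs = {"TPR": ("TP", "FN"), "FPR": ("FP", "TN"),
             "TNR": ("TN", "FP"), "FNR": ("FN", "TP")}
    values: dict[str, float] = {}
    sds: dict[str, float] = {}
    for rate, (num, other) in pairs.items():
        denom = m[num] + m[other]
        values[rate] = float(m[num] / denom) if denom > 0 else float("nan")
        sds[rate] = _delta_ratio_sd(m[num], m[other], s[num], s[other])
    return RateCurve(caller=conf.caller, n_r=conf.n_r, T=conf.T,
                     values=values, sds=sds, universe_size=conf.universe_size)


def null_split(
    design: ExperimentDesign, condition: str, n_r: int,
    rng: np.random.Generator,
) -> tuple[list[str], list[str]]:
    """Two disjoint groups of n_r samples drawn without replacement from one
    condition (the pseudo-conditions of the null false-positive test)."""
    pool = design.samples_in(condition)
    if 2 * n_r > len(pool):
        raise BenchmarkError(
            f"2*n_r={2 * n_r} exceeds condition {condition!r} size {len(pool)}"
        )
    idx = rng.choice(len(pool), size=2 * n_r, replace=False)
    return [pool[j] for j in idx[:n_r]], [pool[j] for j in idx[n_r:]]


def null_fpr_distribution(
    cm: CountMatrix,
    design: ExperimentDesign,
    condition: str,
    caller: str,
    n_r: int,
    i: int,
    cfg: TestConfig | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, dict[str, float]]:
    """Null-split false-positive test within a single condition.

    Per iteration, two disjoint groups of n_r samples are drawn without
    replacement from ``condition``; with no true expression change between
    them, every SDE call is a false positive.  Returns the per-iteration
    false-positive fraction and its boxplot-style summary.
    """
    if cfg is None:
        cfg = TestConfig()
    pool = design.samples_in(condition)
    if 2 * n_r > len(pool):
        raise BenchmarkError(
            f"2*n_r={2 * n_r} exceeds condition {condition!r} size {len(pool)}"
        )
    seeds = _child_seeds(seed, i)
    fractions = np.empty(i)
    for k in range(i):
        child = int(seeds[k])
        rng = np.random.default_rng(child)
        group_a, group_b = null_split(design, condition, n_r, rng)
        pseudo = ExperimentDesign(
            {**{s: "groupA" for s in group_a}, **{s: "groupB" for s in group_b}}
        )
        sub_cm = cm.subset_samples(group_a + group_b)
        res = run_caller(caller, sub_cm, pseudo, replace(cfg, seed=child))
        fractions[k] = res.sde.mean()
    return fractions, distribution_summary(fractions)


@dataclass(frozen=True)
class BreakpointFit:
    T_star: float
    sse: float
    degenerate: bool
    left_slope: float
    right_slope: float


def tpr_breakpoint(T_grid: Sequence[float], tpr: Sequence[float]) -> BreakpointFit:
    """Two-segment continuous piecewise-linear least-squares fit.

    Candidate breakpoints are interior grid points with at least two points
    on each side; the breakpoint minimising total SSE wins, ties going to the
    smallest T.  A flat SSE profile (e.g. an exactly straight line) is
    flagged ``degenerate`` and returns the smallest candidate.
    """
    t = np.asarray(T_grid, dtype=float)
    y = np.asarray(tpr, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise BenchmarkError("T grid and TPR values must be 1-D and same length")
    if len(t) < 4:
        raise BenchmarkError("need >= 4 grid points for a two-segment fit")
    if not np.all(np.diff(t) > 0):
        raise BenchmarkError("T grid must be strictly increasing")
    best: tuple[float, float, np.ndarray] | None = None
    sses = []
    for k in range(1, len(t) - 1):
        knot = t[k]
        X = np.column_stack([np.ones_like(t), t, np.maximum(t - knot, 0.0)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(np.sum((y - X @ coef) ** 2))
        sses.append(sse)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, knot, coef)
    assert best is not None
    sse, knot, coef = best
    spread = max(sses) - min(sses)
    degenerate = spread <= 1e-10 * (1.0 + abs(min(sses)))
    return BreakpointFit(T_star=float(knot), sse=sse, degenerate=degenerate,
                         left_slope=float(coef[1]),
                         right_slope=float(coef[1] + coef[2]))
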