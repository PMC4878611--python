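"""Classical per-gene differential-expression tests and the caller registry.

Five standard two-sample statistics are implemented for gene count vectors
``x1`` (condition 1) and ``x2`` (condition 2):

* pooled-variance t-test:  t = (x̄1 − x̄2) / sqrt(s12² (1/n1 + 1/n2)),
  s12² = [(n1−1)s1² + (n2−1)s2²]/ν, ν = n1 + n2 − 2;
* log-ratio t-test for log-normal-like data:
  t = (ln x̄1 − ln x̄2) / sqrt(s1²/(n1 x̄1²) + s2²/(n2 x̄2²)), ν as above;
* Mann–Whitney U with the tie-corrected normal approximation (no continuity
  correction);
* permutation test on the difference of means (resampling without
  replacement from the pooled vector);
* Studentized bootstrap test: both groups recentred to the pooled mean
  (the common-mean null), resampled with replacement, and the pooled t
  recomputed per bootstrap replicate.

Resampling p-values default to the plain fraction ``#{|stat*| > |stat|}/B``
(strict inequality); ``smooth=True`` switches to ``(# + 1)/(B + 1)``, which
avoids the degenerate p = 0 under Benjamini–Hochberg adjustment.

Scalar functions operate on single gene vectors; each has a vectorised
``*_matrix`` twin operating on genes x replicates arrays, which is what the
registered callers use (a 7000-gene matrix test is a single numpy pass, not
7000 python calls).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, ContractError, RegistryError
from .experiment_io import CountMatrix, ExperimentDesign
from .normalization import normalize, reference_log2fc, size_factors

__all__ = [
    "TestConfig", "DEResult",
    "t_test", "log_ratio_t_test", "mann_whitney", "permutation_test",
    "studentized_bootstrap_test", "bh_adjust",
    "register_caller", "available_callers", "run_caller",
]


@dataclass(frozen=True)
class TestConfig:
    """Shared configuration for the built-in callers.

    ``input_scale`` chooses whether tests see raw counts or
    size-factor-normalized counts (default, since the external tools the
    benchmark compares against normalize internally).
    """

    alpha: float = 0.05
    B: int = 1000
    seed: int | None = None
    input_scale: str = "normalized"  # "raw" | "normalized"
    smooth: bool = False

    def __post_init__(self) -> None:
        errors = []
        if not 0.0 < self.alpha < 1.0:
            errors.append(f"alpha must be in (0,1), got {self.alpha}")
        if self.B < 1:
            errors.append(f"B must be >= 1, got {self.B}")
        if self.input_scale not in ("raw", "normalized"):
            errors.append(f"input_scale must be raw|normalized, got {self.input_scale!r}")
        if errors:
            raise ConfigError(errors)


@dataclass(frozen=True)
class DEResult:
    """Per-gene DE call table: log2fc, p, p_adj, sde (one row per input gene)."""

    table: pd.DataFrame
    caller: str
    config: TestConfig

    @property
    def sde(self) -> pd.Series:
        return self.table["sde"]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            c = self.config
            fh.write(f"# caller={self.caller} alpha={c.alpha} B={c.B} "
                     f"seed={c.seed} input_scale={c.input_scale} smooth={c.smooth}\n")
            self.table.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# vectorised statistic cores (genes x replicates arrays)
# ---------------------------------------------------------------------------

def _as_matrix(x) -> np.ndarray:
    return np.atleast_2d(np.asarray(x, dtype=float))


def pooled_t_matrix(X1: np.ndarray, X2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-variance t and two-sided p per row; zero-variance rows follow
    the convention t=0,p=1 (equal means) / |t|=inf,p=0 (separated means)."""
    n1, n2 = X1.shape[1], X2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("pooled t-test needs >= 2 replicates per condition")
    df = n1 + n2 - 2
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    v1, v2 = X1.var(axis=1, ddof=1), X2.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    degenerate = se == 0
    t[degenerate & (diff == 0)] = 0.0
    t[degenerate & (diff != 0)] = np.sign(diff[degenerate & (diff != 0)]) * np.inf
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[degenerate & (diff == 0)] = 1.0
    p[degenerate & (diff != 0)] = 0.0
    return t, p


def log_ratio_t_matrix(X1: np.ndarray, X2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Log-ratio t and two-sided p per row; rows with a non-positive mean in
    either condition get NaN (result missing, never substituted)."""
    n1, n2 = X1.shape[1], X2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("log-ratio t-test needs >= 2 replicates per condition")
    df = n1 + n2 - 2
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    v1, v2 = X1.var(axis=1, ddof=1), X2.var(axis=1, ddof=1)
    valid = (m1 > 0) & (m2 > 0)
    t = np.full(X1.shape[0], np.nan)
    p = np.full(X1.shape[0], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(v1 / (n1 * m1 ** 2) + v2 / (n2 * m2 ** 2))
        diff = np.log(m1) - np.log(m2)
        tv = diff / se
    degenerate = valid & (se == 0)
    ok = valid & (se > 0)
    t[ok] = tv[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(tv[ok]), df)
    eq = degenerate & (diff == 0)
    ne = degenerate & (diff != 0)
    t[eq], p[eq] = 0.0, 1.0
    t[ne], p[ne] = np.sign(diff[ne]) * np.inf, 0.0
    return t, p


def mann_whitney_matrix(X1: np.ndarray, X2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mann–Whitney U (of the first sample) and the tie-corrected normal
    approximation two-sided p per row.  All-tied rows get p = 1."""
    n1, n2 = X1.shape[1], X2.shape[1]
    N = n1 + n2
    X = np.concatenate([X1, X2], axis=1)
    ranks = stats.rankdata(X, axis=1)
    R1 = ranks[:, :n1].sum(axis=1)
    U = R1 - n1 * (n1 + 1) / 2.0
    # tie correction per row: sum over tie groups of (t^3 - t)
    Xs = np.sort(X, axis=1)
    tie_term = np.zeros(X.shape[0])
    for i in range(X.shape[0]):
        _, counts = np.unique(Xs[i], return_counts=True)
        tie_term[i] = np.sum(counts.astype(float) ** 3 - counts)
    var_u = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    mu_u = n1 * n2 / 2.0
    z = np.zeros(X.shape[0])
    nz = var_u > 0
    z[nz] = (U[nz] - mu_u) / np.sqrt(var_u[nz])
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[~nz] = 1.0
    return U, np.minimum(p, 1.0)


def permutation_matrix(
    X1: np.ndarray, X2: np.ndarray, B: int, rng: np.random.Generator,
    smooth: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation difference-of-means test per row.

    One set of B column permutations is shared across all rows (per-row the
    null distribution is identical in law to independent resampling; sharing
    makes the matrix path a handful of numpy gathers).
    """
    n1, n2 = X1.shape[1], X2.shape[1]
    N = n1 + n2
    X = np.concatenate([X1, X2], axis=1)
    D = X1.mean(axis=1) - X2.mean(axis=1)
    exceed = np.zeros(X.shape[0], dtype=np.int64)
    for _ in range(B):
        perm = rng.permutation(N)
        Dstar = X[:, perm[:n1]].mean(axis=1) - X[:, perm[n1:]].mean(axis=1)
        exceed += np.abs(Dstar) > np.abs(D)
    p = (exceed + 1) / (B + 1) if smooth else exceed / B
    return D, p


def studentized_bootstrap_matrix(
    X1: np.ndarray, X2: np.ndarray, B: int, rng: np.random.Generator,
    smooth: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Studentized bootstrap test per row (shared resampling indices across
    rows, as in :func:`permutation_matrix`).

    Groups are recentred to the pooled mean before resampling with
    replacement, enforcing the common-mean null; a bootstrap replicate with
    zero pooled variance contributes t* = 0.
    """
    n1, n2 = X1.shape[1], X2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("bootstrap test needs >= 2 replicates per condition")
    t_obs, _ = pooled_t_matrix(X1, X2)
    pooled_mean = np.concatenate([X1, X2], axis=1).mean(axis=1, keepdims=True)
    C1 = X1 - X1.mean(axis=1, keepdims=True) + pooled_mean
    C2 = X2 - X2.mean(axis=1, keepdims=True) + pooled_mean
    df = n1 + n2 - 2
    exceed = np.zeros(X1.shape[0], dtype=np.int64)
    for _ in range(B):
        i1 = rng.integers(0, n1, size=n1)
        i2 = rng.integers(0, n2, size=n2)
        S1, S2 = C1[:, i1], C2[:, i2]
        m1, m2 = S1.mean(axis=1), S2.mean(axis=1)
        v1, v2 = S1.var(axis=1, ddof=1), S2.var(axis=1, ddof=1)
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstar = np.where(se > 0, (m1 - m2) / se, 0.0)
        exceed += np.abs(tstar) > np.abs(t_obs)
    p = (exceed + 1) / (B + 1) if smooth else exceed / B
    return t_obs, p


# ---------------------------------------------------------------------------
# scalar API
# ---------------------------------------------------------------------------

def t_test(x1, x2) -> tuple[float, float]:
    """Pooled-variance two-sample t-test (statistic, two-sided p)."""
    t, p = pooled_t_matrix(_as_matrix(x1), _as_matrix(x2))
    return float(t[0]), float(p[0])


def log_ratio_t_test(x1, x2) -> tuple[float, float]:
    """Log-ratio t-test; returns (nan, nan) if either mean is non-positive."""
    t, p = log_ratio_t_matrix(_as_matrix(x1), _as_matrix(x2))
    return float(t[0]), float(p[0])


def mann_whitney(x1, x2) -> tuple[float, float]:
    """Mann–Whitney U test, tie-corrected normal approximation."""
    u, p = mann_whitney_matrix(_as_matrix(x1), _as_matrix(x2))
    return float(u[0]), float(p[0])


def permutation_test(
    x1, x2, B: int = 1000, rng: np.random.Generator | None = None,
    smooth: bool = False, exhaustive: bool = False,
) -> tuple[float, float]:
    """Permutation test on the difference of means.

    With ``exhaustive=True`` all C(n1+n2, n1) assignments of the pooled values
    to group 1 are enumerated instead of sampling B random permutations
    (B is then ignored).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 + n2 < 2:
        raise ValueError("need at least 2 values in total")
    pooled = np.concatenate([x1, x2])
    D = x1.mean() - x2.mean()
    if exhaustive:
        from itertools import combinations

        total = pooled.sum()
        exceed = 0
        count = 0
        for idx in combinations(range(n1 + n2), n1):
            s1 = pooled[list(idx)].sum()
            Dstar = s1 / n1 - (total - s1) / n2
            exceed += abs(Dstar) > abs(D)
            count += 1
        p = (exceed + 1) / (count + 1) if smooth else exceed / count
        return float(D), float(p)
    if rng is None:
        rng = np.random.default_rng()
    exceed = 0
    for _ in range(B):
        perm = rng.permutation(pooled)
        Dstar = perm[:n1].mean() - perm[n1:].mean()
        exceed += abs(Dstar) > abs(D)
    p = (exceed + 1) / (B + 1) if smooth else exceed / B
    return float(D), float(p)


def studentized_bootstrap_test(
    x1, x2, B: int = 1000, rng: np.random.Generator | None = None,
    smooth: bool = False,
) -> tuple[float, float]:
    """Studentized bootstrap test under the common-mean null."""
    if rng is None:
        rng = np.random.default_rng()
    t, p = studentized_bootstrap_matrix(_as_matrix(x1), _as_matrix(x2), B, rng,
                                        smooth=smooth)
    return float(t[0]), float(p[0])


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment over the defined entries only.

    NaN entries are excluded from the BH denominator and stay NaN.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        vals = p[mask]
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[mask] = multipletests(vals, method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# caller registry
# ---------------------------------------------------------------------------

# A registered caller maps (X1, X2, cfg, rng) -> p-value vector, where X1/X2
# are genes x replicates float arrays on the scale named by cfg.input_scale.
_CALLERS: dict[str, Callable] = {}


def register_caller(name: str):
    """Decorator registering a p-value function under ``name``."""

    def deco(fn):
        _CALLERS[name] = fn
        return fn

    return deco


def available_callers() -> list[str]:
    return sorted(_CALLERS)


@register_caller("t_test")
def _caller_t(X1, X2, cfg, rng):
    return pooled_t_matrix(X1, X2)[1]


@register_caller("log_ratio_t")
def _caller_lrt(X1, X2, cfg, rng):
    return log_ratio_t_matrix(X1, X2)[1]


@register_caller("mann_whitney")
def _caller_mw(X1, X2, cfg, rng):
    return mann_whitney_matrix(X1, X2)[1]


@register_caller("permutation")
def _caller_perm(X1, X2, cfg, rng):
    return permutation_matrix(X1, X2, cfg.B, rng, smooth=cfg.smooth)[1]


@register_caller("bootstrap_t")
def _caller_boot(X1, X2, cfg, rng):
    return studentized_bootstrap_matrix(X1, X2, cfg.B, rng, smooth=cfg.smooth)[1]


@register_caller("none_reject")
def _caller_none(X1, X2, cfg, rng):
    """Stub caller that never rejects (p = 1 for every gene)."""
    return np.ones(X1.shape[0])


def run_caller(
    name: str,
    cm: CountMatrix,
    design: ExperimentDesign,
    cfg: TestConfig | None = None,
) -> DEResult:
    """Run a registered caller on a (sub)matrix and assemble a DEResult.

    log2fc is the reference log2 fold change recomputed on the supplied
    matrix; p_adj is Benjamini–Hochberg over the defined p-values; a gene is
    SDE iff its p_adj is defined and <= cfg.alpha.
    """
    if cfg is None:
        cfg = TestConfig()
    if name not in _CALLERS:
        raise RegistryError(
            f"unknown caller {name!r}; registered: {available_callers()}"
        )
    design.check_matches(cm)
    ref = reference_log2fc(cm, design)
    if cfg.input_scale == "normalized":
        scaled = normalize(cm, size_factors(cm))
    else:
        scaled = cm.data.astype(float)
    c1, c2 = design.conditions
    X1 = scaled[design.samples_in(c1)].to_numpy()
    X2 = scaled[design.samples_in(c2)].to_numpy()
    rng = np.random.default_rng(cfg.seed)
    p = np.asarray(_CALLERS[name](X1, X2, cfg, rng), dtype=float)
    if p.shape != (cm.n_genes,):
        raise ContractError(
            f"caller {name!r} returned shape {p.shape}, expected ({cm.n_genes},)"
        )
    defined = ~np.isnan(p)
    if ((p[defined] < 0) | (p[defined] > 1)).any():
        raise ContractError(f"caller {name!r} returned p-values outside [0, 1]")
    p_adj = bh_adjust(p)
    sde = np.where(np.isnan(p_adj), False, p_adj <= cfg.alpha)
    table = pd.DataFrame(
        {"log2fc": ref.log2fc, "p": p, "p_adj": p_adj, "sde": sde.astype(bool)},
        index=cm.data.index,
    )
    return DEResult(table=table, caller=name, config=cfg)
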