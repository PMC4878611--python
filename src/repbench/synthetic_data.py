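"""Seeded two-condition negative-binomial experiment generator with known truth.

The generator emulates a highly replicated, low-variability two-condition
bulk RNA-seq experiment in a small, well-annotated genome: ~7126 genes, two
conditions with 40+ biological replicates each, within-condition replicate
Pearson correlation above 0.97, and a majority (60–75%) of genes genuinely
differentially expressed between conditions.

Model
-----
Per gene g: baseline mean mu_g ~ log-normal (median ``mean_median``, log-sd
``mean_log_sd``); NB dispersion phi_g ~ gamma(shape, mean); a DE flag with
probability ``fraction_de``; for DE genes, |log2FC| ~ exponential(mean
``effect_mean``) with a random sign.  Per sample j: a library-size factor
s_j ~ log-uniform(``libsize_low``, ``libsize_high``) applied to the *mean*
(thinning-equivalent), keeping counts integer and NB-distributed.  Counts:

    count[g, j] ~ NB(mean = s_j * mu_{g, cond(j)},
                     var  = mean + phi_g * mean^2)

with mu_{g, cond2} = mu_g * 2^{true_log2fc_g}.  phi = 0 degenerates to
Poisson.  Everything is driven by one mandatory seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ConsistencyError
from .experiment_io import CountMatrix, ExperimentDesign

__all__ = ["GeneratorConfig", "TruthTable", "simulate_experiment",
           "truth_rates", "null_config"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Generator parameters; defaults are frozen calibration values that
    reproduce the emulated experiment's stated summaries (gene count,
    replicate correlation, gold-standard SDE fraction)."""

    seed: int
    n_genes: int = 7126
    n_rep: int = 42
    mean_median: float = 250.0     # median of the log-normal baseline means
    mean_log_sd: float = 1.0       # sd of log(mu)
    dispersion_mean: float = 0.003  # gamma mean of NB dispersion phi
    dispersion_shape: float = 10.0
    fraction_de: float = 0.65
    effect_mean: float = 1.0       # mean of |log2FC| ~ exponential
    libsize_low: float = 0.7
    libsize_high: float = 1.3
    conditions: tuple[str, str] = ("WT", "mut")

    def __post_init__(self) -> None:
        errors = []
        if self.seed is None:
            errors.append("seed is mandatory")
        if self.n_genes < 1:
            errors.append("n_genes must be >= 1")
        if self.n_rep < 2:
            errors.append("n_rep must be >= 2")
        for name in ("mean_median", "mean_log_sd", "dispersion_shape",
                     "effect_mean", "libsize_low", "libsize_high"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be > 0")
        if self.dispersion_mean < 0:
            errors.append("dispersion_mean must be >= 0")
        if not 0.0 <= self.fraction_de <= 1.0:
            errors.append("fraction_de must be in [0, 1]")
        if self.libsize_high < self.libsize_low:
            errors.append("libsize_high must be >= libsize_low")
        if len(set(self.conditions)) != 2:
            errors.append("conditions must be two distinct labels")
        if errors:
            raise ConfigError(errors)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "conditions" in d:
            d["conditions"] = tuple(d["conditions"])
        return cls(**d)


@dataclass(frozen=True)
class TruthTable:
    """Simulator ground truth: per-gene DE status, true log2FC, mean, dispersion."""

    table: pd.DataFrame  # columns: is_de, true_log2fc, base_mean, dispersion

    @property
    def is_de(self) -> pd.Series:
        return self.table["is_de"]

    @property
    def true_log2fc(self) -> pd.Series:
        return self.table["true_log2fc"]

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path) -> "TruthTable":
        t = pd.read_csv(path, sep="\t", index_col=0)
        t["is_de"] = t["is_de"].astype(bool)
        return cls(t)


def simulate_experiment(
    cfg: GeneratorConfig,
) -> tuple[CountMatrix, ExperimentDesign, TruthTable]:
    """Draw a complete two-condition experiment; bitwise-deterministic in cfg."""
    rng = np.random.default_rng(cfg.seed)
    G, R = cfg.n_genes, cfg.n_rep

    mu = np.exp(rng.normal(np.log(cfg.mean_median), cfg.mean_log_sd, size=G))
    if cfg.dispersion_mean > 0:
        phi = rng.gamma(cfg.dispersion_shape,
                        cfg.dispersion_mean / cfg.dispersion_shape, size=G)
    else:
        phi = np.zeros(G)
    is_de = rng.random(G) < cfg.fraction_de
    magnitude = rng.exponential(cfg.effect_mean, size=G)
    sign = rng.choice([-1.0, 1.0], size=G)
    true_lfc = np.where(is_de, sign * magnitude, 0.0)

    libsize = np.exp(rng.uniform(np.log(cfg.libsize_low),
                                 np.log(cfg.libsize_high), size=2 * R))

    mu_cond = np.stack([mu, mu * 2.0 ** true_lfc], axis=1)  # G x 2
    cond_of_sample = np.repeat([0, 1], R)
    means = mu_cond[:, cond_of_sample] * libsize[None, :]   # G x 2R

    counts = np.empty((G, 2 * R), dtype=np.int64)
    nb = phi > 0
    if nb.any():
        n_param = 1.0 / phi[nb]
        p_param = n_param[:, None] / (n_param[:, None] + means[nb])
        counts[nb] = rng.negative_binomial(n_param[:, None], p_param)
    if (~nb).any():
        counts[~nb] = rng.poisson(means[~nb])

    width = max(4, len(str(G)))
    gene_ids = [f"g{i:0{width}d}" for i in range(G)]
    c1, c2 = cfg.conditions
    sample_ids = [f"{c1}_{j + 1:02d}" for j in range(R)] + \
                 [f"{c2}_{j + 1:02d}" for j in range(R)]
    cm = CountMatrix.from_arrays(gene_ids, sample_ids, counts)
    design = ExperimentDesign(
        {s: (c1 if k < R else c2) for k, s in enumerate(sample_ids)}
    )
    truth = TruthTable(pd.DataFrame(
        {"is_de": is_de, "true_log2fc": true_lfc, "base_mean": mu,
         "dispersion": phi},
        index=pd.Index(gene_ids, name="gene_id"),
    ))
    return cm, design, truth


def truth_rates(result, truth: TruthTable, T: float = 0.0) -> dict[str, float]:
    """TPR and FDR of a DEResult against the simulator's ground truth.

    TPR is restricted to truly DE genes with |true_log2fc| >= T; FDR is the
    fraction of SDE calls that are not truly DE.  Rates with a zero
    denominator are NaN.
    """
    sde = result.table["sde"] if hasattr(result, "table") else pd.Series(result)
    if list(sde.index) != list(truth.table.index):
        raise ConsistencyError("result and truth gene universes differ")
    sde = sde.to_numpy(dtype=bool)
    is_de = truth.is_de.to_numpy()
    eligible = is_de & (np.abs(truth.true_log2fc.to_numpy()) >= T)
    tp_t = np.sum(sde & eligible)
    tpr = tp_t / eligible.sum() if eligible.sum() else np.nan
    n_called = sde.sum()
    fdr = np.sum(sde & ~is_de) / n_called if n_called else np.nan
    return {"TPR": float(tpr), "FDR": float(fdr)}


def null_config(cfg: GeneratorConfig) -> GeneratorConfig:
    """Copy of cfg with fraction_de = 0 (global-null experiment)."""
    return replace(cfg, fraction_de=0.0)
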