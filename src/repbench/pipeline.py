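"""End-to-end orchestration: simulate -> gold -> bench -> nullfpr -> concord -> report.

Every stage writes plain TSV/JSON outputs into the run directory and can be
re-run independently on prior outputs (the CLI exposes one subcommand per
stage).  The whole pipeline is a pure function of (inputs, config, seed): the
manifest records the effective configuration, all derived seeds and a sha256
per output file, and contains no timestamps, so a rerun with the same seed is
checksum-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import benchmark as bm
from . import concordance as cc
from .de_tests import TestConfig, available_callers
from .errors import ConfigError, PipelineError
from .experiment_io import (CountMatrix, ExperimentDesign, read_counts,
                            read_design, write_counts, write_design)
from .normalization import reference_log2fc
from .synthetic_data import GeneratorConfig, simulate_experiment

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

DEFAULT_T_GRID = (0.0, 0.3, 1.0, 2.0)


@dataclass(frozen=True)
class PipelineConfig:
    """Study configuration at a chosen scale.

    Either ``generator`` (simulate the experiment) or ``counts_path`` +
    ``design_path`` (load one) must be set.  Grid defaults mirror the
    full-scale study: i = 100 iterations, T in {0, 0.3, 1, 2}.
    """

    out_dir: str
    seed: int
    callers: tuple[str, ...]
    generator: GeneratorConfig | None = None
    counts_path: str | None = None
    design_path: str | None = None
    nr_grid: tuple[int, ...] = (2, 3, 6, 12, 20, 40)
    t_grid: tuple[float, ...] = DEFAULT_T_GRID
    null_nr_grid: tuple[int, ...] = (3, 5, 10, 20)
    null_condition: str | None = None  # default: first condition
    iterations: int = 100
    alpha: float = 0.05
    B: int = 1000
    input_scale: str = "normalized"
    smooth: bool = False
    au_B: int = 200
    plots: bool = False

    def test_config(self, seed: int | None = None) -> TestConfig:
        return TestConfig(alpha=self.alpha, B=self.B, seed=seed,
                          input_scale=self.input_scale, smooth=self.smooth)


def validate_config(raw: dict | PipelineConfig) -> PipelineConfig:
    """Normalise a config mapping, fill defaults and collect ALL errors.

    Raises :class:`ConfigError` carrying the full error list rather than
    failing on the first problem.
    """
    errors: list[str] = []
    if isinstance(raw, PipelineConfig):
        cfg = raw
    else:
        d = dict(raw)
        gen = d.get("generator")
        if isinstance(gen, dict):
            gen = dict(gen)
            gen.setdefault("seed", d.get("seed", 0))
            try:
                d["generator"] = GeneratorConfig.from_dict(gen)
            except ConfigError as e:
                errors.extend(f"generator: {m}" for m in e.errors)
                d["generator"] = None
        for key in ("callers", "nr_grid", "t_grid", "null_nr_grid"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(d) - known
        if unknown:
            errors.append(f"unknown config key(s): {sorted(unknown)}")
            d = {k: v for k, v in d.items() if k in known}
        if "out_dir" not in d:
            errors.append("out_dir is required")
        if "seed" not in d:
            errors.append("seed is required")
        if errors:
            raise ConfigError(errors)
        cfg = PipelineConfig(**d)

    if not cfg.callers:
        errors.append("no callers configured")
    unknown_callers = [c for c in cfg.callers if c not in available_callers()]
    if unknown_callers:
        errors.append(f"unregistered caller(s): {unknown_callers}; "
                      f"available: {available_callers()}")
    if not cfg.nr_grid:
        errors.append("nr_grid is empty")
    if not cfg.t_grid:
        errors.append("t_grid is empty")
    if cfg.generator is None and not (cfg.counts_path and cfg.design_path):
        errors.append("either generator or counts_path+design_path required")
    if cfg.iterations < 1:
        errors.append("iterations must be >= 1")
    if not 0 < cfg.alpha < 1:
        errors.append(f"alpha must be in (0,1), got {cfg.alpha}")
    if cfg.generator is not None:
        n_rep = cfg.generator.n_rep
        too_big = [n for n in cfg.nr_grid if n > n_rep]
        if too_big:
            errors.append(f"nr_grid values {too_big} exceed n_rep={n_rep}")
        null_big = [n for n in cfg.null_nr_grid if 2 * n > n_rep]
        if null_big:
            errors.append(
                f"null_nr_grid values {null_big} need 2*n_r <= n_rep={n_rep}")
    if errors:
        raise ConfigError(errors)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    """Stable per-stage child seed (< 2**31) derived from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


class _Stages:
    """Pipeline stages sharing a run directory; each is independently callable."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.out = Path(cfg.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.files: dict[str, str] = {}

    def _write_df(self, df: pd.DataFrame, name: str, index: bool = True) -> Path:
        path = self.out / name
        df.to_csv(path, sep="\t", index=index, float_format="%.10g")
        self.files[name] = _sha256(path)
        return path

    # -- stage: simulate / load ------------------------------------------
    def inputs(self) -> tuple[CountMatrix, ExperimentDesign]:
        cfg = self.cfg
        if cfg.generator is not None:
            cm, design, truth = simulate_experiment(cfg.generator)
            write_counts(cm, self.out / "counts.tsv")
            write_design(design, self.out / "design.tsv")
            truth.write(self.out / "truth.tsv")
            for name in ("counts.tsv", "design.tsv", "truth.tsv"):
                self.files[name] = _sha256(self.out / name)
        else:
            cm = read_counts(cfg.counts_path, layout="matrix")
            design = read_design(cfg.design_path)
            design.check_matches(cm)
            self.files["counts.tsv(input)"] = _sha256(Path(cfg.counts_path))
            self.files["design.tsv(input)"] = _sha256(Path(cfg.design_path))
        return cm, design

    # -- stage: gold standards -------------------------------------------
    def gold(self, cm, design) -> dict[str, bm.GoldStandard]:
        out = {}
        for caller in self.cfg.callers:
            cfg_t = self.cfg.test_config(seed=_stage_seed(self.cfg.seed,
                                                          f"gold:{caller}"))
            gs = bm.compute_gold_standard(cm, design, caller, cfg_t)
            gs.result.write(self.out / f"gold_{caller}.tsv")
            self.files[f"gold_{caller}.tsv"] = _sha256(
                self.out / f"gold_{caller}.tsv")
            out[caller] = gs
        ref = reference_log2fc(cm, design)
        ref.write(self.out / "reference_log2fc.tsv")
        self.files["reference_log2fc.tsv"] = _sha256(
            self.out / "reference_log2fc.tsv")
        return out

    # -- stage: bootstrap benchmark --------------------------------------
    def bench(self, cm, design, gold: dict[str, bm.GoldStandard]) -> pd.DataFrame:
        rows = []
        for caller in self.cfg.callers:
            for n_r in self.cfg.nr_grid:
                seed = _stage_seed(self.cfg.seed, f"bench:{caller}:{n_r}")
                run = bm.run_bootstrap(cm, design, caller, n_r,
                                       self.cfg.iterations,
                                       self.cfg.test_config(), seed=seed)
                for T in self.cfg.t_grid:
                    conf = bm.confusion(run, gold[caller], T)
                    rc = bm.rates(conf)
                    row = {"caller": caller, "n_r": n_r, "T": T}
                    for count in ("TP", "FP", "TN", "FN"):
                        row[f"{count}_mean"] = conf.means[count]
                        row[f"{count}_sd"] = conf.sds[count]
                    for rate in ("TPR", "FPR", "TNR", "FNR"):
                        row[rate] = rc.values[rate]
                        row[f"{rate}_sd"] = rc.sds[rate]
                    row["universe_size"] = conf.universe_size
                    rows.append(row)
        df = pd.DataFrame(rows)
        self._write_df(df, "benchmark.tsv", index=False)
        return df

    # -- stage: null-split FPR -------------------------------------------
    def nullfpr(self, cm, design) -> pd.DataFrame:
        condition = self.cfg.null_condition or design.conditions[0]
        rows, summaries = [], []
        for caller in self.cfg.callers:
            for n_r in self.cfg.null_nr_grid:
                seed = _stage_seed(self.cfg.seed, f"null:{caller}:{n_r}")
                fracs, summary = bm.null_fpr_distribution(
                    cm, design, condition, caller, n_r,
                    self.cfg.iterations, self.cfg.test_config(), seed=seed)
                for k, f in enumerate(fracs):
                    rows.append({"caller": caller, "n_r": n_r,
                                 "iteration": k, "fp_fraction": f})
                summaries.append({"caller": caller, "n_r": n_r, **summary})
        self._write_df(pd.DataFrame(rows), "null_fpr.tsv", index=False)
        df = pd.DataFrame(summaries)
        self._write_df(df, "null_fpr_summary.tsv", index=False)
        return df

    # -- stage: concordance ----------------------------------------------
    def concord(self, gold: dict[str, bm.GoldStandard]) -> pd.DataFrame | None:
        if len(gold) < 2:
            logger.info("concordance skipped: fewer than 2 callers")
            return None
        m = cc.sde_matrix({c: g.result for c, g in gold.items()})
        constant = m.index[(m.nunique(axis=1) == 1)].tolist()
        if constant:
            logger.warning("dropping constant SDE vector(s) from clustering: %s",
                           constant)
            m = m.drop(index=constant)
        if m.shape[0] < 2:
            logger.warning("concordance skipped: < 2 non-degenerate vectors")
            return None
        self._write_df(m, "sde_matrix.tsv")
        rng = np.random.default_rng(_stage_seed(self.cfg.seed, "concord"))
        support = cc.au_support(m, B=self.cfg.au_B, rng=rng)
        tree = cc.complete_linkage(cc.correlation_distance(m))
        labels = {frozenset(row.leaves): f"{row.au:.0f}/{row.bp:.0f}"
                  for row in support.itertuples()}
        (self.out / "dendrogram.nwk").write_text(tree.to_newick(labels) + "\n")
        self.files["dendrogram.nwk"] = _sha256(self.out / "dendrogram.nwk")
        writable = support.copy()
        writable["leaves"] = writable["leaves"].map(lambda t: ",".join(t))
        self._write_df(writable, "au_support.tsv", index=False)
        return support

    # -- stage: report ----------------------------------------------------
    def report(self) -> Path:
        manifest = {
            "config": _config_dict(self.cfg),
            "files": dict(sorted(self.files.items())),
        }
        path = self.out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        index = {"outputs": sorted(self.files), "manifest": "manifest.json"}
        (self.out / "report.json").write_text(
            json.dumps(index, indent=2, sort_keys=True) + "\n")
        if self.cfg.plots:
            self._plots()
        return path

    def _plots(self) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        bench_path = self.out / "benchmark.tsv"
        if bench_path.exists():
            df = pd.read_csv(bench_path, sep="\t")
            fig, ax = plt.subplots()
            for (caller, T), grp in df.groupby(["caller", "T"]):
                ax.plot(grp["n_r"], grp["TPR"], marker="o",
                        label=f"{caller} T={T}")
            ax.set_xlabel("replicates per condition")
            ax.set_ylabel("TPR")
            ax.legend(fontsize=6)
            fig.savefig(self.out / "tpr_curves.png", dpi=120)
            plt.close(fig)
        null_path = self.out / "null_fpr.tsv"
        if null_path.exists():
            df = pd.read_csv(null_path, sep="\t")
            fig, ax = plt.subplots()
            for caller, grp in df.groupby("caller"):
                data = [g["fp_fraction"].to_numpy()
                        for _, g in grp.groupby("n_r")]
                ax.boxplot(data, tick_labels=sorted(grp["n_r"].unique()))
            ax.axhline(0.05, color="red", lw=1)
            ax.set_xlabel("replicates per pseudo-condition")
            ax.set_ylabel("false-positive fraction")
            fig.savefig(self.out / "null_fpr_box.png", dpi=120)
            plt.close(fig)


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if cfg.generator is not None:
        d["generator"] = cfg.generator.to_dict()
    for key in ("callers", "nr_grid", "t_grid", "null_nr_grid"):
        d[key] = list(d[key])
    return d


def run_pipeline(cfg: PipelineConfig | dict) -> Path:
    """Run all stages in order; returns the manifest path.

    A stage failure raises :class:`PipelineError` naming the stage; outputs
    written by earlier stages are retained.
    """
    cfg = validate_config(cfg)
    stages = _Stages(cfg)
    state: dict = {}
    plan = [
        ("simulate", lambda: state.update(zip(("cm", "design"),
                                              stages.inputs()))),
        ("gold", lambda: state.update(
            gold=stages.gold(state["cm"], state["design"]))),
        ("bench", lambda: stages.bench(state["cm"], state["design"],
                                       state["gold"])),
        ("nullfpr", lambda: stages.nullfpr(state["cm"], state["design"])),
        ("concord", lambda: stages.concord(state["gold"])),
        ("report", stages.report),
    ]
    for name, step in plan:
        logger.info("pipeline stage: %s", name)
        try:
            step()
        except Exception as e:
            raise PipelineError(f"stage {name!r} failed: {e}") from e
    return Path(cfg.out_dir) / "manifest.json"
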