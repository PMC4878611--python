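import numpy as np
import pandas as pd
import pytest

from repbench import benchmark as bm
from repbench.de_tests import TestConfig
from repbench.errors import BenchmarkError, ConsistencyError

from conftest import make_result


@pytest.fixture(scope="module")
def gold_and_run(small_experiment):
    cm, design, _ = small_experiment
    cfg = TestConfig()
    gold = bm.compute_gold_standard(cm, design, "t_test", cfg)
    run = bm.run_bootstrap(cm, design, "t_test", 4, 8, cfg, seed=5)
    return gold, run


class TestSubselect:
    def test_draws_are_distinct_and_condition_balanced(self, small_experiment):
        _, design, _ = small_experiment
        rng = np.random.default_rng(0)
        chosen = bm.subselect(design, 3, rng)
        assert len(chosen) == len(set(chosen)) == 6
        for cond in design.conditions:
            assert sum(design.condition_of(s) == cond for s in chosen) == 3

    def test_full_condition_is_deterministic(self, small_experiment):
        _, design, _ = small_experiment
        n = len(design.samples_in(design.conditions[0]))
        chosen = bm.subselect(design, n, np.random.default_rng(1))
        assert set(chosen) == set(design.samples)

    def test_oversized_request_rejected(self, small_experiment):
        _, design, _ = small_experiment
        with pytest.raises(BenchmarkError):
            bm.subselect(design, 99, np.random.default_rng(0))

    def test_fixed_seed_repeats(self, small_experiment):
        _, design, _ = small_experiment
        a = bm.subselect(design, 3, np.random.default_rng(7))
        b = bm.subselect(design, 3, np.random.default_rng(7))
        assert a == b


class TestBootstrapRun:
    def test_same_master_seed_identical_outputs(self, small_experiment):
        cm, design, _ = small_experiment
        cfg = TestConfig()
        r1 = bm.run_bootstrap(cm, design, "t_test", 3, 4, cfg, seed=11)
        r2 = bm.run_bootstrap(cm, design, "t_test", 3, 4, cfg, seed=11)
        assert r1.selections == r2.selections
        for a, b in zip(r1.iterations, r2.iterations):
            assert a.table.equals(b.table)

    def test_full_size_single_iteration_equals_gold(self, small_experiment):
        cm, design, _ = small_experiment
        cfg = TestConfig()
        gold = bm.compute_gold_standard(cm, design, "t_test", cfg)
        run = bm.run_bootstrap(cm, design, "t_test", 10, 1, cfg, seed=3)
        it = run.iterations[0]
        # same sample set (order may differ) -> identical p-values and calls
        assert np.allclose(it.table["p"], gold.result.table["p"])
        assert (it.sde == gold.sde).all()

    def test_self_comparison_has_no_errors(self, small_experiment):
        """A gold standard built from the identical single iteration gives
        FP = FN = 0, and comparing gold with itself gives TPR=1, FPR=0."""
        cm, design, _ = small_experiment
        cfg = TestConfig()
        gold = bm.compute_gold_standard(cm, design, "t_test", cfg)
        run = bm.run_bootstrap(cm, design, "t_test", 10, 1, cfg, seed=3)
        conf = bm.confusion(run, gold, 0.0)
        assert (conf.per_iteration["FP"] == 0).all()
        assert (conf.per_iteration["FN"] == 0).all()
        rc = bm.rates(conf)
        assert rc.values["TPR"] == 1.0 and rc.values["FPR"] == 0.0


class TestRepresentativeStats:
    def test_single_iteration_is_identity(self, gold_and_run):
        _, run = gold_and_run
        one = bm.BootstrapRun(caller=run.caller, n_r=run.n_r,
                              iterations=run.iterations[:1],
                              selections=run.selections[:1],
                              seeds=run.seeds[:1], master_seed=None)
        rep = bm.representative_stats(one)
        tbl = run.iterations[0].table
        finite = np.isfinite(tbl["log2fc"])
        assert np.allclose(rep.loc[finite, "mean_log2fc"],
                           tbl.loc[finite, "log2fc"], equal_nan=True)

    def test_even_count_median_is_midpoint(self):
        genes = ["g1"]
        r1 = make_result(genes, [True])
        r2 = make_result(genes, [True])
        r1.table["p_adj"] = [0.2]
        r2.table["p_adj"] = [0.4]
        run = bm.BootstrapRun(caller="stub", n_r=2, iterations=(r1, r2),
                              selections=((), ()), seeds=(0, 1),
                              master_seed=None)
        rep = bm.representative_stats(run)
        assert rep.loc["g1", "median_p_adj"] == pytest.approx(0.3)

    def test_infinite_fold_changes_excluded_from_mean(self):
        genes = ["g1"]
        r1 = make_result(genes, [True], log2fc=[np.inf])
        r2 = make_result(genes, [True], log2fc=[2.0])
        run = bm.BootstrapRun(caller="stub", n_r=2, iterations=(r1, r2),
                              selections=((), ()), seeds=(0, 1),
                              master_seed=None)
        rep = bm.representative_stats(run)
        assert rep.loc["g1", "mean_log2fc"] == 2.0
        assert rep.loc["g1", "n_inf_excluded"] == 1


class TestFractionSDE:
    def test_none_reject_gives_all_zero(self, small_experiment):
        cm, design, _ = small_experiment
        run = bm.run_bootstrap(cm, design, "none_reject", 3, 3,
                               TestConfig(), seed=2)
        fracs, summary = bm.fraction_sde(run)
        assert (fracs == 0).all() and summary["median"] == 0.0

    def test_fractions_bounded(self, gold_and_run):
        _, run = gold_and_run
        fracs, _ = bm.fraction_sde(run)
        assert ((fracs >= 0) & (fracs <= 1)).all()


class TestConfusion:
    def test_counts_match_set_algebra_oracle(self):
        """200-gene toy with hand-built flags vs direct set intersection."""
        rng = np.random.default_rng(17)
        genes = [f"g{i}" for i in range(200)]
        gold_sde = rng.random(200) < 0.5
        run_sde = rng.random(200) < 0.4
        lfc = rng.normal(0, 1.5, 200)
        gold_res = make_result(genes, gold_sde, caller="stub", log2fc=lfc)
        from repbench.normalization import ReferenceFoldChanges
        ref = ReferenceFoldChanges(
            table=pd.DataFrame({"log2fc": lfc, "mean_cond1": 1.0,
                                "mean_cond2": 1.0,
                                "both_zero": False}, index=genes),
            conditions=("a", "b"))
        gold = bm.GoldStandard(caller="stub", result=gold_res, ref_fc=ref,
                               alpha=0.05)
        run = bm.BootstrapRun(
            caller="stub", n_r=3,
            iterations=(make_result(genes, run_sde, caller="stub"),),
            selections=((),), seeds=(0,), master_seed=None)
        T = 1.0
        conf = bm.confusion(run, gold, T)
        universe = {g for g, l in zip(genes, lfc) if abs(l) >= T}
        g_set = {g for g, s in zip(genes, gold_sde) if s} & universe
        r_set = {g for g, s in zip(genes, run_sde) if s} & universe
        row = conf.per_iteration.iloc[0]
        assert row["TP"] == len(g_set & r_set)
        assert row["FP"] == len(r_set - g_set)
        assert row["FN"] == len(g_set - r_set)
        assert row["TN"] == len(universe - g_set - r_set)
        assert conf.universe_size == len(universe)

    def test_counts_sum_to_universe_every_iteration(self, gold_and_run):
        gold, run = gold_and_run
        for T in (0.0, 0.3, 1.0, 2.0):
            conf = bm.confusion(run, gold, T)
            sums = conf.per_iteration.sum(axis=1)
            assert (sums == conf.universe_size).all()

    def test_threshold_zero_universe_is_all_genes(self, gold_and_run):
        gold, run = gold_and_run
        conf = bm.confusion(run, gold, 0.0)
        assert conf.universe_size == len(gold.result.gene_ids)

    def test_caller_mismatch_rejected(self, gold_and_run, small_experiment):
        gold, _ = gold_and_run
        cm, design, _ = small_experiment
        other = bm.run_bootstrap(cm, design, "none_reject", 3, 1,
                                 TestConfig(), seed=1)
        with pytest.raises(ConsistencyError):
            bm.confusion(other, gold, 0.0)

    def test_infinite_fold_change_passes_every_threshold(self, gold_and_run):
        # genes that changed from/to zero have infinite |reference log2FC|
        # and stay in the universe at any T
        gold, run = gold_and_run
        n_inf = int(np.isinf(gold.ref_fc.log2fc).sum())
        assert n_inf > 0
        conf = bm.confusion(run, gold, 999.0)
        assert conf.universe_size == n_inf

    def test_empty_universe_rejected(self):
        from repbench.normalization import ReferenceFoldChanges
        genes = ["g1", "g2"]
        ref = ReferenceFoldChanges(
            table=pd.DataFrame({"log2fc": [0.1, -0.2], "mean_cond1": 1.0,
                                "mean_cond2": 1.0, "both_zero": False},
                               index=genes),
            conditions=("a", "b"))
        gold = bm.GoldStandard(caller="stub",
                               result=make_result(genes, [True, False]),
                               ref_fc=ref, alpha=0.05)
        run = bm.BootstrapRun(
            caller="stub", n_r=2,
            iterations=(make_result(genes, [True, True]),),
            selections=((),), seeds=(0,), master_seed=None)
        with pytest.raises(BenchmarkError):
            bm.confusion(run, gold, 999.0)


class TestRates:
    def _conf(self, tp, fp, tn, fn):
        per = pd.DataFrame([(tp, fp, tn, fn)] * 2,
                           columns=["TP", "FP", "TN", "FN"])
        return bm.ConfusionSummary(caller="x", n_r=3, T=0.0,
                                   per_iteration=per,
                                   universe_size=tp + fp + tn + fn)

    def test_arithmetic(self):
        rc = bm.rates(self._conf(85, 0, 100, 15))
        assert rc.values["TPR"] == pytest.approx(0.85)
        assert rc.values["FPR"] == 0.0
        assert rc.values["TNR"] == 1.0

    def test_complementarity_identities(self, gold_and_run):
        gold, run = gold_and_run
        for T in (0.0, 1.0):
            rc = bm.rates(bm.confusion(run, gold, T))
            v = rc.values
            if not np.isnan(v["TPR"]):
                assert v["TPR"] + v["FNR"] == pytest.approx(1.0)
            if not np.isnan(v["FPR"]):
                assert v["FPR"] + v["TNR"] == pytest.approx(1.0)

    def test_zero_denominator_is_nan_not_zero(self):
        rc = bm.rates(self._conf(0, 5, 10, 0))
        assert np.isnan(rc.values["TPR"]) and np.isnan(rc.values["FNR"])

    def test_delta_method_sd(self):
        per = pd.DataFrame([(80, 1, 100, 20), (90, 3, 98, 10)],
                           columns=["TP", "FP", "TN", "FN"])
        conf = bm.ConfusionSummary(caller="x", n_r=3, T=0.0,
                                   per_iteration=per, universe_size=201)
        rc = bm.rates(conf)
        tp, fn = per["TP"].mean(), per["FN"].mean()
        s_tp, s_fn = per["TP"].std(ddof=1), per["FN"].std(ddof=1)
        expected = np.sqrt((fn * s_tp) ** 2 + (tp * s_fn) ** 2) / (tp + fn) ** 2
        assert rc.sds["TPR"] == pytest.approx(expected)


class TestNullSplit:
    def test_groups_disjoint_and_within_condition(self, small_experiment):
        _, design, _ = small_experiment
        cond = design.conditions[0]
        for seed in range(5):
            a, b = bm.null_split(design, cond, 4, np.random.default_rng(seed))
            assert not set(a) & set(b)
            assert all(design.condition_of(s) == cond for s in a + b)

    def test_none_reject_yields_zero_fractions(self, small_experiment):
        cm, design, _ = small_experiment
        fracs, summary = bm.null_fpr_distribution(
            cm, design, design.conditions[0], "none_reject", 3, 5,
            TestConfig(), seed=4)
        assert (fracs == 0).all() and summary["q3"] == 0.0

    def test_oversized_split_rejected(self, small_experiment):
        cm, design, _ = small_experiment
        with pytest.raises(BenchmarkError):
            bm.null_fpr_distribution(cm, design, design.conditions[0],
                                     "t_test", 6, 2, TestConfig(), seed=0)


class TestBreakpoint:
    @staticmethod
    def _kinked(t, knot, a=0.9, b_low=-0.05, b_high=-0.4):
        """TPR-like curve: shallow above the knot, steep below."""
        return a + b_low * t + (b_high - b_low) * np.minimum(t - knot, 0.0)

    def test_noiseless_kink_recovered_exactly(self):
        t = np.round(np.arange(0.0, 2.01, 0.1), 10)
        y = self._kinked(t, 0.5)
        fit = bm.tpr_breakpoint(t, y)
        assert fit.T_star == pytest.approx(0.5)
        assert not fit.degenerate

    def test_straight_line_is_degenerate_smallest_knot(self):
        t = np.arange(0.0, 1.01, 0.1)
        fit = bm.tpr_breakpoint(t, 1.0 - 0.3 * t)
        assert fit.T_star == pytest.approx(t[1])
        assert fit.degenerate

    def test_noisy_kink_within_one_grid_step(self):
        rng = np.random.default_rng(23)
        t = np.round(np.arange(0.0, 2.01, 0.1), 10)
        y = self._kinked(t, 0.7) + rng.normal(0, 0.01, t.size)
        fit = bm.tpr_breakpoint(t, y)
        assert abs(fit.T_star - 0.7) <= 0.1 + 1e-9

    def test_too_few_points_rejected(self):
        with pytest.raises(BenchmarkError):
            bm.tpr_breakpoint([0.0, 0.1, 0.2], [1, 2, 3])
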