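"""Downstream statistics: enumeration oracles, survival, stratification."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from conexic.io import ClinicalTable, GeneSetCollection, OmicsMatrix
from conexic.learning import DriverResult, Module
from conexic.ng import RegulatoryProgram
from conexic.stats import (
    fisher_exact_2x2,
    gene_set_enrichment,
    km_logrank,
    module_correlation_test,
    split_by_driver,
    wilcoxon_rank_sum,
)


def fisher_enumeration_oracle(table):
    """Two-sided Fisher p by full enumeration of tables with fixed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0

    def prob(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    # probability ordering with the standard 1e-7 relative guard
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-7))


class TestFisher:
    def test_diagonal_table_enumerates_to_one_third(self):
        assert fisher_exact_2x2([[2, 0], [0, 2]]) == pytest.approx(1 / 3)
        assert fisher_enumeration_oracle([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_balanced_table_is_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_transpose_invariance(self):
        t = [[7, 2], [3, 9]]
        tt = [[7, 3], [2, 9]]
        assert fisher_exact_2x2(t) == pytest.approx(fisher_exact_2x2(tt))

    def test_zero_margin_convention(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1.5, 2], [3, 4]])


class TestWilcoxon:
    def test_identical_samples_sit_at_null_mean(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        w, p = wilcoxon_rank_sum(x, x)
        assert w == pytest.approx(len(x) * (2 * len(x) + 1) / 2)
        assert p > 0.9

    def test_all_tied_values_give_p_one(self):
        w, p = wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_disjoint_supports_highly_significant(self):
        x = np.arange(20.0)
        y = np.arange(100.0, 120.0)
        _, p = wilcoxon_rank_sum(x, y)
        assert p < 1e-6

    def test_swap_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 11)
        wx, px = wilcoxon_rank_sum(x, y)
        wy, py = wilcoxon_rank_sum(y, x)
        n = len(x) + len(y)
        assert px == pytest.approx(py)
        assert wx + wy == pytest.approx(n * (n + 1) / 2)

    def test_close_to_exact_enumeration_at_n5(self):
        def exact_p(x, y):
            pooled = np.concatenate([x, y])
            n1 = len(x)
            ranks = rankdata(pooled)
            obs = ranks[:n1].sum()
            mean = n1 * (len(pooled) + 1) / 2
            ws = [
                ranks[list(c)].sum()
                for c in combinations(range(len(pooled)), n1)
            ]
            return float(
                np.mean([abs(w - mean) >= abs(obs - mean) - 1e-12 for w in ws])
            )

        rng = np.random.default_rng(1)
        for _ in range(20):
            x, y = rng.normal(0, 1, 5), rng.normal(0.8, 1, 5)
            _, p = wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(exact_p(x, y), abs=0.025)


class TestModuleCorrelation:
    def test_planted_module_strongly_correlated(self, fixture_data):
        _, expr, _, truth = fixture_data
        d = truth.survival_driver
        p, r_mod, r_bg = module_correlation_test(expr, d, truth.module_genes[d])
        assert p < 1e-6
        assert r_mod > r_bg

    def test_random_module_pvalues_uniform(self):
        rng = np.random.default_rng(2)
        expr = OmicsMatrix(
            "expression",
            [f"g{i}" for i in range(300)],
            [f"S{j}" for j in range(50)],
            rng.normal(0, 1, (300, 50)),
        )
        pvals = []
        for _ in range(200):
            module = [f"g{i}" for i in rng.choice(np.arange(1, 300), 20, replace=False)]
            p, _, _ = module_correlation_test(expr, "g0", module)
            pvals.append(p)
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_driver_only_module_rejected(self, fixture_data):
        _, expr, _, truth = fixture_data
        d = truth.survival_driver
        with pytest.raises(ValueError, match="other than the driver"):
            module_correlation_test(expr, d, [d])


class TestEnrichment:
    def test_module_equal_to_set_reaches_enumeration_floor(self):
        universe = [f"g{i}" for i in range(10)]
        module = universe[:4]
        sets = GeneSetCollection({"s": tuple(module)})
        out = gene_set_enrichment(module, sets, universe)
        # only one of the C(10,4) equally likely draws overlaps completely
        assert out.loc["s", "p"] == pytest.approx(1 / math.comb(10, 4))

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        sets = GeneSetCollection({"s": ("g0", "g1")})
        out = gene_set_enrichment(universe[10:14], sets, universe)
        assert out.loc["s", "p"] == pytest.approx(1.0)

    def test_widening_universe_sharpens_fixed_overlap(self):
        sets = GeneSetCollection({"s": ("g0", "g1", "g2")})
        small = [f"g{i}" for i in range(10)]
        large = [f"g{i}" for i in range(20)]
        p_small = gene_set_enrichment(["g0", "g1"], sets, small).loc["s", "p"]
        p_large = gene_set_enrichment(["g0", "g1"], sets, large).loc["s", "p"]
        assert p_large < p_small

    def test_q_never_below_p(self):
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(50)]
        sets = GeneSetCollection(
            {
                f"s{k}": tuple(
                    np.array(universe)[rng.choice(50, 8, replace=False)]
                )
                for k in range(12)
            }
        )
        out = gene_set_enrichment(universe[:10], sets, universe)
        assert (out["q"] >= out["p"] - 1e-12).all()

    def test_module_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            gene_set_enrichment(
                ["zz"], GeneSetCollection({"s": ("g0",)}), ["g0", "g1"]
            )


def _clinical(times, events, samples=None):
    samples = samples or [f"S{j}" for j in range(len(times))]
    return ClinicalTable(
        pd.DataFrame(
            {"dmfs_time_months": times, "dmfs_event": events},
            index=pd.Index(samples, name="sample_id"),
        )
    )


class TestKMLogrank:
    def test_identical_groups_statistic_zero_p_one(self):
        times = [5.0, 10.0, 15.0, 20.0, 25.0]
        events = [1, 0, 1, 1, 0]
        clin = _clinical(times + times, events + events)
        groups = {
            "a": [f"S{j}" for j in range(5)],
            "b": [f"S{j}" for j in range(5, 10)],
        }
        res = km_logrank(clin, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_km_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(4)
        times = np.sort(rng.exponential(30, 40))
        clin = _clinical(list(times) + [1.0] * 5, [1] * 40 + [1] * 5)
        groups = {
            "a": [f"S{j}" for j in range(40)],
            "b": [f"S{j}" for j in range(40, 45)],
        }
        res = km_logrank(clin, groups)
        curve = res.curves["a"]
        for t, s in zip(curve["time"], curve["survival"]):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)
        # KM estimate is non-increasing
        assert (np.diff(curve["survival"]) <= 1e-12).all()

    def test_all_censored_gives_na_p_and_flat_curve(self):
        clin = _clinical([10.0] * 8, [0] * 8)
        groups = {
            "a": [f"S{j}" for j in range(4)],
            "b": [f"S{j}" for j in range(4, 8)],
        }
        with pytest.warns(UserWarning, match="zero events"):
            res = km_logrank(clin, groups)
        assert math.isnan(res.p)
        assert (res.curves["a"]["survival"] == 1.0).all()

    def test_numbers_at_risk_count_still_under_observation(self):
        clin = _clinical([10.0, 20.0, 30.0, 40.0], [1, 1, 0, 1])
        groups = {"a": ["S0", "S1"], "b": ["S2", "S3"]}
        res = km_logrank(clin, groups, at_risk_times=(0, 25))
        assert res.at_risk.loc["a", "t=0"] == 2
        assert res.at_risk.loc["a", "t=25"] == 0
        assert res.at_risk.loc["b", "t=25"] == 2


class TestSplitByDriver:
    def _setup(self, values):
        expr = OmicsMatrix(
            "expression",
            ["drv"],
            [f"S{j}" for j in range(len(values))],
            np.array([values]),
        )
        module = Module(
            "m1", ("x", "y", "z", "w", "v"), "drv", "positive",
            RegulatoryProgram("drv", 2.5), gain=5.0,
        )
        driver = DriverResult("drv", "amplified", "1q11.1", 5.0, 1.0, ("m1",))
        return expr, driver, [module]

    def test_threshold_semantics(self):
        expr, driver, modules = self._setup([1.0, 2.0, 3.0, 4.0])
        high, low, split = split_by_driver(expr, driver, modules)
        assert split == 2.5
        assert high == ["S2", "S3"] and low == ["S0", "S1"]

    def test_boundary_sample_goes_low(self):
        expr, driver, modules = self._setup([1.0, 2.5, 4.0])
        high, low, _ = split_by_driver(expr, driver, modules)
        assert "S1" in low

    def test_all_below_split_warns_empty_group(self):
        expr, driver, modules = self._setup([0.0, 1.0, 2.0])
        with pytest.warns(UserWarning, match="empty"):
            high, low, _ = split_by_driver(expr, driver, modules)
        assert high == []

    def test_driver_absent_from_matrix_is_hard_error(self):
        expr, driver, modules = self._setup([1.0, 2.0, 3.0])
        other = DriverResult("missing", "amplified", "1q11.1", 5.0, 1.0, ("m1",))
        with pytest.raises(KeyError):
            split_by_driver(expr, other, modules)

    def test_uses_top_scoring_module_split(self, fixture_data, fixture_regions):
        # end-to-end smoke: on the fixture, the survival driver's learned
        # split recovers the planted median threshold and balances groups
        from conexic.learning import LearningConfig, run_driver_discovery
        from conexic.ng import ScoringConfig
        from conexic.simulate import default_fixture_annotation

        cn, expr, clinical, truth = fixture_data
        lcfg = LearningConfig(bootstrap_runs=5, seed=3)
        res = run_driver_discovery(
            expr, cn, default_fixture_annotation(), fixture_regions, lcfg,
            ScoringConfig(),
        )
        target = [d for d in res.drivers if d.gene_id == truth.survival_driver]
        assert target, "survival-designated driver not recovered"
        high, low, split = split_by_driver(expr, target[0], res.modules)
        assert abs(split - truth.true_split[truth.survival_driver]) <= 0.25
        assert abs(len(high) - len(low)) <= 6
        res_km = km_logrank(clinical, {"high": high, "low": low})
        assert res_km.p < 0.05
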