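import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from admark.config import SimConfig
from admark.group_comparisons import (
    holm_adjust,
    mann_whitney_u,
    null_config,
    paired_exposure_test,
    paired_t,
    paired_test_grid,
    run_synthetic_analysis,
    type_one_error,
    wilcoxon_signed_rank,
)
from conftest import oracle_mann_whitney, oracle_signed_rank


class TestWilcoxonSignedRank:
    def test_all_equal_pairs_degenerate(self):
        res = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert res.degenerate and res.p_value == 1.0

    def test_three_positive_differences_exact_one_sided(self):
        res = wilcoxon_signed_rank([2, 3, 4], [1, 1, 1], alternative="greater")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 8)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(1, 9))
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 5, n).astype(float)
            for alt in ("two-sided", "greater", "less"):
                res = wilcoxon_signed_rank(x, y, alternative=alt)
                w_o, p_o = oracle_signed_rank(x, y, alternative=alt)
                if res.degenerate:
                    assert p_o == 1.0
                    continue
                assert res.statistic == pytest.approx(w_o)
                assert res.p_value == pytest.approx(p_o, abs=1e-12)

    def test_approx_agrees_with_scipy_on_untied_data(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.3, 1.0, 80)
        y = rng.normal(0.0, 1.0, 80)
        res = wilcoxon_signed_rank(x, y)
        ref = stats.wilcoxon(x, y, zero_method="wilcox", correction=False,
                             mode="approx")
        assert res.method == "approx"
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_medians_reported(self):
        res = wilcoxon_signed_rank([2, 2, 2, 4], [1, 1, 1, 1])
        assert res.group_stats["median_x"] == 2.0
        assert res.group_stats["median_y"] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([], [])


class TestMannWhitneyU:
    def test_complete_separation(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0

    def test_identical_groups_symmetry(self):
        res = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == pytest.approx(8.0)  # n_a n_b / 2
        assert res.p_value == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            na = int(rng.integers(1, 5))
            nb = int(rng.integers(1, 5))
            a = rng.integers(0, 4, na).astype(float)
            b = rng.integers(0, 4, nb).astype(float)
            for alt in ("two-sided", "greater", "less"):
                res = mann_whitney_u(a, b, alternative=alt)
                u_o, p_o = oracle_mann_whitney(a, b, alternative=alt)
                assert res.statistic == pytest.approx(u_o)
                assert res.p_value == pytest.approx(p_o, abs=1e-12), (a, b, alt)

    def test_approx_agrees_with_scipy(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 5, 60).astype(float)
        b = rng.integers(0, 5, 50).astype(float) + 0.5
        res = mann_whitney_u(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                                 use_continuity=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_all_tied_degenerate(self):
        res = mann_whitney_u([2.0] * 20, [2.0] * 20)
        assert res.degenerate and res.p_value == 1.0


class TestPairedT:
    def test_closed_form_oracle(self):
        d = np.array([1.0, -1.0, 2.0, 0.0])
        x = d
        y = np.zeros_like(d)
        res = paired_t(x, y)
        t_want = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        assert res.statistic == pytest.approx(t_want)
        assert res.p_value == pytest.approx(
            2 * stats.t.sf(abs(t_want), len(d) - 1))

    def test_identical_strata_degenerate(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.p_value == 1.0

    def test_constant_nonzero_difference(self):
        res = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.statistic == math.inf and res.p_value == 0.0

    def test_matches_scipy(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(1, 2, 40), rng.normal(0, 2, 40)
        res = paired_t(x, y)
        ref = stats.ttest_rel(x, y)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)


class TestPairedExposure:
    @pytest.fixture()
    def ads(self):
        rng = np.random.default_rng(14)
        n = 60
        return pd.DataFrame({
            "ad_id": [f"AD{i:03d}" for i in range(n)],
            "emotional_variety": rng.integers(0, 5, n),
            "rational_variety": rng.integers(0, 5, n),
            "wimp_female": rng.uniform(1000, 5000, n),
            "wimp_male": rng.uniform(1000, 5000, n),
        })

    def test_same_stratum_degenerate(self, ads):
        res = paired_exposure_test(ads, "female", "female")
        assert res.degenerate and res.p_value == 1.0

    def test_empty_level_graceful(self, ads):
        ads = ads[ads["emotional_variety"] != 3]
        res = paired_exposure_test(ads, "female", "male", 3, "emotional")
        assert res.n == 0 and res.degenerate
        assert math.isnan(res.p_value)

    def test_level_restriction(self, ads):
        res = paired_exposure_test(ads, "female", "male", 2, "emotional")
        assert res.n == int((ads["emotional_variety"] == 2).sum())

    def test_missing_stratum_column(self, ads):
        with pytest.raises(KeyError, match="ses_low"):
            paired_exposure_test(ads, "female", "ses_low")

    def test_grid_shape(self, ads):
        grid = paired_test_grid(ads, [("female", "male")])
        assert len(grid) == 2 * 5  # strategies x levels
        assert set(grid["strategy"]) == {"emotional", "rational"}

    def test_gender_gap_significant_at_every_level(self):
        cfg = SimConfig(seed=11, n_unique_ads=500, gender_gap=1.3)
        bundle = run_synthetic_analysis(cfg, top_fraction=1.0)
        grid = bundle["gender_grid"]
        populated = grid[grid["n"] >= 3]
        assert (populated["mean_a"] > populated["mean_b"]).all()
        # significance needs a handful of ads per cell; tiny cells only get
        # the ordering check above
        assert (grid.loc[grid["n"] >= 10, "p_value"] < 0.05).all()


class TestHolm:
    def test_known_example(self):
        # sorted: .01 -> 3x = .03; .03 -> 2x = .06; .04 -> max(.06, 1x.04) = .06
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.03, 0.06, 0.06])

    def test_monotone_and_capped(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 20)
        adj = np.array(holm_adjust(p))
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_nan_passthrough(self):
        adj = holm_adjust([0.01, math.nan, 0.02])
        assert math.isnan(adj[1])


class TestFullAnalysis:
    def test_deterministic_bundle(self):
        from admark.interface_io import bundle_to_json
        cfg = SimConfig(seed=33, n_unique_ads=60)
        j1 = bundle_to_json(run_synthetic_analysis(cfg))
        j2 = bundle_to_json(run_synthetic_analysis(cfg))
        assert j1 == j2

    def test_no_high_in_graceful(self):
        cfg = SimConfig(seed=5, n_unique_ads=50, frac_high_in=0.0)
        bundle = run_synthetic_analysis(cfg)
        res = bundle["tests"]["mwu_emotional_by_high_in"]
        assert res.degenerate and res.method == "empty"

    def test_headline_directions_at_500_ads(self):
        bundle = run_synthetic_analysis(SimConfig(seed=1, n_unique_ads=500),
                                        top_fraction=1.0)
        tests = bundle["tests"]
        w = tests["wilcoxon_emotional_vs_rational"]
        assert w.p_value < 0.001
        assert w.group_stats["median_x"] > w.group_stats["median_y"]
        m = tests["mwu_emotional_by_high_in"]
        assert m.p_value < 0.001
        for grid_key, order_holds in (("gender_grid", None), ("ses_grid", None)):
            grid = bundle[grid_key]
            populated = grid[grid["n"] >= 3]
            assert (populated["mean_a"] > populated["mean_b"]).all()

    def test_holm_flag_adds_column(self):
        cfg = SimConfig(seed=19, n_unique_ads=40)
        bundle = run_synthetic_analysis(cfg, holm=True)
        assert "p_holm" in bundle["gender_grid"].columns


class TestNullCalibration:
    def test_small_replicate_batch_sane(self):
        # full 1000-replicate calibration lives in the acceptance suite
        rates = type_one_error(n_reps=40, seed=123, n_unique_ads=80)
        for test, rate in rates.items():
            assert 0.0 <= rate <= 0.25, (test, rate)

    def test_null_config_is_null(self):
        cfg = null_config(seed=0)
        assert cfg.gender_gap == 1.0
        assert cfg.ses_gradient == (1.0, 1.0, 1.0)
        assert cfg.populations.female == cfg.populations.male
        pairs = set(cfg.appeal_prevalence.values())
        assert len(pairs) == 1
        p_hi, p_not = pairs.pop()
        assert p_hi == p_not
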