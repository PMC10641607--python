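import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from admark.appeal_scoring import (
    Codebook,
    appeal_prevalence_table,
    product_level_table,
    variety_percentage_table,
    variety_scores,
    variety_table,
)
from admark.config import SimConfig
from admark.nutrient_profiling import classify_table
from admark.synthetic_data import simulate_airings, simulate_codings, simulate_products


class TestCodebook:
    def test_default_carries_expected_types(self, codebook):
        assert {"senses", "cartoons", "positive_emotions"} <= set(codebook.emotional_types)
        assert {"health", "nutrition", "freshness", "ingredients",
                "quality"} <= set(codebook.rational_types)

    def test_strategies_partition_types(self, codebook):
        assert set(codebook.emotional_types) | set(codebook.rational_types) == set(
            codebook.appeal_types)
        assert not set(codebook.emotional_types) & set(codebook.rational_types)

    def test_bad_strategy_rejected(self):
        with pytest.raises(ValueError):
            Codebook(strategies={"x": "subliminal"})


class TestVarietyScores:
    def test_all_zero(self, codebook):
        flags = {t: 0 for t in codebook.appeal_types}
        s = variety_scores("A", flags, codebook)
        assert (s.emotional_variety, s.rational_variety) == (0, 0)
        assert s.no_coded_appeal

    def test_cap_at_four(self, codebook):
        flags = {t: 1 for t in codebook.emotional_types}  # 5 emotional types
        flags["health"] = 1
        s = variety_scores("A", flags, codebook)
        assert s.emotional_variety == 4
        assert s.rational_variety == 1

    def test_identity_below_cap(self, codebook):
        flags = {t: 0 for t in codebook.appeal_types}
        for t in codebook.emotional_types[:3]:
            flags[t] = 1
        for t in codebook.rational_types[:3]:
            flags[t] = 1
        s = variety_scores("A", flags, codebook)
        assert (s.emotional_variety, s.rational_variety) == (3, 3)

    def test_unknown_type_rejected(self, codebook):
        with pytest.raises(ValueError, match="mystery"):
            variety_scores("A", {"mystery": 1}, codebook)

    def test_nonbinary_flag_rejected(self, codebook):
        with pytest.raises(ValueError, match="senses"):
            variety_scores("A", {"senses": 2}, codebook)


@settings(max_examples=60, deadline=None)
@given(st.lists(st.booleans(), min_size=10, max_size=10),
       st.integers(0, 9))
def test_variety_monotone_when_flag_added(bits, idx):
    codebook = Codebook.default()
    types = list(codebook.appeal_types)
    flags = dict(zip(types, map(int, bits)))
    before = variety_scores("A", flags, codebook)
    flags[types[idx]] = 1
    after = variety_scores("A", flags, codebook)
    assert after.emotional_variety >= before.emotional_variety
    assert after.rational_variety >= before.rational_variety


@settings(max_examples=30, deadline=None)
@given(st.lists(st.booleans(), min_size=10, max_size=10), st.randoms(use_true_random=False))
def test_variety_permutation_invariant(bits, rand):
    codebook = Codebook.default()
    types = list(codebook.appeal_types)
    flags = dict(zip(types, map(int, bits)))
    shuffled = list(flags.items())
    rand.shuffle(shuffled)
    s1 = variety_scores("A", flags, codebook)
    s2 = variety_scores("A", dict(shuffled), codebook)
    assert (s1.emotional_variety, s1.rational_variety) == (
        s2.emotional_variety, s2.rational_variety)


class TestVarietyTable:
    def test_matches_scalar(self, codebook):
        rng = np.random.default_rng(0)
        types = list(codebook.appeal_types)
        rows = []
        for i in range(50):
            row = {"ad_id": f"AD{i:03d}"}
            row.update({t: int(rng.random() < 0.4) for t in types})
            rows.append(row)
        table = variety_table(pd.DataFrame(rows), codebook)
        for row, (_, got) in zip(rows, table.iterrows()):
            s = variety_scores(row["ad_id"], {t: row[t] for t in types}, codebook)
            assert got["emotional_variety"] == s.emotional_variety
            assert got["rational_variety"] == s.rational_variety
            assert got["no_coded_appeal"] == s.no_coded_appeal

    def test_duplicate_ads_rejected(self, codebook):
        df = pd.DataFrame({"ad_id": ["A", "A"], "senses": [1, 0]})
        with pytest.raises(ValueError, match="A"):
            variety_table(df, codebook)


def build_product_inputs(seed=3, n_ads=80):
    cfg = SimConfig(seed=seed, n_unique_ads=n_ads)
    airings = simulate_airings(cfg)
    nutrition = simulate_products(cfg)
    ads = airings[["ad_id", "product_ids"]].drop_duplicates(subset="ad_id")
    codings = simulate_codings(cfg, ads, nutrition)
    coder1 = codings[codings["coder_id"] == 1].drop(columns="coder_id")
    verdicts = classify_table(nutrition)
    ads = ads.copy()
    ads["n_instances"] = 1
    ads["wimp_overall"] = 100.0
    pairs = pd.DataFrame(
        [(r["ad_id"], p) for _, r in ads.iterrows() for p in r["product_ids"]],
        columns=["ad_id", "product_id"])
    return cfg, ads, pairs, coder1, verdicts


class TestProductLevelTable:
    def test_broadcast_to_products(self, codebook):
        _, ads, pairs, coder1, verdicts = build_product_inputs()
        table = product_level_table(pairs, coder1, verdicts, ads, codebook)
        assert len(table) == len(pairs)
        # all products of one ad share that ad's scores
        per_ad = table.groupby("ad_id")["emotional_variety"].nunique()
        assert (per_ad == 1).all()

    def test_unmatched_product_rejected(self, codebook):
        _, ads, pairs, coder1, verdicts = build_product_inputs()
        bad = pd.concat([pairs, pd.DataFrame([{"ad_id": ads.iloc[0]["ad_id"],
                                               "product_id": "GHOST"}])],
                        ignore_index=True)
        with pytest.raises(ValueError, match="GHOST"):
            product_level_table(bad, coder1, verdicts, ads, codebook)

    def test_unmatched_ad_rejected(self, codebook):
        _, ads, pairs, coder1, verdicts = build_product_inputs()
        coder1 = coder1.iloc[1:]
        with pytest.raises(ValueError, match="coding"):
            product_level_table(pairs, coder1, verdicts, ads, codebook)


class TestSummaryTables:
    def test_group_percentages_simple(self, codebook):
        products = pd.DataFrame({
            "ad_id": ["A", "B", "C"], "product_id": ["P1", "P2", "P3"],
            "emotional_variety": [0, 1, 2], "rational_variety": [0, 0, 0],
            "overall_high_in": [True, True, True],
        })
        table = variety_percentage_table(products)
        row = table[(table["strategy"] == "emotional") & (table["group"] == "high_in")].iloc[0]
        for lvl, want in [(0, 100 / 3), (1, 100 / 3), (2, 100 / 3), (3, 0.0), (4, 0.0)]:
            assert row[f"pct_variety_{lvl}"] == pytest.approx(want, abs=0.01)

    def test_percentages_sum_to_100(self, codebook):
        _, ads, pairs, coder1, verdicts = build_product_inputs(seed=9)
        products = product_level_table(pairs, coder1, verdicts, ads, codebook)
        table = variety_percentage_table(products)
        pct_cols = [c for c in table.columns if c.startswith("pct_")]
        sums = table[pct_cols].sum(axis=1)
        nonempty = table["n"] > 0
        assert np.allclose(sums[nonempty], 100.0, atol=0.01)

    def test_both_strategy_fraction_near_analytic(self, codebook):
        # closed form under independence, mixing over the ad's high-in status
        cfg, ads, pairs, coder1, verdicts = build_product_inputs(seed=23, n_ads=550)
        products = product_level_table(pairs, coder1, verdicts, ads, codebook)
        assert len(products) >= 700

        hi_products = set(verdicts.loc[verdicts["overall_high_in"], "product_id"])
        p_ad_hi = np.mean([any(p in hi_products for p in pl) for pl in ads["product_ids"]])

        def p_both(which):
            idx = 0 if which else 1
            p_no_emo = np.prod([1 - cfg.appeal_prevalence[t][idx]
                                for t in codebook.emotional_types])
            p_no_rat = np.prod([1 - cfg.appeal_prevalence[t][idx]
                                for t in codebook.rational_types])
            return (1 - p_no_emo) * (1 - p_no_rat)

        # product rows inherit their *ad's* status mix; weight by ad-level rate
        analytic = p_ad_hi * p_both(True) + (1 - p_ad_hi) * p_both(False)
        realized = products["both_strategies"].mean()
        assert realized == pytest.approx(analytic, abs=0.05)

    def test_prevalence_table_shape(self, codebook):
        _, ads, pairs, coder1, verdicts = build_product_inputs(seed=4)
        products = product_level_table(pairs, coder1, verdicts, ads, codebook)
        table = appeal_prevalence_table(products, coder1, codebook)
        assert set(table["appeal_type"]) >= set(codebook.appeal_types)
        summary = table[table["strategy"] == "summary"]
        assert set(summary["appeal_type"]) == {
            "any_emotional", "any_rational", "both_strategies", "no_coded_appeal"}
        assert ((table["pct_all"].dropna() >= 0) & (table["pct_all"].dropna() <= 100)).all()
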