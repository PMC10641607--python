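"""Inferential stage: signed-rank, rank-sum and paired-t comparisons.

The rank tests are implemented directly (mid-ranks, tie-corrected normal
approximation, exact small-sample distributions) so their behaviour on the
heavily tied ordinal variety scales is fully specified and testable against
enumeration oracles:

* Wilcoxon signed-rank: zero differences discarded; exact distribution by
  convolution over doubled mid-ranks for n <= 25, otherwise a normal
  approximation with tie-corrected variance.
* Mann-Whitney U: U counts pairs won by group A (+0.5 per tie); exact by
  enumeration of group assignments for pooled n <= 12, otherwise normal
  approximation with tie correction.
* Paired t: closed form on the differences, with explicit degenerate
  handling when the differences have zero variance.

All p-values are two-sided by default; no multiple-testing correction is
applied unless :func:`holm_adjust` is requested.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import reliability as _reliability
from .appeal_scoring import (
    STRATEGIES,
    VARIETY_LEVELS,
    Codebook,
    appeal_prevalence_table,
    product_level_table,
    variety_percentage_table,
    variety_table,
)
from .config import PopulationTable, SimConfig
from .exposure_metrics import (
    add_weekly_impressions,
    apply_sample_filters,
    group_unique,
    select_top_fraction,
)
from .synthetic_data import simulate_airings, simulate_codings, simulate_products

__all__ = [
    "TestResult",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "paired_exposure_test",
    "paired_test_grid",
    "holm_adjust",
    "run_full_analysis",
    "run_synthetic_analysis",
    "null_config",
    "type_one_error",
]


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    method: str = ""
    z: Optional[float] = None
    n: int = 0
    group_stats: Dict[str, float] = field(default_factory=dict)
    degenerate: bool = False
    note: str = ""

    def as_dict(self) -> dict:
        return asdict(self)


def _norm_p(z: float, alternative: str) -> float:
    if alternative == "two-sided":
        return 2.0 * stats.norm.sf(abs(z))
    if alternative == "greater":
        return float(stats.norm.sf(z))
    if alternative == "less":
        return float(stats.norm.cdf(z))
    raise ValueError(f"unknown alternative {alternative!r}")


def _tail_p(p_ge: float, p_le: float, alternative: str) -> float:
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(p_ge, p_le))
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    raise ValueError(f"unknown alternative {alternative!r}")


def _signed_rank_exact_dist(doubled_ranks: np.ndarray) -> np.ndarray:
    """Exact distribution of 2x(sum of positive ranks) by convolution."""
    total = int(doubled_ranks.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = dist + shifted
    return dist / dist.sum()


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_limit: int = 25,
    name: str = "wilcoxon_signed_rank",
) -> TestResult:
    """Signed-rank test on paired samples, statistic W+ (sum of positive ranks).

    Zero differences are discarded (classical treatment — relevant here
    because ordinal variety scores guarantee many ties).  Ties among the
    absolute differences receive mid-ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or x.size != y.size:
        raise ValueError("wilcoxon_signed_rank: need equal-length, non-empty paired samples")
    stats_groups = {
        "median_x": float(np.median(x)),
        "median_y": float(np.median(y)),
    }
    d = x - y
    nz = d[d != 0]
    n = nz.size
    if n == 0:
        return TestResult(name, 0.0, 1.0, method="degenerate", n=0,
                          group_stats=stats_groups, degenerate=True,
                          note="all paired differences are zero")
    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    if n <= exact_limit:
        doubled = np.rint(2 * ranks).astype(int)
        dist = _signed_rank_exact_dist(doubled)
        w2 = int(round(2 * w_plus))
        p_ge = float(dist[w2:].sum())
        p_le = float(dist[: w2 + 1].sum())
        p = _tail_p(p_ge, p_le, alternative)
        return TestResult(name, w_plus, p, method="exact", n=n, group_stats=stats_groups)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(nz), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        ((tie_counts**3 - tie_counts) / 48.0).sum()
    )
    if var <= 0:
        return TestResult(name, w_plus, 1.0, method="approx", n=n,
                          group_stats=stats_groups, degenerate=True,
                          note="zero variance after tie correction")
    z = (w_plus - mu) / math.sqrt(var)
    return TestResult(name, w_plus, _norm_p(z, alternative), method="approx",
                      z=z, n=n, group_stats=stats_groups)


def mann_whitney_u(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two-sided",
    exact_limit: int = 12,
    name: str = "mann_whitney_u",
) -> TestResult:
    """Rank-sum test; the statistic is U for group A (pairs won + half-ties)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney_u: both groups must be non-empty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    group_stats = {
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "n_a": na,
        "n_b": nb,
    }
    n_total = na + nb
    if n_total <= exact_limit:
        us = []
        idx = range(n_total)
        for comb in itertools.combinations(idx, na):
            sel = np.fromiter(comb, int)
            us.append(float(ranks[sel].sum() - na * (na + 1) / 2.0))
        us = np.asarray(us)
        eps = 1e-9
        p_ge = float(np.mean(us >= u_a - eps))
        p_le = float(np.mean(us <= u_a + eps))
        return TestResult(name, u_a, _tail_p(p_ge, p_le, alternative),
                          method="exact", n=n_total, group_stats=group_stats)
    mu = na * nb / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n_total * (n_total - 1))
    var = na * nb / 12.0 * ((n_total + 1) - tie_term)
    if var <= 0:
        return TestResult(name, u_a, 1.0, method="approx", n=n_total,
                          group_stats=group_stats, degenerate=True,
                          note="all pooled values identical")
    z = (u_a - mu) / math.sqrt(var)
    return TestResult(name, u_a, _norm_p(z, alternative), method="approx",
                      z=z, n=n_total, group_stats=group_stats)


def paired_t(
    x: Sequence[float], y: Sequence[float], name: str = "paired_t"
) -> TestResult:
    """Two-sided paired t-test with explicit degenerate handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or x.size != y.size:
        raise ValueError("paired_t: need equal-length, non-empty paired samples")
    d = x - y
    n = d.size
    group_stats = {"mean_x": float(x.mean()), "mean_y": float(y.mean()),
                   "mean_diff": float(d.mean())}
    if n == 1:
        return TestResult(name, math.nan, math.nan, method="degenerate", n=1,
                          group_stats=group_stats, degenerate=True,
                          note="single pair: no variance estimate")
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if d.mean() == 0.0:
            return TestResult(name, 0.0, 1.0, method="degenerate", n=n,
                              group_stats=group_stats, degenerate=True,
                              note="identical paired values")
        t = math.inf if d.mean() > 0 else -math.inf
        return TestResult(name, t, 0.0, method="degenerate", n=n,
                          group_stats=group_stats, degenerate=True,
                          note="constant non-zero difference (infinite separation)")
    t = float(d.mean() / (sd / math.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return TestResult(name, t, p, method="t", n=n, group_stats=group_stats)


def paired_exposure_test(
    ads: pd.DataFrame,
    stratum_a: str,
    stratum_b: str,
    variety_level: Optional[int] = None,
    strategy: Optional[str] = None,
) -> TestResult:
    """Paired t-test on per-ad weekly impressions between two strata.

    When ``strategy``/``variety_level`` are given, the test restricts to ads
    whose variety on that strategy equals the level (level 4 covers 4+).  An
    empty stratum yields an explicit empty result, never an exception.
    """
    name = f"paired_t[{stratum_a} vs {stratum_b}"
    sub = ads
    if strategy is not None:
        if strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
        if variety_level not in VARIETY_LEVELS:
            raise ValueError(f"variety_level must be one of {VARIETY_LEVELS}")
        name += f", {strategy} variety {variety_level}"
        sub = ads[ads[f"{strategy}_variety"] == variety_level]
    name += "]"
    for stratum in (stratum_a, stratum_b):
        if f"wimp_{stratum}" not in ads.columns:
            raise KeyError(f"ads table lacks weekly impressions for stratum {stratum!r}")
    if len(sub) == 0:
        return TestResult(name, math.nan, math.nan, method="empty", n=0,
                          degenerate=True, note="no ads at the requested variety level")
    return paired_t(sub[f"wimp_{stratum_a}"], sub[f"wimp_{stratum_b}"], name=name)


def paired_test_grid(
    ads: pd.DataFrame,
    stratum_pairs: Sequence[Tuple[str, str]],
    strategies: Sequence[str] = STRATEGIES,
    levels: Sequence[int] = VARIETY_LEVELS,
) -> pd.DataFrame:
    """Grid of paired exposure tests by strategy x variety level x stratum pair."""
    rows = []
    for strategy in strategies:
        for level in levels:
            for sa, sb in stratum_pairs:
                res = paired_exposure_test(ads, sa, sb, level, strategy)
                rows.append({
                    "strategy": strategy,
                    "variety_level": level,
                    "stratum_a": sa,
                    "stratum_b": sb,
                    "n": res.n,
                    "mean_a": res.group_stats.get("mean_x", math.nan),
                    "mean_b": res.group_stats.get("mean_y", math.nan),
                    "t": res.statistic,
                    "p_value": res.p_value,
                    "degenerate": res.degenerate,
                })
    return pd.DataFrame(rows)


def holm_adjust(p_values: Sequence[float]) -> List[float]:
    """Holm step-down adjusted p-values (NaNs passed through)."""
    p = np.asarray(p_values, dtype=float)
    adjusted = np.full(p.shape, np.nan)
    valid = np.where(~np.isnan(p))[0]
    m = valid.size
    order = valid[np.argsort(p[valid], kind="mergesort")]
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adjusted[idx] = min(1.0, running)
    return list(adjusted)


# ---------------------------------------------------------------------------
# End-to-end orchestration


def run_full_analysis(
    airings: pd.DataFrame,
    nutrition: pd.DataFrame,
    codings: pd.DataFrame,
    populations: PopulationTable,
    *,
    top_fraction: float = 0.20,
    stratum: str = "overall",
    codebook: Optional[Codebook] = None,
    holm: bool = False,
    subsample_fraction: Optional[float] = 0.10,
    seed: Optional[int] = 0,
) -> Dict:
    """Run the whole pipeline and return the report bundle.

    Stages: unique-ad grouping -> weekly impressions -> top-quantile
    selection -> sample filters -> high-in classification -> variety scoring
    -> reliability -> descriptive tables -> rank tests -> paired-t grids.
    Any stage error is re-raised with the stage name prefixed.
    """
    from . import nutrient_profiling

    codebook = codebook or Codebook.default()
    bundle: Dict = {}

    def stage(label, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {label!r} failed: {exc}") from exc

    unique = stage("group_unique", group_unique, airings)
    unique = stage("weekly_impressions", add_weekly_impressions, unique, populations)
    selected, report = stage("select_top_fraction", select_top_fraction,
                             unique, top_fraction, stratum)
    final_ads, product_pairs, report = stage("apply_sample_filters", apply_sample_filters,
                                             selected, nutrition, report=report)
    bundle["selection_report"] = report

    with_nutrition = nutrition[nutrition["energy_kcal"].notna()]
    verdicts = stage("classify", nutrient_profiling.classify_table, with_nutrition)
    bundle["verdicts"] = verdicts

    coder1 = codings[codings["coder_id"] == 1].drop(columns="coder_id")
    coder2 = codings[codings["coder_id"] == 2].drop(columns="coder_id")
    coded_ads = set(coder1["ad_id"])
    uncoded = sorted(set(final_ads["ad_id"]) - coded_ads)
    if uncoded:
        raise RuntimeError(f"stage 'codings' failed: final ads without coding: {uncoded}")
    coder1_final = coder1[coder1["ad_id"].isin(final_ads["ad_id"])]

    if len(coder2):
        bundle["reliability"] = stage(
            "reliability", _reliability.reliability_report,
            coder1, coder2, subsample_fraction=subsample_fraction, seed=seed,
        )

    # keep only products that actually have a nutrition record for product-level work
    pairs_with_nutrition = product_pairs[
        product_pairs["product_id"].isin(verdicts["product_id"])
    ].reset_index(drop=True)
    products = stage("product_level_table", product_level_table,
                     pairs_with_nutrition, coder1_final, verdicts, final_ads, codebook)
    varieties = stage("variety_table", variety_table, coder1_final, codebook)
    final_with_scores = final_ads.merge(varieties, on="ad_id", how="left")
    bundle["final_ads"] = final_with_scores
    bundle["product_table"] = products

    bundle["variety_percentages"] = stage("variety_percentages",
                                          variety_percentage_table, products)
    bundle["appeal_prevalence"] = stage("appeal_prevalence", appeal_prevalence_table,
                                        products, coder1_final, codebook)

    tests: Dict[str, TestResult] = {}
    tests["wilcoxon_emotional_vs_rational"] = stage(
        "wilcoxon", wilcoxon_signed_rank,
        products["emotional_variety"], products["rational_variety"],
        name="wilcoxon_emotional_vs_rational",
    )
    hi_mask = products["overall_high_in"].to_numpy(bool)
    for strategy in STRATEGIES:
        key = f"mwu_{strategy}_by_high_in"
        col = products[f"{strategy}_variety"].to_numpy()
        if hi_mask.any() and (~hi_mask).any():
            tests[key] = stage("mann_whitney", mann_whitney_u,
                               col[hi_mask], col[~hi_mask], name=key)
        else:
            tests[key] = TestResult(key, math.nan, math.nan, method="empty",
                                    degenerate=True,
                                    note="one high-in group is empty")
    bundle["tests"] = tests

    ses_pairs = [("ses_low", "ses_mid"), ("ses_low", "ses_high"), ("ses_mid", "ses_high")]
    bundle["gender_grid"] = stage("gender_grid", paired_test_grid,
                                  final_with_scores, [("female", "male")])
    bundle["ses_grid"] = stage("ses_grid", paired_test_grid, final_with_scores, ses_pairs)

    if holm:
        for grid_key in ("gender_grid", "ses_grid"):
            grid = bundle[grid_key]
            grid["p_holm"] = holm_adjust(grid["p_value"])
    return bundle


def run_synthetic_analysis(config: SimConfig, **kwargs) -> Dict:
    """Simulate a full dataset from ``config`` and analyse it."""
    airings = simulate_airings(config)
    nutrition = simulate_products(config)
    ads = airings[["ad_id", "product_ids"]].drop_duplicates(subset="ad_id")
    codings = simulate_codings(config, ads, nutrition)
    kwargs.setdefault("seed", config.seed)
    return run_full_analysis(airings, nutrition, codings, config.populations, **kwargs)


# ---------------------------------------------------------------------------
# Null calibration


def null_config(seed: int, n_unique_ads: int = 120) -> SimConfig:
    """A generator configuration under which all three tests' nulls hold.

    Emotional and rational prevalence vectors are identical (so the paired
    signed-rank null holds), prevalence pairs are equal across high-in groups
    (rank-sum null), and gender multipliers *and* gender populations are equal
    (paired-t null).
    """
    flat = {t: (0.3, 0.3) for t in Codebook.default().appeal_types}
    pops = PopulationTable(overall=2_000_000, female=1_000_000, male=1_000_000,
                           ses_low=1_000_000, ses_mid=1_000_000, ses_high=1_000_000)
    return SimConfig(
        seed=seed,
        n_unique_ads=n_unique_ads,
        appeal_prevalence=flat,
        gender_gap=1.0,
        ses_gradient=(1.0, 1.0, 1.0),
        frac_high_in=0.5,
        populations=pops,
        instances_per_ad={"log_mean": 2.0, "log_sd": 0.8},
    )


def _one_null_replicate(config: SimConfig, codebook: Codebook) -> Dict[str, float]:
    # Unit of analysis is the ad: each test sees independent units, so the
    # replicate exercises the test implementations' calibration rather than
    # any within-ad clustering of broadcast product rows.
    from . import nutrient_profiling

    airings = simulate_airings(config)
    unique = add_weekly_impressions(group_unique(airings), config.populations)
    nutrition = simulate_products(config)
    codings = simulate_codings(config, unique, nutrition, codebook)
    coder1 = codings[codings["coder_id"] == 1].drop(columns="coder_id")
    varieties = variety_table(coder1, codebook)
    unique = unique.merge(varieties, on="ad_id", how="left")

    verdicts = nutrient_profiling.classify_table(nutrition)
    hi_products = set(verdicts.loc[verdicts["overall_high_in"], "product_id"])
    ad_high = np.array([
        any(p in hi_products for p in pl) for pl in unique["product_ids"]
    ])

    w = wilcoxon_signed_rank(unique["emotional_variety"], unique["rational_variety"])
    col = unique["emotional_variety"].to_numpy()
    if ad_high.any() and (~ad_high).any():
        m_p = mann_whitney_u(col[ad_high], col[~ad_high]).p_value
    else:
        m_p = 1.0
    t = paired_exposure_test(unique, "female", "male")
    return {"wilcoxon": w.p_value, "mann_whitney": m_p, "paired_t": t.p_value}


def type_one_error(
    n_reps: int = 1000, seed: int = 0, n_unique_ads: int = 120, alpha: float = 0.05
) -> Dict[str, float]:
    """Empirical type-I error of each test under the null generator."""
    codebook = Codebook.default()
    child_seeds = np.random.SeedSequence(seed).generate_state(n_reps)
    hits = {"wilcoxon": 0, "mann_whitney": 0, "paired_t": 0}
    for s in child_seeds:
        cfg = null_config(int(s), n_unique_ads=n_unique_ads)
        ps = _one_null_replicate(cfg, codebook)
        for k, p in ps.items():
            if p < alpha:
                hits[k] += 1
    return {k: v / n_reps for k, v in hits.items()}
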