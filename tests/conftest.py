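"""Shared fixtures and independent oracle implementations.

The oracles deliberately use brute-force strategies (position counting, sign
enumeration, label-assignment enumeration, per-instance summation) so they
stay independent of the library code paths they check.
"""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from admark.appeal_scoring import Codebook
from admark.config import PopulationTable, SimConfig


@pytest.fixture(scope="session")
def codebook() -> Codebook:
    return Codebook.default()


@pytest.fixture(scope="session")
def populations() -> PopulationTable:
    return PopulationTable()


@pytest.fixture()
def small_config() -> SimConfig:
    return SimConfig(seed=42, n_unique_ads=40)


def make_unique_ads(ratings_overall, n_instances=1, prefix="AD") -> pd.DataFrame:
    """Minimal unique-ad table with overall ratings only."""
    n = len(ratings_overall)
    if np.isscalar(n_instances):
        n_instances = [n_instances] * n
    return pd.DataFrame({
        "ad_id": [f"{prefix}{i:05d}" for i in range(1, n + 1)],
        "n_instances": list(n_instances),
        "avg_rating_overall": list(ratings_overall),
        "product_ids": [[f"P{i:06d}"] for i in range(1, n + 1)],
    })


# ---------------------------------------------------------------------------
# Oracles


def oracle_weekly_impressions(instance_ratings, population) -> float:
    """Per-instance brute-force sum: each instance reaches rating% of the
    population; the yearly total is spread over 52 weeks."""
    return sum(r / 100.0 * population for r in instance_ratings) / 52.0


def _midranks(values) -> list:
    """Mid-ranks computed by direct position counting (no scipy)."""
    values = list(values)
    ranks = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def oracle_signed_rank(x, y, alternative="two-sided"):
    """Exact signed-rank p by enumerating all sign assignments."""
    d = [xi - yi for xi, yi in zip(x, y) if xi != yi]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = _midranks([abs(v) for v in d])
    w_obs = sum(r for r, v in zip(ranks, d) if v > 0)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    eps = 1e-9
    p_ge = float(np.mean(ws >= w_obs - eps))
    p_le = float(np.mean(ws <= w_obs + eps))
    if alternative == "greater":
        return w_obs, p_ge
    if alternative == "less":
        return w_obs, p_le
    return w_obs, min(1.0, 2.0 * min(p_ge, p_le))


def oracle_u_statistic(a, b) -> float:
    """U for group a by direct pairwise comparison."""
    return float(sum(1.0 if ai > bi else (0.5 if ai == bi else 0.0)
                     for ai in a for bi in b))


def oracle_mann_whitney(a, b, alternative="two-sided"):
    """Exact rank-sum p by enumerating all group-label assignments."""
    pooled = list(a) + list(b)
    na = len(a)
    u_obs = oracle_u_statistic(a, b)
    us = []
    for comb in itertools.combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in range(len(pooled)) if i not in comb]
        us.append(oracle_u_statistic(ga, gb))
    us = np.asarray(us)
    eps = 1e-9
    p_ge = float(np.mean(us >= u_obs - eps))
    p_le = float(np.mean(us <= u_obs + eps))
    if alternative == "greater":
        return u_obs, p_ge
    if alternative == "less":
        return u_obs, p_le
    return u_obs, min(1.0, 2.0 * min(p_ge, p_le))


def make_filter_fixture(
    n_available=547, n_excluded=16, n_products=1091, n_excluded_products=78
):
    """Ad/nutrition fixture matching the sample-accounting bookkeeping.

    ``n_excluded`` ads carry only products with no nutrition record; those
    ads hold ``n_excluded_products`` products in total.  The remaining ads
    split the remaining products (each ad gets >= 1).
    """
    n_kept = n_available - n_excluded
    n_kept_products = n_products - n_excluded_products

    def split(total, bins):
        if bins == 0:
            return []
        base = total // bins
        sizes = [base] * bins
        for i in range(total - base * bins):
            sizes[i] += 1
        return sizes

    kept_sizes = split(n_kept_products, n_kept)
    excl_sizes = split(n_excluded_products, n_excluded)

    rows, nut_rows = [], []
    pid = 0
    for i, size in enumerate(kept_sizes + excl_sizes):
        lacking = i >= n_kept
        products = []
        for _ in range(size):
            pid += 1
            name = f"P{pid:06d}"
            products.append(name)
            nut_rows.append({
                "product_id": name,
                "energy_kcal": np.nan if lacking else 100.0,
                "free_sugars_g": 0.0, "total_fat_g": 0.0, "saturated_fat_g": 0.0,
                "trans_fat_g": 0.0, "sodium_mg": 0.0,
                "has_noncaloric_sweetener": False,
                "processing_category": "processed",
                "category": "food", "available_for_purchase": True,
            })
        rows.append({
            "ad_id": f"AD{i + 1:05d}",
            "n_instances": 1,
            "avg_rating_overall": 1.0,
            "product_ids": products,
        })
    return pd.DataFrame(rows), pd.DataFrame(nut_rows)
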