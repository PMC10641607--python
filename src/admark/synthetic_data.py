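"""Seeded generator of airing logs, nutrition tables and appeal codings.

The generator reproduces the statistical structure the downstream analysis
assumes — heavy-tailed airing counts, demographic exposure gradients, a
configurable fraction of high-in products, and appeal prevalences that are
conditional on whether an ad promotes any high-in product — without touching
any proprietary source.  Everything is driven by ``SimConfig.seed`` through
independent child streams, so each table is reproducible on its own and the
three tables are mutually consistent.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import nutrient_profiling
from .appeal_scoring import Codebook
from .config import SimConfig

_STREAMS = ("assignment", "airings", "products", "codings")


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(stream)])


@dataclass(frozen=True)
class _Assignment:
    """Deterministic ad/product structure shared by all three tables."""

    ad_ids: List[str]
    products_by_ad: Dict[str, List[str]]
    product_ids: List[str]
    product_high_in: np.ndarray  # bool, aligned with product_ids


def _assignment(config: SimConfig) -> _Assignment:
    rng = _rng(config, "assignment")
    n = config.n_unique_ads
    ad_ids = [f"AD{i:05d}" for i in range(1, n + 1)]
    ks = np.array(sorted(config.products_per_ad))
    ps = np.array([config.products_per_ad[k] for k in ks], dtype=float)
    ps = ps / ps.sum()
    counts = rng.choice(ks, size=n, p=ps)
    products_by_ad: Dict[str, List[str]] = {}
    product_ids: List[str] = []
    next_id = 1
    for ad_id, c in zip(ad_ids, counts):
        ids = [f"P{j:06d}" for j in range(next_id, next_id + int(c))]
        next_id += int(c)
        products_by_ad[ad_id] = ids
        product_ids.extend(ids)
    high_in = rng.random(len(product_ids)) < config.frac_high_in
    return _Assignment(ad_ids, products_by_ad, product_ids, high_in)


def _mean_one_lognormal(rng: np.random.Generator, sigma: float, size: int) -> np.ndarray:
    """Multiplicative noise with expectation exactly 1."""
    if sigma == 0:
        return np.ones(size)
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_airings(config: SimConfig) -> pd.DataFrame:
    """Generate one year of airing instances.

    Each unique ad gets >= 1 instances (log-normal counts, heavy tailed),
    one or two duration versions, and per-stratum rating points centred on
    ``rating_base`` and scaled by ``gender_gap`` / ``ses_gradient``.  The
    overall rating is derived from the gender strata so that impressions add
    up across genders; SES strata are left unconstrained.  Timestamps fall
    within the configured calendar year between 06:00 and 22:00.
    """
    asg = _assignment(config)
    rng = _rng(config, "airings")
    n_ads = config.n_unique_ads
    pops = config.populations

    base = config.rating_base * _mean_one_lognormal(rng, config.rating_ad_sd, n_ads)
    raw = rng.lognormal(
        mean=config.instances_per_ad.log_mean,
        sigma=config.instances_per_ad.log_sd,
        size=n_ads,
    )
    n_inst = np.maximum(1, np.rint(raw).astype(int))
    two_versions = rng.random(n_ads) < config.two_version_prob

    gap = config.gender_gap
    f_scale = 2.0 * gap / (1.0 + gap)
    m_scale = 2.0 / (1.0 + gap)
    grad = dict(zip(("ses_low", "ses_mid", "ses_high"), config.ses_gradient))

    rows: List[dict] = []
    window_start = 6 * 3600
    window_len = (22 - 6) * 3600
    year_start = pd.Timestamp(config.year, 1, 1)
    n_days = (pd.Timestamp(config.year + 1, 1, 1) - year_start).days

    for i, ad_id in enumerate(asg.ad_ids):
        k = int(n_inst[i])
        if two_versions[i]:
            durations = np.where(rng.random(k) < 0.5, 15.0, 30.0)
            if k >= 2:  # guarantee both versions actually air
                durations[0], durations[1] = 15.0, 30.0
        else:
            durations = np.full(k, float(rng.choice([15.0, 20.0, 30.0])))
        version_of = {15.0: "v15", 20.0: "v20", 30.0: "v30"}

        day = rng.integers(0, n_days, size=k)
        sec = rng.integers(0, window_len, size=k) + window_start
        ts = year_start + pd.to_timedelta(day * 86400 + sec, unit="s")

        noise = {s: _mean_one_lognormal(rng, config.rating_noise_sd, k)
                 for s in ("female", "male", "ses_low", "ses_mid", "ses_high")}
        r_female = base[i] * f_scale * noise["female"]
        r_male = base[i] * m_scale * noise["male"]
        r_overall = (r_female * pops.female + r_male * pops.male) / pops.overall
        channel = f"CH{rng.integers(1, 9):02d}"
        program = f"PR{rng.integers(1, 41):03d}"
        for j in range(k):
            rows.append({
                "ad_id": ad_id,
                "version_id": f"{ad_id}-{version_of[float(durations[j])]}",
                "timestamp": ts[j],
                "duration_s": float(durations[j]),
                "channel": channel,
                "program": program,
                "product_ids": list(asg.products_by_ad[ad_id]),
                "rating_overall": float(r_overall[j]),
                "rating_female": float(r_female[j]),
                "rating_male": float(r_male[j]),
                "rating_ses_low": float(base[i] * grad["ses_low"] * noise["ses_low"][j]),
                "rating_ses_mid": float(base[i] * grad["ses_mid"] * noise["ses_mid"][j]),
                "rating_ses_high": float(base[i] * grad["ses_high"] * noise["ses_high"][j]),
            })
    return pd.DataFrame(rows)


def simulate_products(config: SimConfig) -> pd.DataFrame:
    """Generate a nutrition table whose high-in fraction targets frac_high_in.

    Nutrient draws are constructed per target label and then *verified* by
    running them through :func:`nutrient_profiling.classify_table`; a mismatch
    is a generator bug and raises.
    """
    asg = _assignment(config)
    rng = _rng(config, "products")
    n = len(asg.product_ids)
    hi = asg.product_high_in

    energy = rng.uniform(50.0, 500.0, size=n)
    fs_frac = np.zeros(n)
    fat_frac = np.zeros(n)
    sat_frac = np.zeros(n)
    trans_frac = np.zeros(n)
    na_ratio = np.zeros(n)
    sweet = np.zeros(n, dtype=bool)
    category = np.empty(n, dtype=object)

    # --- not-high-in: half out-of-scope categories, half compliant products
    not_hi = ~hi
    n_not = int(not_hi.sum())
    if n_not:
        out_of_scope = rng.random(n_not) < 0.5
        cats = np.where(
            out_of_scope,
            np.where(rng.random(n_not) < 0.7,
                     "unprocessed_minimally_processed", "culinary_ingredient"),
            np.where(rng.random(n_not) < 0.5, "processed", "ultra_processed"),
        )
        category[not_hi] = cats
        fs_frac[not_hi] = rng.uniform(0.0, 0.09, n_not)
        fat_frac[not_hi] = rng.uniform(0.0, 0.28, n_not)
        sat_frac[not_hi] = np.minimum(rng.uniform(0.0, 0.09, n_not), fat_frac[not_hi])
        na_ratio[not_hi] = rng.uniform(0.0, 0.9, n_not)

    # --- high-in: in-scope category, at least one criterion forced to fire
    n_hi = int(hi.sum())
    if n_hi:
        category[hi] = np.where(rng.random(n_hi) < 0.8, "ultra_processed", "processed")
        fire_fs = rng.random(n_hi) < 0.6
        fire_fat = rng.random(n_hi) < 0.4
        fire_sat = rng.random(n_hi) < 0.3
        fire_na = rng.random(n_hi) < 0.3
        fire_sw = rng.random(n_hi) < 0.15
        fire_tr = rng.random(n_hi) < 0.05
        none_fired = ~(fire_fs | fire_fat | fire_sat | fire_na | fire_sw | fire_tr)
        fire_fs |= none_fired
        fs_frac[hi] = np.where(fire_fs, rng.uniform(0.10, 0.55, n_hi),
                               rng.uniform(0.0, 0.09, n_hi))
        fat_frac[hi] = np.where(fire_fat, rng.uniform(0.30, 0.65, n_hi),
                                rng.uniform(0.0, 0.28, n_hi))
        sat_raw = np.where(fire_sat, rng.uniform(0.10, 0.25, n_hi),
                           np.minimum(rng.uniform(0.0, 0.09, n_hi), fat_frac[hi]))
        sat_frac[hi] = sat_raw
        fat_frac[hi] = np.maximum(fat_frac[hi], sat_raw)  # total fat >= saturated
        trans_frac[hi] = np.where(fire_tr, rng.uniform(0.01, 0.03, n_hi), 0.0)
        na_ratio[hi] = np.where(fire_na, rng.uniform(1.0, 3.0, n_hi),
                                rng.uniform(0.0, 0.9, n_hi))
        sweet[hi] = fire_sw

    table = pd.DataFrame({
        "product_id": asg.product_ids,
        "energy_kcal": energy,
        "free_sugars_g": fs_frac * energy / nutrient_profiling.KCAL_PER_G_SUGAR,
        "total_fat_g": fat_frac * energy / nutrient_profiling.KCAL_PER_G_FAT,
        "saturated_fat_g": sat_frac * energy / nutrient_profiling.KCAL_PER_G_FAT,
        "trans_fat_g": trans_frac * energy / nutrient_profiling.KCAL_PER_G_FAT,
        "sodium_mg": na_ratio * energy,
        "has_noncaloric_sweetener": sweet,
        "processing_category": category,
        "category": "food",
        "available_for_purchase": True,
    })
    verdicts = nutrient_profiling.classify_table(table)
    if not np.array_equal(verdicts["overall_high_in"].to_numpy(), hi):
        raise RuntimeError("generator bug: drawn nutrients disagree with the classifier")
    return table


def simulate_codings(
    config: SimConfig,
    ads: pd.DataFrame,
    products: pd.DataFrame,
    codebook: Optional[Codebook] = None,
) -> pd.DataFrame:
    """Generate the two-coder appeal-flag table.

    Coder 1's flags are Bernoulli draws whose probability depends on whether
    the ad promotes any high-in product (as judged by the classifier, never a
    shortcut label); coder 2 equals coder 1 with each flag independently
    flipped at ``coder_error_rate``.
    """
    codebook = codebook or Codebook.default()
    unknown = sorted(set(config.appeal_prevalence) - set(codebook.appeal_types))
    if unknown:
        raise ValueError(
            f"appeal_prevalence has unknown appeal types {unknown}; "
            f"valid types: {sorted(codebook.appeal_types)}"
        )
    rng = _rng(config, "codings")

    verdicts = nutrient_profiling.classify_table(products)
    hi_products = set(verdicts.loc[verdicts["overall_high_in"], "product_id"])

    if "product_ids" in ads.columns:
        ad_rows = ads[["ad_id", "product_ids"]].drop_duplicates(subset="ad_id")
    else:
        raise ValueError("ads table must carry a product_ids column")
    ad_ids = ad_rows["ad_id"].to_numpy()
    ad_high = np.array([
        any(p in hi_products for p in pl) for pl in ad_rows["product_ids"]
    ])

    n = len(ad_ids)
    coder1 = {"ad_id": ad_ids, "coder_id": np.full(n, 1)}
    coder2 = {"ad_id": ad_ids, "coder_id": np.full(n, 2)}
    for appeal in codebook.appeal_types:
        p_hi, p_not = config.appeal_prevalence.get(appeal, (0.0, 0.0))
        p = np.where(ad_high, p_hi, p_not)
        flags = (rng.random(n) < p).astype(int)
        flips = rng.random(n) < config.coder_error_rate
        coder1[appeal] = flags
        coder2[appeal] = np.where(flips, 1 - flags, flags)
    return pd.concat([pd.DataFrame(coder1), pd.DataFrame(coder2)], ignore_index=True)


def simulate_dataset(config: SimConfig) -> Dict[str, pd.DataFrame]:
    """Generate the full consistent bundle of synthetic inputs."""
    airings = simulate_airings(config)
    products = simulate_products(config)
    ads = airings[["ad_id", "product_ids"]].drop_duplicates(subset="ad_id")
    codings = simulate_codings(config, ads, products)
    return {"airings": airings, "nutrition": products, "codings": codings}
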