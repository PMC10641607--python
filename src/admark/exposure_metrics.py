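"""Exposure metrics: unique-ad grouping, weekly impressions, top-quantile
selection and sample-filter bookkeeping.

Conventions (documented because source data dictionaries tend to omit them):

* Rating points are percentages of the stratum audience: a rating of 1.0
  reaches 1 % of the stratum population, so ratings are divided by 100
  before multiplying by population counts.
* Average weekly impressions = (avg_rating / 100) x population x
  n_instances / 52.  The divisor is fixed at 52 regardless of leap years.
* The top-quantile count is floor(fraction x N); boundary ties are broken
  by ascending ad_id so selection is deterministic.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .config import STRATA, PopulationTable

WEEKS_PER_YEAR = 52.0

#: Product categories excluded from the content-analysis sample.
DEFAULT_EXCLUDED_CATEGORIES = ("alcoholic_beverages", "cooking_ingredients")


@dataclass
class SelectionReport:
    """Bookkeeping for selection and filtering, with arithmetic invariants."""

    n_unique_in: int = 0
    fraction: float = 0.0
    n_selected: int = 0
    threshold_impressions: float = float("nan")
    n_after_category_filter: Optional[int] = None
    n_available_for_purchase: Optional[int] = None
    n_excluded_no_nutrition: Optional[int] = None
    n_final_ads: Optional[int] = None
    n_final_products: Optional[int] = None
    exclusions: List[Dict[str, str]] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_selected != math.floor(self.fraction * self.n_unique_in):
            raise ValueError(
                f"n_selected={self.n_selected} != floor({self.fraction} x {self.n_unique_in})"
            )
        if self.n_final_ads is not None:
            if self.n_final_ads != self.n_available_for_purchase - self.n_excluded_no_nutrition:
                raise ValueError(
                    "n_final_ads must equal n_available_for_purchase - n_excluded_no_nutrition"
                )

    def as_dict(self) -> dict:
        return asdict(self)


def _rating_cols(df: pd.DataFrame) -> List[str]:
    return [c for c in df.columns if c.startswith("rating_")]


def group_unique(instances: pd.DataFrame) -> pd.DataFrame:
    """Collapse airing instances into one row per unique ad.

    Versions of an ad differing only in duration are merged; the longest
    version is recorded as the extended version (the one used downstream for
    content coding).  Per-stratum average ratings are arithmetic means over
    every instance of every version.
    """
    if instances is None or len(instances) == 0:
        raise ValueError("group_unique: instance table is empty")
    rating_cols = _rating_cols(instances)
    if not rating_cols:
        raise ValueError("group_unique: no rating_* columns present")
    for col in rating_cols:
        bad = instances.loc[instances[col].isna(), "ad_id"]
        if len(bad):
            raise ValueError(
                f"group_unique: missing {col} for ad(s) {sorted(bad.unique())}"
            )

    rows = []
    for ad_id, grp in instances.groupby("ad_id", sort=True):
        longest = grp.loc[grp["duration_s"].idxmax()]
        products: set = set()
        for pl in grp["product_ids"]:
            products.update(pl)
        row = {
            "ad_id": ad_id,
            "n_instances": int(len(grp)),
            "n_versions": int(grp["version_id"].nunique()),
            "extended_version_id": longest["version_id"],
            "extended_duration_s": float(longest["duration_s"]),
            "product_ids": sorted(products),
        }
        for col in rating_cols:
            row[col.replace("rating_", "avg_rating_")] = float(grp[col].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def weekly_impressions(
    ad: Mapping, populations: PopulationTable | Mapping[str, int], stratum: str
) -> float:
    """Average weekly impressions of one unique ad for one stratum.

    Equals (avg_rating / 100) x population x n_instances / 52, which is
    identical to summing per-instance impressions and dividing by 52.
    """
    key = f"avg_rating_{stratum}"
    if key not in ad:
        raise KeyError(f"ad has no average rating for stratum {stratum!r}")
    pop = populations[stratum] if not isinstance(populations, PopulationTable) else populations[stratum]
    return float(ad[key]) / 100.0 * pop * int(ad["n_instances"]) / WEEKS_PER_YEAR


def add_weekly_impressions(
    unique_ads: pd.DataFrame, populations: PopulationTable | Mapping[str, int]
) -> pd.DataFrame:
    """Add a ``wimp_<stratum>`` column for every stratum with an avg rating."""
    out = unique_ads.copy()
    pops = populations.as_dict() if isinstance(populations, PopulationTable) else dict(populations)
    for stratum, pop in pops.items():
        col = f"avg_rating_{stratum}"
        if col in out.columns:
            out[f"wimp_{stratum}"] = (
                out[col] / 100.0 * pop * out["n_instances"] / WEEKS_PER_YEAR
            )
    return out


def select_top_fraction(
    ads: pd.DataFrame, fraction: float, stratum: str = "overall"
) -> Tuple[pd.DataFrame, SelectionReport]:
    """Select the floor(fraction x N) ads with the highest weekly impressions.

    Ties at the selection boundary are broken by ascending ad_id.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    col = f"wimp_{stratum}"
    if col not in ads.columns:
        raise KeyError(f"ads table has no weekly-impressions column for stratum {stratum!r}")
    n = len(ads)
    n_selected = math.floor(fraction * n)
    ranked = ads.sort_values(
        [col, "ad_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    selected = ranked.iloc[:n_selected].reset_index(drop=True)
    report = SelectionReport(
        n_unique_in=n,
        fraction=fraction,
        n_selected=n_selected,
        threshold_impressions=float(selected[col].min()) if n_selected else float("nan"),
    )
    report.validate()
    return selected, report


def apply_sample_filters(
    selected_ads: pd.DataFrame,
    nutrition: pd.DataFrame,
    excluded_categories: Iterable[str] = DEFAULT_EXCLUDED_CATEGORIES,
    report: Optional[SelectionReport] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, SelectionReport]:
    """Apply the content-analysis sample filters, in order.

    1. Drop ads whose products all belong to excluded categories
       (alcoholic beverages, cooking ingredients).
    2. Drop ads with no product available for purchase.
    3. Drop ads for which no promoted product has a nutrition record
       (``energy_kcal`` missing in the nutrition table).

    Returns (final ads, per-(ad, product) pair table of surviving ads,
    report).  All removals are logged in ``report.exclusions``.
    """
    report = report or SelectionReport(
        n_unique_in=len(selected_ads), fraction=1.0, n_selected=len(selected_ads)
    )
    excluded_categories = set(excluded_categories)

    missing = sorted(
        {p for pl in selected_ads["product_ids"] for p in pl}
        - set(nutrition["product_id"])
    )
    if missing:
        raise ValueError(f"products referenced by ads but absent from nutrition table: {missing}")

    nut = nutrition.set_index("product_id")
    category = nut["category"] if "category" in nut.columns else pd.Series("food", index=nut.index)
    if "available_for_purchase" in nut.columns:
        available = nut["available_for_purchase"].astype(bool)
    else:
        available = pd.Series(True, index=nut.index)
    has_nutrition = nut["energy_kcal"].notna()

    ads = selected_ads
    keep, dropped = [], []
    for _, row in ads.iterrows():
        cats = {category[p] for p in row["product_ids"]}
        if cats and cats <= excluded_categories:
            dropped.append({"ad_id": row["ad_id"], "stage": "category",
                            "reason": f"all products in excluded categories {sorted(cats)}"})
        else:
            keep.append(row["ad_id"])
    report.exclusions.extend(dropped)
    ads = ads[ads["ad_id"].isin(keep)]
    report.n_after_category_filter = len(ads)

    keep, dropped = [], []
    for _, row in ads.iterrows():
        if any(available[p] for p in row["product_ids"]):
            keep.append(row["ad_id"])
        else:
            dropped.append({"ad_id": row["ad_id"], "stage": "availability",
                            "reason": "no product available for purchase"})
    report.exclusions.extend(dropped)
    ads = ads[ads["ad_id"].isin(keep)]
    report.n_available_for_purchase = len(ads)

    keep, dropped = [], []
    for _, row in ads.iterrows():
        if any(has_nutrition[p] for p in row["product_ids"]):
            keep.append(row["ad_id"])
        else:
            dropped.append({"ad_id": row["ad_id"], "stage": "nutrition",
                            "reason": "no nutrition record for any promoted product"})
    report.exclusions.extend(dropped)
    report.n_excluded_no_nutrition = len(dropped)
    final_ads = ads[ads["ad_id"].isin(keep)].reset_index(drop=True)
    report.n_final_ads = len(final_ads)

    pairs = [
        {"ad_id": row["ad_id"], "product_id": p}
        for _, row in final_ads.iterrows()
        for p in row["product_ids"]
    ]
    product_table = pd.DataFrame(pairs, columns=["ad_id", "product_id"])
    report.n_final_products = len(product_table)
    report.validate()
    return final_ads, product_table, report
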