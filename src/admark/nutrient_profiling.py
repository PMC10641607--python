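"""Nutrient-profile classification of advertised products.

Processed and ultra-processed products are flagged "high-in" when they meet
any of six criteria on the excess of critical nutrients:

1. >= 10 % of total energy from free sugars,
2. >= 30 % of total energy from total fat,
3. >= 10 % of total energy from saturated fat,
4. >= 1 % of total energy from trans fat,
5. >= 1 mg of sodium per kcal,
6. any non-caloric sweetener among the ingredients.

All thresholds are inclusive.  Unprocessed/minimally-processed products and
culinary ingredients are out of the model's scope: they are reported as
``applicable=False`` with every flag off.

Energy conversion uses the standard Atwater factors (4 kcal/g for sugars,
9 kcal/g for fats).  Zero-energy products with a positive problematic
nutrient are treated as an infinite energy fraction, so the criterion fires.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

KCAL_PER_G_SUGAR = 4.0
KCAL_PER_G_FAT = 9.0

PROCESSING_CATEGORIES = (
    "unprocessed_minimally_processed",
    "culinary_ingredient",
    "processed",
    "ultra_processed",
)

#: Categories the high-in thresholds apply to.
APPLICABLE_CATEGORIES = frozenset({"processed", "ultra_processed"})

#: Inclusive thresholds, in the unit of the corresponding criterion.
THRESHOLDS = {
    "free_sugars": 0.10,   # fraction of total energy
    "total_fat": 0.30,     # fraction of total energy
    "saturated_fat": 0.10, # fraction of total energy
    "trans_fat": 0.01,     # fraction of total energy
    "sodium": 1.0,         # mg per kcal
}

CRITERIA = ("free_sugars", "total_fat", "saturated_fat", "trans_fat", "sodium", "sweetener")


@dataclass(frozen=True)
class ProductNutrition:
    """Label-derived nutrient amounts for one product (per reference amount)."""

    product_id: str
    energy_kcal: float
    free_sugars_g: float
    total_fat_g: float
    saturated_fat_g: float
    trans_fat_g: float
    sodium_mg: float
    has_noncaloric_sweetener: bool
    processing_category: str

    def __post_init__(self) -> None:
        for f in ("energy_kcal", "free_sugars_g", "total_fat_g",
                  "saturated_fat_g", "trans_fat_g", "sodium_mg"):
            v = getattr(self, f)
            if v < 0 or math.isnan(v):
                raise ValueError(f"{f} must be >= 0, got {v!r} for product {self.product_id!r}")
        if self.processing_category not in PROCESSING_CATEGORIES:
            raise ValueError(
                f"unknown processing_category {self.processing_category!r} for product "
                f"{self.product_id!r}; expected one of {PROCESSING_CATEGORIES}"
            )


@dataclass(frozen=True)
class HighInVerdict:
    """Per-criterion flags plus the overall high-in decision for one product."""

    product_id: str
    applicable: bool
    free_sugars: bool
    total_fat: bool
    saturated_fat: bool
    trans_fat: bool
    sodium: bool
    sweetener: bool
    overall_high_in: bool

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def energy_fraction(nutrient_grams: float, kcal_per_gram: float, energy_kcal: float) -> float:
    """Fraction of total energy contributed by a nutrient.

    Returns ``inf`` when ``energy_kcal`` is zero but the nutrient is present
    (the criterion then fires by convention), and 0 when both are zero.
    """
    if nutrient_grams < 0 or kcal_per_gram < 0 or energy_kcal < 0:
        raise ValueError("energy_fraction: all inputs must be >= 0")
    if energy_kcal == 0:
        return math.inf if nutrient_grams * kcal_per_gram > 0 else 0.0
    return nutrient_grams * kcal_per_gram / energy_kcal


def _sodium_per_kcal(sodium_mg: float, energy_kcal: float) -> float:
    if energy_kcal == 0:
        return math.inf if sodium_mg > 0 else 0.0
    return sodium_mg / energy_kcal


def classify(product: ProductNutrition) -> HighInVerdict:
    """Apply the six high-in criteria to one product.

    Pure function: same input, same verdict.
    """
    applicable = product.processing_category in APPLICABLE_CATEGORIES
    if not applicable:
        return HighInVerdict(product.product_id, False,
                             False, False, False, False, False, False, False)
    e = product.energy_kcal
    flags = {
        "free_sugars": energy_fraction(product.free_sugars_g, KCAL_PER_G_SUGAR, e)
        >= THRESHOLDS["free_sugars"],
        "total_fat": energy_fraction(product.total_fat_g, KCAL_PER_G_FAT, e)
        >= THRESHOLDS["total_fat"],
        "saturated_fat": energy_fraction(product.saturated_fat_g, KCAL_PER_G_FAT, e)
        >= THRESHOLDS["saturated_fat"],
        "trans_fat": energy_fraction(product.trans_fat_g, KCAL_PER_G_FAT, e)
        >= THRESHOLDS["trans_fat"],
        "sodium": _sodium_per_kcal(product.sodium_mg, e) >= THRESHOLDS["sodium"],
        "sweetener": bool(product.has_noncaloric_sweetener),
    }
    return HighInVerdict(
        product_id=product.product_id,
        applicable=True,
        overall_high_in=any(flags.values()),
        **flags,
    )


def classify_table(nutrition: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`classify` over a nutrition table.

    Returns one row per product with the seven boolean columns plus
    ``applicable``.  Rows whose ``processing_category`` is unknown raise.
    """
    required = ["product_id", "energy_kcal", "free_sugars_g", "total_fat_g",
                "saturated_fat_g", "trans_fat_g", "sodium_mg",
                "has_noncaloric_sweetener", "processing_category"]
    missing = [c for c in required if c not in nutrition.columns]
    if missing:
        raise ValueError(f"nutrition table is missing columns: {missing}")
    bad_cat = sorted(set(nutrition["processing_category"]) - set(PROCESSING_CATEGORIES))
    if bad_cat:
        raise ValueError(
            f"unknown processing_category values {bad_cat}; expected one of {PROCESSING_CATEGORIES}"
        )

    e = nutrition["energy_kcal"].to_numpy(dtype=float)
    for col in required[1:7]:
        vals = nutrition[col].to_numpy(dtype=float)
        if np.any(vals < 0) or np.any(np.isnan(vals)):
            bad = nutrition.loc[(nutrition[col] < 0) | nutrition[col].isna(), "product_id"]
            raise ValueError(f"{col} must be >= 0; offending products: {list(bad)}")

    def frac(grams: np.ndarray, kcal_per_g: float) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(e > 0, grams * kcal_per_g / np.where(e > 0, e, 1.0),
                           np.where(grams * kcal_per_g > 0, np.inf, 0.0))
        return out

    applicable = nutrition["processing_category"].isin(APPLICABLE_CATEGORIES).to_numpy()
    flags = {
        "free_sugars": frac(nutrition["free_sugars_g"].to_numpy(float), KCAL_PER_G_SUGAR)
        >= THRESHOLDS["free_sugars"],
        "total_fat": frac(nutrition["total_fat_g"].to_numpy(float), KCAL_PER_G_FAT)
        >= THRESHOLDS["total_fat"],
        "saturated_fat": frac(nutrition["saturated_fat_g"].to_numpy(float), KCAL_PER_G_FAT)
        >= THRESHOLDS["saturated_fat"],
        "trans_fat": frac(nutrition["trans_fat_g"].to_numpy(float), KCAL_PER_G_FAT)
        >= THRESHOLDS["trans_fat"],
        "sodium": np.where(
            e > 0,
            nutrition["sodium_mg"].to_numpy(float) / np.where(e > 0, e, 1.0),
            np.where(nutrition["sodium_mg"].to_numpy(float) > 0, np.inf, 0.0),
        )
        >= THRESHOLDS["sodium"],
        "sweetener": nutrition["has_noncaloric_sweetener"].astype(bool).to_numpy(),
    }
    out = pd.DataFrame({"product_id": nutrition["product_id"].to_numpy()})
    out["applicable"] = applicable
    overall = np.zeros(len(out), dtype=bool)
    for name, vals in flags.items():
        gated = vals & applicable
        out[name] = gated
        overall |= gated
    out["overall_high_in"] = overall
    return out
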