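"""Appeal codebook handling and emotional/rational variety scoring.

Each ad is coded for the presence (1) or absence (0) of a set of appeal
types, each belonging to either the *emotional* or the *rational* persuasive
strategy.  The variety score for a strategy is the number of distinct flagged
types of that strategy, capped at 4, giving an ordinal 0-4 scale.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

STRATEGIES = ("emotional", "rational")
VARIETY_CAP = 4
VARIETY_LEVELS = (0, 1, 2, 3, 4)


@dataclass(frozen=True)
class Codebook:
    """Maps appeal-type ids to their strategy and definitional text."""

    strategies: Dict[str, str]
    definitions: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {t: s for t, s in self.strategies.items() if s not in STRATEGIES}
        if bad:
            raise ValueError(f"appeal strategies must be one of {STRATEGIES}; got {bad}")

    @property
    def appeal_types(self) -> Tuple[str, ...]:
        return tuple(self.strategies)

    def types_for(self, strategy: str) -> Tuple[str, ...]:
        if strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
        return tuple(t for t, s in self.strategies.items() if s == strategy)

    @property
    def emotional_types(self) -> Tuple[str, ...]:
        return self.types_for("emotional")

    @property
    def rational_types(self) -> Tuple[str, ...]:
        return self.types_for("rational")

    @classmethod
    def from_mapping(cls, payload: Mapping) -> "Codebook":
        types = payload["appeal_types"]
        return cls(
            strategies={t: spec["strategy"] for t, spec in types.items()},
            definitions={t: spec.get("definition", "") for t, spec in types.items()},
        )

    @classmethod
    def load(cls, path: str | Path) -> "Codebook":
        with open(path, encoding="utf-8") as fh:
            return cls.from_mapping(json.load(fh))

    @classmethod
    def default(cls) -> "Codebook":
        ref = resources.files("admark.data").joinpath("codebook.json")
        return cls.from_mapping(json.loads(ref.read_text(encoding="utf-8")))


@dataclass(frozen=True)
class VarietyScore:
    ad_id: str
    emotional_variety: int
    rational_variety: int

    @property
    def any_emotional(self) -> bool:
        return self.emotional_variety >= 1

    @property
    def any_rational(self) -> bool:
        return self.rational_variety >= 1

    @property
    def no_coded_appeal(self) -> bool:
        return self.emotional_variety == 0 and self.rational_variety == 0


def variety_scores(ad_id: str, flags: Mapping[str, int], codebook: Codebook) -> VarietyScore:
    """Score one ad's flag map into the two ordinal 0-4 variety scales."""
    unknown = sorted(set(flags) - set(codebook.appeal_types))
    if unknown:
        raise ValueError(
            f"ad {ad_id!r}: flags for unknown appeal types {unknown}; "
            f"valid types: {sorted(codebook.appeal_types)}"
        )
    for t, v in flags.items():
        if v not in (0, 1, True, False):
            raise ValueError(f"ad {ad_id!r}: flag for {t!r} must be 0 or 1, got {v!r}")
    counts = {s: sum(int(flags.get(t, 0)) for t in codebook.types_for(s)) for s in STRATEGIES}
    return VarietyScore(
        ad_id=ad_id,
        emotional_variety=min(counts["emotional"], VARIETY_CAP),
        rational_variety=min(counts["rational"], VARIETY_CAP),
    )


def variety_table(codings: pd.DataFrame, codebook: Codebook) -> pd.DataFrame:
    """Vectorised variety scoring for a one-coder codings table.

    ``codings`` must hold one row per ad with one 0/1 column per appeal type
    (extra non-appeal columns other than ad_id/coder_id are rejected).
    """
    if "ad_id" not in codings.columns:
        raise ValueError("codings table must have an ad_id column")
    flag_cols = [c for c in codings.columns if c not in ("ad_id", "coder_id")]
    unknown = sorted(set(flag_cols) - set(codebook.appeal_types))
    if unknown:
        raise ValueError(
            f"codings table has flags for unknown appeal types {unknown}; "
            f"valid types: {sorted(codebook.appeal_types)}"
        )
    if codings["ad_id"].duplicated().any():
        dupes = sorted(codings.loc[codings["ad_id"].duplicated(), "ad_id"].unique())
        raise ValueError(f"variety_table expects one row per ad; duplicated ad_ids: {dupes}")
    vals = codings[flag_cols].to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("appeal flags must be binary 0/1")
    out = pd.DataFrame({"ad_id": codings["ad_id"].to_numpy()})
    for strategy in STRATEGIES:
        cols = [t for t in codebook.types_for(strategy) if t in flag_cols]
        counts = codings[cols].to_numpy().sum(axis=1) if cols else np.zeros(len(codings), int)
        out[f"{strategy}_variety"] = np.minimum(counts, VARIETY_CAP).astype(int)
    out["any_emotional"] = out["emotional_variety"] >= 1
    out["any_rational"] = out["rational_variety"] >= 1
    out["both_strategies"] = out["any_emotional"] & out["any_rational"]
    out["no_coded_appeal"] = ~out["any_emotional"] & ~out["any_rational"]
    return out


def product_level_table(
    product_pairs: pd.DataFrame,
    codings: pd.DataFrame,
    verdicts: pd.DataFrame,
    ads: pd.DataFrame,
    codebook: Codebook,
) -> pd.DataFrame:
    """Assemble the per-product analysis table.

    One row per (ad, product) pair carrying the ad's variety scores and
    per-stratum weekly impressions, plus the product's high-in status.
    Variety scores are coded once per ad (on its extended version) and
    broadcast to all products the ad promotes.
    """
    varieties = variety_table(codings, codebook)
    missing_cod = sorted(set(product_pairs["ad_id"]) - set(varieties["ad_id"]))
    if missing_cod:
        raise ValueError(f"ads without a reconciled coding: {missing_cod}")
    missing_v = sorted(set(product_pairs["product_id"]) - set(verdicts["product_id"]))
    if missing_v:
        raise ValueError(f"products without a high-in verdict: {missing_v}")

    wimp_cols = [c for c in ads.columns if c.startswith("wimp_")]
    table = product_pairs.merge(varieties, on="ad_id", how="left")
    table = table.merge(
        verdicts[["product_id", "applicable", "overall_high_in"]], on="product_id", how="left"
    )
    table = table.merge(ads[["ad_id", "n_instances", *wimp_cols]], on="ad_id", how="left")
    return table.sort_values(["ad_id", "product_id"], kind="mergesort").reset_index(drop=True)


def _pct(counts: np.ndarray, total: int) -> np.ndarray:
    if total == 0:
        return np.full(counts.shape, np.nan)
    return 100.0 * counts / total


def variety_percentage_table(products: pd.DataFrame) -> pd.DataFrame:
    """Percentage of products at each variety level, per strategy and group.

    Groups: all products, products classified high-in, products not high-in.
    Percentages within each (strategy, group) sum to 100 when the group is
    non-empty.
    """
    groups = {
        "all": np.ones(len(products), dtype=bool),
        "high_in": products["overall_high_in"].to_numpy(bool),
        "not_high_in": ~products["overall_high_in"].to_numpy(bool),
    }
    rows = []
    for strategy in STRATEGIES:
        scores = products[f"{strategy}_variety"].to_numpy()
        for gname, mask in groups.items():
            sub = scores[mask]
            counts = np.array([(sub == lvl).sum() for lvl in VARIETY_LEVELS])
            pct = _pct(counts, len(sub))
            row = {"strategy": strategy, "group": gname, "n": len(sub)}
            row.update({f"pct_variety_{lvl}": pct[i] for i, lvl in enumerate(VARIETY_LEVELS)})
            rows.append(row)
    return pd.DataFrame(rows)


def appeal_prevalence_table(
    products: pd.DataFrame, codings: pd.DataFrame, codebook: Codebook
) -> pd.DataFrame:
    """Percentage of products promoted in ads featuring each appeal type.

    Also reports the any-emotional / any-rational / both / none summary rows,
    all split by high-in group.
    """
    merged = products.merge(codings, on="ad_id", how="left", validate="many_to_one")
    groups = {
        "all": np.ones(len(merged), dtype=bool),
        "high_in": merged["overall_high_in"].to_numpy(bool),
        "not_high_in": ~merged["overall_high_in"].to_numpy(bool),
    }
    rows = []
    summary_cols = {
        "any_emotional": merged["any_emotional"],
        "any_rational": merged["any_rational"],
        "both_strategies": merged["both_strategies"],
        "no_coded_appeal": merged["no_coded_appeal"],
    }
    for appeal in codebook.appeal_types:
        flagged = merged[appeal].to_numpy(bool)
        row = {"appeal_type": appeal, "strategy": codebook.strategies[appeal]}
        for gname, mask in groups.items():
            n = int(mask.sum())
            row[f"pct_{gname}"] = 100.0 * flagged[mask].sum() / n if n else np.nan
        rows.append(row)
    for name, series in summary_cols.items():
        vals = series.to_numpy(bool)
        row = {"appeal_type": name, "strategy": "summary"}
        for gname, mask in groups.items():
            n = int(mask.sum())
            row[f"pct_{gname}"] = 100.0 * vals[mask].sum() / n if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
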