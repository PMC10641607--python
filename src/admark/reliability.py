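"""Intercoder reliability: percent agreement and Cohen's kappa per code.

Kappa is chance-corrected agreement, kappa = (p_o - p_e) / (1 - p_e), with
p_e the product-of-marginals expected agreement.  When p_e = 1 (both coders
used a single identical category) kappa is undefined and reported as NaN
with ``kappa_defined = False`` rather than coerced to 0 or 1.
"""
from __future__ import annotations

import math
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd


def _as_binary(v: Sequence) -> np.ndarray:
    arr = np.asarray(v)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError("flag vectors must be 1-D with length >= 1")
    return arr


def percent_agreement(flags1: Sequence, flags2: Sequence) -> float:
    """Percentage of positions on which the two coders agree."""
    a, b = _as_binary(flags1), _as_binary(flags2)
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    return 100.0 * float(np.mean(a == b))


def cohens_kappa(flags1: Sequence, flags2: Sequence) -> float:
    """Cohen's kappa for two coders; NaN when expected agreement is 1."""
    a, b = _as_binary(flags1), _as_binary(flags2)
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    n = a.size
    categories = np.union1d(a, b)
    p_o = float(np.mean(a == b))
    p_e = sum(
        float(np.mean(a == c)) * float(np.mean(b == c)) for c in categories
    )
    if abs(1.0 - p_e) < 1e-12:
        return math.nan
    return (p_o - p_e) / (1.0 - p_e)


def subsample_ads(
    ad_ids: Sequence, fraction: float = 0.10, min_n: int = 59, seed: Optional[int] = None
) -> np.ndarray:
    """Seeded random subsample of ads for a reliability assessment.

    Size is max(ceil(fraction x n), min_n), capped at the number of ads.
    """
    ids = np.asarray(sorted(ad_ids))
    size = min(len(ids), max(math.ceil(fraction * len(ids)), min_n))
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(ids, size=size, replace=False))


def reliability_report(
    coder1: pd.DataFrame,
    coder2: pd.DataFrame,
    subsample_fraction: Optional[float] = 0.10,
    min_n: int = 59,
    seed: Optional[int] = None,
) -> Dict:
    """Per-code agreement and kappa on a (sub)sample of commonly coded ads.

    ``coder1`` / ``coder2`` are one-row-per-ad flag tables.  Pass
    ``subsample_fraction=None`` to use every commonly coded ad.
    """
    flag_cols = [c for c in coder1.columns if c not in ("ad_id", "coder_id")]
    if set(flag_cols) != {c for c in coder2.columns if c not in ("ad_id", "coder_id")}:
        raise ValueError("coder tables must share the same appeal-type columns")
    common = sorted(set(coder1["ad_id"]) & set(coder2["ad_id"]))
    if not common:
        raise ValueError("no commonly coded ads between the two coders")
    if subsample_fraction is not None:
        common = list(subsample_ads(common, subsample_fraction, min_n, seed))
    a = coder1.set_index("ad_id").loc[common, flag_cols]
    b = coder2.set_index("ad_id").loc[common, flag_cols]

    rows = []
    for col in flag_cols:
        pa = percent_agreement(a[col], b[col])
        k = cohens_kappa(a[col], b[col])
        rows.append({
            "appeal_type": col,
            "n_ads": len(common),
            "percent_agreement": pa,
            "kappa": k,
            "kappa_defined": not math.isnan(k),
        })
    per_code = pd.DataFrame(rows)
    defined = per_code.loc[per_code["kappa_defined"], "kappa"]
    summary = {
        "n_ads": len(common),
        "agreement_min": float(per_code["percent_agreement"].min()),
        "agreement_max": float(per_code["percent_agreement"].max()),
        "kappa_min": float(defined.min()) if len(defined) else math.nan,
        "kappa_max": float(defined.max()) if len(defined) else math.nan,
        "n_undefined_kappa": int((~per_code["kappa_defined"]).sum()),
    }
    return {"per_code": per_code, "summary": summary}
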