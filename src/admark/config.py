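"""Configuration models shared across the pipeline.

All randomness in the package flows through :class:`SimConfig.seed`; a fixed
seed yields byte-identical outputs.
"""
from __future__ import annotations

from typing import Dict, Optional, Tuple

from pydantic import BaseModel, ConfigDict, Field, model_validator

#: Audience strata carried on every airing record.  Rating points are
#: expressed per stratum: 1 point = 1 % of that stratum's audience.
STRATA: Tuple[str, ...] = ("overall", "female", "male", "ses_low", "ses_mid", "ses_high")

SES_STRATA: Tuple[str, ...] = ("ses_low", "ses_mid", "ses_high")


class PopulationTable(BaseModel):
    """Child-population counts (persons) per audience stratum.

    The gender split must be internally consistent (female + male = overall);
    the SES strata are deliberately left unconstrained because published
    projection tables are not always consistent with the overall figure.
    """

    model_config = ConfigDict(frozen=True)

    overall: int = 2_470_700
    female: int = 1_260_057
    male: int = 1_210_643
    ses_low: int = 1_235_350
    ses_mid: int = 938_866
    ses_high: int = 444_726

    @model_validator(mode="after")
    def _check(self) -> "PopulationTable":
        for name in STRATA:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name}: population count must be a positive integer")
        if self.female + self.male != self.overall:
            raise ValueError(
                f"female ({self.female}) + male ({self.male}) must equal "
                f"overall ({self.overall})"
            )
        return self

    def as_dict(self) -> Dict[str, int]:
        return {s: getattr(self, s) for s in STRATA}

    def __getitem__(self, stratum: str) -> int:
        if stratum not in STRATA:
            raise KeyError(f"unknown stratum {stratum!r}; expected one of {STRATA}")
        return getattr(self, stratum)


class InstanceCountParams(BaseModel):
    """Log-normal parameters for airings-per-ad counts.

    Counts are heavy-tailed on purpose: a few creatives air very often, which
    is what makes a top-quantile exposure selection meaningful.
    """

    model_config = ConfigDict(frozen=True)

    log_mean: float = 3.0
    log_sd: float = Field(default=1.0, gt=0)


def _default_appeal_prevalence() -> Dict[str, Tuple[float, float]]:
    # (P(flag | ad promotes a high-in product), P(flag | no high-in product)).
    # Emotional types dominate and are more prevalent on high-in ads; rational
    # types use identical pairs so group differences on the rational scale are
    # null by construction.
    return {
        "senses": (0.458, 0.335),
        "cartoons": (0.288, 0.212),
        "positive_emotions": (0.318, 0.215),
        "characters": (0.62, 0.05),
        "fun_adventure": (0.65, 0.05),
        "health": (0.28, 0.28),
        "nutrition": (0.30, 0.30),
        "freshness": (0.22, 0.22),
        "ingredients": (0.26, 0.26),
        "quality": (0.20, 0.20),
    }


class SimConfig(BaseModel):
    """Parameters for the synthetic airing-log / nutrition / coding generator."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    year: int = 2017
    n_unique_ads: int = Field(default=500, ge=1)
    instances_per_ad: InstanceCountParams = Field(default_factory=InstanceCountParams)
    #: Mean rating points (1 point = 1 % of the stratum audience).
    rating_base: float = Field(default=0.3, gt=0)
    #: Multiplicative female/male exposure ratio.
    gender_gap: float = Field(default=1.2, gt=0)
    #: Multipliers for (low, mid, high) SES exposure.
    ses_gradient: Tuple[float, float, float] = (1.6, 1.0, 0.6)
    frac_high_in: float = Field(default=0.776, ge=0.0, le=1.0)
    appeal_prevalence: Dict[str, Tuple[float, float]] = Field(
        default_factory=_default_appeal_prevalence
    )
    products_per_ad: Dict[int, float] = Field(
        default_factory=lambda: {1: 0.50, 2: 0.30, 3: 0.20}
    )
    populations: PopulationTable = Field(default_factory=PopulationTable)
    coder_error_rate: float = Field(default=0.03, ge=0.0, le=1.0)
    #: Probability that an ad has a second, longer duration version.
    two_version_prob: float = Field(default=0.3, ge=0.0, le=1.0)
    #: Log-scale spread of the per-ad base rating around rating_base.
    rating_ad_sd: float = Field(default=0.5, ge=0)
    #: Log-scale spread of per-instance, per-stratum rating noise.
    rating_noise_sd: float = Field(default=0.4, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        for k in self.ses_gradient:
            if k <= 0:
                raise ValueError("ses_gradient: all multipliers must be > 0")
        for appeal, pair in self.appeal_prevalence.items():
            if len(pair) != 2:
                raise ValueError(
                    f"appeal_prevalence[{appeal!r}]: expected a (high_in, not_high_in) pair"
                )
            for p in pair:
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"appeal_prevalence[{appeal!r}]: probabilities must lie in [0, 1]"
                    )
        bad_keys = set(self.products_per_ad) - {1, 2, 3}
        if bad_keys:
            raise ValueError(f"products_per_ad: keys must be in {{1, 2, 3}}, got {sorted(bad_keys)}")
        total = sum(self.products_per_ad.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"products_per_ad: probabilities must sum to 1, got {total}")
        for p in self.products_per_ad.values():
            if p < 0:
                raise ValueError("products_per_ad: probabilities must be >= 0")
        return self


class RunConfig(BaseModel):
    """End-to-end run settings binding inputs, selection and analysis flags."""

    model_config = ConfigDict(frozen=True)

    airings: Optional[str] = None
    nutrition: Optional[str] = None
    codings: Optional[str] = None
    populations: Optional[str] = None
    sim: SimConfig = Field(default_factory=SimConfig)
    top_fraction: float = Field(default=0.20, gt=0.0, le=1.0)
    stratum: str = "overall"
    year: int = 2017
    window: Tuple[int, int] = (6, 22)
    seed: Optional[int] = None
    out_dir: Optional[str] = None
    holm_adjust: bool = False
    subsample_fraction: float = Field(default=0.10, gt=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        start, end = self.window
        if not (0 <= start < end <= 24):
            raise ValueError(f"window: require 0 <= start < end <= 24, got {self.window}")
        if self.stratum not in STRATA:
            raise ValueError(f"stratum: unknown stratum {self.stratum!r}; expected one of {STRATA}")
        return self
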