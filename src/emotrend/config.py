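"""Configuration models shared across the pipeline.

The default numbers ship as the ``paper_defaults`` profile: a 52-week year
with an interruption at week 11, a 3.5% minority cohort, and segmented
posting-rate parameters for the two cohorts on the general community.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

#: Community identifiers: one general teen community, three mental-health ones.
TEEN_COMMUNITY = "teen"
MH_COMMUNITIES = ("depression", "anxiety", "suicidewatch")
COMMUNITIES = (TEEN_COMMUNITY,) + MH_COMMUNITIES

#: Cohort labels: MH = teen-community authors also active in a mental-health
#: community during the year; NMH = the rest.
MH, NMH = "MH", "NMH"
COHORTS = (NMH, MH)

EMOTIONS = ("anger", "fear", "happiness", "sadness", "surprise")
MIX_CLASSES = EMOTIONS + ("neutral",)

#: Author placeholder for removed accounts; such records are filtered on ingest.
DELETED_MARKER = "[deleted]"


class RateParams(BaseModel):
    """Segmented weekly posting intensity: ``level + slope*t`` before the
    interruption week T0, plus ``level_change + slope_change*(t - T0)`` from
    T0 onward (so the level change applies at T0 itself)."""

    model_config = ConfigDict(frozen=True)

    level: float
    slope: float = 0.0
    level_change: float = 0.0
    slope_change: float = 0.0

    def intensity(self, t, t0: int):
        """Expected weekly posts at week index ``t`` (1-based, scalar or array)."""
        t = np.asarray(t, dtype=float)
        post = t >= t0
        out = self.level + self.slope * t
        out = out + post * (self.level_change + self.slope_change * (t - t0))
        return out


# Planted segmented-trend analogues for the two cohorts. The NMH values are
# the b0..b3 defaults of the shipped profile; the MH values are the NMH values
# plus the group-contrast defaults (b4..b7).
DEFAULT_RATES: Dict[str, RateParams] = {
    NMH: RateParams(level=4.948, slope=-0.028, level_change=0.741, slope_change=0.032),
    MH: RateParams(level=9.832, slope=-0.160, level_change=2.253, slope_change=0.146),
}

# Emotion mixtures (token-class proportions) per community; the teen community
# is split by cohort. Compound analogues: teen 0.23/0.25, depression 0.40,
# anxiety 0.44, suicidewatch 0.48.
DEFAULT_EMOTION_MIX: Dict[str, Dict[str, float]] = {
    "teen:NMH": {"anger": 0.06, "fear": 0.08, "happiness": 0.03, "sadness": 0.12, "surprise": 0.03, "neutral": 0.68},
    "teen:MH": {"anger": 0.07, "fear": 0.09, "happiness": 0.04, "sadness": 0.13, "surprise": 0.03, "neutral": 0.64},
    "depression": {"anger": 0.08, "fear": 0.10, "happiness": 0.03, "sadness": 0.25, "surprise": 0.02, "neutral": 0.52},
    "anxiety": {"anger": 0.06, "fear": 0.25, "happiness": 0.02, "sadness": 0.15, "surprise": 0.02, "neutral": 0.50},
    "suicidewatch": {"anger": 0.08, "fear": 0.12, "happiness": 0.02, "sadness": 0.30, "surprise": 0.02, "neutral": 0.46},
}


class SimConfig(BaseModel):
    """Parameters of the synthetic corpus generator."""

    model_config = ConfigDict(frozen=True)

    n_users: int = Field(1000, gt=0)
    fraction_mh: float = Field(0.035, ge=0.0, le=1.0)
    n_weeks: int = Field(52, gt=0)
    interruption_week: int = 11
    year: int = 2020
    rate_params: Dict[str, RateParams] = Field(default_factory=lambda: dict(DEFAULT_RATES))
    mh_community_rate: float = Field(1.0, gt=0.0)
    user_heterogeneity: float = Field(0.15, ge=0.0)
    emotion_mix: Dict[str, Dict[str, float]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EMOTION_MIX.items()}
    )
    text_length_range: Tuple[int, int] = (5, 20)
    post_fraction: float = Field(0.2, ge=0.0, le=1.0)
    deleted_fraction: float = Field(0.0, ge=0.0, le=1.0)
    intensity_floor: float = Field(0.05, gt=0.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if not 1 <= self.interruption_week <= self.n_weeks:
            raise ValueError(
                f"interruption_week must lie in [1, n_weeks]; got "
                f"{self.interruption_week} with n_weeks={self.n_weeks}"
            )
        if set(self.rate_params) != {MH, NMH}:
            raise ValueError("rate_params must have exactly the keys 'MH' and 'NMH'")
        for key, mix in self.emotion_mix.items():
            unknown = set(mix) - set(MIX_CLASSES)
            if unknown:
                raise ValueError(f"emotion_mix[{key!r}] has unknown classes {sorted(unknown)}")
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"emotion_mix[{key!r}] proportions sum to {total}, not 1")
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"emotion_mix[{key!r}] has negative proportions")
        lo, hi = self.text_length_range
        if not (0 < lo <= hi):
            raise ValueError("text_length_range must satisfy 0 < lo <= hi")
        t = np.arange(1, self.n_weeks + 1)
        for cohort, rp in self.rate_params.items():
            lam = np.maximum(rp.intensity(t, self.interruption_week), self.intensity_floor)
            if np.any(lam <= 0):
                raise ValueError(f"non-positive weekly intensity for cohort {cohort}")
        return self

    def mix_for(self, community: str, cohort: str) -> Dict[str, float]:
        """Token-class mixture for a (community, cohort) pair, with the teen
        community split by cohort and a community-level fallback."""
        for key in (f"{community}:{cohort}", community):
            if key in self.emotion_mix:
                return self.emotion_mix[key]
        raise KeyError(f"no emotion mixture configured for community {community!r}")


class PipelineConfig(BaseModel):
    """End-to-end run configuration (simulate -> score -> aggregate -> itsa
    -> report)."""

    model_config = ConfigDict(frozen=True)

    sim: SimConfig = Field(default_factory=SimConfig)
    t0: int = 11
    lag: int = 12
    display_scale: float = Field(30.0, gt=0.0)
    seed: int = 0
    stages: Tuple[str, ...] = ("simulate", "score", "aggregate", "itsa", "report")
    events_path: Optional[str] = None  # None -> bundled pandemic-timeline file
    lexicon_path: Optional[str] = None  # None -> bundled lexicon

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if not 1 <= self.t0 <= self.sim.n_weeks:
            raise ValueError(f"t0={self.t0} outside [1, {self.sim.n_weeks}]")
        if self.lag < 0 or self.lag >= self.sim.n_weeks:
            raise ValueError(f"lag={self.lag} invalid for {self.sim.n_weeks}-week series")
        known = {"simulate", "score", "aggregate", "itsa", "report"}
        bad = set(self.stages) - known
        if bad:
            raise ValueError(f"unknown stages {sorted(bad)}")
        return self


def paper_defaults(seed: int = 0, n_users: int = 1000) -> PipelineConfig:
    """The shipped default profile: 52 weeks, interruption at week 11,
    12-week lag, 3.5% MH fraction, display scale factor 30."""
    return PipelineConfig(sim=SimConfig(n_users=n_users, seed=seed), seed=seed)
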