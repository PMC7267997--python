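"""Validated configuration objects for the simulation and analysis pipeline.

All tunable study parameters live here: cohort composition, the activity
state-chain and its count-emission bands, parent-reporting accuracy, EMA
prompt scheduling, accelerometer validity criteria, and regression design
specifications.  Defaults reproduce the study conditions of a cohort of 140
parent-child dyads observed for 8 days with four signal-contingent surveys
per day.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "STATES",
    "WORN_STATES",
    "CohortConfig",
    "ActivityTruthParams",
    "ReportingParams",
    "EmaScheduleParams",
    "CutpointSet",
    "ValidityCriteria",
    "DesignSpec",
    "PipelineConfig",
    "load_pipeline_config",
]

#: Minute-level ground-truth states.  ``off_body`` and ``asleep`` emit zero
#: counts; the other three emit counts inside their cutpoint band.
STATES: tuple[str, ...] = ("off_body", "asleep", "sedentary", "light", "mvpa")
WORN_STATES: tuple[str, ...] = ("sedentary", "light", "mvpa")


def _check_prob_vector(probs: Mapping[str, float], name: str) -> None:
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} probabilities sum to {total!r}, expected 1")
    if any(p < 0 for p in probs.values()):
        raise ValueError(f"{name} contains a negative probability")


class CohortConfig(BaseModel):
    """Composition of the simulated dyad cohort.

    Category probabilities default to the observed sample proportions:
    66/140 girls, six racial/ethnic groups of 21-25 children each, 67/140
    overweight, 70% household income below $35k, child age 6.4 (SD 0.8)
    years.
    """

    n_dyads: int = Field(140, ge=1)
    study_days: int = Field(8, ge=1)
    seed: int = 0
    sex_probs: dict[str, float] = {"girl": 66 / 140, "boy": 74 / 140}
    race_ethnicity_probs: dict[str, float] = {
        "african_american": 21 / 140,
        "american_indian": 24 / 140,
        "hispanic_latino": 25 / 140,
        "hmong": 24 / 140,
        "somali": 22 / 140,
        "white": 24 / 140,
    }
    weight_status_probs: dict[str, float] = {
        "normal_weight": 73 / 140,
        "overweight_obese": 67 / 140,
    }
    income_probs: dict[str, float] = {"lt_35k": 0.70, "ge_35k": 0.30}
    season_probs: dict[str, float] = {"school_year": 0.75, "summer": 0.25}
    age_mean: float = 6.4
    age_sd: float = Field(0.8, ge=0)
    #: calendar year anchoring simulated start dates (weekday/weekend labels
    #: and the season<->date correspondence are derived from real dates)
    calendar_year: int = 2017

    @model_validator(mode="after")
    def _validate_probs(self) -> "CohortConfig":
        for name in (
            "sex_probs",
            "race_ethnicity_probs",
            "weight_status_probs",
            "income_probs",
            "season_probs",
        ):
            _check_prob_vector(getattr(self, name), name)
        return self


class ActivityTruthParams(BaseModel):
    """Generative model of a child's minute-level activity.

    Waking minutes follow a first-order Markov chain over the worn states
    (sedentary / light / mvpa); off-body episodes are superimposed as
    contiguous blocks (Poisson number per day, uniform duration).  Each
    minute emits an integer counts-per-minute value drawn uniformly from the
    emitting state's cutpoint band, then split across four 15-s epochs.
    """

    transition_matrix: dict[str, dict[str, float]] = {
        "sedentary": {"sedentary": 0.92, "light": 0.07, "mvpa": 0.01},
        "light": {"sedentary": 0.10, "light": 0.85, "mvpa": 0.05},
        "mvpa": {"sedentary": 0.05, "light": 0.25, "mvpa": 0.70},
    }
    initial_probs: dict[str, float] = {
        "sedentary": 0.60,
        "light": 0.35,
        "mvpa": 0.05,
    }
    #: inclusive counts/min emission band per worn state
    emission_bands: dict[str, tuple[int, int]] = {
        "sedentary": (0, 100),
        "light": (101, 2295),
        "mvpa": (2296, 6000),
    }
    #: probability a worn minute emits from a uniformly chosen *other* band
    emission_noise: float = Field(0.0, ge=0.0, le=1.0)
    #: expected off-body episodes per day and their duration range (minutes)
    nonwear_episodes_per_day: float = Field(2.0, ge=0.0)
    nonwear_duration_minutes: tuple[int, int] = (90, 240)
    day_start_hour: int = Field(7, ge=0, le=23)
    day_end_hour: int = Field(22, ge=1, le=24)

    @model_validator(mode="after")
    def _validate(self) -> "ActivityTruthParams":
        for state, row in self.transition_matrix.items():
            if state not in WORN_STATES:
                raise ValueError(f"transition row for unknown state {state!r}")
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValueError(f"transition row {state!r} does not sum to 1")
            if any(p < 0 for p in row.values()):
                raise ValueError(f"negative transition probability in row {state!r}")
        _check_prob_vector(self.initial_probs, "initial_probs")
        lo_s, hi_s = self.emission_bands["sedentary"]
        lo_l, hi_l = self.emission_bands["light"]
        lo_m, _ = self.emission_bands["mvpa"]
        if not (0 <= lo_s and hi_s <= 100):
            raise ValueError("sedentary emission band must lie within [0, 100] cpm")
        if not (101 <= lo_l and hi_l <= 2295):
            raise ValueError("light emission band must lie within [101, 2295] cpm")
        if lo_m < 2296:
            raise ValueError("mvpa emission band must start at >= 2296 cpm")
        if self.day_start_hour >= self.day_end_hour:
            raise ValueError("day_start_hour must precede day_end_hour")
        d_lo, d_hi = self.nonwear_duration_minutes
        if not (0 < d_lo <= d_hi):
            raise ValueError("nonwear duration range must satisfy 0 < lo <= hi")
        return self

    def transition_array(self) -> np.ndarray:
        """Row-stochastic matrix over WORN_STATES, in that fixed order."""
        mat = np.zeros((3, 3))
        for i, s in enumerate(WORN_STATES):
            for j, t in enumerate(WORN_STATES):
                mat[i, j] = self.transition_matrix[s].get(t, 0.0)
        return mat


class ReportingParams(BaseModel):
    """Parent yes/no reporting as a noisy channel on the pre-period truth.

    The "true" binary state is 1 when the pre-period contains at least
    ``*_threshold_minutes`` of the behaviour (LPA+MVPA for the activity
    item, sedentary time for the screen-behaviour proxy item).  Responses
    are then drawn with the stated sensitivity/specificity; accuracy shifts
    additively on the log-odds scale by weekend, child sex, and season.
    """

    pa_sensitivity: float = Field(0.85, ge=0.0, le=1.0)
    pa_specificity: float = Field(0.80, ge=0.0, le=1.0)
    sb_sensitivity: float = Field(0.85, ge=0.0, le=1.0)
    sb_specificity: float = Field(0.80, ge=0.0, le=1.0)
    #: additive log-odds shift of reporting *accuracy* per active modifier
    modifier_effects: dict[str, float] = {"weekend": 0.0, "boy": 0.0, "summer": 0.0}
    pa_threshold_minutes: float = Field(10.0, ge=0.0)
    sb_threshold_minutes: float = Field(30.0, ge=0.0)


class EmaScheduleParams(BaseModel):
    """Signal-contingent prompting: four random prompts per day.

    Windows default to 7-10 am, 12-2 pm, 3-6 pm and 7-10 pm; the survey
    link expires 60 minutes after the prompt; completion is a per-prompt
    Bernoulli draw (default rate 0.83, echoing observed compliance).
    """

    windows: list[tuple[int, int]] = [(7, 10), (12, 14), (15, 18), (19, 22)]
    expiry_minutes: int = Field(60, ge=1)
    compliance: float = Field(0.83, ge=0.0, le=1.0)
    #: response delay is uniform on [0, min(max_delay, expiry)); None = expiry
    max_delay_minutes: float | None = Field(None, ge=0)

    @field_validator("windows")
    @classmethod
    def _windows_ordered(cls, v: list[tuple[int, int]]) -> list[tuple[int, int]]:
        prev_end = -1
        for lo, hi in v:
            if not (0 <= lo < hi <= 24):
                raise ValueError(f"invalid prompt window ({lo}, {hi})")
            if lo < prev_end:
                raise ValueError("prompt windows must not overlap")
            prev_end = hi
        return v


class CutpointSet(BaseModel):
    """Child counts-per-minute intensity thresholds (Evenson defaults)."""

    st_max: int = Field(100, ge=0)
    lpa_max: int = 2295
    name: str = "Evenson (children)"

    @model_validator(mode="after")
    def _ordered(self) -> "CutpointSet":
        if not self.st_max < self.lpa_max:
            raise ValueError("st_max must be below lpa_max")
        return self


class ValidityCriteria(BaseModel):
    """Wear-time validity rules for days and participants.

    A day is valid at ``min_hours_per_day`` worn hours (4 by default; 8 for
    the strict sensitivity setting); a participant needs ``min_days`` valid
    days including ``min_weekdays`` weekdays and ``min_weekend_days``
    weekend days.  Nonwear is any run of zero-count minutes strictly longer
    than ``nonwear_run_minutes``.
    """

    min_days: int = Field(4, ge=1)
    min_weekdays: int = Field(3, ge=0)
    min_weekend_days: int = Field(1, ge=0)
    min_hours_per_day: float = Field(4.0, gt=0)
    nonwear_run_minutes: int = Field(60, ge=1)

    @model_validator(mode="after")
    def _consistent(self) -> "ValidityCriteria":
        if self.min_weekdays + self.min_weekend_days > self.min_days:
            raise ValueError("min_weekdays + min_weekend_days must be <= min_days")
        return self


class DesignSpec(BaseModel):
    """One marginal model: outcome ~ exposure (+ modifier interaction) + covariates."""

    outcome: Literal["st_min_per_hr", "lpa_min_per_hr", "mvpa_min_per_hr"]
    exposure: Literal["pa_reported", "sb_reported"]
    covariates: list[str] = [
        "race_ethnicity",
        "weight_status",
        "weekend",
        "sex",
        "age_years",
        "season",
        "income",
    ]
    modifier: Literal["none", "weekend", "sex", "season"] = "none"
    reference_levels: dict[str, str] = {
        "sex": "girl",
        "season": "school_year",
        "race_ethnicity": "white",
        "weight_status": "normal_weight",
        "income": "lt_35k",
    }

    @model_validator(mode="after")
    def _modifier_in_model(self) -> "DesignSpec":
        if self.modifier != "none" and self.modifier not in self.covariates:
            # the modifier's main effect must be present alongside the product
            self.covariates = [*self.covariates, self.modifier]
        return self


def default_design_specs() -> list[DesignSpec]:
    """The full moderation grid: 2 exposures x 3 outcomes x 3 modifiers."""
    return [
        DesignSpec(outcome=o, exposure=e, modifier=m)
        for e in ("pa_reported", "sb_reported")
        for o in ("st_min_per_hr", "lpa_min_per_hr", "mvpa_min_per_hr")
        for m in ("weekend", "sex", "season")
    ]


class PipelineConfig(BaseModel):
    """Single document driving simulate -> process -> match -> fit -> report."""

    cohort: CohortConfig = CohortConfig()
    activity: ActivityTruthParams = ActivityTruthParams()
    reporting: ReportingParams = ReportingParams()
    ema: EmaScheduleParams = EmaScheduleParams()
    cutpoints: CutpointSet = CutpointSet()
    validity: ValidityCriteria = ValidityCriteria()
    designs: list[DesignSpec] = Field(default_factory=default_design_specs)
    #: decimal places for percentages in reports
    percent_decimals: int = 1

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))


def load_pipeline_config(path: str | Path | None) -> PipelineConfig:
    return PipelineConfig() if path is None else PipelineConfig.from_json(path)


def season_of(date: dt.date) -> str:
    """Summer (June-August) vs school year, by calendar month."""
    return "summer" if date.month in (6, 7, 8) else "school_year"
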