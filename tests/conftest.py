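"""Shared fixtures: simulated studies at three scales.

Everything is generated in memory at test time; the heavier cohorts are
session-scoped so the simulate -> process -> match chain runs once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from emaaccel.accelerometry import (
    filter_valid_participants,
    process_stream,
    summarize_days,
)
from emaaccel.config import CohortConfig, PipelineConfig
from emaaccel.ema import assemble_analysis_table
from emaaccel.synthetic import simulate_study


def run_study(n_dyads: int, study_days: int, seed: int, apply_eligibility: bool = True) -> dict:
    """simulate -> process -> match, returning every intermediate."""
    cfg = PipelineConfig(
        cohort=CohortConfig(n_dyads=n_dyads, study_days=study_days, seed=seed)
    )
    study = simulate_study(cfg)
    minutes = pd.concat(
        [process_stream(s.epochs, cfg.cutpoints, cfg.validity) for s in study.streams.values()],
        ignore_index=True,
    )
    day_summaries = summarize_days(minutes)
    eligible, day_summaries = filter_valid_participants(day_summaries, cfg.validity)
    table = assemble_analysis_table(
        study.surveys, minutes, study.cohort, eligible if apply_eligibility else None
    )
    return {
        "config": cfg,
        "study": study,
        "minutes": minutes,
        "day_summaries": day_summaries,
        "eligible": eligible,
        "table": table,
    }


@pytest.fixture(scope="session")
def small_run() -> dict:
    """12 dyads x 8 days: quick fixture for structural checks."""
    return run_study(12, 8, seed=42)


@pytest.fixture(scope="session")
def full_run() -> dict:
    """140 dyads x 8 days: the study-scale cohort for calibration checks."""
    return run_study(140, 8, seed=11)


@pytest.fixture(scope="session")
def null_interaction_pvalues(reduced_run) -> np.ndarray:
    """1000 interaction Wald P values under a null outcome generator.

    The 40 dyads x 4 days design is held fixed; outcomes are redrawn as
    y = X beta + cluster effect + noise with a zero product coefficient.
    """
    from emaaccel.config import DesignSpec
    from emaaccel.gee import build_design_matrix, fit_gee_independence, wald_test
    from emaaccel.synthetic import simulate_clustered_outcomes

    table = reduced_run["table"]
    spec = DesignSpec(
        outcome="st_min_per_hr",
        exposure="pa_reported",
        covariates=["weekend", "sex", "age_years"],
        modifier="weekend",
    )
    y, X, clusters, names = build_design_matrix(table, spec)
    j = names.index("pa_reported:weekend")
    beta0 = np.zeros(X.shape[1])
    beta0[0] = 35.0
    beta0[names.index("pa_reported")] = -4.0
    rng = np.random.default_rng(123)
    L = np.zeros((1, X.shape[1]))
    L[0, j] = 1.0
    pvals = np.empty(1000)
    for r in range(1000):
        ysim = simulate_clustered_outcomes(X, beta0, clusters, 3.0, 10.0, rng)
        fit = fit_gee_independence(ysim, X, clusters, names)
        pvals[r] = wald_test(fit, L).p_value
    return pvals


@pytest.fixture(scope="session")
def reduced_run() -> dict:
    """40 dyads x 4 days, without the participant eligibility screen.

    Used for estimator-calibration experiments, where the cluster count —
    not the wear-time screen — is the condition under study.
    """
    return run_study(40, 4, seed=7, apply_eligibility=False)
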