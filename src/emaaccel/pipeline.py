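"""Orchestration and reporting: simulate -> process -> match -> fit,
compliance statistics, per-survey-order descriptives, and formatted
moderation results.

Every stage writes its artifact to disk with a manifest recording inputs,
seed, and package version; record counts are logged after each filter so
attrition (dyads dropped by wear-time validity, surveys dropped by window
construction) is auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .accelerometry import (
    filter_valid_participants,
    process_stream,
    summarize_days,
    write_actigraph_csv,
)
from .config import PipelineConfig
from .ema import assemble_analysis_table, validate_response_days
from .gee import GEEFit, fit_design, interaction_wald, stratum_estimates
from .synthetic import StudyData, simulate_study

__all__ = [
    "round_half_up",
    "format_p",
    "format_estimate_ci",
    "ComplianceReport",
    "compliance_report",
    "descriptive_table1",
    "moderation_report",
    "run_pipeline",
]

logger = logging.getLogger("emaaccel")


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (the convention of printed percentages)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def format_p(p: float) -> str:
    """Journal-style P rendering: ``<.001``, ``.005``, ``.049``, ``.02``, ``.37``."""
    if p < 0.001:
        return "<.001"
    if p < 0.01:
        text = f"{round_half_up(p, 3):.3f}"
    else:
        rounded2 = round_half_up(p, 2)
        # keep a third decimal when two would blur a conventional boundary
        if rounded2 in (0.05,) and round_half_up(p, 3) != rounded2:
            text = f"{round_half_up(p, 3):.3f}"
        else:
            text = f"{rounded2:.2f}"
    return text.lstrip("0")


def format_estimate_ci(estimate: float, ci_low: float, ci_high: float) -> str:
    """Render e.g. ``-5.1 (95% CI -6.9 to -3.3)`` with 1-decimal rounding."""
    e, lo, hi = (round_half_up(v, 1) for v in (estimate, ci_low, ci_high))
    return f"{e:.1f} (95% CI {lo:.1f} to {hi:.1f})"


@dataclasses.dataclass
class ComplianceReport:
    surveys_delivered: int
    surveys_completed: int
    percent_compliant: float
    percent_three_plus: float
    mean_daily_wear_hours: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def compliance_report(
    surveys: pd.DataFrame, day_summaries: pd.DataFrame | None = None, decimals: int = 1
) -> ComplianceReport:
    """Survey compliance and wear summary.

    ``percent_compliant`` = 100 x completed/delivered, half-up rounded.
    ``percent_three_plus`` is the share of respondents whose average daily
    completed-survey count is at least 3 (a per-day-average reading of
    "completed at least three or more surveys").
    """
    delivered = int(len(surveys))
    if delivered == 0:
        raise ValueError("no surveys delivered; compliance undefined")
    completed = int(surveys["completed"].sum())
    percent = round_half_up(100.0 * completed / delivered, decimals)
    per_day = surveys.groupby(["participant_id", "date"])["completed"].sum()
    per_participant = per_day.groupby("participant_id").mean()
    three_plus = round_half_up(100.0 * float((per_participant >= 3).mean()), decimals)
    wear = (
        float(day_summaries["wear_hours"].mean())
        if day_summaries is not None and len(day_summaries)
        else float("nan")
    )
    return ComplianceReport(
        surveys_delivered=delivered,
        surveys_completed=completed,
        percent_compliant=percent,
        percent_three_plus=three_plus,
        mean_daily_wear_hours=wear,
    )


def descriptive_table1(analysis_table: pd.DataFrame) -> pd.DataFrame:
    """Per-survey-order descriptives of the matched pre-periods.

    One row per daily survey order 1-4: mean completion clock time, mean
    window wear hours, mean ST/LPA/MVPA minutes per hour, and each class's
    integer-percent share of the worn hour.  Orders with no observations
    are emitted with missing markers.
    """
    rows = []
    for order in (1, 2, 3, 4):
        sub = analysis_table[analysis_table["window_index"] == order] if len(analysis_table) else analysis_table
        if len(sub) == 0:
            rows.append(
                {
                    "survey_order": order,
                    "mean_completion_time": None,
                    "mean_wear_hours": np.nan,
                    "st_min_per_hr": np.nan,
                    "lpa_min_per_hr": np.nan,
                    "mvpa_min_per_hr": np.nan,
                    "st_share_pct": np.nan,
                    "lpa_share_pct": np.nan,
                    "mvpa_share_pct": np.nan,
                    "n": 0,
                }
            )
            continue
        ct = pd.to_datetime(sub["completion_time"])
        secs = (ct.dt.hour * 3600 + ct.dt.minute * 60 + ct.dt.second).mean()
        mean_time = f"{int(secs // 3600):02d}:{int(secs % 3600 // 60):02d}"
        means = {c: float(sub[c].mean()) for c in ("st_min_per_hr", "lpa_min_per_hr", "mvpa_min_per_hr")}
        rows.append(
            {
                "survey_order": order,
                "mean_completion_time": mean_time,
                "mean_wear_hours": float(sub["wear_minutes"].mean()) / 60.0,
                **means,
                "st_share_pct": round_half_up(100.0 * means["st_min_per_hr"] / 60.0, 0),
                "lpa_share_pct": round_half_up(100.0 * means["lpa_min_per_hr"] / 60.0, 0),
                "mvpa_share_pct": round_half_up(100.0 * means["mvpa_min_per_hr"] / 60.0, 0),
                "n": int(len(sub)),
            }
        )
    return pd.DataFrame(rows)


def compliance_wear_wald(
    surveys: pd.DataFrame, day_summaries: pd.DataFrame, cohort: pd.DataFrame
) -> dict:
    """Adjusted Wald chi-square tests of whether daily survey compliance
    and accelerometer wear time differ by day of week, child sex, and
    season.

    Day-level GEE-independence fits (clusters = participants) of the
    completed-survey count and of wear hours on weekend, sex, and season,
    adjusted for the main covariate set; each factor's single-coefficient
    Wald test is reported.  If the full covariate battery is collinear on
    a small sample, the factors of interest alone are retained.
    """
    from .gee import fit_gee_independence, wald_test

    per_day = (
        surveys.groupby(["participant_id", "date"])["completed"].sum().rename("n_completed").reset_index()
    )
    days = day_summaries.merge(per_day, on=["participant_id", "date"], how="inner")
    days = days.merge(cohort, on="participant_id", how="left")

    def _design(full: bool) -> tuple[np.ndarray, list[str]]:
        cols = {
            "intercept": np.ones(len(days)),
            "weekend": days["weekend"].astype(int).to_numpy(),
            "sex[boy]": (days["sex"] == "boy").astype(int).to_numpy(),
            "season[summer]": (days["season"] == "summer").astype(int).to_numpy(),
        }
        if full:
            cols["age_years"] = days["age_years"].to_numpy(dtype=float)
            cols["weight[overweight_obese]"] = (
                (days["weight_status"] == "overweight_obese").astype(int).to_numpy()
            )
            cols["income[ge_35k]"] = (days["income"] == "ge_35k").astype(int).to_numpy()
            for level in sorted(days["race_ethnicity"].unique()):
                if level != "white":
                    cols[f"race[{level}]"] = (days["race_ethnicity"] == level).astype(int).to_numpy()
        names = list(cols)
        return np.column_stack([cols[c] for c in names]), names

    X, names = _design(full=True)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        X, names = _design(full=False)
    out: dict = {}
    for outcome in ("n_completed", "wear_hours"):
        y = days[outcome].to_numpy(dtype=float)
        fit = fit_gee_independence(y, X, days["participant_id"].to_numpy(), names)
        tests = {}
        for factor, col in (("weekend", "weekend"), ("sex", "sex[boy]"), ("season", "season[summer]")):
            L = np.zeros((1, len(names)))
            L[0, names.index(col)] = 1.0
            res = wald_test(fit, L)
            tests[factor] = {"chi2": res.statistic, "df": res.df, "p": res.p_value, "p_text": format_p(res.p_value)}
        out[outcome] = tests
    return out


def moderation_report(fits: list[GEEFit]) -> list[dict]:
    """Formatted moderation results, one block per fitted model.

    Each block carries the interaction Wald chi-square with a
    journal-rendered P value, and the exposure effect with 95% CI in each
    modifier stratum, alongside the raw (unrounded) numbers.
    """
    blocks = []
    for fit in fits:
        block: dict = {
            "outcome": fit.outcome,
            "exposure": fit.exposure,
            "modifier": fit.modifier,
            "n_obs": fit.n_obs,
            "n_clusters": fit.n_clusters,
            "exposure_estimate": fit.coef(fit.exposure),
        }
        if fit.modifier != "none":
            wald = interaction_wald(fit)
            block["interaction_wald_chi2"] = wald.statistic
            block["interaction_df"] = wald.df
            block["interaction_p"] = wald.p_value
            block["interaction_p_text"] = format_p(wald.p_value)
            block["strata"] = [
                {
                    "level": s.level,
                    "estimate": s.estimate,
                    "ci_low": s.ci_low,
                    "ci_high": s.ci_high,
                    "text": format_estimate_ci(s.estimate, s.ci_low, s.ci_high),
                }
                for s in stratum_estimates(fit)
            ]
        blocks.append(block)
    return blocks


def _stage(name: str, message: str) -> None:
    logger.info("[%s] %s", name, message)


def run_pipeline(config: PipelineConfig | None = None, outdir: str | Path = "results") -> dict:
    """Run simulate -> process -> match -> fit -> report end to end.

    All artifacts (epoch CSVs, minute series, day summaries, analysis
    table, model results, reports, manifest) land under ``outdir``.
    Deterministic for a fixed config: rerunning rewrites identical CSVs.
    Returns the in-memory bundle.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    (outdir / "accel").mkdir(parents=True, exist_ok=True)

    _stage("simulate", f"{config.cohort.n_dyads} dyads x {config.cohort.study_days} days, seed {config.cohort.seed}")
    study: StudyData = simulate_study(config)
    study.cohort.to_csv(outdir / "cohort.csv", index=False)
    study.surveys.to_csv(outdir / "surveys.csv", index=False)
    truth_frames = []
    for pid, stream in study.streams.items():
        write_actigraph_csv(stream.epochs, outdir / "accel" / f"{pid}.csv", pid)
        truth_frames.append(stream.truth)
    pd.concat(truth_frames, ignore_index=True).to_csv(outdir / "truth_labels.csv", index=False)

    _stage("process-accel", f"{len(study.streams)} epoch streams")
    minute_frames = [
        process_stream(stream.epochs, config.cutpoints, config.validity)
        for stream in study.streams.values()
    ]
    minutes = pd.concat(minute_frames, ignore_index=True)
    minutes.to_csv(outdir / "minutes.csv", index=False)
    day_summaries = summarize_days(minutes)
    eligible, day_summaries = filter_valid_participants(day_summaries, config.validity)
    day_summaries.to_csv(outdir / "day_summaries.csv", index=False)
    _stage("process-accel", f"{len(eligible)}/{config.cohort.n_dyads} participants meet wear-time validity")

    _stage("match", "building pre-period windows")
    day_flags = validate_response_days(study.surveys)
    table = assemble_analysis_table(study.surveys, minutes, study.cohort, eligible)
    table.to_csv(outdir / "analysis_table.csv", index=False)
    _stage(
        "match",
        f"{len(table)} matched observations from "
        f"{int(day_flags['valid_day'].sum())} valid response days",
    )

    _stage("fit", f"{len(config.designs)} model specifications")
    fits, results_rows = [], []
    for spec in config.designs:
        fit = fit_design(table, spec)
        fits.append(fit)
        se = fit.se()
        for name, b, s in zip(fit.column_names, fit.beta, se):
            results_rows.append(
                {
                    "outcome": spec.outcome,
                    "exposure": spec.exposure,
                    "modifier": spec.modifier,
                    "term": name,
                    "estimate": b,
                    "robust_se": s,
                    "ci_low": b - 1.96 * s,
                    "ci_high": b + 1.96 * s,
                }
            )
    pd.DataFrame(results_rows).to_csv(outdir / "model_results.csv", index=False)

    _stage("report", "compliance, descriptives, moderation")
    eligible_days = day_summaries[day_summaries["participant_id"].isin(eligible)]
    compliance = compliance_report(
        study.surveys[study.surveys["participant_id"].isin(eligible)],
        eligible_days,
        config.percent_decimals,
    )
    table1 = descriptive_table1(table)
    table1.to_csv(outdir / "table1.csv", index=False)
    moderation = moderation_report(fits)
    wald_comparisons = compliance_wear_wald(
        study.surveys[study.surveys["participant_id"].isin(eligible)],
        eligible_days,
        study.cohort,
    )

    bundle = {
        "compliance": compliance.as_dict(),
        "compliance_wear_wald": wald_comparisons,
        "n_eligible": len(eligible),
        "n_matched_observations": int(len(table)),
        "n_valid_response_days": int(day_flags["valid_day"].sum()),
        "moderation": moderation,
    }
    with open(outdir / "results.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=float)
    manifest = {
        "version": __version__,
        "seed": config.cohort.seed,
        "config": config.model_dump(mode="json"),
        "artifacts": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {"config": config, "study": study, "minutes": minutes,
            "day_summaries": day_summaries, "eligible": eligible,
            "analysis_table": table, "fits": fits, "bundle": bundle}
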