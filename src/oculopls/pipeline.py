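"""End-to-end orchestration: simulate/load -> impute -> correlate -> model
-> permute -> report.

Every stage draws its seed from a stable hash of (master_seed, stage,
outcome, group), so adding an outcome never perturbs another outcome's
results and a re-run with the same config reproduces every number.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import presets
from .cohort import CohortTable, write_cohort
from .permutation import (PermutationResult, permute_r2_difference,
                          permute_rho_difference)
from .pls import (ModelingConfig, PLSModelReport, build_score_model,
                  complete_oculo_block, predicted_age_analysis)
from .stats import (bh_adjust, correlation_screen, mann_whitney_u,
                    spearman_rho, task_average_abs_rho)

logger = logging.getLogger(__name__)

ALL_OUTCOMES = ("Age", "TMTA", "TMTB", "COWAT", "SDMT", "MoCA", "HVLT", "BAI")
#: outcomes collected in both groups (Fig-6-style comparisons)
SHARED_OUTCOMES = ("TMTA", "TMTB", "COWAT", "MoCA", "HVLT")


@dataclass(frozen=True)
class PipelineConfig:
    outcomes: tuple[str, ...] = ALL_OUTCOMES
    include_age: bool = False      # also fit age-augmented HC score models
    n_top: int = 20
    subset_cap: int = 12
    n_folds: int = 10
    n_replicates: int = 1000
    alpha: float = 0.05
    ppca_rank: int = 4
    master_seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        unknown = set(self.outcomes) - set(ALL_OUTCOMES)
        if unknown:
            raise ValueError(f"unknown outcomes: {sorted(unknown)}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def sub_seed(self, stage: str, outcome: str = "", group: str = "") -> int:
        key = f"{self.master_seed}:{stage}:{outcome}:{group}".encode()
        return zlib.crc32(key) & 0x7FFFFFFF

    def modeling(self, outcome: str = "", group: str = "") -> ModelingConfig:
        return ModelingConfig(
            n_top=self.n_top, subset_cap=self.subset_cap,
            n_folds=self.n_folds, ppca_rank=self.ppca_rank,
            seed=self.sub_seed("model", outcome, group),
        )


@dataclass
class ReportBundle:
    config: PipelineConfig
    cohorts: dict[str, CohortTable]
    completed: dict[str, pd.DataFrame]
    correlation_tables: dict[tuple[str, str], pd.DataFrame]
    age_score_table: pd.DataFrame | None
    model_reports: dict[tuple[str, str], PLSModelReport]
    age_augmented_reports: dict[str, PLSModelReport]
    predicted_age_table: pd.DataFrame | None
    comparison_table: pd.DataFrame | None
    task_rho_comparison: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)

    def model_report(self, group: str, outcome: str) -> PLSModelReport:
        return self.model_reports[(group, outcome)]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for group, cohort in self.cohorts.items():
            write_cohort(cohort, out / f"cohort_{group}.csv")
        for (group, outcome), frame in self.correlation_tables.items():
            frame.to_csv(out / f"correlations_{group}_{outcome}.csv",
                         index=False)
        if self.age_score_table is not None:
            self.age_score_table.to_csv(out / "age_score_correlations.csv",
                                        index=False)
        models = [r.to_dict() for r in self.model_reports.values()]
        models += [r.to_dict() for r in self.age_augmented_reports.values()]
        (out / "model_reports.json").write_text(json.dumps(models, indent=2))
        for (group, outcome), report in self.model_reports.items():
            report.predictions.to_csv(
                out / f"predictions_{group}_{outcome}.csv", index=False)
        if self.predicted_age_table is not None:
            self.predicted_age_table.to_csv(out / "predicted_age.csv",
                                            index=False)
        if self.comparison_table is not None:
            self.comparison_table.to_csv(out / "group_comparison.csv",
                                         index=False)
        if self.task_rho_comparison is not None:
            self.task_rho_comparison.to_csv(out / "task_rho_comparison.csv",
                                            index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def _age_score_correlations(cohort: CohortTable, outcomes,
                            config: PipelineConfig) -> pd.DataFrame:
    """Fig-1-style table: rho(age, score) overall and per sex, with a
    permutation test of the male-female rho difference."""
    rows = []
    frame = cohort.frame
    for outcome in outcomes:
        if outcome == "Age":
            continue
        score = cohort.outcome_values(outcome)
        keep = score.notna()
        overall = spearman_rho(frame.loc[keep, "age"], score[keep])
        per_sex = {}
        for sex in ("male", "female"):
            sel = keep & (frame["sex"] == sex)
            per_sex[sex] = spearman_rho(frame.loc[sel, "age"], score[sel])
        males = keep & (frame["sex"] == "male")
        females = keep & (frame["sex"] == "female")
        perm = permute_rho_difference(
            frame.loc[males, "age"], score[males],
            frame.loc[females, "age"], score[females],
            n_replicates=config.n_replicates,
            seed=config.sub_seed("sex_rho", outcome),
        )
        rows.append({
            "outcome": outcome, "n": int(keep.sum()),
            "rho": overall.rho, "p_raw": overall.p_raw,
            "rho_male": per_sex["male"].rho,
            "rho_female": per_sex["female"].rho,
            "sex_difference_p": perm.p_two_tailed,
        })
    table = pd.DataFrame(rows)
    table["p_adj"], table["significant"] = bh_adjust(table["p_raw"],
                                                     config.alpha)
    return table


def _model_features_frame(bundle_completed: pd.DataFrame, cohort: CohortTable,
                          report: PLSModelReport) -> pd.DataFrame:
    """Feature rows (modeled participants only) for permutation refits."""
    y_all = cohort.outcome_values(report.outcome)
    rows = y_all.notna().to_numpy()
    frame = bundle_completed.loc[rows].reset_index(drop=True).copy()
    frame["age"] = cohort.frame.loc[rows, "age"].to_numpy(dtype=float)
    return frame


def compare_groups_report(bundle: ReportBundle) -> pd.DataFrame:
    """Per shared outcome: group adjusted R^2, prediction-truth rho,
    permutation p-values for both differences, and Mann-Whitney U on the
    score distributions (BH-corrected)."""
    config = bundle.config
    rows = []
    for outcome in SHARED_OUTCOMES:
        key_hc, key_pd = ("HC", outcome), ("PD", outcome)
        if key_hc not in bundle.model_reports or key_pd not in bundle.model_reports:
            continue
        rep_hc = bundle.model_reports[key_hc]
        rep_pd = bundle.model_reports[key_pd]
        hc_scores = bundle.cohorts["HC"].outcome_values(outcome).dropna()
        pd_scores = bundle.cohorts["PD"].outcome_values(outcome).dropna()
        U, p_mwu = mann_whitney_u(hc_scores, pd_scores)
        rho_perm = permute_rho_difference(
            rep_pd.predictions["true"], rep_pd.predictions["predicted"],
            rep_hc.predictions["true"], rep_hc.predictions["predicted"],
            n_replicates=config.n_replicates,
            seed=config.sub_seed("rho_perm", outcome),
        )
        X_hc = _model_features_frame(bundle.completed["HC"],
                                     bundle.cohorts["HC"], rep_hc)
        X_pd = _model_features_frame(bundle.completed["PD"],
                                     bundle.cohorts["PD"], rep_pd)
        r2_perm = permute_r2_difference(
            X_pd, rep_pd.predictions["true"].to_numpy(),
            X_hc, rep_hc.predictions["true"].to_numpy(),
            rep_pd, rep_hc,
            n_replicates=config.n_replicates,
            seed=config.sub_seed("r2_perm", outcome),
        )
        rows.append({
            "outcome": outcome,
            "hc_n": rep_hc.n_used, "pd_n": rep_pd.n_used,
            "hc_r2_adjusted": rep_hc.r2_adjusted,
            "pd_r2_adjusted": rep_pd.r2_adjusted,
            "hc_rho_pred_true": rep_hc.spearman_pred_vs_true.rho,
            "pd_rho_pred_true": rep_pd.spearman_pred_vs_true.rho,
            "mwu_U": U, "mwu_p_raw": p_mwu,
            "rho_difference_p": rho_perm.p_two_tailed,
            "r2_difference_observed": r2_perm.observed_difference,
            "r2_difference_p": r2_perm.p_two_tailed,
        })
    table = pd.DataFrame(rows)
    if not table.empty:
        table["mwu_p_adj"], table["mwu_significant"] = bh_adjust(
            table["mwu_p_raw"], config.alpha)
    return table


def _task_rho_comparison(bundle: ReportBundle) -> pd.DataFrame:
    """Fig-6f-j analog: per (outcome, task) mean |rho| in each group and a
    Mann-Whitney comparison of the per-parameter |rho| sets, BH-corrected
    within the outcome family."""
    frames = []
    for outcome in SHARED_OUTCOMES:
        per_group = {}
        for group in ("HC", "PD"):
            key = (group, outcome)
            if key not in bundle.correlation_tables:
                continue
            per_group[group] = bundle.correlation_tables[key]
        if len(per_group) < 2:
            continue
        catalog = bundle.cohorts["HC"].catalog
        rows = []
        for task in sorted(set(catalog.tasks)):
            names = set(catalog.parameters_for(task))
            sub = {g: t[t["parameter"].isin(names)]["rho"].dropna().abs()
                   for g, t in per_group.items()}
            if min(len(v) for v in sub.values()) == 0:
                continue
            U, p = mann_whitney_u(sub["HC"], sub["PD"])
            rows.append({
                "outcome": outcome, "task": task,
                "hc_mean_abs_rho": float(sub["HC"].mean()),
                "pd_mean_abs_rho": float(sub["PD"].mean()),
                "mwu_U": U, "p_raw": p,
            })
        frame = pd.DataFrame(rows)
        frame["p_adj"], frame["significant"] = bh_adjust(
            frame["p_raw"], bundle.config.alpha)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def run_full_pipeline(config: PipelineConfig = PipelineConfig(),
                      hc_cohort: CohortTable | None = None,
                      pd_cohort: CohortTable | None = None) -> ReportBundle:
    """Execute every stage; returns the bundle (and writes it if configured).

    Cohorts default to the frozen HC/PD presets simulated with
    stage-derived seeds. The age model is fit for the HC group and drives
    the predicted-age analysis; per-score models are fit in both groups
    for the outcomes each group collected.
    """
    config.validate()
    t0 = time.time()
    stage_log: list[tuple[str, float]] = []

    def tick(stage):
        stage_log.append((stage, round(time.time() - t0, 2)))
        logger.info("stage %s done at %.1fs", stage, time.time() - t0)

    from .simulate import generate_cohort

    if hc_cohort is None:
        hc_cohort, _ = generate_cohort(
            presets.hc_default(seed=config.sub_seed("simulate", group="HC")))
    if pd_cohort is None:
        pd_cohort, _ = generate_cohort(
            presets.pd_default(seed=config.sub_seed("simulate", group="PD")))
    cohorts = {"HC": hc_cohort, "PD": pd_cohort}
    tick("simulate")

    completed = {}
    for group, cohort in cohorts.items():
        completed[group], _ = complete_oculo_block(
            cohort, config.modeling(group=group))
    tick("impute")

    correlation_tables = {}
    for group, cohort in cohorts.items():
        for outcome in config.outcomes:
            if outcome != "Age" and cohort.available_n(outcome) < 3:
                continue
            table = correlation_screen(cohort, outcome, alpha=config.alpha)
            correlation_tables[(group, outcome)] = table.frame
    age_score_table = _age_score_correlations(
        cohorts["HC"], config.outcomes, config)
    tick("correlate")

    model_reports: dict[tuple[str, str], PLSModelReport] = {}
    for group, cohort in cohorts.items():
        for outcome in config.outcomes:
            if group == "PD" and outcome == "Age":
                continue  # the age model is a healthy-baseline construct
            try:
                report = build_score_model(
                    cohort, outcome, config=config.modeling(outcome, group),
                    completed=completed[group])
            except ValueError as exc:
                logger.info("skipping %s/%s: %s", group, outcome, exc)
                continue
            model_reports[(group, outcome)] = report
    age_augmented: dict[str, PLSModelReport] = {}
    if config.include_age:
        for outcome in config.outcomes:
            if outcome == "Age" or ("HC", outcome) not in model_reports:
                continue
            age_augmented[outcome] = build_score_model(
                cohorts["HC"], outcome, include_age=True,
                config=config.modeling(outcome + "+age", "HC"),
                completed=completed["HC"])
    tick("model")

    predicted_age_table = None
    if ("HC", "Age") in model_reports:
        score_outcomes = [o for o in config.outcomes
                          if o != "Age" and ("HC", o) in model_reports]
        predicted_age_table = predicted_age_analysis(
            cohorts["HC"], model_reports[("HC", "Age")], score_outcomes)
    tick("predicted_age")

    bundle = ReportBundle(
        config=config, cohorts=cohorts, completed=completed,
        correlation_tables=correlation_tables,
        age_score_table=age_score_table,
        model_reports=model_reports, age_augmented_reports=age_augmented,
        predicted_age_table=predicted_age_table,
        comparison_table=None, task_rho_comparison=None,
    )
    bundle.comparison_table = compare_groups_report(bundle)
    bundle.task_rho_comparison = _task_rho_comparison(bundle)
    tick("compare")

    bundle.manifest = {
        "config": {
            "outcomes": list(config.outcomes),
            "include_age": config.include_age,
            "n_top": config.n_top, "subset_cap": config.subset_cap,
            "n_folds": config.n_folds, "n_replicates": config.n_replicates,
            "alpha": config.alpha, "ppca_rank": config.ppca_rank,
            "master_seed": config.master_seed,
        },
        "stage_seconds": dict(stage_log),
        "stage_seeds": {
            "simulate_HC": config.sub_seed("simulate", group="HC"),
            "simulate_PD": config.sub_seed("simulate", group="PD"),
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if config.output_dir:
        bundle.write(config.output_dir)
    return bundle
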