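"""End-to-end orchestration: trial I/O, validation, and the full analysis sequence.

``run_full_pipeline`` reproduces the analysis order of a multi-task
confidence study: per-subject-task summaries (d', mean confidence, AUROC2),
paired t-tests with Bonferroni correction, cross-task Pearson correlation
tables for performance and confidence, the hierarchical fit with group
Mratio posteriors, pairwise Mratio differences and cross-task rho summaries,
and finally the nonhierarchical MLE-Mratio correlations after the
low-performance exclusion rule.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import InvalidParameterError
from .hier import (
    HierarchicalModelSpec,
    McmcConfig,
    counts_by_subject_task,
    fit_hmetad_multitask,
    summarize_correlations,
)
from .sdt import build_counts, compute_auroc2, compute_dprime, fit_metad_mle
from .simulate import GroupConfig, simulate_group, TRIAL_COLUMNS
from .stats import (
    bonferroni_threshold,
    compute_confidence_level,
    exclude_low_performance,
    paired_ttest,
    pearson_with_ci,
)

log = logging.getLogger("metacov")

REQUIRED_COLUMNS = ["subject", "task", "stimulus", "response", "confidence_level"]


@dataclass(frozen=True)
class RunConfig:
    """Settings of one full pipeline run.

    Defaults reproduce the target study conditions: 40 trials per task on an
    11-level confidence scale, Bonferroni alpha = .05 over all task pairs,
    exclusion of subjects with d' < 0.10 (nonhierarchical path only).
    """

    input_path: str | None = None
    simulation: GroupConfig | None = None
    column_map: dict | None = None
    n_levels: int = 11
    collapse_to: int | None = 4
    exclusion_threshold: float = 0.10
    alpha: float = 0.05
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    output_dir: str | None = None
    seed: int | None = None
    prior_only: bool = False

    def __post_init__(self):
        if (self.input_path is None) == (self.simulation is None):
            raise InvalidParameterError(
                "exactly one of input_path or simulation must be given"
            )


# ---------------------------------------------------------------------------
# trial table I/O
# ---------------------------------------------------------------------------


def validate_trials(trials: pd.DataFrame, n_levels: int) -> None:
    """Schema checks with row-level error locations."""
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise InvalidParameterError(f"trial table is missing required columns: {missing}")
    for col in ("stimulus", "response"):
        bad = trials.index[~trials[col].isin(["S1", "S2"])]
        if len(bad):
            raise InvalidParameterError(
                f"column '{col}' must be 'S1'/'S2'; first bad row: {bad[0]}"
            )
    conf = pd.to_numeric(trials["confidence_level"], errors="coerce")
    bad = trials.index[conf.isna() | (conf < 0) | (conf >= n_levels) | (conf % 1 != 0)]
    if len(bad):
        raise InvalidParameterError(
            f"confidence_level outside 0..{n_levels - 1} at row {bad[0]} "
            f"(value {trials.loc[bad[0], 'confidence_level']!r})"
        )
    tasks = set(trials["task"].unique())
    by_subject = trials.groupby("subject")["task"].agg(lambda s: set(s))
    partial = [str(s) for s, t in by_subject.items() if t != tasks]
    if partial:
        raise InvalidParameterError(
            f"subjects missing tasks (every subject needs all {len(tasks)}): {partial[:5]}"
        )


def read_trials(path, n_levels: int = 11, column_map: dict | None = None) -> pd.DataFrame:
    """Read a delimited trial table; ``column_map`` renames foreign dialects.

    Unknown extra columns are warned about and kept; missing required columns
    are fatal.  ``accurate`` and ``confidence_pct`` are derived if absent.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    extra = [c for c in df.columns if c not in TRIAL_COLUMNS]
    if extra:
        log.warning("ignoring unknown columns in %s: %s", path, extra)
    validate_trials(df, n_levels)
    if "accurate" not in df.columns:
        df["accurate"] = (df["response"] == df["stimulus"]).astype(int)
    if "confidence_pct" not in df.columns:
        df["confidence_pct"] = df["confidence_level"] * (100.0 / (n_levels - 1))
    return df


def write_trials(trials: pd.DataFrame, path, truth: dict | None = None) -> None:
    trials.to_csv(path, index=False)
    if truth is not None:
        sidecar = Path(path).with_suffix(".truth.json")
        with open(sidecar, "w") as fh:
            json.dump(truth, fh, indent=2, default=float)


# ---------------------------------------------------------------------------
# analysis stages
# ---------------------------------------------------------------------------


def subject_task_summaries(
    trials: pd.DataFrame, n_levels: int, collapse_to: int | None = None, with_mle: bool = False
) -> pd.DataFrame:
    """Per subject-task: d', criterion, mean confidence, AUROC2, optional MLE Mratio."""
    rows = []
    for (subj, task), block in trials.groupby(["subject", "task"], sort=True):
        counts = build_counts(block, n_levels, collapse_to)
        est = compute_dprime(counts, correction="loglinear")
        try:
            auroc2 = compute_auroc2(counts)
        except Exception:
            auroc2 = np.nan
        row = {
            "subject": subj,
            "task": task,
            "dprime": est.dprime,
            "criterion": est.criterion,
            "mean_confidence": compute_confidence_level(block),
            "auroc2": auroc2,
        }
        if with_mle:
            fit = fit_metad_mle(counts)
            row["metad_mle"] = fit.metad
            row["mratio_mle"] = fit.mratio
        rows.append(row)
    return pd.DataFrame(rows)


def _pairwise_tables(summaries: pd.DataFrame, value: str, alpha_corr: float):
    """Paired t-tests and Pearson correlations over all task pairs of ``value``."""
    wide = summaries.pivot(index="subject", columns="task", values=value).sort_index(axis=1)
    tasks = list(wide.columns)
    t_rows, r_rows = [], []
    for ti, tj in combinations(tasks, 2):
        tt = paired_ttest(wide[ti], wide[tj], alpha_corrected=alpha_corr)
        t_rows.append(
            {
                "task_i": ti,
                "task_j": tj,
                "t": tt.t,
                "df": tt.df,
                "p": tt.p,
                "dz": tt.dz,
                "significant": tt.significant_after_correction,
            }
        )
        cr = pearson_with_ci(wide[ti], wide[tj], alpha_corrected=alpha_corr)
        r_rows.append(
            {
                "task_i": ti,
                "task_j": tj,
                "r": cr.r,
                "ci_lo": cr.ci95[0],
                "ci_hi": cr.ci95[1],
                "p": cr.p,
                "significant": cr.significant_after_correction,
            }
        )
    return pd.DataFrame(t_rows), pd.DataFrame(r_rows)


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis sequence; returns the report bundle as a dict."""
    if config.simulation is not None:
        sim = config.simulation
        if config.seed is not None and sim.seed is None:
            sim = dataclasses.replace(sim, seed=config.seed)
        log.info("simulating group: %d subjects x %d tasks x %d trials",
                 sim.n_subjects, sim.n_tasks, sim.n_trials)
        trials, truth = simulate_group(sim)
        n_levels = sim.n_levels
    else:
        trials = read_trials(config.input_path, config.n_levels, config.column_map)
        truth = None
        n_levels = config.n_levels
    validate_trials(trials, n_levels)

    tasks = sorted(trials["task"].unique())
    n_pairs = len(tasks) * (len(tasks) - 1) // 2
    alpha_corr = bonferroni_threshold(config.alpha, max(n_pairs, 1))
    log.info("loaded %d trials, %d subjects, %d tasks; corrected alpha = %.4g",
             len(trials), trials["subject"].nunique(), len(tasks), alpha_corr)

    summaries = subject_task_summaries(trials, n_levels, config.collapse_to, with_mle=True)

    dprime_tests, dprime_corr = _pairwise_tables(summaries, "dprime", alpha_corr)
    conf_tests, conf_corr = _pairwise_tables(summaries, "mean_confidence", alpha_corr)

    # hierarchical fit on the full confidence scale (zero cells are fine
    # in the Bayesian path); collapse_to applies to the MLE summaries only
    counts = counts_by_subject_task(trials, n_levels, None)
    mcmc = config.mcmc
    if mcmc.seed is None and config.seed is not None:
        mcmc = dataclasses.replace(mcmc, seed=config.seed)
    posterior = fit_hmetad_multitask(
        counts, HierarchicalModelSpec(n_tasks=len(tasks)), mcmc,
        prior_only=config.prior_only,
    )
    log.info("hierarchical fit done; max R-hat %.3f", posterior.max_rhat())
    hier_report = summarize_correlations(posterior) if n_pairs else {"rho": None}

    kept, exclusion_log = exclude_low_performance(summaries, config.exclusion_threshold)
    log.info("nonhierarchical path: excluded %d subjects (d' < %.2f)",
             summaries["subject"].nunique() - kept["subject"].nunique(),
             config.exclusion_threshold)
    wide_mratio = kept.pivot(index="subject", columns="task", values="mratio_mle")
    mratio_rows = []
    for ti, tj in combinations(tasks, 2):
        cr = pearson_with_ci(wide_mratio[ti], wide_mratio[tj], alpha_corrected=alpha_corr)
        mratio_rows.append(
            {
                "task_i": ti, "task_j": tj, "r": cr.r,
                "ci_lo": cr.ci95[0], "ci_hi": cr.ci95[1],
                "p": cr.p, "significant": cr.significant_after_correction,
            }
        )

    bundle = {
        "config": {
            "n_levels": n_levels,
            "collapse_to": config.collapse_to,
            "alpha": config.alpha,
            "alpha_corrected": alpha_corr,
            "exclusion_threshold": config.exclusion_threshold,
            "seed": config.seed,
            "mcmc": dataclasses.asdict(mcmc),
            "version": __version__,
        },
        "trials": trials,
        "truth": truth,
        "summaries": summaries,
        "dprime_ttests": dprime_tests,
        "dprime_correlations": dprime_corr,
        "confidence_ttests": conf_tests,
        "confidence_correlations": conf_corr,
        "posterior": posterior,
        "group_mratio_summary": posterior.summary(),
        "rho_report": hier_report.get("rho"),
        "mratio_difference_report": hier_report.get("mratio_difference"),
        "nonhier_mratio_correlations": pd.DataFrame(mratio_rows),
        "exclusions": exclusion_log,
    }
    if config.output_dir is not None:
        write_report(bundle, config.output_dir)
    return bundle


def write_report(bundle: dict, outdir) -> list:
    """Write the bundle to ``outdir`` as CSV/JSON files; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    def _csv(name, df):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths.append(p)

    write_trials(bundle["trials"], outdir / "trials.csv", bundle.get("truth"))
    paths.append(outdir / "trials.csv")
    for name in (
        "summaries",
        "dprime_ttests",
        "dprime_correlations",
        "confidence_ttests",
        "confidence_correlations",
        "group_mratio_summary",
        "rho_report",
        "mratio_difference_report",
        "nonhier_mratio_correlations",
        "exclusions",
    ):
        df = bundle.get(name)
        if df is not None:
            _csv(name, df)
    bundle["posterior"].draws_to_csv(outdir / "posterior_draws.csv")
    bundle["posterior"].to_json(outdir / "posterior_summary.json")
    with open(outdir / "run_config.json", "w") as fh:
        json.dump(bundle["config"], fh, indent=2, default=float)
    paths += [outdir / "posterior_draws.csv", outdir / "posterior_summary.json",
              outdir / "run_config.json"]
    return paths
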