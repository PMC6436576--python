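"""Behavioural outcomes and group-level statistics.

Draws to decision (DTD) is the primary outcome; accuracy is the Bayesian
posterior of the chosen lake given the colours and number of fish seen, so
it is defined whether or not the ground-truth lake is known.  The
dichotomous jumping-to-conclusions (JTC) classification flags decisions made
after one or two pieces of information; a subject exhibits JTC in a block
when their median trial DTD is at most 2 (the per-trial flags are exposed
too, so tabulations of JTC-in-all-blocks styles can be recomputed).

Group comparisons use Mann–Whitney U for skewed metrics (DTD, fitted CS), a
t test for the temperature, and Spearman rank correlations against supplied
covariates.  Within-block consistency of DTD is quantified with a two-way
mixed, single-measure, consistency-type intraclass correlation, ICC(3,1)
(trials as raters, subjects as targets).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .pomdp import posterior_gold
from .task import BlockSpec, Dataset, TaskConfig, default_blocks

__all__ = [
    "trial_table",
    "summarize",
    "group_compare",
    "spearman_assoc",
    "icc_consistency",
    "flag_point_outliers",
]

JTC_MAX_DRAWS = 2  # a decision after <= 2 pieces of information


def trial_table(
    dataset: Dataset,
    blocks: list[BlockSpec] | None = None,
    config: TaskConfig | None = None,
) -> pd.DataFrame:
    """Per-trial outcomes: DTD, posterior accuracy, correctness, points, JTC.

    Points are the block's win/loss (NaN when the true lake is unknown)
    minus the objective sampling charges of draws 2..DTD.
    """
    config = config or TaskConfig()
    blocks = blocks or default_blocks(config)
    by_id = {b.block_id: b for b in blocks}
    rows = []
    for r in dataset:
        if r.block_id not in by_id:
            raise KeyError(f"unknown block id {r.block_id}")
        b = by_id[r.block_id]
        p_g = posterior_gold(r.dtd, r.n_gold, config.majority_prob)
        acc = p_g if r.declared_lake == "G" else 1.0 - p_g
        sampling = sum(b.cost_of_draw(k) for k in range(2, r.dtd + 1))
        if r.correct is None:
            points = np.nan
        else:
            points = (b.reward_correct if r.correct else -b.cost_wrong) - sampling
        rows.append(
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "block": r.block_id,
                "trial": r.trial,
                "dtd": r.dtd,
                "accuracy": float(acc),
                "correct": r.correct,
                "points": points,
                "jtc": r.dtd <= JTC_MAX_DRAWS,
            }
        )
    return pd.DataFrame(rows)


def summarize(
    dataset: Dataset,
    blocks: list[BlockSpec] | None = None,
    config: TaskConfig | None = None,
) -> pd.DataFrame:
    """Per subject × block summary of the behavioural outcomes.

    Columns: mean and median DTD, mean posterior accuracy of the chosen
    lake, fraction correct (NaN without ground truth), total points, number
    of JTC trials, and the subject-level JTC flag (median DTD <= 2).
    Invariant to the row order of the input.
    """
    trials = trial_table(dataset, blocks, config)
    grouped = trials.groupby(["subject_id", "group", "block"], sort=True)
    out = grouped.agg(
        n_trials=("dtd", "size"),
        mean_dtd=("dtd", "mean"),
        median_dtd=("dtd", "median"),
        mean_accuracy=("accuracy", "mean"),
        frac_correct=("correct", lambda c: np.nan if c.isna().any() else float(np.mean(c))),
        total_points=("points", lambda p: np.nan if p.isna().any() else float(np.sum(p))),
        n_jtc_trials=("jtc", "sum"),
    ).reset_index()
    out["jtc"] = out["median_dtd"] <= JTC_MAX_DRAWS
    return out


def group_compare(
    df: pd.DataFrame,
    metric: str,
    group_col: str = "group",
    method: str = "mannwhitney",
) -> dict:
    """Two-group comparison on one metric.

    ``method`` is ``"mannwhitney"`` (two-sided U test; the convention for
    skewed metrics such as DTD or fitted CS), ``"ttest"`` (Student, pooled
    variance) or ``"welch"``.  The exact test used is recorded in the
    returned report.
    """
    groups = [g for g, _ in df.groupby(group_col, sort=True)]
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, found {groups}")
    x = df.loc[df[group_col] == groups[0], metric].to_numpy(dtype=float)
    y = df.loc[df[group_col] == groups[1], metric].to_numpy(dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two subjects")
    if method == "mannwhitney":
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        name = "Mann-Whitney U (two-sided)"
    elif method in ("ttest", "welch"):
        res = stats.ttest_ind(x, y, equal_var=(method == "ttest"))
        name = "Student t (pooled)" if method == "ttest" else "Welch t"
    else:
        raise ValueError(f"unknown method {method!r}")
    return {
        "metric": metric,
        "method": name,
        "groups": groups,
        "n": (len(x), len(y)),
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
    }


def spearman_assoc(df: pd.DataFrame, x: str, y: str) -> dict:
    """Spearman rank correlation between two columns."""
    sub = df[[x, y]].dropna()
    rho, p = stats.spearmanr(sub[x], sub[y])
    return {"x": x, "y": y, "method": "Spearman rho", "n": len(sub),
            "rho": float(rho), "p_value": float(p)}


def icc_consistency(
    dataset_or_trials,
    blocks: list[BlockSpec] | None = None,
    config: TaskConfig | None = None,
) -> pd.DataFrame:
    """ICC(3,1) of trial DTD per group × block.

    Consistency of each subject's DTD across the repeated trials of a
    block: two-way mixed model, single measure, consistency type, with
    trials as raters and subjects as targets.  Blocks with fewer than two
    trials raise; a degenerate block (no between-subject variance) reports
    NaN.
    """
    import pingouin as pg

    trials = (
        dataset_or_trials
        if isinstance(dataset_or_trials, pd.DataFrame)
        else trial_table(dataset_or_trials, blocks, config)
    )
    rows = []
    for (grp, blk), sub in trials.groupby(["group", "block"], sort=True):
        if sub.groupby("subject_id")["trial"].count().min() < 2:
            raise ValueError(f"block {blk} of group {grp} has single-trial subjects")
        if np.allclose(sub.groupby("subject_id")["dtd"].mean().var(ddof=1), 0.0):
            icc = np.nan  # identical subjects: between-target variance is zero
        else:
            res = pg.intraclass_corr(
                data=sub, targets="subject_id", raters="trial", ratings="dtd"
            )
            # two-way mixed, single measure, consistency; pingouin labels
            # this ICC3 or ICC(C,1) depending on version
            row = res[res["Type"].isin(["ICC3", "ICC(C,1)"])].iloc[0]
            icc = float(row["ICC"])
        rows.append({"group": grp, "block": blk, "icc": icc, "type": "ICC(3,1) consistency"})
    return pd.DataFrame(rows)


def flag_point_outliers(summary: pd.DataFrame, sd_threshold: float = 2.0,
                        per_group: bool = True) -> pd.DataFrame:
    """Flag subjects whose total points lie beyond ``sd_threshold`` SDs.

    Report-only (no automatic exclusion); the SD is taken within group by
    default, or pooled with ``per_group=False``.
    """
    pts = summary.groupby(["subject_id", "group"], sort=False)["total_points"].sum().reset_index()

    def _flag(g: pd.DataFrame) -> pd.DataFrame:
        mu, sd = g["total_points"].mean(), g["total_points"].std(ddof=1)
        g = g.copy()
        g["outlier"] = (g["total_points"] - mu).abs() > sd_threshold * sd if sd > 0 else False
        return g

    if per_group:
        return pd.concat(
            [_flag(g) for _, g in pts.groupby("group", sort=False)], ignore_index=True
        )
    return _flag(pts)
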