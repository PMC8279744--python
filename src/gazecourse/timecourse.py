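"""Condition time courses, log-ratio preference scores, adjusted CIs.

The preference score for each participant x trial x bin is the empirical
log-ratio ln((female + 0.5) / (male + 0.5)) of 1-ms sample counts on the two
characters; positive values indicate a preference for the female character.
Condition means aggregate in two stages (trials to participant, participants
to condition) and carry 95% confidence intervals adjusted for the
within-subject design: Cousineau normalization (remove each participant's
mean across conditions, add back the grand mean) with the Morey
sqrt(C/(C-1)) inflation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CONDITION_COLS = ["occupation_stereotype", "action_stereotype"]


def log_ratio(female_samples, male_samples, bin_size: int = 100, smoothing: float = 0.5):
    """Empirical log-ratio of female- vs male-character sample counts.

    Additive smoothing keeps the score finite at zero counts and makes it
    exactly antisymmetric under swapping the arguments.
    """
    f = np.asarray(female_samples, dtype=float)
    m = np.asarray(male_samples, dtype=float)
    if (f < 0).any() or (m < 0).any():
        raise ValueError("sample counts must be non-negative")
    if (f > bin_size).any() or (m > bin_size).any():
        raise ValueError(f"sample counts cannot exceed the bin size ({bin_size})")
    # difference of logs, not log of ratio: bitwise antisymmetric under swap
    return np.log(f + smoothing) - np.log(m + smoothing)


def add_log_ratio(bin_series: pd.DataFrame, bin_ms: int = 100, smoothing: float = 0.5) -> pd.DataFrame:
    """Attach the per-row log-ratio to a binned series (counts recovered from
    the proportions)."""
    out = bin_series.copy()
    out["log_ratio"] = log_ratio(
        out["p_female"].to_numpy() * bin_ms,
        out["p_male"].to_numpy() * bin_ms,
        bin_size=bin_ms,
        smoothing=smoothing,
    )
    return out


def within_subject_ci(matrix: pd.DataFrame, level: float = 0.95) -> pd.Series:
    """Per-condition CI half-widths for a participants x conditions matrix.

    Cousineau-normalizes (subtract participant means, add the grand mean),
    takes the per-condition SEM of the normalized scores, inflates by the
    Morey factor sqrt(C/(C-1)), and multiplies by the t quantile with n-1 df.
    Participants with missing cells are dropped with a warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two conditions for the within-subject adjustment")
    complete = matrix.dropna()
    if len(complete) < len(matrix):
        logger.warning("dropping %d participant(s) with missing cells", len(matrix) - len(complete))
    n, c = complete.shape
    if n < 2:
        raise ValueError("need at least two complete participants")
    if not 0.0 <= level < 1.0:
        raise ValueError("confidence level must lie in [0, 1)")
    normalized = complete.sub(complete.mean(axis=1), axis=0) + complete.to_numpy().mean()
    sem = normalized.std(axis=0, ddof=1) / np.sqrt(n)
    morey = np.sqrt(c / (c - 1))
    tq = stats.t.ppf(0.5 + level / 2.0, df=n - 1) if level > 0 else 0.0
    return sem * morey * tq


def condition_timecourse(
    bin_series: pd.DataFrame,
    value_cols: list[str] | None = None,
    condition_cols: list[str] | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Two-stage condition means with adjusted CIs, per bin and value column.

    Stage 1 averages trials within participant x condition x bin (missing
    bins simply do not contribute); stage 2 averages participants. The CI
    half-width treats the condition combinations present at each bin as the
    within-subject factor levels.
    """
    if value_cols is None:
        value_cols = [c for c in bin_series.columns if c.startswith("p_")] + (
            ["log_ratio"] if "log_ratio" in bin_series.columns else []
        )
    if condition_cols is None:
        condition_cols = [c for c in CONDITION_COLS if c in bin_series.columns]
    if bin_series["participant"].nunique() < 2:
        raise ValueError("need at least two participants")

    stage1 = (
        bin_series.groupby(["participant", *condition_cols, "bin", "bin_start"])[value_cols]
        .mean()
        .reset_index()
    )
    rows = []
    for (bin_idx, bin_start), sub in stage1.groupby(["bin", "bin_start"]):
        for val in value_cols:
            wide = sub.pivot_table(
                index="participant", columns=condition_cols, values=val, aggfunc="mean"
            )
            if wide.shape[1] >= 2:
                half = within_subject_ci(wide, level=level)
            else:
                sem = wide.std(axis=0, ddof=1) / np.sqrt(wide.notna().sum())
                half = sem * stats.t.ppf(0.5 + level / 2.0, df=wide.notna().sum() - 1)
            means = wide.mean(axis=0)
            for cond, mean in means.items():
                cond_t = cond if isinstance(cond, tuple) else (cond,)
                rows.append(
                    {
                        "bin": bin_idx,
                        "bin_start": bin_start,
                        **dict(zip(condition_cols, cond_t)),
                        "measure": val,
                        "mean": mean,
                        "ci_half_width": float(half.get(cond, np.nan)),
                        "n_participants": int(wide[cond].notna().sum()),
                    }
                )
    return pd.DataFrame(rows)


def score_accuracy(filler_responses: pd.DataFrame) -> pd.DataFrame:
    """Per-participant proportion of correct engagement-check responses.

    Responses are coded 1 (correct) / 0 (incorrect); the participant score is
    their mean.
    """
    vals = filler_responses["correct"]
    if not vals.isin([0, 1]).all():
        raise ValueError("filler responses must be binary 0/1")
    per = vals.groupby(filler_responses["participant"]).agg(["mean", "size"])
    per.columns = ["accuracy", "n_questions"]
    return per.reset_index()


def accuracy_summary(per_participant: pd.DataFrame) -> dict:
    acc = per_participant["accuracy"]
    return {"mean": float(acc.mean()), "min": float(acc.min()), "max": float(acc.max())}
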