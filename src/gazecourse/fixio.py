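"""Fixation-report I/O, AOI assignment, and time-locked binning.

Fixations arrive as one row per fixation (participant, trial, start/end in
ms on the trial clock, and either an AOI label or gaze coordinates), the
dialect of a Data-Viewer-style fixation report. Analysis operates on 1-ms
samples: a sample at integer time ``w`` (ms relative to noun onset) belongs
to a fixation iff ``start <= w < end``; samples covered by no fixation count
as "elsewhere". Samples are then aggregated into consecutive 100-ms bins
tiling the analysis window, by default [-2000, +1000) ms around the critical
noun onset. The implementation uses closed-form interval overlap counts
(``ceil(hi) - ceil(lo)`` integers in ``[lo, hi)``) and is exactly equivalent
to materializing the 1-ms indicator vectors.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AOI_NAMES = ("female", "male", "object1", "object2")
ALL_LABELS = AOI_NAMES + ("elsewhere",)

DEFAULT_WINDOW = (-2000, 1000)
DEFAULT_BIN_MS = 100

REQUIRED_COLUMNS = ("participant", "trial_id", "fix_start", "fix_end")


class FormatError(ValueError):
    """The input file does not match the expected fixation-report dialect."""


def read_fixation_report(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a fixation-report TSV.

    ``column_map`` maps file column names to the canonical names
    (participant, trial_id, fix_start, fix_end, aoi | x, y). Rows failing
    validation (non-numeric times, end <= start, negative times) are dropped
    and logged with their line numbers.
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"fixation report is missing required column(s): {missing}")
    if "aoi" not in df.columns and not {"x", "y"}.issubset(df.columns):
        raise FormatError("fixation report needs either an 'aoi' column or 'x'/'y' columns")
    return validate_fixations(df)


def validate_fixations(df: pd.DataFrame) -> pd.DataFrame:
    start = pd.to_numeric(df["fix_start"], errors="coerce")
    end = pd.to_numeric(df["fix_end"], errors="coerce")
    bad = start.isna() | end.isna() | (end <= start) | (start < 0)
    if bad.any():
        for line in df.index[bad]:
            logger.warning("dropping invalid fixation row at line %d", line + 2)
    out = df.loc[~bad].copy()
    out["fix_start"] = start[~bad]
    out["fix_end"] = end[~bad]
    return out.reset_index(drop=True)


def write_fixation_report(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# AOI assignment


def read_aoi_map(path) -> pd.DataFrame:
    """AOI map TSV: trial_id, aoi_name, x0, y0, x1, y1."""
    df = pd.read_csv(path, sep="\t")
    need = {"trial_id", "aoi_name", "x0", "y0", "x1", "y1"}
    if not need.issubset(df.columns):
        raise FormatError(f"AOI map is missing column(s): {sorted(need - set(df.columns))}")
    if ((df["x1"] <= df["x0"]) | (df["y1"] <= df["y0"])).any():
        raise FormatError("AOI rectangles must have positive area")
    return df


def assign_aoi(x: float, y: float, rects: pd.DataFrame, strict: bool = True) -> str:
    """Classify a gaze point against half-open rectangles [x0,x1) x [y0,y1).

    Returns the AOI name, or "elsewhere" when the point falls outside all
    rectangles. If overlapping rectangles both contain the point, strict mode
    raises; otherwise the first rectangle in row order wins.
    """
    inside = rects[
        (rects["x0"] <= x) & (x < rects["x1"]) & (rects["y0"] <= y) & (y < rects["y1"])
    ]
    if len(inside) > 1 and strict:
        raise ValueError(
            f"point ({x}, {y}) falls in multiple AOIs: {inside['aoi_name'].tolist()}"
        )
    if len(inside) == 0:
        return "elsewhere"
    return str(inside["aoi_name"].iloc[0])


def assign_aois(fix_df: pd.DataFrame, aoi_map: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Vector version: add/overwrite the ``aoi`` column from x/y coordinates,
    using each trial's rectangles (an AOI map without per-trial rows applies
    to every trial)."""
    out = fix_df.copy()
    per_trial = "trial_id" in aoi_map.columns and aoi_map["trial_id"].notna().all()
    labels = []
    for _, row in out.iterrows():
        rects = aoi_map[aoi_map["trial_id"] == row["trial_id"]] if per_trial else aoi_map
        labels.append(assign_aoi(row["x"], row["y"], rects, strict=strict))
    out["aoi"] = labels
    return out


# ---------------------------------------------------------------------------
# 1-ms expansion and 100-ms binning


def _check_window(window: tuple[int, int], bin_ms: int) -> int:
    w0, w1 = window
    if w1 <= w0:
        raise ValueError("window must be increasing")
    if (w1 - w0) % bin_ms or w0 % bin_ms or w1 % bin_ms:
        raise ValueError(f"window bounds {window} must be multiples of bin width {bin_ms}")
    return (w1 - w0) // bin_ms


def _overlap_counts(starts, ends, window, bin_ms):
    """(n_fix, n_bins) counts of integer 1-ms samples of each bin covered by
    each fixation; times are ms relative to noun onset."""
    n_bins = _check_window(window, bin_ms)
    edges = window[0] + bin_ms * np.arange(n_bins + 1)
    lo = np.maximum(np.asarray(starts, float)[:, None], edges[None, :-1])
    hi = np.minimum(np.asarray(ends, float)[:, None], edges[None, 1:])
    return np.maximum(0, np.ceil(hi) - np.ceil(lo)).astype(np.int64)


def expand_and_bin(
    fix_df: pd.DataFrame,
    noun_onset: float,
    window: tuple[int, int] = DEFAULT_WINDOW,
    bin_ms: int = DEFAULT_BIN_MS,
) -> pd.DataFrame:
    """Bin one trial's fixations into per-AOI sample proportions.

    Returns one row per bin with columns ``bin`` (index), ``bin_start`` (ms
    relative to noun onset), ``p_<aoi>`` for the four AOIs, ``p_elsewhere``
    (complement, including inter-fixation gaps), and ``n_valid`` (number of
    1-ms samples covered by any fixation). A trial with no fixations in the
    window yields all-zero proportions with ``n_valid`` 0.
    """
    n_bins = _check_window(window, bin_ms)
    counts = np.zeros((5, n_bins), dtype=np.int64)
    if len(fix_df):
        ov = _overlap_counts(
            fix_df["fix_start"].to_numpy() - noun_onset,
            fix_df["fix_end"].to_numpy() - noun_onset,
            window,
            bin_ms,
        )
        aoi_idx = np.array([ALL_LABELS.index(a) for a in fix_df["aoi"]])
        np.add.at(counts, aoi_idx, ov)
    n_valid = counts.sum(axis=0)
    out = pd.DataFrame({"bin": np.arange(n_bins), "bin_start": window[0] + bin_ms * np.arange(n_bins)})
    for k, name in enumerate(AOI_NAMES):
        out[f"p_{name}"] = counts[k] / bin_ms
    out["p_elsewhere"] = (bin_ms - counts[:4].sum(axis=0)) / bin_ms
    out["n_valid"] = n_valid
    return out


def bin_experiment(
    fixations: pd.DataFrame,
    meta: pd.DataFrame,
    window: tuple[int, int] = DEFAULT_WINDOW,
    bin_ms: int = DEFAULT_BIN_MS,
) -> pd.DataFrame:
    """Bin all experimental trials, vectorized across fixations.

    ``meta`` must carry (participant, trial_id, noun_onset) plus the
    condition columns, which are propagated to the output. Returns a long
    frame keyed by (participant, trial_id, bin).
    """
    n_bins = _check_window(window, bin_ms)
    trials = meta[meta["trial_type"] == "experimental"] if "trial_type" in meta.columns else meta
    trials = trials.reset_index(drop=True)
    key = ["participant", "trial_id"]
    trial_idx = {t: i for i, t in enumerate(map(tuple, trials[key].to_numpy()))}

    fx = fixations.merge(trials[key + ["noun_onset"]], on=key, how="inner")
    arr = np.zeros((len(trials), 5, n_bins), dtype=np.int64)
    if len(fx):
        ov = _overlap_counts(
            fx["fix_start"].to_numpy() - fx["noun_onset"].to_numpy(),
            fx["fix_end"].to_numpy() - fx["noun_onset"].to_numpy(),
            window,
            bin_ms,
        )
        ti = np.array([trial_idx[t] for t in map(tuple, fx[key].to_numpy())])
        ai = np.array([ALL_LABELS.index(a) for a in fx["aoi"]])
        np.add.at(arr, (ti, ai), ov)

    reps = np.repeat(np.arange(len(trials)), n_bins)
    out = trials.loc[reps].reset_index(drop=True)
    out["bin"] = np.tile(np.arange(n_bins), len(trials))
    out["bin_start"] = window[0] + bin_ms * out["bin"]
    for k, name in enumerate(AOI_NAMES):
        out[f"p_{name}"] = arr[:, k, :].reshape(-1) / bin_ms
    out["p_elsewhere"] = (bin_ms - arr[:, :4, :].sum(axis=1).reshape(-1)) / bin_ms
    out["n_valid"] = arr.sum(axis=1).reshape(-1)
    n_empty = int((out.groupby(key)["n_valid"].sum() == 0).sum())
    if n_empty:
        logger.warning("%d trial(s) had no fixations in the analysis window", n_empty)
    return out
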