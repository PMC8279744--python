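"""Cluster-based randomization inference on log-ratio time series.

Two-stage procedure. Stage 1 tests every 100-ms bin: the log-ratio is
contrasted either between the two occupation conditions (within each action
condition) or against a zero reference (no preference) within one
occupation condition. Consecutive significant bins of the same t sign form
clusters scored by their summed t. Stage 2 builds a null distribution of
the largest |summed t| per iteration by re-running the whole stage-1
analysis on label-scrambled data — occupation labels permuted within
participant, or real/zero labels swapped per trial series — and a cluster
is significant when its |summed t| exceeds the 97.5th percentile of its
null (two-tailed 2.5% criterion, add-one p estimator).

Stage-1 statistics: the default ``stat="paired"`` collapses trials to
participant-level means and uses a paired (or one-sample) t — fast enough
to vectorize across thousands of permutation iterations, and exact as a
permutation test because the identical statistic scores observed and
permuted data. ``stat="mixed"`` instead fits the per-bin linear mixed model
with crossed random intercepts for participants and items; it is intended
for the observed stage or small iteration counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

SCHEMES = ("condition-swap", "female-vs-zero", "male-vs-zero")


@dataclass(frozen=True)
class BinTestResult:
    bin: int
    t: float
    p: float
    contrast: str
    scope: tuple
    converged: bool = True


@dataclass(frozen=True)
class Cluster:
    contrast: str
    scope: tuple
    start_bin: int
    end_bin: int  # inclusive
    t_values: tuple[float, ...]

    @property
    def summed_t(self) -> float:
        return float(sum(self.t_values))

    @property
    def length(self) -> int:
        return self.end_bin - self.start_bin + 1


@dataclass
class PermutationNull:
    scheme: str
    scope: tuple
    n_iterations: int
    max_abs_summed_t: np.ndarray
    seed: int


@dataclass
class ClusterSignificance:
    cluster: Cluster
    p: float
    significant: bool


# ---------------------------------------------------------------------------
# rectangular stacking of a log-ratio table


@dataclass
class _Stacked:
    """Log-ratio series stacked as (participants, series, bins) with NaN
    padding for ragged designs; ``labels`` holds each series' 0/1 contrast
    label (1 = the focal level)."""

    values: np.ndarray  # (P, I, B)
    labels: np.ndarray  # (P, I), NaN-padded series get label -1
    participants: np.ndarray
    bins: np.ndarray


def _stack(table: pd.DataFrame, label_from: str | None, focal_level: str | None) -> _Stacked:
    bins = np.sort(table["bin"].unique())
    b_idx = {b: i for i, b in enumerate(bins)}
    parts = np.sort(table["participant"].unique())
    p_idx = {p: i for i, p in enumerate(parts)}
    series_keys = table[["participant", "trial_id"]].drop_duplicates()
    max_i = series_keys.groupby("participant").size().max()
    values = np.full((len(parts), max_i, len(bins)), np.nan)
    labels = np.full((len(parts), max_i), -1, dtype=np.int64)

    # assign a slot per (participant, trial) in deterministic order
    slot: dict[tuple, tuple[int, int]] = {}
    counter: dict[int, int] = {}
    for p, t in series_keys.sort_values(["participant", "trial_id"]).itertuples(index=False):
        pi = p_idx[p]
        si = counter.get(pi, 0)
        counter[pi] = si + 1
        slot[(p, t)] = (pi, si)

    pi_arr = np.empty(len(table), dtype=np.int64)
    si_arr = np.empty(len(table), dtype=np.int64)
    keys = table[["participant", "trial_id"]].to_numpy()
    for r, (p, t) in enumerate(map(tuple, keys)):
        pi_arr[r], si_arr[r] = slot[(p, t)]
    bi_arr = table["bin"].map(b_idx).to_numpy()
    values[pi_arr, si_arr, bi_arr] = table["log_ratio"].to_numpy()
    if label_from is not None:
        lab = (table[label_from].to_numpy() == focal_level).astype(np.int64)
        labels[pi_arr, si_arr] = lab
    else:
        labels[pi_arr, si_arr] = 1
    return _Stacked(values=values, labels=labels, participants=parts, bins=bins)


def _t_from_participant_stats(per_participant: np.ndarray) -> tuple[np.ndarray, int]:
    """t statistic across the participant axis (axis -2) of a (..., P, B)
    array; zero-variance bins yield t = 0."""
    n = per_participant.shape[-2]
    mean = np.nanmean(per_participant, axis=-2)
    sd = np.nanstd(per_participant, axis=-2, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t, n - 1


def _contrast_t(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Paired t per bin for the two-level contrast.

    ``labels`` may be (P, I) for the observed stage or (T, P, I) for T
    permutation iterations; returns t with shape (B,) or (T, B).
    """
    v = values  # (P, I, B)
    valid = ~np.isnan(v)
    v0 = np.where(valid, v, 0.0)
    lab1 = (labels == 1).astype(float)
    lab0 = (labels == 0).astype(float)
    if labels.ndim == 2:
        ein = "pib,pi->pb"
    else:
        ein = "pib,tpi->tpb"
    n1 = np.einsum(ein, valid.astype(float), lab1)
    n0 = np.einsum(ein, valid.astype(float), lab0)
    s1 = np.einsum(ein, v0, lab1)
    s0 = np.einsum(ein, v0, lab0)
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = s1 / n1 - s0 / n0  # (.., P, B)
    return _t_from_participant_stats(diff)


def _zero_t(values: np.ndarray, signs: np.ndarray | None = None) -> tuple[np.ndarray, int]:
    """One-sample t per bin of participant-mean log-ratio; ``signs``
    ((T, P, I), +/-1) encode real/zero label swaps per trial series."""
    valid = ~np.isnan(values)
    v0 = np.where(valid, values, 0.0)
    if signs is None:
        with np.errstate(invalid="ignore"):
            m = np.nansum(v0, axis=1) / valid.sum(axis=1)  # (P, B)
    else:
        num = np.einsum("pib,tpi->tpb", v0, signs.astype(float))
        den = valid.sum(axis=1)[None, :, :]
        m = num / den
    # a swapped series contributes -v/2 vs +v/2 under the paired real-zero
    # reading; the factor 1/2 cancels in the t statistic, so plain signed
    # means are equivalent
    return _t_from_participant_stats(m)


# ---------------------------------------------------------------------------
# public per-bin test (table interface)


def zero_reference(table: pd.DataFrame) -> pd.DataFrame:
    """Augment a log-ratio table with zero pseudo-observations.

    Every real row gets a mirror with ``log_ratio`` 0 and ``ref_label``
    "zero" (real rows get "real"), mirroring participant/item/bin keys so a
    real-vs-zero contrast can be run with the same machinery.
    """
    real = table.copy()
    real["ref_label"] = "real"
    zero = table.copy()
    zero["log_ratio"] = 0.0
    zero["ref_label"] = "zero"
    # keep pseudo-series distinct from their real counterparts
    zero["trial_id"] = -zero["trial_id"].astype(np.int64) - 1
    return pd.concat([real, zero], ignore_index=True)


def _mixed_t(sub: pd.DataFrame, label_col: str, focal_level: str) -> tuple[float, bool]:
    """Fixed-effect t from the per-bin mixed model with crossed random
    intercepts (participants, items), via variance components on a single
    trivial group. Falls back (converged=False) on failure."""
    from statsmodels.regression.mixed_linear_model import MixedLM

    data = sub.copy()
    data["__x"] = (data[label_col] == focal_level).astype(float)
    data["__g"] = 1
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM.from_formula(
                "log_ratio ~ __x",
                groups="__g",
                vc_formula={"pp": "0 + C(participant)", "it": "0 + C(trial_id)"},
                data=data,
            )
            fit = model.fit(reml=True)
        t = float(fit.params["__x"] / fit.bse["__x"])
        if not np.isfinite(t):
            raise ValueError("non-finite t")
        return t, True
    except Exception:  # noqa: BLE001 - any optimizer failure triggers fallback
        return np.nan, False


def per_bin_test(
    table: pd.DataFrame,
    bin_index: int,
    contrast: str = "condition",
    label_col: str = "occupation_stereotype",
    focal_level: str = "female",
    stat: str = "paired",
    scope: tuple = (),
) -> BinTestResult:
    """Test one bin's log-ratios on a two-level contrast.

    ``contrast="condition"`` contrasts ``focal_level`` against the other
    level of ``label_col``; ``contrast="zero"`` expects a
    :func:`zero_reference`-augmented table and contrasts real vs zero.
    """
    sub = table[table["bin"] == bin_index]
    if contrast == "zero":
        label_col, focal_level = "ref_label", "real"
    if sub.empty:
        raise ValueError(f"no data for bin {bin_index} in scope {scope}")
    levels = sub[label_col].unique()
    if len(levels) < 2:
        raise ValueError(f"contrast needs two levels in bin {bin_index}, got {levels}")
    if sub["participant"].nunique() < 2 or sub["trial_id"].nunique() < 2:
        raise ValueError("need at least two participants and two items")

    converged = True
    if stat == "mixed":
        t, converged = _mixed_t(sub, label_col, focal_level)
        if converged:
            # normal-approximation p; crossed random-intercept df are contested
            # and the permutation stage calibrates the final inference
            p = 2.0 * sps.norm.sf(abs(t))
            return BinTestResult(bin_index, t, p, contrast, scope, True)
    # paired path (also the mixed-model fallback)
    agg = sub.groupby(["participant", label_col])["log_ratio"].mean().unstack(label_col)
    other = [l for l in agg.columns if l != focal_level]
    diff = (agg[focal_level] - agg[other].mean(axis=1)).dropna()
    sd = diff.std(ddof=1)
    t = 0.0 if sd == 0 else float(diff.mean() / (sd / np.sqrt(len(diff))))
    p = 2.0 * sps.t.sf(abs(t), df=len(diff) - 1) if sd > 0 else 1.0
    return BinTestResult(bin_index, t, p, contrast, scope, converged)


# ---------------------------------------------------------------------------
# clusters


def find_clusters(
    bin_results: list[BinTestResult], alpha: float = 0.05, min_length: int = 1
) -> list[Cluster]:
    """Maximal runs of consecutive significant bins sharing a t sign."""
    clusters: list[Cluster] = []
    run: list[BinTestResult] = []

    def close() -> None:
        if len(run) >= min_length:
            clusters.append(
                Cluster(
                    contrast=run[0].contrast,
                    scope=run[0].scope,
                    start_bin=run[0].bin,
                    end_bin=run[-1].bin,
                    t_values=tuple(r.t for r in run),
                )
            )
        run.clear()

    ordered = sorted(bin_results, key=lambda r: r.bin)
    for r in ordered:
        sig = r.p < alpha and r.t != 0
        if not sig:
            close()
            continue
        if run and (r.bin != run[-1].bin + 1 or np.sign(r.t) != np.sign(run[-1].t)):
            close()
        run.append(r)
    close()
    return clusters


def _max_cluster_mass(t: np.ndarray, t_crit: float) -> float:
    """Largest |summed t| over same-sign runs of |t| >= t_crit bins; 0 when
    no bin is significant."""
    sig = np.abs(t) >= t_crit
    best = 0.0
    acc = 0.0
    prev_sign = 0.0
    for ti, s in zip(t, sig):
        if not s:
            acc, prev_sign = 0.0, 0.0
            continue
        sign = np.sign(ti)
        if sign != prev_sign:
            acc = 0.0
        acc += ti
        prev_sign = sign
        best = max(best, abs(acc))
    return best


# ---------------------------------------------------------------------------
# permutation engine


def _permuted_labels(labels: np.ndarray, n_iter: int, rng: np.random.Generator) -> np.ndarray:
    """Permute each participant's series labels independently per iteration
    (shape (T, P, I)); padded slots (label -1) stay in place."""
    P, I = labels.shape
    keys = rng.random((n_iter, P, I))
    keys[:, labels < 0] = np.inf  # padded slots sort last and keep label -1
    order = np.argsort(keys, axis=-1)
    return np.take_along_axis(np.broadcast_to(labels, (n_iter, P, I)), order, axis=-1)


def permutation_null(
    table: pd.DataFrame,
    scheme: str,
    n_iterations: int = 2000,
    seed: int = 0,
    alpha_bin: float = 0.05,
    scope: tuple = (),
) -> PermutationNull:
    """Null distribution of the largest |summed t| under label scrambling.

    ``condition-swap`` permutes occupation labels within participant across
    that participant's trial series (whole series move together, preserving
    within-trial time correlation); the vs-zero schemes swap real/zero
    labels per series, i.e. flip the series' sign in the one-sample test.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    rng = np.random.default_rng(seed)
    if scheme == "condition-swap":
        stacked = _stack(table, "occupation_stereotype", "female")
        perm = _permuted_labels(stacked.labels, n_iterations, rng)
        t, df = _contrast_t(stacked.values, perm)
    else:
        stacked = _stack(table, None, None)
        P, I = stacked.labels.shape
        signs = rng.integers(0, 2, size=(n_iterations, P, I)) * 2 - 1
        t, df = _zero_t(stacked.values, signs)
    t_crit = sps.t.ppf(1.0 - alpha_bin / 2.0, df=df)
    maxima = np.array([_max_cluster_mass(t[i], t_crit) for i in range(n_iterations)])
    return PermutationNull(scheme, scope, n_iterations, maxima, seed)


def cluster_pvalue(cluster: Cluster, null: PermutationNull, criterion: float = 0.025) -> ClusterSignificance:
    """Add-one permutation p; significant iff p < criterion (strict)."""
    exceed = int((null.max_abs_summed_t >= abs(cluster.summed_t)).sum())
    p = (1 + exceed) / (1 + null.n_iterations)
    return ClusterSignificance(cluster, p, p < criterion)


# ---------------------------------------------------------------------------
# full analysis


def _observed_bin_tests(
    table: pd.DataFrame, scheme: str, scope: tuple, stat: str, alpha_bin: float
) -> list[BinTestResult]:
    if stat == "mixed":
        work = zero_reference(table) if scheme != "condition-swap" else table
        contrast = "condition" if scheme == "condition-swap" else "zero"
        return [
            per_bin_test(work, b, contrast=contrast, stat="mixed", scope=scope)
            for b in np.sort(table["bin"].unique())
        ]
    # fast path: identical statistic to the permutation engine
    if scheme == "condition-swap":
        stacked = _stack(table, "occupation_stereotype", "female")
        t, df = _contrast_t(stacked.values, stacked.labels)
        contrast = "condition"
    else:
        stacked = _stack(table, None, None)
        t, df = _zero_t(stacked.values)
        contrast = "zero"
    p = np.where(t != 0, 2.0 * sps.t.sf(np.abs(t), df=df), 1.0)
    return [
        BinTestResult(int(b), float(t[i]), float(p[i]), contrast, scope)
        for i, b in enumerate(stacked.bins)
    ]


def cluster_analysis(
    logratio: pd.DataFrame,
    schemes: tuple[str, ...] = SCHEMES,
    n_iterations: int = 2000,
    seed: int = 0,
    alpha_bin: float = 0.05,
    criterion: float = 0.025,
    min_length: int = 1,
    stat: str = "paired",
    contrast_factor: str = "occupation",
    bin_ms: int = 100,
    window_start: int = -2000,
) -> dict:
    """Run the full two-stage analysis over every scheme and scope.

    The condition contrast compares the two levels of ``contrast_factor``
    ("occupation": female- vs male-stereotypical occupations within each
    action condition; "action": female- vs male-stereotypical actions within
    each occupation condition). The vs-zero schemes test the log-ratio
    against no-preference within each occupation x action cell.

    Returns ``{"clusters": DataFrame, "nulls": {key: PermutationNull},
    "bin_tests": {key: [BinTestResult]}}``; cluster rows carry start/end in
    both bin indices and ms relative to noun onset.
    """
    if contrast_factor == "occupation":
        scope_col, label_col = "action_stereotype", "occupation_stereotype"
    elif contrast_factor == "action":
        scope_col, label_col = "occupation_stereotype", "action_stereotype"
    else:
        raise ValueError("contrast_factor must be 'occupation' or 'action'")

    ss = np.random.SeedSequence(seed)
    rows = []
    nulls: dict = {}
    bin_tests: dict = {}
    scope_levels = sorted(logratio[scope_col].unique())
    jobs = []
    for scope_level in scope_levels:
        scoped = logratio[logratio[scope_col] == scope_level]
        if "condition-swap" in schemes and scoped[label_col].nunique() == 2:
            jobs.append(("condition-swap", (scope_col, scope_level), scoped))
        for scheme, occ in (("female-vs-zero", "female"), ("male-vs-zero", "male")):
            if scheme in schemes:
                cell = scoped[scoped["occupation_stereotype"] == occ]
                if len(cell):
                    jobs.append((scheme, (scope_col, scope_level, "occupation", occ), cell))

    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(jobs))]
    for (scheme, scope, sub), child in zip(jobs, child_seeds):
        tests = _observed_bin_tests(sub, scheme, scope, stat, alpha_bin)
        clusters = find_clusters(tests, alpha=alpha_bin, min_length=min_length)
        null = permutation_null(
            sub, scheme, n_iterations=n_iterations, seed=child, alpha_bin=alpha_bin, scope=scope
        )
        key = (scheme, *scope)
        nulls[key] = null
        bin_tests[key] = tests
        for cl in clusters:
            sig = cluster_pvalue(cl, null, criterion=criterion)
            rows.append(
                {
                    "scheme": scheme,
                    "scope": "/".join(str(s) for s in scope),
                    "start_bin": cl.start_bin,
                    "end_bin": cl.end_bin,
                    "start_ms": window_start + bin_ms * cl.start_bin,
                    "end_ms": window_start + bin_ms * (cl.end_bin + 1),
                    "summed_t": cl.summed_t,
                    "n_bins": cl.length,
                    "p": sig.p,
                    "significant": sig.significant,
                    "n_iterations": n_iterations,
                    "seed": child,
                }
            )
    columns = [
        "scheme", "scope", "start_bin", "end_bin", "start_ms", "end_ms",
        "summed_t", "n_bins", "p", "significant", "n_iterations", "seed",
    ]
    return {
        "clusters": pd.DataFrame(rows, columns=columns),
        "nulls": nulls,
        "bin_tests": bin_tests,
    }
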