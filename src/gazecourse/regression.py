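"""Cluster-level OLS of anticipatory gaze preference on attitude scores.

For every pre-noun significant cluster, each participant's log-ratio is
averaged over the cluster's bins and the trials of the cluster's own
occupation x action cell. Clusters expressing a male-character preference
(negative aggregate) are sign-flipped so all clusters are on a common
"stereotype-consistent preference" scale. The model regresses these
aggregates on the three z-standardized attitude scores, a three-level
cluster factor (treatment-coded), and their interactions; refitting with
each cluster as the reference level reads out each scale's simple effect
per cluster, leaving fitted values unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterOfInterest:
    """A pre-noun significant cluster entering the attitude regression."""

    cluster_id: str
    occupation_stereotype: str
    action_stereotype: str
    start_bin: int
    end_bin: int  # inclusive
    flip: bool = False


def clusters_of_interest_from_table(clusters: pd.DataFrame, n_prenoun_bins: int = 20) -> list[ClusterOfInterest]:
    """Select pre-noun significant vs-zero clusters from a cluster table.

    A cluster is pre-noun when it starts before the noun-onset bin. The flip
    flag marks clusters with negative summed t (male-character preference).
    """
    out = []
    sig = clusters[(clusters["significant"]) & (clusters["start_bin"] < n_prenoun_bins)]
    sig = sig[sig["scheme"].isin(["female-vs-zero", "male-vs-zero"])]
    for _, row in sig.iterrows():
        parts = row["scope"].split("/")
        action = parts[1]
        occ = parts[3]
        out.append(
            ClusterOfInterest(
                cluster_id=f"{occ}-occ/{action}-act",
                occupation_stereotype=occ,
                action_stereotype=action,
                start_bin=int(row["start_bin"]),
                end_bin=int(min(row["end_bin"], n_prenoun_bins - 1)),
                flip=row["summed_t"] < 0,
            )
        )
    return out


def aggregate_cluster_logratio(
    logratio: pd.DataFrame, clusters: list[ClusterOfInterest]
) -> pd.DataFrame:
    """Mean log-ratio per participant and cluster of interest.

    Only trials of the cluster's own condition cell and bins within the
    cluster extent contribute; flipped clusters store the value multiplied
    by -1 along with the flag.
    """
    rows = []
    for cl in clusters:
        sub = logratio[
            (logratio["occupation_stereotype"] == cl.occupation_stereotype)
            & (logratio["action_stereotype"] == cl.action_stereotype)
            & (logratio["bin"] >= cl.start_bin)
            & (logratio["bin"] <= cl.end_bin)
        ]
        agg = sub.groupby("participant")["log_ratio"].mean()
        missing = set(logratio["participant"].unique()) - set(agg.index)
        if missing:
            logger.warning(
                "cluster %s: no valid trials for participant(s) %s", cl.cluster_id, sorted(missing)
            )
        for pid, val in agg.items():
            rows.append(
                {
                    "participant": pid,
                    "cluster": cl.cluster_id,
                    "value": -val if cl.flip else val,
                    "flipped": cl.flip,
                }
            )
    return pd.DataFrame(rows)


PREDICTORS = ("z_NGRO", "z_ASI_BS", "z_ASI_HS")


def fit_attitude_model(
    aggregates: pd.DataFrame,
    scale_scores: pd.DataFrame,
    reference_cluster: str,
    predictors: tuple[str, ...] = PREDICTORS,
):
    """OLS of cluster aggregates on attitude scores x cluster factor.

    ``scale_scores`` carries one row per participant with the z-standardized
    predictor columns. Treatment coding puts ``reference_cluster`` at the
    intercept; the full interaction structure is included, so each scale's
    main-effect row reads as its slope within the reference cluster.
    Raises on rank deficiency, naming the aliased terms.
    """
    data = aggregates.merge(scale_scores, on="participant", how="inner")
    lost = len(aggregates) - len(data)
    if lost:
        logger.warning("dropping %d aggregate row(s) without scale scores", lost)
    if data["cluster"].nunique() < 2:
        raise ValueError("need at least two clusters to fit the cluster factor")
    terms = " + ".join(predictors)
    formula = (
        f"value ~ ({terms}) * C(cluster, Treatment(reference='{reference_cluster}'))"
    )
    fit = smf.ols(formula, data=data).fit()
    exog = fit.model.exog
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        # name the columns whose removal restores full rank
        aliased = []
        for j, name in enumerate(fit.model.exog_names):
            reduced = np.delete(exog, j, axis=1)
            if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(exog):
                aliased.append(name)
        raise ValueError(f"design matrix is rank deficient; aliased terms: {aliased}")
    table = pd.DataFrame(
        {
            "term": fit.params.index,
            "estimate": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
    return table, fit


def fit_rotated_models(
    aggregates: pd.DataFrame,
    scale_scores: pd.DataFrame,
    predictors: tuple[str, ...] = PREDICTORS,
) -> dict[str, pd.DataFrame]:
    """One model per reference cluster; identical fit, rotated coefficients."""
    out = {}
    fitted_ref = None
    for ref in sorted(aggregates["cluster"].unique()):
        table, fit = fit_attitude_model(aggregates, scale_scores, ref, predictors)
        out[ref] = table
        if fitted_ref is None:
            fitted_ref = fit.fittedvalues
        else:
            assert np.allclose(fitted_ref, fit.fittedvalues, atol=1e-10)
    return out


# ---------------------------------------------------------------------------
# synthetic data for calibrating the regression


def simulate_attitude_dataset(
    n_participants: int,
    cluster_ids: tuple[str, ...] = ("A", "B", "C"),
    intercepts: dict[str, float] | None = None,
    slopes: dict[str, float] | None = None,
    noise_sd: float = 0.15,
    seed: int = 0,
    predictors: tuple[str, ...] = PREDICTORS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (aggregates, scale_scores) with known slopes.

    Scale scores are independent normals, z-standardized; each aggregate is
    the cluster intercept plus the injected per-SD slopes times the z scores
    plus Gaussian noise. Defaults mirror the study: 3 clusters, aggregate
    means near 0.07, residual spread near the Table-scale SEs.
    """
    from .scales import zscore

    rng = np.random.default_rng(seed)
    intercepts = intercepts or {c: 0.07 for c in cluster_ids}
    slopes = slopes or {p: 0.0 for p in predictors}
    scores = pd.DataFrame({"participant": np.arange(1, n_participants + 1)})
    for p in predictors:
        scores[p] = zscore(rng.normal(size=n_participants))
    rows = []
    for c in cluster_ids:
        mu = intercepts[c] + sum(slopes.get(p, 0.0) * scores[p] for p in predictors)
        vals = mu + rng.normal(0.0, noise_sd, n_participants)
        for pid, v in zip(scores["participant"], vals):
            rows.append({"participant": pid, "cluster": c, "value": v, "flipped": False})
    return pd.DataFrame(rows), scores
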