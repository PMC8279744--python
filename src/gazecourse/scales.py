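"""Likert-scale scoring, reliability, and standardization.

Implements mean scoring (with optional reverse-keyed items), Cronbach's
alpha as the internal-consistency estimate, and z-standardization of the
per-participant scale scores used as regression predictors. The three
instruments of the study — NGRO (29 items, 1-7) and the two 11-item ASI
subscales (0-5) — ship as default definitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScaleDefinition:
    name: str
    item_ids: tuple[str, ...]
    minimum: int
    maximum: int
    reverse_coded: tuple[str, ...] = ()
    min_coverage: float = 0.8  # fraction of items a participant must answer

    def __post_init__(self) -> None:
        if self.minimum >= self.maximum:
            raise ValueError("scale minimum must be < maximum")
        unknown = set(self.reverse_coded) - set(self.item_ids)
        if unknown:
            raise ValueError(f"reverse-coded items not in the scale: {sorted(unknown)}")


def default_scales() -> dict[str, ScaleDefinition]:
    """The study's instruments; the published instruments' reverse keying is
    external to this pipeline, so no items are flagged by default
    (configurable per definition)."""
    return {
        "NGRO": ScaleDefinition("NGRO", tuple(f"item_{i}" for i in range(1, 30)), 1, 7),
        "ASI-BS": ScaleDefinition("ASI-BS", tuple(f"item_{i}" for i in range(1, 12)), 0, 5),
        "ASI-HS": ScaleDefinition("ASI-HS", tuple(f"item_{i}" for i in range(1, 12)), 0, 5),
    }


def score_scale(responses: pd.DataFrame, definition: ScaleDefinition) -> pd.DataFrame:
    """Per-participant mean score for one scale.

    ``responses`` is wide (participants x items). Reverse-coded items are
    flipped as min + max - x before averaging. Participants answering fewer
    than ``min_coverage`` of the items are flagged (``complete`` False).
    """
    items = [c for c in definition.item_ids if c in responses.columns]
    missing = set(definition.item_ids) - set(items)
    if missing:
        raise ValueError(f"{definition.name}: response table lacks items {sorted(missing)}")
    mat = responses[items].astype(float).copy()
    bad = (mat < definition.minimum) | (mat > definition.maximum)
    if bad.any().any():
        rows = mat.index[bad.any(axis=1)].tolist()
        raise ValueError(
            f"{definition.name}: out-of-bounds responses for participant(s) {rows}"
        )
    for item in definition.reverse_coded:
        mat[item] = definition.minimum + definition.maximum - mat[item]
    coverage = mat.notna().mean(axis=1)
    flagged = coverage < definition.min_coverage
    if flagged.any():
        logger.warning(
            "%s: %d participant(s) below %.0f%% item coverage",
            definition.name, int(flagged.sum()), 100 * definition.min_coverage,
        )
    return pd.DataFrame(
        {
            "participant": mat.index,
            "score": mat.mean(axis=1).to_numpy(),
            "n_items_answered": mat.notna().sum(axis=1).to_numpy(),
            "complete": (~flagged).to_numpy(),
        }
    ).reset_index(drop=True)


def cronbach_alpha(item_matrix: pd.DataFrame) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum item variances / variance of sum),
    with n-1 sample variances."""
    mat = np.asarray(item_matrix, dtype=float)
    n, k = mat.shape
    if k < 2:
        raise ValueError("alpha needs at least two items")
    if n < 3:
        raise ValueError("alpha needs at least three respondents")
    item_vars = mat.var(axis=0, ddof=1)
    total_var = mat.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance; alpha is undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, SD 1 (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("z-standardization needs at least two values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("z-standardization is undefined for constant input")
    return (x - x.mean()) / sd


@dataclass
class ScoredBattery:
    """Scored questionnaire battery: per-participant means, z scores, alphas."""

    scores: pd.DataFrame  # participant, one column per scale (mean) and z_<scale>
    alphas: dict[str, float] = field(default_factory=dict)


def score_battery(
    batteries: dict[str, pd.DataFrame],
    definitions: dict[str, ScaleDefinition] | None = None,
) -> ScoredBattery:
    """Score several scales and z-standardize each across participants."""
    definitions = definitions or default_scales()
    merged: pd.DataFrame | None = None
    alphas: dict[str, float] = {}
    for name, responses in batteries.items():
        definition = definitions[name]
        scored = score_scale(responses, definition)
        alphas[name] = cronbach_alpha(responses[list(definition.item_ids)])
        col = scored[["participant", "score"]].rename(columns={"score": name})
        merged = col if merged is None else merged.merge(col, on="participant")
    assert merged is not None
    for name in batteries:
        merged[f"z_{name}"] = zscore(merged[name])
    return ScoredBattery(scores=merged, alphas=alphas)
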