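"""End-to-end pipeline: design -> simulate/ingest -> bin -> time courses ->
cluster inference -> attitude regression, reproducible under fixed seeds.

Every stage writes its tabular output as TSV under the run directory and the
consolidated report as JSON. The report echoes the merged configuration and
all seeds, so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .design import build_item_set, latin_square_lists, lists_to_frame
from .fixio import bin_experiment, read_fixation_report
from .timecourse import accuracy_summary, add_log_ratio, condition_timecourse, score_accuracy
from .clusters import cluster_analysis
from .scales import score_battery
from .simulate import (
    GeneratorParams,
    null_profiles,
    simulate_experiment,
    simulate_scale_battery,
)
from .regression import (
    aggregate_cluster_logratio,
    clusters_of_interest_from_table,
    fit_rotated_models,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "run"
    # analysis window and thresholds
    window: tuple[int, int] = (-2000, 1000)
    bin_ms: int = 100
    alpha_bin: float = 0.05
    criterion: float = 0.025
    n_iterations: int = 2000
    contrast_factor: str = "occupation"
    stat: str = "paired"
    # design
    n_occupations: int = 14
    displays_per_occupation: int = 3
    n_fillers: int = 28
    # generation
    n_participants: int = 51
    null_profile: bool = False
    generator_overrides: dict = field(default_factory=dict)
    # seeds
    simulation_seed: int = 1
    permutation_seed: int = 2
    scales_seed: int = 3
    # optional ingestion instead of simulation
    fixations_path: str | None = None
    meta_path: str | None = None
    filler_path: str | None = None


def validate_config(raw: dict | RunConfig | None) -> tuple[RunConfig, list[str]]:
    """Fill defaults, check invariants; returns the config and *all* problems."""
    if raw is None:
        raw = {}
    if isinstance(raw, RunConfig):
        cfg = raw
    else:
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(raw) - known
        cfg = RunConfig(**{k: v for k, v in raw.items() if k in known})
        errors = [f"unknown config key: {k}" for k in sorted(unknown)]
        if isinstance(cfg.window, list):
            cfg.window = tuple(cfg.window)
        cfg_errors = _check(cfg)
        return cfg, errors + cfg_errors
    return cfg, _check(cfg)


def _check(cfg: RunConfig) -> list[str]:
    errors = []
    w0, w1 = cfg.window
    if w1 <= w0:
        errors.append("window must be increasing")
    if cfg.bin_ms <= 0:
        errors.append("bin_ms must be positive")
    elif w0 % cfg.bin_ms or w1 % cfg.bin_ms:
        errors.append(f"window bounds {cfg.window} must be multiples of bin_ms {cfg.bin_ms}")
    for name in ("alpha_bin", "criterion"):
        v = getattr(cfg, name)
        if not 0.0 < v < 1.0:
            errors.append(f"{name} must lie in (0, 1)")
    if cfg.n_iterations < 1:
        errors.append("n_iterations must be >= 1")
    if cfg.n_participants < 1:
        errors.append("n_participants must be >= 1")
    if cfg.contrast_factor not in ("occupation", "action"):
        errors.append("contrast_factor must be 'occupation' or 'action'")
    if cfg.stat not in ("paired", "mixed"):
        errors.append("stat must be 'paired' or 'mixed'")
    return errors


def _generator_params(cfg: RunConfig) -> GeneratorParams:
    params = GeneratorParams(n_participants=cfg.n_participants)
    if cfg.null_profile:
        params.profiles = null_profiles()
    for key, value in cfg.generator_overrides.items():
        if not hasattr(params, key):
            raise ValueError(f"unknown generator parameter {key!r}")
        setattr(params, key, value)
    return params


def run_pipeline(config: dict | RunConfig | None = None) -> dict:
    """Execute all stages; returns the consolidated run report (also written
    to ``<out_dir>/report.json``). Raises on the first stage failure, after
    writing a FAILED marker naming the stage."""
    cfg, errors = validate_config(config)
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": dataclasses.asdict(cfg),
        "version": __version__,
        "stages": {},
    }
    stage = "design"
    try:
        item_set = build_item_set(cfg.n_occupations, cfg.displays_per_occupation, cfg.n_fillers)
        lists = latin_square_lists(item_set)
        lists_to_frame(lists).to_csv(out / "lists.tsv", sep="\t", index=False)
        report["stages"]["design"] = {
            "n_items": item_set.n_items,
            "n_fillers": item_set.n_fillers,
            "n_lists": len(lists),
        }

        stage = "data"
        if cfg.fixations_path:
            fixations = read_fixation_report(cfg.fixations_path)
            meta = pd.read_csv(cfg.meta_path, sep="\t")
            fillers = pd.read_csv(cfg.filler_path, sep="\t") if cfg.filler_path else None
        else:
            params = _generator_params(cfg)
            data = simulate_experiment(item_set, lists, params, cfg.simulation_seed)
            fixations, meta, fillers = data["fixations"], data["meta"], data["filler_responses"]
            fixations.to_csv(out / "fixations.tsv", sep="\t", index=False)
            meta.to_csv(out / "meta.tsv", sep="\t", index=False)
            fillers.to_csv(out / "filler_responses.tsv", sep="\t", index=False)
        report["stages"]["data"] = {
            "n_fixations": len(fixations),
            "n_trials": len(meta),
            "n_participants": int(meta["participant"].nunique()),
        }

        stage = "binning"
        bins = bin_experiment(fixations, meta, window=cfg.window, bin_ms=cfg.bin_ms)
        logratio = add_log_ratio(bins, bin_ms=cfg.bin_ms)
        logratio.to_csv(out / "bin_series.tsv", sep="\t", index=False)
        n_bins = (cfg.window[1] - cfg.window[0]) // cfg.bin_ms
        report["stages"]["binning"] = {"n_rows": len(bins), "n_bins": n_bins}

        stage = "timecourse"
        summary = condition_timecourse(logratio, value_cols=["p_female", "p_male", "log_ratio"])
        summary.to_csv(out / "timecourse.tsv", sep="\t", index=False)
        report["stages"]["timecourse"] = {"n_rows": len(summary)}

        stage = "accuracy"
        if fillers is not None and len(fillers):
            acc = score_accuracy(fillers)
            acc.to_csv(out / "accuracy.tsv", sep="\t", index=False)
            report["stages"]["accuracy"] = accuracy_summary(acc)

        stage = "clusters"
        result = cluster_analysis(
            logratio,
            n_iterations=cfg.n_iterations,
            seed=cfg.permutation_seed,
            alpha_bin=cfg.alpha_bin,
            criterion=cfg.criterion,
            stat=cfg.stat,
            contrast_factor=cfg.contrast_factor,
            bin_ms=cfg.bin_ms,
            window_start=cfg.window[0],
        )
        clusters = result["clusters"]
        clusters.to_csv(out / "clusters.tsv", sep="\t", index=False)
        report["stages"]["clusters"] = {
            "n_clusters": len(clusters),
            "n_significant": int(clusters["significant"].sum()) if len(clusters) else 0,
            "table": clusters.to_dict(orient="records"),
        }

        stage = "scales"
        battery = simulate_scale_battery(cfg.n_participants, cfg.scales_seed)
        scored = score_battery(battery)
        scores = scored.scores.rename(
            columns={"z_NGRO": "z_NGRO", "z_ASI-BS": "z_ASI_BS", "z_ASI-HS": "z_ASI_HS"}
        )
        scores.to_csv(out / "scale_scores.tsv", sep="\t", index=False)
        report["stages"]["scales"] = {"alphas": scored.alphas}

        stage = "attitude_regression"
        n_prenoun = -cfg.window[0] // cfg.bin_ms
        cois = clusters_of_interest_from_table(clusters, n_prenoun_bins=n_prenoun)
        if len(cois) >= 2:
            aggregates = aggregate_cluster_logratio(logratio, cois)
            models = fit_rotated_models(aggregates, scores)
            for ref, table in models.items():
                table.to_csv(out / f"attitude_model_ref_{ref.replace('/', '_')}.tsv", sep="\t", index=False)
            report["stages"]["attitude_regression"] = {
                "clusters_of_interest": [c.cluster_id for c in cois],
                "models": {ref: t.to_dict(orient="records") for ref, t in models.items()},
            }
        else:
            logger.info("fewer than two pre-noun significant clusters; regression skipped")
            report["stages"]["attitude_regression"] = {
                "clusters_of_interest": [c.cluster_id for c in cois],
                "models": {},
            }
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\n{exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, default=_json_default))
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
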