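"""End-to-end pipeline: simulate a cohort, extract features, score recall,
run the statistical analyses, and write every stage's output.

Stages are pure functions of (config, seed); rerunning with the same config
and seed reproduces every file byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as wio
from .config import PipelineConfig
from .cohort import simulate_cohort
from .features import blocks_table, features_table, predictive_proportion_final_blocks
from .recall import score_cohort
from .sequences import load_stimulus_table, stimulus_sequences
from .stats import (
    awareness_correlations,
    excess_score_test,
    fit_learning_model,
    learning_table,
    low_awareness_subset,
    mediation_residuals,
    proportion_histogram,
    recall_regressions,
    uniformity_chisq,
)

log = logging.getLogger("wagertrack")


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run every stage on the shipped stimulus set; returns the results bundle."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: seed=%d config=%s", config.seed, config.config_hash())

    table = load_stimulus_table()
    seqs = stimulus_sequences()
    cohort = simulate_cohort(
        seqs, n_per_sequence=config.n_per_sequence, params=config.agent,
        layout=config.layout, seed=config.seed, sequence_ids=list(table["id"]),
    )
    wio.write_cohort(cohort, out)
    log.info("simulated %d participants", len(cohort))

    fkw = dict(layout=config.layout, metric=config.distance_metric,
               predictive_threshold=config.predictive_threshold_px,
               correct_threshold=config.correct_threshold_px)
    features = features_table(cohort, **fkw)
    blocks = blocks_table(cohort, **fkw)
    features.to_csv(out / "features.csv", index=False)
    blocks.to_csv(out / "blocks.csv", index=False)

    scores = score_cohort(cohort, blocks, method=config.match_method)
    scores.to_csv(out / "recall_scores.csv", index=False)

    results = analyze(features, blocks, scores, config)
    with open(out / "analysis.json", "w") as fh:
        json.dump(results, fh, indent=2, default=_jsonable)
    _write_report(results, out / "report.txt", config)
    log.info("pipeline done: %s", out)
    return results


def analyze(features: pd.DataFrame, blocks: pd.DataFrame, scores: pd.DataFrame,
            config: PipelineConfig) -> dict:
    """The statistical stage alone, on already-extracted tables."""
    learning = learning_table(features, scores)
    results: dict = {"config_hash": config.config_hash(), "seed": config.seed}

    for resp in ("rt_ms", "dist_to_next", "dist_from_prev"):
        fit = fit_learning_model(learning, response=resp)
        results[f"learning_model_{resp}"] = {
            "coef": fit.terms, "F": fit.f_stats, "n_obs": fit.n_obs,
            "backend": fit.backend, "flags": fit.flags,
        }

    chis = {}
    for b, grp in blocks.groupby("block"):
        hist = proportion_histogram(grp["prop_predictive"])
        stat, dof, p = uniformity_chisq(hist)
        chis[int(b)] = {"chi2": stat, "df": dof, "p": p, "hist": hist.tolist()}
    results["block_uniformity_chisq"] = chis

    results["excess_tests"] = {
        int(b): excess_score_test(grp["excess_score"])
        for b, grp in blocks.groupby("block")
    }

    results["recall"] = recall_regressions(scores)
    results["awareness"] = awareness_correlations(scores)
    ok = scores[~scores["flagged"]].dropna(subset=["pred_prop_final"])
    results["mediation"] = mediation_residuals(
        ok["training_G"], ok["pred_prop_final"], ok["awareness"]
    )
    try:
        low = low_awareness_subset(learning, scores, cutoff=config.awareness_cutoff)
        results["low_awareness_model"] = {
            "coef": low.terms, "F": low.f_stats, "n_obs": low.n_obs,
            "backend": low.backend, "flags": low.flags,
            "n_subjects": int(scores["awareness"].lt(config.awareness_cutoff).sum()),
        }
    except ValueError as err:
        results["low_awareness_model"] = {"error": str(err)}
    return results


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _write_report(results: dict, path: Path, config: PipelineConfig) -> None:
    lines = [
        "wagertrack analysis report",
        f"seed={config.seed} config={results['config_hash']}",
        "",
    ]
    rt = results["learning_model_rt_ms"]["coef"]
    lines.append(
        f"RT model: G coef {rt.get('G', float('nan')):.2f} ms/unit-G, "
        f"trial coef {rt.get('trial', float('nan')):.3f} ms/trial, "
        f"interaction {rt.get('G:trial', float('nan')):.3f}"
    )
    final_block = max(results["block_uniformity_chisq"])
    chi = results["block_uniformity_chisq"][final_block]
    lines.append(
        f"final-block predictive-proportion chi2(6) = {chi['chi2']:.1f}, p = {chi['p']:.2g}"
    )
    med = results["mediation"]
    lines.append(
        "mediation: r(pred | G removed) = "
        f"{med['r_pred_given_G']:.3f}, r(G | pred removed) = {med['r_G_given_pred']:.3f}"
    )
    path.write_text("\n".join(lines) + "\n")
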