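"""End-to-end runs: simulate the grid, analyze LT series, report tables.

Each stage is rerunnable from the previous stage's on-disk output, and a
JSON manifest records the configuration, base seed and written artifacts
so that a manifest plus the code version determines every output byte
(manifest timestamps excepted).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .evaluation import EvaluationConfig, _eval_id, run_treatment_grid
from .reporting import aggregate_treatments, summaries_to_frame
from .segmentation import summarize_evaluation, summarize_histories
from .evaluation import load_lt_history

logger = logging.getLogger("leadsim")

__all__ = ["run_pipeline", "simulate_stage", "analyze_stage", "report_stage"]


def _evaluation_config(config: RunConfig) -> EvaluationConfig:
    return EvaluationConfig(
        group_size=config.group_sizes[0],
        initial_lt=config.initial_lts[0],
        attempts_multiplier=config.attempts_multiplier,
        replicate_count=config.replicate_count,
        seed=config.seed,
        model=config.model,
        adapt=config.adapt,
    )


def simulate_stage(config: RunConfig, out_dir: Path):
    """Run the full treatment grid, writing per-cell attempt and LT logs."""
    out_dir.mkdir(parents=True, exist_ok=True)

    def progress(n, lt0, count):
        logger.info("cell N=%d initial_lt=%g done (%d evaluations)", n, lt0, count)

    results = run_treatment_grid(
        config.group_sizes,
        config.initial_lts,
        _evaluation_config(config),
        out_dir=out_dir,
        progress=progress,
    )
    return results


def analyze_stage(config: RunConfig, out_dir: Path, results=None) -> pd.DataFrame:
    """Changepoint analysis per evaluation; writes differentiation_summary.csv.

    With ``results`` given, analyzes in memory; otherwise re-reads the
    LT-history CSVs written by the simulate stage.
    """
    rows = []
    if results is not None:
        for res in results:
            s = summarize_evaluation(res, config.analysis, evaluation_id=_eval_id(res))
            rows.append(_summary_row(s, res.config.group_size, res.config.initial_lt))
    else:
        for cfg_path in sorted(out_dir.glob("*_config.json")):
            stem = cfg_path.name[: -len("_config.json")]
            cell_cfg = json.loads(cfg_path.read_text())
            hists = load_lt_history(out_dir / f"{stem}_lt_history.csv", cfg_path)
            for eid, agent_hists in hists.items():
                s = summarize_histories(
                    agent_hists,
                    cell_cfg["attempts_multiplier"] * cell_cfg["group_size"],
                    config.analysis,
                    evaluation_id=eid,
                )
                rows.append(_summary_row(s, cell_cfg["group_size"], cell_cfg["initial_lt"]))
    frame = pd.DataFrame(rows)
    frame.to_csv(out_dir / "differentiation_summary.csv", index=False)
    return frame


def _summary_row(s, group_size: int, initial_lt: float) -> dict:
    return {
        "evaluation_id": s.evaluation_id,
        "group_size": group_size,
        "initial_lt": initial_lt,
        "differentiation_attempt": s.differentiation_attempt,
        "differentiation_fraction": s.differentiation_fraction,
        "low_to_high": s.low_to_high_count,
        "high_to_low": s.high_to_low_count,
        "final_high_count": s.final_high_count,
    }


def report_stage(config: RunConfig, out_dir: Path, results=None):
    """Aggregate per-evaluation metrics into treatment summary and comparison tables.

    With ``results`` given, works in memory; otherwise rebuilds the
    per-evaluation metric table from the on-disk attempt logs and the
    analyze stage's differentiation_summary.csv.
    """
    if results is not None:
        per_eval = summaries_to_frame(results, config.analysis)
    else:
        per_eval = _per_eval_from_disk(out_dir)
    summary, comparisons = aggregate_treatments(per_eval)
    per_eval.to_csv(out_dir / "per_evaluation_metrics.csv", index=False)
    summary.to_csv(out_dir / "treatment_summary.csv", index=False)
    comparisons.to_csv(out_dir / "treatment_comparisons.csv", index=False)
    return summary, comparisons


def _per_eval_from_disk(out_dir: Path) -> pd.DataFrame:
    """Per-evaluation metric table from attempt logs + differentiation summary."""
    diff = pd.read_csv(out_dir / "differentiation_summary.csv")
    rows = []
    for cfg_path in sorted(out_dir.glob("*_config.json")):
        stem = cfg_path.name[: -len("_config.json")]
        cell_cfg = json.loads(cfg_path.read_text())
        attempts = pd.read_csv(out_dir / f"{stem}_attempts.csv")
        for eid, sub in attempts.groupby("evaluation_id", sort=True):
            rows.append(
                {
                    "evaluation_id": eid,
                    "group_size": cell_cfg["group_size"],
                    "initial_lt": cell_cfg["initial_lt"],
                    "replicate": int(str(eid).rsplit("rep", 1)[1]),
                    "adaptive": cell_cfg["adaptive"],
                    "success_pct": 100.0 * sub["success"].mean(),
                }
            )
    frame = pd.DataFrame(rows)
    diff = diff.drop(columns=["group_size", "initial_lt"], errors="ignore")
    frame = frame.merge(diff, on="evaluation_id", how="left")
    n = frame["group_size"]
    frame["differentiation_pct"] = 100.0 * frame["differentiation_fraction"]
    frame["low_to_high_pct"] = 100.0 * frame["low_to_high"] / n
    frame["high_lt_pct"] = 100.0 * frame["final_high_count"] / n
    return frame


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> analyze -> report; returns the run manifest (also written)."""
    out_dir = Path(config.out_dir)
    t0 = time.time()
    results = simulate_stage(config, out_dir)
    analyze_stage(config, out_dir, results=results)
    report_stage(config, out_dir, results=results)
    manifest = {
        "config": {
            "group_sizes": list(config.group_sizes),
            "initial_lts": list(config.initial_lts),
            "attempts_multiplier": config.attempts_multiplier,
            "replicate_count": config.replicate_count,
            "seed": config.seed,
            "model": asdict(config.model),
            "adapt": asdict(config.adapt),
            "analysis": asdict(config.analysis),
        },
        "outputs": sorted(p.name for p in out_dir.glob("*.csv")),
        "elapsed_seconds": round(time.time() - t0, 3),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
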