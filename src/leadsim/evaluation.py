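"""Evaluations: long sequences of attempts with persistent LT values.

An *evaluation* runs ``attempts_multiplier * N`` attempts in sequence with
LT values carried over from one attempt to the next, so experience
accumulates; LTs reset at the start of each evaluation.  A *treatment* is
a (group size, initial LT) cell; each is run with `replicate_count`
replicates whose RNG seeds derive from (base seed, replicate index) only,
never from the treatment, so replicate r of every cell shares identical
random streams ("matched seeds").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import simulate_attempt
from .model import AdaptationParameters, ModelParameters, k_factor

__all__ = [
    "EvaluationConfig",
    "LTHistory",
    "EvaluationResult",
    "rng_for_replicate",
    "run_evaluation",
    "run_treatment_grid",
    "attempts_to_csv",
    "lt_history_to_csv",
    "load_lt_history",
]


def rng_for_replicate(base_seed: int, replicate_index: int) -> np.random.Generator:
    """Deterministic generator for one replicate, treatment-independent.

    Uses a SeedSequence spawn key so streams for different replicates are
    statistically independent while replicate i is bit-identical across
    treatment cells.
    """
    return np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=(replicate_index,)))


@dataclass(frozen=True)
class EvaluationConfig:
    """Full description of one treatment cell's evaluations."""

    group_size: int = 10
    initial_lt: float = 0.5
    attempts_multiplier: int = 2000
    replicate_count: int = 50
    seed: int = 0
    model: ModelParameters = field(default_factory=ModelParameters)
    adapt: AdaptationParameters = field(default_factory=AdaptationParameters)

    def __post_init__(self) -> None:
        if self.group_size < 2:
            raise ValueError(f"group_size must be >= 2, got {self.group_size}")
        if self.attempts_multiplier < 1:
            raise ValueError(f"attempts_multiplier must be >= 1, got {self.attempts_multiplier}")
        if self.replicate_count < 1:
            raise ValueError(f"replicate_count must be >= 1, got {self.replicate_count}")
        if not self.adapt.lt_min <= self.initial_lt <= self.adapt.lt_max:
            raise ValueError(
                f"initial_lt {self.initial_lt} outside [{self.adapt.lt_min}, {self.adapt.lt_max}]"
            )

    @property
    def n_attempts(self) -> int:
        return self.attempts_multiplier * self.group_size


@dataclass
class LTHistory:
    """Sparse LT history of one agent: change records within an evaluation.

    ``attempts[k]`` is the attempt index at which the agent initiated and
    its LT was updated to ``values[k]``; the new value takes effect from
    attempt ``attempts[k] + 1``.  The dense per-attempt series (the value
    in force *during* each attempt) is reconstructed by piecewise-constant
    carry-forward from ``initial_lt``.
    """

    agent_id: int
    initial_lt: float
    n_attempts: int
    attempts: np.ndarray  # int indices, strictly increasing
    values: np.ndarray  # LT value after each recorded update

    def dense(self) -> np.ndarray:
        """Dense series of length ``n_attempts``; entry t is the LT used in attempt t."""
        starts = np.concatenate(([0], np.asarray(self.attempts) + 1, [self.n_attempts]))
        vals = np.concatenate(([self.initial_lt], np.asarray(self.values)))
        lengths = np.diff(starts)
        keep = lengths > 0  # a final-attempt update has no attempt left to act in
        return np.repeat(vals[: keep.size][keep], lengths[keep])


@dataclass
class EvaluationResult:
    """Raw per-attempt records and LT histories for one evaluation."""

    config: EvaluationConfig
    replicate_index: int
    initiator_ids: np.ndarray
    successes: np.ndarray
    final_departed: np.ndarray
    lt_histories: list[LTHistory]
    final_lts: np.ndarray

    @property
    def n_attempts(self) -> int:
        return int(self.initiator_ids.size)

    @property
    def success_count(self) -> int:
        return int(self.successes.sum())


def run_evaluation(config: EvaluationConfig, replicate_index: int = 0) -> EvaluationResult:
    """Run one evaluation: ``attempts_multiplier * N`` sequential attempts.

    All agents start at ``config.initial_lt``; only initiators' LTs
    change, and only when adaptation is on.  The RNG stream depends on
    (seed, replicate_index) alone.
    """
    rng = rng_for_replicate(config.seed, replicate_index)
    n = config.group_size
    total = config.n_attempts
    lts = np.full(n, float(config.initial_lt))
    params, adapt = config.model, config.adapt
    # k vectors maintained incrementally: only the initiator's LT changes.
    k_init = np.asarray(k_factor(lts, params))
    k_follow = np.asarray(k_factor(1.0 - lts, params))

    initiator_ids = np.empty(total, dtype=np.int32)
    successes = np.empty(total, dtype=bool)
    final_departed = np.empty(total, dtype=np.int32)
    change_attempts: list[list[int]] = [[] for _ in range(n)]
    change_values: list[list[float]] = [[] for _ in range(n)]

    for t in range(total):
        res = simulate_attempt(
            lts, params, adapt, rng, collect_log=False, k_init=k_init, k_follow=k_follow
        )
        i = res.initiator_id
        initiator_ids[t] = i
        successes[t] = res.success
        final_departed[t] = res.final_departed
        if adapt.adaptive:
            change_attempts[i].append(t)
            change_values[i].append(res.initiator_lt_after)
            if res.initiator_lt_after != res.initiator_lt_before:
                k_init[i] = k_factor(lts[i], params)
                k_follow[i] = k_factor(1.0 - lts[i], params)

    histories = [
        LTHistory(
            agent_id=i,
            initial_lt=float(config.initial_lt),
            n_attempts=total,
            attempts=np.asarray(change_attempts[i], dtype=np.int64),
            values=np.asarray(change_values[i], dtype=float),
        )
        for i in range(n)
    ]
    return EvaluationResult(
        config=config,
        replicate_index=replicate_index,
        initiator_ids=initiator_ids,
        successes=successes,
        final_departed=final_departed,
        lt_histories=histories,
        final_lts=lts.copy(),
    )


def run_treatment_grid(
    group_sizes,
    initial_lts,
    base_config: EvaluationConfig,
    out_dir: str | Path | None = None,
    progress=None,
) -> list[EvaluationResult]:
    """Run every (group size, initial LT) cell of the grid.

    Replicate r of every cell uses the same seed derivation, honouring
    the matched-seed design.  With ``out_dir`` set, each cell's attempt
    log and LT history are also written as CSV (plus a JSON sidecar).
    """
    group_sizes = list(group_sizes)
    initial_lts = list(initial_lts)
    if not group_sizes or not initial_lts:
        raise ValueError("group_sizes and initial_lts must be non-empty")
    results: list[EvaluationResult] = []
    for n in group_sizes:
        for lt0 in initial_lts:
            config = replace(base_config, group_size=n, initial_lt=lt0)
            cell = [run_evaluation(config, rep) for rep in range(config.replicate_count)]
            results.extend(cell)
            if out_dir is not None:
                write_cell(cell, Path(out_dir))
            if progress is not None:
                progress(n, lt0, len(cell))
    return results


def _eval_id(result: EvaluationResult) -> str:
    lt = f"{result.config.initial_lt:g}".replace(".", "p")
    return f"N{result.config.group_size}_lt{lt}_rep{result.replicate_index}"


def attempts_to_csv(results: list[EvaluationResult], path: str | Path) -> None:
    """Write per-attempt records: evaluation_id, attempt, initiator_id, success, final_departed."""
    frames = []
    for res in results:
        frames.append(
            pd.DataFrame(
                {
                    "evaluation_id": _eval_id(res),
                    "attempt": np.arange(res.n_attempts),
                    "initiator_id": res.initiator_ids,
                    "success": res.successes.astype(int),
                    "final_departed": res.final_departed,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def lt_history_to_csv(results: list[EvaluationResult], path: str | Path) -> None:
    """Write sparse LT change records: evaluation_id, agent_id, attempt, lt_value."""
    rows = []
    for res in results:
        eid = _eval_id(res)
        for h in res.lt_histories:
            rows.append(
                pd.DataFrame(
                    {
                        "evaluation_id": eid,
                        "agent_id": h.agent_id,
                        "attempt": h.attempts,
                        "lt_value": h.values,
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def write_cell(cell: list[EvaluationResult], out_dir: Path) -> None:
    """Write one treatment cell's logs plus a JSON sidecar echoing the config."""
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = cell[0].config
    stem = _eval_id(cell[0]).rsplit("_rep", 1)[0]
    attempts_to_csv(cell, out_dir / f"{stem}_attempts.csv")
    lt_history_to_csv(cell, out_dir / f"{stem}_lt_history.csv")
    sidecar = {
        "group_size": cfg.group_size,
        "initial_lt": cfg.initial_lt,
        "attempts_multiplier": cfg.attempts_multiplier,
        "replicate_count": cfg.replicate_count,
        "seed": cfg.seed,
        "adaptive": cfg.adapt.adaptive,
        "lambda_rate": cfg.adapt.lambda_rate,
        "lt_min": cfg.adapt.lt_min,
        "lt_max": cfg.adapt.lt_max,
        "model": {k: getattr(cfg.model, k) for k in ModelParameters.__dataclass_fields__},
    }
    (out_dir / f"{stem}_config.json").write_text(json.dumps(sidecar, indent=2))


def load_lt_history(
    history_csv: str | Path, config_json: str | Path
) -> dict[str, list[LTHistory]]:
    """Rebuild per-agent LT histories from an on-disk cell (for re-analysis)."""
    cfg = json.loads(Path(config_json).read_text())
    total = cfg["attempts_multiplier"] * cfg["group_size"]
    df = pd.read_csv(history_csv)
    out: dict[str, list[LTHistory]] = {}
    for eid, sub in df.groupby("evaluation_id", sort=True):
        hists = []
        for agent in range(cfg["group_size"]):
            rec = sub[sub["agent_id"] == agent].sort_values("attempt")
            hists.append(
                LTHistory(
                    agent_id=agent,
                    initial_lt=cfg["initial_lt"],
                    n_attempts=total,
                    attempts=rec["attempt"].to_numpy(dtype=np.int64),
                    values=rec["lt_value"].to_numpy(dtype=float),
                )
            )
        out[str(eid)] = hists
    return out
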