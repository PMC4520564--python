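"""Run configuration: a flat, human-readable YAML file with full defaults.

Every model constant, adaptation parameter, analysis knob and experiment
dimension is overridable; an empty file yields the default study
configuration (observed rate constants, lambda = 0.02, LT bounds
[0.1, 0.9], 2000 x N attempts, 50 replicates, initial LTs
{0.2, 0.5, 0.8}).  Unknown keys and out-of-range values raise with the
offending key named.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .model import AdaptationParameters, ModelParameters
from .segmentation import AnalysisParameters

__all__ = ["RunConfig", "load_config"]

DEFAULT_GROUP_SIZES = (10, 15, 20, 30, 40, 50, 60, 70, 80, 90, 100, 110, 120, 130, 140, 150)
DEFAULT_INITIAL_LTS = (0.2, 0.5, 0.8)

_MODEL_KEYS = {f.name for f in fields(ModelParameters)}
_ADAPT_KEYS = {f.name for f in fields(AdaptationParameters)}
_ANALYSIS_KEYS = {f.name for f in fields(AnalysisParameters)}
_RUN_KEYS = {
    "group_sizes",
    "initial_lts",
    "attempts_multiplier",
    "replicate_count",
    "seed",
    "out_dir",
}


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a full experiment grid."""

    group_sizes: tuple[int, ...] = DEFAULT_GROUP_SIZES
    initial_lts: tuple[float, ...] = DEFAULT_INITIAL_LTS
    attempts_multiplier: int = 2000
    replicate_count: int = 50
    seed: int = 0
    out_dir: str = "leadsim_out"
    model: ModelParameters = field(default_factory=ModelParameters)
    adapt: AdaptationParameters = field(default_factory=AdaptationParameters)
    analysis: AnalysisParameters = field(default_factory=AnalysisParameters)

    def __post_init__(self) -> None:
        if not self.group_sizes or any(n < 2 for n in self.group_sizes):
            raise ValueError(f"group_sizes must be non-empty with every N >= 2: {self.group_sizes}")
        if not self.initial_lts:
            raise ValueError("initial_lts must be non-empty")
        for lt in self.initial_lts:
            if not self.adapt.lt_min <= lt <= self.adapt.lt_max:
                raise ValueError(
                    f"initial_lts entry {lt} outside [{self.adapt.lt_min}, {self.adapt.lt_max}]"
                )
        if self.attempts_multiplier < 1:
            raise ValueError(f"attempts_multiplier must be >= 1, got {self.attempts_multiplier}")
        if self.replicate_count < 1:
            raise ValueError(f"replicate_count must be >= 1, got {self.replicate_count}")


def _build(section: dict, cls, label: str):
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid {label} configuration: {exc}") from exc


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; missing keys take study defaults.

    Keys may be given flat (``lambda_rate: 0.05``) and are routed to the
    model / adaptation / analysis section they belong to, or nested under
    explicit ``model:``, ``adapt:`` and ``analysis:`` mappings.
    ``overrides`` (e.g. from CLI flags) win over file values.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config root must be a mapping, got {type(loaded).__name__}")
        raw.update(loaded)
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})

    model_kw = dict(raw.pop("model", {}) or {})
    adapt_kw = dict(raw.pop("adapt", {}) or {})
    analysis_kw = dict(raw.pop("analysis", {}) or {})
    run_kw: dict = {}
    for key, value in raw.items():
        if key in _RUN_KEYS:
            run_kw[key] = value
        elif key in _MODEL_KEYS:
            model_kw[key] = value
        elif key in _ADAPT_KEYS:
            adapt_kw[key] = value
        elif key in _ANALYSIS_KEYS:
            analysis_kw[key] = value
        else:
            raise ValueError(f"unknown configuration key: {key!r}")
    for section, allowed, label in (
        (model_kw, _MODEL_KEYS, "model"),
        (adapt_kw, _ADAPT_KEYS, "adapt"),
        (analysis_kw, _ANALYSIS_KEYS, "analysis"),
    ):
        bad = set(section) - allowed
        if bad:
            raise ValueError(f"unknown {label} key(s): {sorted(bad)}")

    if "group_sizes" in run_kw:
        run_kw["group_sizes"] = tuple(int(n) for n in run_kw["group_sizes"])
    if "initial_lts" in run_kw:
        run_kw["initial_lts"] = tuple(float(x) for x in run_kw["initial_lts"])
    return RunConfig(
        model=_build(model_kw, ModelParameters, "model"),
        adapt=_build(adapt_kw, AdaptationParameters, "adapt"),
        analysis=_build(analysis_kw, AnalysisParameters, "analysis"),
        **run_kw,
    )
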