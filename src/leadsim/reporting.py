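"""Aggregate statistics across replicates and treatments.

Per-evaluation metrics (success percentage, differentiation fraction,
transition counts, final share of high-LT individuals) are averaged over
replicates with standard errors, and treatment cells are compared with
two-sample Student's t-tests (pooled variance, with a Welch variant for
robustness); pairwise p-values are reported both raw and Holm-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .evaluation import EvaluationResult
from .segmentation import AnalysisParameters, DifferentiationSummary, summarize_evaluation

__all__ = [
    "TTestResult",
    "TreatmentSummary",
    "success_percentage",
    "high_lt_percentage",
    "two_sample_t_test",
    "summaries_to_frame",
    "aggregate_treatments",
]

METRICS = (
    "success_pct",
    "differentiation_pct",
    "low_to_high_pct",
    "high_lt_pct",
)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    welch_t: float
    welch_p: float


@dataclass(frozen=True)
class TreatmentSummary:
    group_size: int
    initial_lt: float
    metric: str
    mean: float
    se: float
    n: int


def success_percentage(result: EvaluationResult) -> float:
    """Percentage of the evaluation's attempts that recruited the whole group."""
    return 100.0 * result.success_count / result.n_attempts


def high_lt_percentage(
    result: EvaluationResult, analysis: AnalysisParameters = AnalysisParameters()
) -> float:
    """Percentage of the group whose final LT segment is classified high."""
    summary = summarize_evaluation(result, analysis)
    return 100.0 * summary.final_high_count / result.config.group_size


def two_sample_t_test(sample_a, sample_b) -> TTestResult:
    """Two-sided two-sample Student's t-test (pooled variance), plus Welch.

    Computed from the textbook formula.  Degenerate zero-variance inputs
    follow the convention p = 1 for equal means (no evidence of a
    difference) and p = 0 otherwise (complete separation).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least 2 observations")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    if sp2 == 0.0:
        p = 1.0 if ma == mb else 0.0
        t = 0.0 if ma == mb else np.copysign(np.inf, ma - mb)
        return TTestResult(t=t, df=float(df), p=p, welch_t=t, welch_p=p)
    t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), df)
    # Welch variant: unequal variances, Satterthwaite degrees of freedom.
    se2 = va / na + vb / nb
    wt = (ma - mb) / np.sqrt(se2)
    wdf = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    wp = 2.0 * stats.t.sf(abs(wt), wdf)
    return TTestResult(t=float(t), df=float(df), p=float(p), welch_t=float(wt), welch_p=float(wp))


def evaluation_metrics(
    result: EvaluationResult,
    summary: DifferentiationSummary | None = None,
    analysis: AnalysisParameters = AnalysisParameters(),
) -> dict[str, float]:
    """All per-evaluation scalar metrics, on the percentage scales of the figures."""
    if summary is None:
        summary = summarize_evaluation(result, analysis)
    n = result.config.group_size
    return {
        "success_pct": success_percentage(result),
        "differentiation_pct": (
            100.0 * summary.differentiation_fraction
            if summary.differentiation_fraction is not None
            else np.nan
        ),
        "low_to_high_pct": 100.0 * summary.low_to_high_count / n,
        "high_lt_pct": 100.0 * summary.final_high_count / n,
    }


def summaries_to_frame(
    results: list[EvaluationResult], analysis: AnalysisParameters = AnalysisParameters()
) -> pd.DataFrame:
    """One row of metrics per evaluation (long format plus cell labels)."""
    rows = []
    for res in results:
        m = evaluation_metrics(res, analysis=analysis)
        m.update(
            group_size=res.config.group_size,
            initial_lt=res.config.initial_lt,
            replicate=res.replicate_index,
            adaptive=res.config.adapt.adaptive,
        )
        rows.append(m)
    return pd.DataFrame(rows)


def aggregate_treatments(per_eval: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean/SE per metric per cell, and pairwise cell comparisons.

    ``per_eval`` is the frame from :func:`summaries_to_frame`; cells are
    (group_size, initial_lt, adaptive) triples.  Comparisons are run per
    metric between every pair of cells sharing a group size (the paper's
    contrasts: between initial-LT treatments and adaptive vs original at
    matched seeds); p-values are reported raw and Holm-corrected within
    each metric.
    """
    keys = ["group_size", "initial_lt", "adaptive"]
    records = []
    for cell, sub in per_eval.groupby(keys):
        for metric in METRICS:
            vals = sub[metric].dropna().to_numpy()
            if vals.size == 0:
                continue
            se = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
            records.append(
                dict(
                    zip(keys, cell),
                    metric=metric,
                    mean=float(vals.mean()),
                    se=float(se),
                    n=int(vals.size),
                )
            )
    summary = pd.DataFrame(records)

    comparisons = []
    cells = list(per_eval.groupby(keys))
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            (ca, sa), (cb, sb) = cells[i], cells[j]
            if ca[0] != cb[0]:  # compare within a group size only
                continue
            for metric in METRICS:
                va = sa[metric].dropna().to_numpy()
                vb = sb[metric].dropna().to_numpy()
                if va.size < 2 or vb.size < 2:
                    continue
                res = two_sample_t_test(va, vb)
                comparisons.append(
                    {
                        "cell_a": f"N{ca[0]}_lt{ca[1]:g}_{'adaptive' if ca[2] else 'fixed'}",
                        "cell_b": f"N{cb[0]}_lt{cb[1]:g}_{'adaptive' if cb[2] else 'fixed'}",
                        "metric": metric,
                        "t": res.t,
                        "df": res.df,
                        "p_raw": res.p,
                        "welch_p": res.welch_p,
                    }
                )
    comp = pd.DataFrame(comparisons)
    if not comp.empty:
        comp["p_holm"] = np.nan
        for metric in comp["metric"].unique():
            mask = comp["metric"] == metric
            comp.loc[mask, "p_holm"] = multipletests(comp.loc[mask, "p_raw"], method="holm")[1]
    return summary, comp
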