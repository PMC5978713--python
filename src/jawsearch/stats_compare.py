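"""Dosimetric endpoint extraction and paired plan-class comparison.

Endpoints follow the RTOG 0822-style reporting convention: V_D is the
relative volume (%) receiving at least D Gy, and the mean dose (Gy) is the
fine-grid MDVP divided by 100.  Best-vs-conformal (or any two plan
classes) comparisons across patients use the classical paired t-test on
per-patient differences; a cohort summary reports min/max/mean +/- sample
SD per organ and metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from jawsearch.dvh_core import DVHError, PlanDose, mean_dose, volume_at_dose
from jawsearch.scoring import OrganScoreTable

__all__ = [
    "DegenerateVarianceError",
    "DEFAULT_METRICS",
    "endpoint_metrics",
    "paired_t",
    "holm_adjust",
    "cohort_summary",
]

DEFAULT_METRICS = ("V35", "V40", "V45", "V50", "mean_dose")


class DegenerateVarianceError(DVHError):
    """All paired differences are identical: the t statistic is undefined."""


def endpoint_metrics(
    plan: PlanDose,
    metrics: tuple[str, ...] = DEFAULT_METRICS,
    structures: list[str] | None = None,
) -> pd.DataFrame:
    """Per-structure endpoint values for one (normalized) plan.

    Metric names: ``"V<D>"`` for the volume (%) at dose D Gy (e.g. V40) and
    ``"mean_dose"`` for the mean dose in Gy.  Returns a tidy frame with
    columns plan_id, structure_id, metric, value.
    """
    sids = structures if structures is not None else list(plan.curves)
    rows = []
    for sid in sids:
        curve = plan.curve(sid)
        for metric in metrics:
            if metric == "mean_dose":
                val = mean_dose(curve)
            elif metric.startswith("V"):
                val = volume_at_dose(curve, float(metric[1:]))
            else:
                raise DVHError(f"unknown endpoint metric {metric!r}")
            rows.append(
                {"plan_id": plan.plan_id, "structure_id": sid, "metric": metric, "value": val}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    df: int
    mean_diff: float


def paired_t(best: np.ndarray, other: np.ndarray) -> PairedTResult:
    """Classical paired t-test on per-patient differences (two-sided).

    Raises :class:`DegenerateVarianceError` when the differences have zero
    sample SD (including the all-zero case): p is then undefined and must
    not be reported as 0 or 1.
    """
    best = np.asarray(best, dtype=float)
    other = np.asarray(other, dtype=float)
    if best.shape != other.shape or best.ndim != 1:
        raise DVHError("paired samples must be equal-length 1-D vectors")
    n = best.size
    if n < 2:
        raise DVHError("paired t-test needs at least 2 pairs")
    diff = best - other
    sd = float(np.std(diff, ddof=1))
    if sd == 0.0:
        raise DegenerateVarianceError("zero variance of paired differences")
    t, p = stats.ttest_rel(best, other)
    return PairedTResult(t=float(t), p=float(p), df=n - 1, mean_diff=float(np.mean(diff)))


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values for a family of endpoints."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvals, dtype=float), method="holm")[1]


def cohort_summary(table: OrganScoreTable, accepted_only: bool = True) -> pd.DataFrame:
    """Min/max/mean/sample-SD of MDVP, HDVP and normalized score per OAR.

    ``accepted_only`` restricts the statistics to hotspot-free plans (the
    usual reporting convention); set False to summarize the whole cohort.
    A singleton selection reports SD 0 with ``degenerate=True``.
    """
    if accepted_only:
        keep = table.per_plan.index[table.per_plan["accepted"]]
    else:
        keep = table.per_plan.index
    if len(keep) == 0:
        raise DVHError("empty selection for cohort summary")
    sel = table.per_organ.loc[list(keep)]
    rows = []
    for sid, grp in sel.groupby("structure_id"):
        for metric in ("mdvp", "hdvp", "normalized_score"):
            vals = grp[metric].to_numpy()
            degenerate = vals.size == 1
            rows.append(
                {
                    "structure_id": sid,
                    "metric": metric,
                    "n": vals.size,
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                    "mean": float(vals.mean()),
                    "sd": 0.0 if degenerate else float(np.std(vals, ddof=1)),
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)
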