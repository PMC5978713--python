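"""Organ-at-risk sparing metrics and cohort-normalized plan scoring.

Two per-structure metrics are computed from the sampled cumulative DVH
(dose samples d_j, cumulative volumes V_j, with the trailing convention
V_{n+1} = 0):

* MDVP (mean dose volume product), ``sum_j d_j (V_j - V_{j+1})`` in Gy*% --
  a Riemann sum of dose times differential volume, i.e. 100x the mean dose
  as the grid refines;
* HDVP (high dose volume product), the same sum restricted to samples with
  ``d_j > d_t`` (strict), where d_t is an organ-specific high-dose
  threshold (35 Gy small bowel, 40 Gy femoral head and bladder under the
  RTOG 0822 constraint set).

Per organ, the weighted combination ``w_m*MDVP + w_h*HDVP`` is divided by
its mean over a normalization cohort, so each organ contributes a
dimensionless score with cohort mean exactly 1; a plan's total score is the
sum over organs.  Lower is better.  Ranking considers accepted
(hotspot-free) plans only, with deterministic lowest-index tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from jawsearch.dvh_core import DVHCurve, DVHError, PlanDose, resample

__all__ = [
    "OARSpec",
    "OrganScoreTable",
    "RankResult",
    "DegenerateNormalizationError",
    "EmptyCohortError",
    "mdvp",
    "hdvp",
    "score_cohort",
    "rank_plans",
]

DEFAULT_BIN_WIDTH_GY = 0.1


class DegenerateNormalizationError(DVHError):
    """An OAR's mean combined metric is zero over the normalization cohort."""


class EmptyCohortError(DVHError):
    """No accepted plans to rank."""


@dataclass(frozen=True)
class OARSpec:
    """Scoring configuration for one organ at risk.

    ``hdvp_threshold`` is the high-dose threshold d_t in Gy; the MDVP/HDVP
    weights default to 1.0 each (equal weighting) and may encode
    institutional trade-offs.
    """

    structure_id: str
    hdvp_threshold: float
    weight_mdvp: float = 1.0
    weight_hdvp: float = 1.0

    def __post_init__(self) -> None:
        if self.hdvp_threshold < 0:
            raise DVHError(f"{self.structure_id}: hdvp_threshold must be >= 0")
        if self.weight_mdvp < 0 or self.weight_hdvp < 0:
            raise DVHError(f"{self.structure_id}: weights must be >= 0")


def mdvp(curve: DVHCurve) -> float:
    """Mean dose volume product, ``sum_j d_j (V_j - V_{j+1})`` in Gy*%.

    The index runs one past the last sample with V_{n+1} = 0, so the final
    term is ``d_n * V_n`` and the sum equals the full Riemann sum of dose
    times differential volume over the curve's support.
    """
    d = curve.dose_gy
    v = curve.volume_pct
    v_next = np.append(v[1:], 0.0)
    return float(np.sum(d * (v - v_next)))


def hdvp(curve: DVHCurve, d_t: float) -> float:
    """High dose volume product: the MDVP sum restricted to ``d_j > d_t``.

    The threshold is strict; ``hdvp(curve, 0) == mdvp(curve)`` because the
    excluded d_j = 0 term contributes nothing.
    """
    if d_t < 0:
        raise DVHError("hdvp threshold must be >= 0")
    d = curve.dose_gy
    v = curve.volume_pct
    v_next = np.append(v[1:], 0.0)
    mask = d > d_t
    return float(np.sum(d[mask] * (v[mask] - v_next[mask])))


@dataclass
class OrganScoreTable:
    """Per-plan, per-OAR metrics and cohort-normalized total scores.

    ``per_organ`` is indexed by (plan_id, structure_id) with columns
    ``mdvp``, ``hdvp``, ``combined`` and ``normalized_score``;
    ``per_plan`` is indexed by plan_id (in cohort order) with columns
    ``total_score`` and ``accepted``.  ``cohort_mean`` holds the per-OAR
    normalization constants (mean combined value over the normalization
    set).
    """

    per_organ: pd.DataFrame
    per_plan: pd.DataFrame
    cohort_mean: pd.Series
    normalization_set: str = "all"
    oars: tuple[OARSpec, ...] = field(default_factory=tuple)

    @property
    def plan_ids(self) -> list[str]:
        return list(self.per_plan.index)

    def total_score(self, plan_id: str) -> float:
        return float(self.per_plan.loc[plan_id, "total_score"])


def score_cohort(
    plans: list[PlanDose],
    oars: list[OARSpec],
    accepted: dict[str, bool] | None = None,
    normalization_set: str = "all",
    bin_width: float = DEFAULT_BIN_WIDTH_GY,
) -> OrganScoreTable:
    """Score a cohort of normalized plans against a set of OAR specs.

    Each plan's curves are resampled onto a uniform ``bin_width`` grid
    before metric computation so the threshold sums are grid-independent.
    ``normalization_set`` selects which plans define the per-OAR mean used
    as the normalization constant: ``"all"`` (every plan handed in,
    including hotspot-excluded ones -- the default) or ``"accepted"``.
    Ranking downstream always uses accepted plans only.
    """
    if not plans:
        raise EmptyCohortError("cannot score an empty cohort")
    if not oars:
        raise DVHError("at least one OAR spec is required")
    if normalization_set not in ("all", "accepted"):
        raise DVHError(f"unknown normalization_set policy {normalization_set!r}")
    if accepted is None:
        accepted = {p.plan_id: True for p in plans}

    rows = []
    for plan in plans:
        for oar in oars:
            c = resample(plan.curve(oar.structure_id), bin_width)
            m = mdvp(c)
            h = hdvp(c, oar.hdvp_threshold)
            rows.append(
                {
                    "plan_id": plan.plan_id,
                    "structure_id": oar.structure_id,
                    "mdvp": m,
                    "hdvp": h,
                    "combined": oar.weight_mdvp * m + oar.weight_hdvp * h,
                }
            )
    per_organ = pd.DataFrame(rows).set_index(["plan_id", "structure_id"])

    norm_ids = [
        p.plan_id
        for p in plans
        if normalization_set == "all" or accepted.get(p.plan_id, False)
    ]
    if not norm_ids:
        raise EmptyCohortError("normalization set is empty")
    norm_slice = per_organ.loc[norm_ids]
    cohort_mean = norm_slice.groupby("structure_id")["combined"].mean()
    zero = cohort_mean[cohort_mean == 0]
    if len(zero):
        raise DegenerateNormalizationError(
            f"zero mean combined metric for OAR(s): {list(zero.index)}"
        )

    per_organ["normalized_score"] = per_organ["combined"] / per_organ.index.get_level_values(
        "structure_id"
    ).map(cohort_mean)

    plan_order = [p.plan_id for p in plans]
    totals = (
        per_organ.groupby("plan_id")["normalized_score"].sum().reindex(plan_order)
    )
    per_plan = pd.DataFrame(
        {
            "total_score": totals,
            "accepted": [bool(accepted.get(pid, False)) for pid in plan_order],
        },
        index=pd.Index(plan_order, name="plan_id"),
    )
    return OrganScoreTable(
        per_organ=per_organ,
        per_plan=per_plan,
        cohort_mean=cohort_mean,
        normalization_set=normalization_set,
        oars=tuple(oars),
    )


@dataclass(frozen=True)
class RankResult:
    """Ranking of accepted plans by ascending total score."""

    order: tuple[str, ...]
    best: str
    worst: str
    conformal: str | None
    conformal_accepted: bool | None


def rank_plans(table: OrganScoreTable, conformal_plan_id: str | None = None) -> RankResult:
    """Rank accepted plans ascending by total score (lower = better spared).

    Ties are broken by the plan's position in the cohort (lowest index
    wins), making the ranking deterministic.  The conformal plan, when
    identified by the caller, is reported regardless of whether it was
    accepted; only accepted plans participate in the ranking itself.
    """
    acc = table.per_plan[table.per_plan["accepted"]]
    if acc.empty:
        raise EmptyCohortError("no accepted plans to rank")
    # stable mergesort on score preserves cohort (index) order among ties
    ordered = acc["total_score"].sort_values(kind="mergesort")
    order = tuple(ordered.index)
    conformal_accepted = None
    if conformal_plan_id is not None:
        conformal_accepted = bool(
            table.per_plan.loc[conformal_plan_id, "accepted"]
        ) if conformal_plan_id in table.per_plan.index else False
    return RankResult(
        order=order,
        best=order[0],
        worst=order[-1],
        conformal=conformal_plan_id,
        conformal_accepted=conformal_accepted,
    )
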