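"""End-to-end jaw search: grid -> dose engine -> normalize -> filter -> score -> rank.

The pipeline mirrors a TPS-scripting workflow in which candidate plans are
disposable and per-plan *text records* are the durable artifact: for every
candidate the record stores the jaw setting, acceptance status, the
normalization scale factor, the jaw-blind predicted DVH block and the final
(normalized) DVH block, all in the package's DVH CSV dialect.  Re-running
with an identical configuration and seed reproduces every record
byte-identically.

Every candidate ends in exactly one state:

* ``accepted``  -- normalized, hotspot within the limit, enters the ranking;
* ``hotspot``   -- normalized but maximum dose > limit (default 107 % of
  prescription); excluded from ranking, still part of the default
  normalization cohort;
* ``invalid``   -- geometry below the minimum field width (or a degenerate
  normalization); never simulated/ranked.

The n x n heat map of total scores (rows: bank-1 travel, columns: bank-2
travel) encodes excluded cells with sentinel tokens so the matrix stays
complete.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field

from jawsearch.dvh_core import (
    DegeneratePlanError,
    PlanDose,
    DVHError,
    dumps_dvh_csv,
    is_hotspot_unacceptable,
    loads_dvh_csv,
    normalize_to_prescription,
)
from jawsearch.jaw_grid import BEVExtent, JawSetting, conformal_jaws, generate_grid
from jawsearch.scoring import (
    EmptyCohortError,
    OARSpec,
    OrganScoreTable,
    RankResult,
    rank_plans,
    score_cohort,
)
from jawsearch.surrogate_engine import SurrogateConfig, predict_dvh_stub, simulate_plan

__all__ = [
    "SearchConfig",
    "SearchResult",
    "run_search",
    "score_external",
    "export_heatmap",
    "read_heatmap",
    "HOTSPOT_TOKEN",
    "INVALID_TOKEN",
]

log = logging.getLogger("jawsearch")

HOTSPOT_TOKEN = "HOTSPOT"
INVALID_TOKEN = "INVALID"


class OARSpecModel(BaseModel):
    """JSON-facing mirror of :class:`jawsearch.scoring.OARSpec`."""

    structure_id: str
    hdvp_threshold: float = Field(ge=0)
    weight_mdvp: float = Field(default=1.0, ge=0)
    weight_hdvp: float = Field(default=1.0, ge=0)

    def to_spec(self) -> OARSpec:
        return OARSpec(self.structure_id, self.hdvp_threshold, self.weight_mdvp, self.weight_hdvp)


def _default_oar_specs() -> list[OARSpecModel]:
    # RTOG 0822-style high-dose thresholds for a rectal cohort
    return [
        OARSpecModel(structure_id="small_bowel", hdvp_threshold=35.0),
        OARSpecModel(structure_id="femoral_head", hdvp_threshold=40.0),
        OARSpecModel(structure_id="urinary_bladder", hdvp_threshold=40.0),
    ]


class SearchConfig(BaseModel):
    """Full jaw-search configuration (JSON-serializable)."""

    prescription_gy: float = Field(default=50.0, gt=0)
    coverage_volume_pct: float = Field(default=95.0, gt=0, le=100)
    hotspot_limit_pct: float = Field(default=107.0, gt=100)
    step_mm: float = Field(default=5.0, gt=0)
    n_steps_per_bank: int = Field(default=10, ge=1)
    min_width_mm: float = Field(default=20.0, gt=0)
    leaf_width_mm: float = Field(default=5.0, ge=0)
    target_id: str = "ptv"
    oars: list[OARSpecModel] = Field(default_factory=_default_oar_specs, min_length=1)
    normalization_set: str = "all"
    engine: str = "surrogate"
    seed: int = 0
    bin_width_gy: float = Field(default=0.1, gt=0)
    surrogate: SurrogateConfig = Field(default_factory=SurrogateConfig)

    def oar_specs(self) -> list[OARSpec]:
        return [o.to_spec() for o in self.oars]

    def bound_surrogate(self, extent: BEVExtent) -> SurrogateConfig:
        """Surrogate config tied to this search: prescription, width, seed."""
        return self.surrogate.model_copy(
            update={
                "prescription_gy": self.prescription_gy,
                "conformal_width_mm": extent.x_max - extent.x_min,
                "target_id": self.target_id,
                "seed": self.seed,
            }
        )


@dataclass
class SearchResult:
    """Everything the search produced, ready for export and comparison."""

    config: SearchConfig
    extent: BEVExtent
    settings: list[JawSetting]
    statuses: dict[str, str]                  # plan_id -> accepted|hotspot|invalid
    plans: dict[str, PlanDose]                # normalized plans (accepted + hotspot)
    table: OrganScoreTable
    rank: RankResult
    records: dict[str, str] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        c = {"total": len(self.settings), "accepted": 0, "hotspot": 0, "invalid": 0}
        for s in self.statuses.values():
            c[s] += 1
        return c

    @property
    def n(self) -> int:
        return self.config.n_steps_per_bank

    def heatmap_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(scores, status) n x n arrays, row = bank-1 offset index."""
        n = self.n
        scores = np.full((n, n), np.nan)
        status = np.empty((n, n), dtype=object)
        for s in self.settings:
            i, j = divmod(s.index - 1, n)
            st = self.statuses[s.plan_id]
            status[i, j] = st
            if st != "invalid":
                scores[i, j] = self.table.total_score(s.plan_id)
        return scores, status

    @property
    def best_plan_id(self) -> str:
        return self.rank.best

    @property
    def worst_plan_id(self) -> str:
        return self.rank.worst

    @property
    def conformal_plan_id(self) -> str:
        return self.rank.conformal


def _plan_record(
    jaws: JawSetting,
    status: str,
    scale: float,
    predicted: PlanDose | None,
    final: PlanDose | None,
) -> str:
    lines = [
        "# jawsearch plan record",
        f"plan_id: {jaws.plan_id}",
        f"index: {jaws.index}",
        f"x1_mm: {jaws.x1!r}",
        f"x2_mm: {jaws.x2!r}",
        f"y1_mm: {jaws.y1!r}",
        f"y2_mm: {jaws.y2!r}",
        f"offset1_mm: {jaws.offset1!r}",
        f"offset2_mm: {jaws.offset2!r}",
        f"status: {status}",
        f"scale_applied: {scale!r}",
    ]
    if predicted is not None:
        lines.append("[predicted_dvh]")
        lines.append(dumps_dvh_csv(predicted).rstrip("\n"))
    if final is not None:
        lines.append("[final_dvh]")
        lines.append(dumps_dvh_csv(final).rstrip("\n"))
    return "\n".join(lines) + "\n"


def run_search(
    cfg: SearchConfig,
    extent: BEVExtent,
    records_dir: str | Path | None = None,
) -> SearchResult:
    """Execute the full search over the X-jaw grid.

    Stages: build the grid from the conformal baseline; simulate each valid
    setting with the dose engine; normalize to prescription at the
    configured coverage level; screen hotspots; score the cohort with
    cohort-mean normalization; rank accepted plans.  Per-plan text records
    are written to ``records_dir`` (if given) before ranking.
    Deterministic at fixed config and seed.
    """
    if cfg.engine != "surrogate":
        raise DVHError(f"unknown dose engine {cfg.engine!r}")
    scfg = cfg.bound_surrogate(extent)
    conformal = conformal_jaws(extent, cfg.leaf_width_mm)
    settings = generate_grid(conformal, cfg.step_mm, cfg.n_steps_per_bank, cfg.min_width_mm)
    log.info("grid: %d candidate settings (%d per bank)", len(settings), cfg.n_steps_per_bank)

    statuses: dict[str, str] = {}
    plans: dict[str, PlanDose] = {}
    records: dict[str, str] = {}
    for jaws in settings:
        pid = jaws.plan_id
        if not jaws.valid:
            statuses[pid] = "invalid"
            records[pid] = _plan_record(jaws, "invalid", 1.0, None, None)
            continue
        raw = simulate_plan(jaws, scfg)
        predicted = predict_dvh_stub(jaws, scfg)
        try:
            norm = normalize_to_prescription(
                raw, cfg.target_id, cfg.prescription_gy, cfg.coverage_volume_pct
            )
        except DegeneratePlanError:
            statuses[pid] = "invalid"
            records[pid] = _plan_record(jaws, "degenerate", 1.0, predicted, raw)
            continue
        hot = is_hotspot_unacceptable(norm, cfg.target_id, cfg.prescription_gy, cfg.hotspot_limit_pct)
        statuses[pid] = "hotspot" if hot else "accepted"
        plans[pid] = norm
        records[pid] = _plan_record(jaws, statuses[pid], norm.scale_applied, predicted, norm)

    if records_dir is not None:
        records_dir = Path(records_dir)
        records_dir.mkdir(parents=True, exist_ok=True)
        for pid, text in records.items():
            (records_dir / f"{pid}.txt").write_text(text, encoding="utf-8")

    counts = {"accepted": 0, "hotspot": 0, "invalid": 0}
    for s in statuses.values():
        counts[s] += 1
    log.info("normalization/filter: %(accepted)d accepted, %(hotspot)d hotspot-excluded, "
             "%(invalid)d invalid", counts)
    if counts["accepted"] == 0:
        raise EmptyCohortError(
            f"all plans excluded (hotspot: {counts['hotspot']}, invalid: {counts['invalid']})"
        )

    cohort = [plans[s.plan_id] for s in settings if s.plan_id in plans]
    accepted = {pid: statuses[pid] == "accepted" for pid in plans}
    table = score_cohort(
        cohort,
        cfg.oar_specs(),
        accepted=accepted,
        normalization_set=cfg.normalization_set,
        bin_width=cfg.bin_width_gy,
    )
    conformal_pid = settings[0].plan_id  # index 1, offsets (0, 0)
    rank = rank_plans(table, conformal_plan_id=conformal_pid)
    log.info("ranked %d accepted plans: best=%s worst=%s conformal=%s",
             counts["accepted"], rank.best, rank.worst, conformal_pid)
    return SearchResult(
        config=cfg,
        extent=extent,
        settings=settings,
        statuses=statuses,
        plans=plans,
        table=table,
        rank=rank,
        records=records,
    )


def score_external(
    raw_plans: list[PlanDose],
    cfg: SearchConfig,
) -> tuple[OrganScoreTable, RankResult, dict[str, str]]:
    """Normalize, filter and score externally produced DVHs (no surrogate).

    Each plan must contain the target and every configured OAR curve.
    Returns the score table, the ranking over accepted plans and the
    per-plan status map.
    """
    statuses: dict[str, str] = {}
    normed: list[PlanDose] = []
    for plan in raw_plans:
        try:
            norm = normalize_to_prescription(
                plan, cfg.target_id, cfg.prescription_gy, cfg.coverage_volume_pct
            )
        except DegeneratePlanError:
            statuses[plan.plan_id] = "invalid"
            continue
        hot = is_hotspot_unacceptable(norm, cfg.target_id, cfg.prescription_gy, cfg.hotspot_limit_pct)
        statuses[plan.plan_id] = "hotspot" if hot else "accepted"
        normed.append(norm)
    if not normed:
        raise EmptyCohortError("no plan could be normalized")
    accepted = {p.plan_id: statuses[p.plan_id] == "accepted" for p in normed}
    table = score_cohort(
        normed, cfg.oar_specs(), accepted=accepted,
        normalization_set=cfg.normalization_set, bin_width=cfg.bin_width_gy,
    )
    rank = rank_plans(table)
    return table, rank, statuses


# ---------------------------------------------------------------------------
# Heat-map matrix serialization: n x n CSV, rows = bank-1 offsets, columns =
# bank-2 offsets; hotspot-excluded cells carry the token HOTSPOT and invalid
# geometry the token INVALID.  Scores are written with shortest round-trip
# repr so read-back is exact.
# ---------------------------------------------------------------------------

def export_heatmap(result: SearchResult, path: str | Path) -> None:
    """Write the n x n total-score matrix as CSV with sentinel tokens."""
    scores, status = result.heatmap_matrix()
    n = result.n
    offsets = [i * result.config.step_mm for i in range(n)]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["offset1_mm"] + [repr(float(o)) for o in offsets])
        for i in range(n):
            row: list[str] = [repr(float(offsets[i]))]
            for j in range(n):
                if status[i, j] == "invalid":
                    row.append(INVALID_TOKEN)
                elif status[i, j] == "hotspot":
                    row.append(HOTSPOT_TOKEN)
                else:
                    row.append(repr(float(scores[i, j])))
            w.writerow(row)


def read_heatmap(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a heat-map CSV back: (scores, status, offsets_mm).

    Sentinel cells come back as NaN in ``scores`` with their token in
    ``status``; numeric cells read back bit-exactly.
    """
    with open(path, encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh))
    header, body = rows[0], rows[1:]
    offsets = np.array([float(x) for x in header[1:]])
    n = len(offsets)
    scores = np.full((n, n), np.nan)
    status = np.empty((n, n), dtype=object)
    for i, row in enumerate(body):
        for j, cell in enumerate(row[1:]):
            if cell in (HOTSPOT_TOKEN, INVALID_TOKEN):
                status[i, j] = "hotspot" if cell == HOTSPOT_TOKEN else "invalid"
            else:
                status[i, j] = "accepted"
                scores[i, j] = float(cell)
    return scores, status, offsets
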