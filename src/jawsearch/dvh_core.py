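"""Cumulative DVH data model and algebra.

A :class:`DVHCurve` stores a sampled cumulative dose-volume histogram for a
single structure: ``volume_pct[j]`` is the relative volume (%) receiving at
least ``dose_gy[j]`` Gy.  Curves always start at (0 Gy, 100 %) and are
non-increasing in volume.  All metric computation downstream (MDVP/HDVP,
V_D, mean dose) operates on this representation, usually after resampling
onto a uniform dose grid so that threshold sums are grid-independent.

Plans are bundles of curves (:class:`PlanDose`).  Plan-level operations --
normalization to prescription and hotspot screening -- act uniformly on all
curves of a plan: rescaling dose to meet prescription multiplies every
structure's dose axis by the same factor and leaves volumes untouched.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DVHCurve",
    "PlanDose",
    "DVHError",
    "DegeneratePlanError",
    "resample",
    "dose_at_volume",
    "volume_at_dose",
    "max_dose",
    "mean_dose",
    "normalize_to_prescription",
    "is_hotspot_unacceptable",
    "read_dvh_csv",
    "write_dvh_csv",
    "curves_equal",
]

_VOL_TOL = 1e-9


class DVHError(ValueError):
    """Invalid DVH input (empty curve, broken monotonicity, bad query)."""


class DegeneratePlanError(DVHError):
    """Plan cannot be normalized: target dose at the coverage level is zero."""


@dataclass
class DVHCurve:
    """Cumulative dose-volume curve for one structure.

    Parameters
    ----------
    structure_id
        Label of the structure (e.g. ``"small_bowel"``).
    dose_gy
        Strictly increasing dose samples in Gy, starting at 0.
    volume_pct
        Relative volume (%) receiving at least the corresponding dose;
        starts at 100, non-increasing, all values in [0, 100].
    """

    structure_id: str
    dose_gy: np.ndarray
    volume_pct: np.ndarray

    def __post_init__(self) -> None:
        self.dose_gy = np.asarray(self.dose_gy, dtype=float)
        self.volume_pct = np.asarray(self.volume_pct, dtype=float)
        if self.dose_gy.ndim != 1 or self.dose_gy.size == 0:
            raise DVHError(f"{self.structure_id}: empty or non-1D dose grid")
        if self.dose_gy.shape != self.volume_pct.shape:
            raise DVHError(f"{self.structure_id}: dose/volume length mismatch")
        if self.dose_gy[0] < 0 or abs(self.dose_gy[0]) > _VOL_TOL:
            raise DVHError(f"{self.structure_id}: dose grid must start at 0 Gy")
        if np.any(np.diff(self.dose_gy) <= 0):
            raise DVHError(f"{self.structure_id}: dose grid not strictly increasing")
        if abs(self.volume_pct[0] - 100.0) > _VOL_TOL:
            raise DVHError(f"{self.structure_id}: volume at 0 Gy must be 100 %")
        if np.any(np.diff(self.volume_pct) > _VOL_TOL):
            raise DVHError(f"{self.structure_id}: cumulative volume must be non-increasing")
        if np.any(self.volume_pct < -_VOL_TOL) or np.any(self.volume_pct > 100 + _VOL_TOL):
            raise DVHError(f"{self.structure_id}: volumes outside [0, 100] %")

    def scaled(self, s: float) -> "DVHCurve":
        """Return a copy with every dose multiplied by ``s`` (> 0)."""
        if s <= 0:
            raise DVHError("dose scale factor must be positive")
        return DVHCurve(self.structure_id, self.dose_gy * s, self.volume_pct.copy())


@dataclass
class PlanDose:
    """Per-plan bundle of DVH curves, one per structure.

    ``scale_applied`` records the cumulative multiplicative dose factor
    already applied to the curves (1.0 when raw from the dose engine).
    """

    plan_id: str
    curves: dict[str, DVHCurve] = field(default_factory=dict)
    scale_applied: float = 1.0

    def __post_init__(self) -> None:
        if self.scale_applied <= 0:
            raise DVHError(f"{self.plan_id}: scale_applied must be positive")
        for sid, c in self.curves.items():
            if c.structure_id != sid:
                raise DVHError(f"{self.plan_id}: curve key {sid!r} != structure_id {c.structure_id!r}")

    def curve(self, structure_id: str) -> DVHCurve:
        try:
            return self.curves[structure_id]
        except KeyError:
            raise DVHError(f"plan {self.plan_id}: no curve for structure {structure_id!r}") from None


def resample(curve: DVHCurve, bin_width: float) -> DVHCurve:
    """Resample a curve onto the uniform grid 0, h, 2h, ...

    The grid extends to the first multiple of ``bin_width`` at or beyond the
    curve's last dose sample; values are linearly interpolated and the
    volume beyond the last input sample is 0.
    """
    if bin_width <= 0:
        raise DVHError("bin_width must be positive")
    dmax = float(curve.dose_gy[-1])
    n_bins = max(1, int(np.ceil(dmax / bin_width - 1e-12)))
    grid = np.arange(n_bins + 1, dtype=float) * bin_width
    vol = np.interp(grid, curve.dose_gy, curve.volume_pct, right=0.0)
    # clamp interpolation round-off so invariants survive
    vol = np.clip(vol, 0.0, 100.0)
    vol[0] = 100.0
    return DVHCurve(curve.structure_id, grid, vol)


def volume_at_dose(curve: DVHCurve, d: float) -> float:
    """Relative volume (%) receiving at least ``d`` Gy (V_D).

    Linear interpolation of the cumulative curve; doses beyond the last
    sample return 0.
    """
    if d < 0:
        raise DVHError("dose query must be non-negative")
    return float(np.interp(d, curve.dose_gy, curve.volume_pct, right=0.0))


def dose_at_volume(curve: DVHCurve, v: float) -> float:
    """Dose (Gy) received by at least ``v`` % of the structure (D_v).

    Returns the largest dose at which the interpolated cumulative volume is
    still >= ``v``; on a flat 100 % plateau this is the plateau's far edge,
    and ``v=0`` returns the last dose sample.
    """
    if not 0.0 <= v <= 100.0:
        raise DVHError("volume query must be in [0, 100] %")
    vol = curve.volume_pct
    dose = curve.dose_gy
    idx = int(np.nonzero(vol >= v)[0][-1])  # exists: vol[0] == 100 >= v
    if idx == len(dose) - 1:
        return float(dose[-1])
    # vol[idx] >= v > vol[idx+1], segment strictly decreasing
    frac = (vol[idx] - v) / (vol[idx] - vol[idx + 1])
    return float(dose[idx] + frac * (dose[idx + 1] - dose[idx]))


def max_dose(curve: DVHCurve, epsilon: float = 0.0) -> float:
    """Largest dose with volume above ``epsilon`` %, by linear interpolation.

    With the default ``epsilon=0`` this is the support endpoint of the
    sampled curve: the dose at which the cumulative volume first reaches 0
    (or the last grid point if it never does).
    """
    vol = curve.volume_pct
    dose = curve.dose_gy
    below = np.nonzero(vol <= epsilon)[0]
    if below.size == 0:
        return float(dose[-1])
    idx = int(below[0])
    if idx == 0:
        return float(dose[0])
    frac = (vol[idx - 1] - epsilon) / (vol[idx - 1] - vol[idx])
    return float(dose[idx - 1] + frac * (dose[idx] - dose[idx - 1]))


def mean_dose(curve: DVHCurve, bin_width: float = 0.01) -> float:
    """Mean dose (Gy) of the structure, computed as MDVP/100 on a fine grid."""
    from jawsearch.scoring import mdvp  # local import: scoring builds on this module

    return mdvp(resample(curve, bin_width)) / 100.0


def normalize_to_prescription(
    plan: PlanDose,
    target_id: str,
    prescription: float,
    coverage_volume: float = 95.0,
) -> PlanDose:
    """Rescale all doses so the target's D_{coverage_volume} equals prescription.

    Every curve's dose grid is multiplied by
    ``s = prescription / dose_at_volume(target, coverage_volume)``; volumes
    are unchanged and ``scale_applied`` is updated.  Raises
    :class:`DegeneratePlanError` when the target receives zero dose at the
    coverage level (the caller should flag, not drop, such a plan).
    """
    target = plan.curve(target_id)
    d_cov = dose_at_volume(target, coverage_volume)
    if d_cov <= 0:
        raise DegeneratePlanError(
            f"plan {plan.plan_id}: target D{coverage_volume:g} is zero, cannot normalize"
        )
    s = prescription / d_cov
    return PlanDose(
        plan_id=plan.plan_id,
        curves={sid: c.scaled(s) for sid, c in plan.curves.items()},
        scale_applied=plan.scale_applied * s,
    )


def is_hotspot_unacceptable(
    plan: PlanDose,
    target_id: str,
    prescription: float,
    limit_pct: float = 107.0,
) -> bool:
    """True iff the plan's hotspot exceeds ``limit_pct`` % of prescription.

    Strict inequality: a maximum dose of exactly ``limit_pct`` % is kept.
    The hotspot statistic is the maximum dose of the designated hotspot
    structure (by convention the target, lacking a body contour).
    """
    return max_dose(plan.curve(target_id)) > (limit_pct / 100.0) * prescription


# ---------------------------------------------------------------------------
# DVH CSV dialect: header `plan_id,structure,dose_gy,volume_pct`, one row per
# sample, doses ascending per structure, UTF-8.  Floats are written with
# Python's shortest round-trip repr so write -> read is bit-exact.
# ---------------------------------------------------------------------------

_CSV_HEADER = ["plan_id", "structure", "dose_gy", "volume_pct"]


def write_dvh_csv(plans, fh) -> None:
    """Write one or more :class:`PlanDose` objects in the DVH CSV dialect."""
    if isinstance(plans, PlanDose):
        plans = [plans]
    w = csv.writer(fh, lineterminator="\n")
    w.writerow(_CSV_HEADER)
    for plan in plans:
        for sid in plan.curves:
            c = plan.curves[sid]
            for d, v in zip(c.dose_gy, c.volume_pct):
                w.writerow([plan.plan_id, sid, repr(float(d)), repr(float(v))])


def read_dvh_csv(fh) -> list[PlanDose]:
    """Read the DVH CSV dialect back into :class:`PlanDose` objects.

    Plans appear in file order; ``scale_applied`` is not part of the dialect
    and is restored as 1.0 (the file records the curves as-is).
    """
    r = csv.reader(fh)
    header = next(r, None)
    if header != _CSV_HEADER:
        raise DVHError(f"bad DVH CSV header: {header!r}")
    acc: dict[str, dict[str, tuple[list[float], list[float]]]] = {}
    order: list[str] = []
    for row in r:
        if not row:
            continue
        pid, sid, d, v = row
        if pid not in acc:
            acc[pid] = {}
            order.append(pid)
        dose, vol = acc[pid].setdefault(sid, ([], []))
        dose.append(float(d))
        vol.append(float(v))
    plans = []
    for pid in order:
        curves = {
            sid: DVHCurve(sid, np.array(d), np.array(v))
            for sid, (d, v) in acc[pid].items()
        }
        plans.append(PlanDose(plan_id=pid, curves=curves))
    return plans


def curves_equal(a: DVHCurve, b: DVHCurve) -> bool:
    """Bit-exact equality of two curves (same samples, same structure id)."""
    return (
        a.structure_id == b.structure_id
        and a.dose_gy.shape == b.dose_gy.shape
        and np.array_equal(a.dose_gy, b.dose_gy)
        and np.array_equal(a.volume_pct, b.volume_pct)
    )


def dumps_dvh_csv(plans) -> str:
    """Serialize plans to a DVH CSV string (convenience for text records)."""
    buf = io.StringIO()
    write_dvh_csv(plans, buf)
    return buf.getvalue()


def loads_dvh_csv(text: str) -> list[PlanDose]:
    """Parse a DVH CSV string (inverse of :func:`dumps_dvh_csv`)."""
    return read_dvh_csv(io.StringIO(text))
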