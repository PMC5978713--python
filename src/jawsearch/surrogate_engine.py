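"""Parametric synthetic dose engine for jaw-search experiments.

Maps a jaw setting to per-structure DVHs with the qualitative structure
observed when X-jaw aperture is varied on real VMAT plans:

* each organ at risk receives a mean dose with two competing aperture
  terms -- a *leakage* penalty proportional to the open fraction ``a``
  (larger fields leak more MLC transmission dose) and a *modulation*
  penalty proportional to ``(1 - a)^2`` (over-closed jaws starve the
  optimizer of modulation room) -- so each OAR has its own analytic
  optimum aperture and the OARs trade off against each other;
* the target DVH degrades once the combined jaw travel *encroaches* on the
  target by more than a margin: coverage (D95) drops and the relative
  maximum dose rises, so after normalization to prescription the hotspot
  is amplified and sufficiently closed settings fail the 107 % screen;
* optional Gaussian noise on each OAR mean dose stands in for optimizer
  run-to-run variability, with an independent substream per
  (plan, structure) derived from one master seed.

OAR curves come from a two-parameter stretched-exponential (Weibull
survival) family ``V(d) = 100 * exp(-ln2 * (d / D50)^k)`` whose mean has
the closed form ``D50 * Gamma(1 + 1/k) / (ln2)^(1/k)``; the engine inverts
this (:func:`d50_for_mean`) so the generated curve's mean dose equals the
configured value.  No claim of dosimetric realism is made: the engine
encodes qualitative structure for testing the search pipeline.
"""

from __future__ import annotations

import math

import numpy as np
from pydantic import BaseModel, Field, model_validator

from jawsearch.dvh_core import DVHCurve, PlanDose
from jawsearch.jaw_grid import GridError, JawSetting

__all__ = [
    "OARSurrogate",
    "SurrogateConfig",
    "DegenerateApertureError",
    "d50_for_mean",
    "weibull_survival_curve",
    "simulate_plan",
    "predict_dvh_stub",
]


class DegenerateApertureError(GridError):
    """Jaw travel meets or exceeds the conformal width: no open field left."""


def d50_for_mean(mean_dose: float, k: float) -> float:
    """Half-volume dose D50 of the Weibull-survival DVH with a given mean.

    For ``V(d) = 100 * exp(-ln2 * (d/D50)^k)`` the underlying dose
    distribution is Weibull with shape ``k`` and scale
    ``D50 / (ln2)^(1/k)``, whose mean is ``scale * Gamma(1 + 1/k)``.
    Inverting: ``D50 = mean * (ln2)^(1/k) / Gamma(1 + 1/k)``.
    """
    if mean_dose <= 0 or k <= 0:
        raise ValueError("mean_dose and shape k must be positive")
    return mean_dose * math.log(2) ** (1.0 / k) / math.gamma(1.0 + 1.0 / k)


def weibull_survival_curve(
    structure_id: str,
    mean_dose: float,
    k: float,
    grid_step: float = 0.1,
    tail_volume_pct: float = 1e-3,
) -> DVHCurve:
    """Sample the Weibull-survival DVH with the requested mean dose.

    The grid runs from 0 to the dose where the cumulative volume falls to
    ``tail_volume_pct`` %, in ``grid_step`` Gy steps.
    """
    d50 = d50_for_mean(mean_dose, k)
    # V(d_cut) = tail_volume_pct  =>  (d_cut/d50)^k = log2(100/tail)
    d_cut = d50 * (math.log2(100.0 / tail_volume_pct)) ** (1.0 / k)
    n = max(2, int(math.ceil(d_cut / grid_step)) + 1)
    dose = np.arange(n, dtype=float) * grid_step
    vol = 100.0 * np.exp(-math.log(2) * (dose / d50) ** k)
    vol[0] = 100.0
    return DVHCurve(structure_id, dose, vol)


class OARSurrogate(BaseModel):
    """Aperture-response parameters of one synthetic organ at risk.

    Mean dose model (Gy): ``baseline + leakage * a + modulation * (1-a)^2``
    where ``a`` is the open fraction of the conformal width.  ``shape`` is
    the Weibull DVH shape k (>0): larger k = steeper curve, thinner
    high-dose tail.
    """

    structure_id: str
    baseline_gy: float = Field(ge=0)
    leakage_gy: float = Field(ge=0)
    modulation_gy: float = Field(ge=0)
    shape: float = Field(gt=0)

    def mean_dose(self, open_fraction: float) -> float:
        """Noise-free mean dose (Gy) at open fraction ``a``."""
        a = open_fraction
        return self.baseline_gy + self.leakage_gy * a + self.modulation_gy * (1.0 - a) ** 2

    def optimal_open_fraction(self) -> float:
        """Analytic argmin of the mean-dose model over a in (0, 1]."""
        if self.modulation_gy == 0:
            return 0.0  # monotone increasing: best at the smallest aperture
        return max(0.0, min(1.0, 1.0 - self.leakage_gy / (2.0 * self.modulation_gy)))


def _default_oars() -> list[OARSurrogate]:
    # Rectal-plan cohort: small bowel with a 35 Gy tail, femoral head low
    # dose with negligible tail, bladder between.  Leakage/modulation are
    # chosen so the analytic optima sit at different interior apertures
    # (0.80, 0.67, 0.81 of the conformal width) and the fully open
    # (conformal) setting is neither the best nor the worst of the
    # hotspot-accepted range.
    return [
        OARSurrogate(structure_id="small_bowel", baseline_gy=16.0, leakage_gy=4.0,
                     modulation_gy=10.0, shape=3.0),
        OARSurrogate(structure_id="femoral_head", baseline_gy=9.0, leakage_gy=2.0,
                     modulation_gy=3.0, shape=3.0),
        OARSurrogate(structure_id="urinary_bladder", baseline_gy=15.0, leakage_gy=7.0,
                     modulation_gy=18.0, shape=2.0),
    ]


class SurrogateConfig(BaseModel):
    """Parameters of the synthetic dose engine.

    ``cold_dose_coeff`` scales how strongly jaw encroachment past
    ``encroachment_margin_mm`` degrades target coverage and inflates the
    relative hotspot; ``noise_sd_gy`` is the SD of the Gaussian mean-dose
    perturbation per (plan, structure).
    """

    prescription_gy: float = Field(default=50.0, gt=0)
    conformal_width_mm: float = Field(default=120.0, gt=0)
    target_id: str = "ptv"
    cold_dose_coeff: float = Field(default=0.15, ge=0)
    encroachment_margin_mm: float = Field(default=40.0, ge=0)
    noise_sd_gy: float = Field(default=0.3, ge=0)
    seed: int = 0
    grid_step_gy: float = Field(default=0.1, gt=0)
    oars: list[OARSurrogate] = Field(default_factory=_default_oars)

    @model_validator(mode="after")
    def _unique_structures(self) -> "SurrogateConfig":
        ids = [o.structure_id for o in self.oars]
        if len(set(ids)) != len(ids) or self.target_id in ids:
            raise ValueError("structure ids must be unique and distinct from the target")
        return self


def open_fraction(jaws: JawSetting, cfg: SurrogateConfig) -> float:
    """Open fraction a = (W0 - offset1 - offset2) / W0 of the conformal width."""
    return (cfg.conformal_width_mm - jaws.offset1 - jaws.offset2) / cfg.conformal_width_mm


def encroachment(jaws: JawSetting, cfg: SurrogateConfig) -> float:
    """Travel beyond the safe margin, e = max(0, offset1+offset2-m), in mm."""
    return max(0.0, jaws.offset1 + jaws.offset2 - cfg.encroachment_margin_mm)


def oar_mean_doses(jaws: JawSetting, cfg: SurrogateConfig, with_noise: bool = True) -> dict[str, float]:
    """Per-OAR mean dose (Gy) at this jaw setting, optionally with noise.

    The noise substream for each (plan, structure) is derived from the
    master seed and the jaw offsets, so a fixed seed reproduces the whole
    cohort and the conformal-setting draw is shared with the prediction
    stub.
    """
    a = open_fraction(jaws, cfg)
    if a <= 0:
        raise DegenerateApertureError(
            f"jaw travel {jaws.offset1 + jaws.offset2:g} mm >= conformal width "
            f"{cfg.conformal_width_mm:g} mm"
        )
    out: dict[str, float] = {}
    for s_idx, oar in enumerate(cfg.oars):
        mean = oar.mean_dose(a)
        if with_noise and cfg.noise_sd_gy > 0:
            ss = np.random.SeedSequence(
                [cfg.seed, int(round(jaws.offset1 * 1000)), int(round(jaws.offset2 * 1000)), s_idx]
            )
            eps = float(np.random.default_rng(ss).normal(0.0, cfg.noise_sd_gy))
            mean = max(1e-6, mean + eps)
        out[oar.structure_id] = mean
    return out


def _target_curve(jaws: JawSetting, cfg: SurrogateConfig) -> DVHCurve:
    """Step-like target DVH whose D95 and Dmax encode jaw encroachment.

    Pre-normalization: D95 = Rx*(1 - c*e/W0), Dmax = Rx*(1.03 + c*e/W0).
    After normalization to D95 = Rx the relative hotspot becomes
    (1.03 + x)/(1 - x) with x = c*e/W0, so encroachment past the margin
    amplifies the hotspot and eventually trips the 107 % screen.
    """
    rx = cfg.prescription_gy
    x = cfg.cold_dose_coeff * encroachment(jaws, cfg) / cfg.conformal_width_mm
    if x >= 1.0:
        raise DegenerateApertureError("encroachment drives target coverage to zero")
    d95 = rx * (1.0 - x)
    dmax = rx * (1.03 + x)
    shoulder = 0.95 * d95
    dose = np.array([0.0, shoulder, d95, dmax])
    vol = np.array([100.0, 100.0, 95.0, 0.0])
    return DVHCurve(cfg.target_id, dose, vol)


def simulate_plan(jaws: JawSetting, cfg: SurrogateConfig) -> PlanDose:
    """Synthesize the unnormalized PlanDose for one jaw setting.

    The returned plan has the target curve plus one Weibull-survival curve
    per configured OAR; ``scale_applied`` is 1.0 (normalization is the
    caller's job).  With ``noise_sd_gy=0`` the output is a deterministic
    function of (jaws, config).
    """
    means = oar_mean_doses(jaws, cfg, with_noise=True)
    curves = {cfg.target_id: _target_curve(jaws, cfg)}
    for oar in cfg.oars:
        curves[oar.structure_id] = weibull_survival_curve(
            oar.structure_id, means[oar.structure_id], oar.shape, cfg.grid_step_gy
        )
    return PlanDose(plan_id=jaws.plan_id, curves=curves, scale_applied=1.0)


def predict_dvh_stub(jaws: JawSetting, cfg: SurrogateConfig) -> PlanDose:
    """Knowledge-based DVH prediction stub: blind to the actual jaws.

    Emulates a geometry-based estimator that always assumes target-conformal
    jaws: whatever setting is passed in, it returns the DVHs of the
    conformal (zero-offset) plan, byte-identical across the grid at a fixed
    seed.  Useful as a negative control -- its predictions cannot rank jaw
    settings.
    """
    conformal = JawSetting(
        x1=jaws.x1 - jaws.offset1,
        x2=jaws.x2 + jaws.offset2,
        y1=jaws.y1,
        y2=jaws.y2,
        offset1=0.0,
        offset2=0.0,
        index=jaws.index,
        valid=True,
    )
    plan = simulate_plan(conformal, cfg)
    return PlanDose(plan_id="predicted_conformal", curves=plan.curves, scale_applied=1.0)


def closed_form_scores(
    settings: list[JawSetting],
    cfg: SurrogateConfig,
    oar_specs,
    normalization_set: str = "all",
) -> dict[str, float]:
    """Analytic total scores from the closed-form mean doses (noise-free).

    Independent of the DVH sampling path: for each valid, hotspot-accepted
    setting the combined per-OAR metric is computed from the analytic mean
    dose and the exact Weibull tail expectation, then cohort-normalized
    exactly as the pipeline does.  Intended as a brute-force oracle for the
    noise-free engine.
    """
    from jawsearch.scoring import DegenerateNormalizationError

    spec_by_id = {s.structure_id: s for s in oar_specs}
    per_plan: dict[str, dict[str, float]] = {}
    accepted: dict[str, bool] = {}
    for jaws in settings:
        if not jaws.valid:
            continue
        means = oar_mean_doses(jaws, cfg, with_noise=False)
        x = cfg.cold_dose_coeff * encroachment(jaws, cfg) / cfg.conformal_width_mm
        s = 1.0 / (1.0 - x)  # normalization factor: D95 -> prescription
        accepted[jaws.plan_id] = (1.03 + x) * s <= 1.07
        combined: dict[str, float] = {}
        for oar in cfg.oars:
            spec = spec_by_id[oar.structure_id]
            mean = means[oar.structure_id] * s  # normalization scales dose
            k = oar.shape
            d50 = d50_for_mean(mean, k)
            lam = d50 / math.log(2) ** (1.0 / k)
            # E[D] restricted to D > d_t for Weibull(lam, k), times 100 (%)
            t = (spec.hdvp_threshold / lam) ** k
            tail_mean = lam * math.gamma(1.0 + 1.0 / k) * _upper_gamma_reg(1.0 + 1.0 / k, t)
            combined[oar.structure_id] = (
                spec.weight_mdvp * 100.0 * mean + spec.weight_hdvp * 100.0 * tail_mean
            )
        per_plan[jaws.plan_id] = combined
    norm_ids = [
        pid for pid in per_plan if normalization_set == "all" or accepted[pid]
    ]
    scores: dict[str, float] = {}
    for oar in cfg.oars:
        sid = oar.structure_id
        m = sum(per_plan[pid][sid] for pid in norm_ids) / len(norm_ids)
        if m == 0:
            raise DegenerateNormalizationError(sid)
        for pid in per_plan:
            scores[pid] = scores.get(pid, 0.0) + per_plan[pid][sid] / m
    return {pid: scores[pid] for pid in per_plan if accepted[pid]}


def _upper_gamma_reg(a: float, x: float) -> float:
    """Regularized upper incomplete gamma Q(a, x)."""
    from scipy.special import gammaincc

    return float(gammaincc(a, x))
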