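# Methods

## Pipeline model

`jawsearch` treats X-jaw selection for a VMAT plan as a grid search over
per-bank inward offsets from a PTV-conformal baseline. The stages are:

1. **Conformal baseline.** The X jaws are placed exactly on the target's
   beam's-eye-view border (no margin); the Y jaws are retracted outward by
   one adjacent MLC leaf width to capture scatter. Coordinates are signed
   millimetres at the isocenter plane (bank 1 negative), with the isocenter
   at the target centroid.
2. **Grid.** Each bank's offset runs over {0, s, …, (n−1)s}; the Cartesian
   product gives n² candidates, indexed row-major from 1 with the conformal
   setting first. By default s = 5 mm and n = 10, i.e. 100 candidates with
   at most 45 mm travel per bank. Settings whose residual field width falls
   below `min_width_mm` (default 20) are flagged invalid rather than
   dropped, keeping the index space dense and the heat map complete.
3. **Dose.** A pluggable engine maps each valid setting to per-structure
   cumulative DVHs (shipped: the synthetic surrogate below).
4. **Normalization.** Every plan is rescaled so the target's dose at the
   coverage level (default D95) equals prescription; the same factor
   multiplies every structure's dose axis and is recorded per plan. The
   coverage criterion is a package decision — "meet the prescription" does
   not pin down a convention — and is configurable.
5. **Hotspot screen.** Plans whose maximum target dose exceeds
   `hotspot_limit_pct` (default 107 %, strict inequality) of prescription
   after normalization are excluded from ranking. The hotspot statistic is
   the maximum dose of a configurable hotspot structure, defaulting to the
   target because the surrogate carries no body contour; with clinical
   data a near-maximum statistic such as D0.03cc on the body could be
   substituted.
6. **Scoring and ranking.** See below. Per-plan text records (jaw
   coordinates, status, scale factor, predicted and final DVH blocks) are
   written before ranking; plans themselves are disposable, the records are
   the artifact.

## Score function

Per OAR, on a cumulative DVH resampled to a uniform grid (default 0.1 Gy),
with V_{n+1} = 0:

* MDVP = Σ_j d_j (V_j − V_{j+1}) — Gy·%, equal to 100× mean dose up to a
  one-bin discretization bias (the bin's mass is assigned its left-edge
  dose, so the bias is bounded by the bin width).
* HDVP = the same sum restricted to d_j > d_t (strict). The thresholds
  default to 35 Gy (small bowel) and 40 Gy (femoral head, urinary
  bladder).

The combined value w_m·MDVP + w_h·HDVP (weights default 1.0/1.0, exposed
for institutional trade-offs) is divided by its mean over a normalization
cohort; the plan score is the sum of these dimensionless ratios over OARs.
The normalization cohort defaults to *all* plans that completed dose
calculation, including hotspot-excluded ones (`normalization_set="all"`);
ranking always uses accepted plans only. Ties are broken by the lowest
grid index, making the ranking deterministic where a random pick among
equal scores would not be.

The trailing-bin convention V_{n+1} = 0 makes MDVP the full Riemann sum of
dose × differential volume; the strict threshold follows the d_j > d_t
notation. The cohort normalization forces the per-OAR mean score to be
exactly 1 over the normalization set — an identity the tests assert — so a
score is only meaningful relative to its cohort.

## Synthetic dose engine

The surrogate emulates, qualitatively, how plan quality responds to X-jaw
aperture on a rectal VMAT cohort (one PTV, three OARs). It makes no claim
of dosimetric realism; it exists so the search, filtering, scoring and
statistics can be exercised and tested end to end.

**OAR mean dose.** With open fraction a = (W0 − offset1 − offset2)/W0 of
the conformal width W0, each OAR's mean dose is

    D̄_i = b_i + l_i·a + g_i·(1 − a)² + ε,   ε ~ Normal(0, σ²),

a leakage term growing with aperture plus a modulation-penalty term growing
as the jaws over-close. The analytic optimum a*_i = 1 − l_i/(2g_i) differs
per OAR, creating the inter-organ trade-off in which no single aperture
minimizes every organ simultaneously. Defaults (prescription 50 Gy,
W0 = 120 mm):

| structure       | b (Gy) | l (Gy) | g (Gy) | k   | a*   | d_t (Gy) |
|-----------------|--------|--------|--------|-----|------|----------|
| small_bowel     | 16     | 4      | 10     | 3.0 | 0.80 | 35       |
| femoral_head    | 9      | 2      | 3      | 3.0 | 0.67 | 40       |
| urinary_bladder | 15     | 7      | 18     | 2.0 | 0.81 | 40       |

These place the open-field mean doses near 20/11/22 Gy — magnitudes typical
of a normalized rectal plan — and make the fully open (conformal) setting
neither the best nor the worst of the accepted range, the qualitative
regime the tool is meant to explore.

**DVH family.** OAR curves are stretched-exponential (Weibull survival):
V(d) = 100·exp(−ln2·(d/D50)^k). The underlying dose distribution is
Weibull with shape k and scale D50/(ln2)^{1/k}, so the mean is
D50·Γ(1+1/k)/(ln2)^{1/k}; the engine inverts this closed form
(`d50_for_mean`) so each generated curve's mean equals D̄_i. Curves are
sampled at 0.1 Gy down to a 10⁻³ % tail volume; the fine-grid MDVP/100 of a
generated curve reproduces the configured mean within 0.05 Gy.

**Target and hotspot coupling.** The target DVH is step-like with
pre-normalization D95 = Rx·(1 − c·e/W0) and maximum dose
Rx·(1.03 + c·e/W0), where e = max(0, offset1 + offset2 − m) is the jaw
travel beyond an encroachment margin m (default 40 mm) and c = 0.15. After
normalization to D95 = Rx the relative hotspot is (1.03 + x)/(1 − x) with
x = c·e/W0: encroachment simultaneously under-doses the target and, once
normalized away, inflates the hotspot. Under the defaults this excludes
the 28 most-closed of the 100 grid settings (combined travel ≥ 60 mm) —
roughly the quarter-of-the-cohort exclusion pattern one sees when
over-shrunk jaws meet a 107 % hotspot limit.

**Noise.** ε is drawn per (plan, structure) from a `SeedSequence` keyed on
the master seed, the two jaw offsets (in µm) and the structure index:
a fixed seed reproduces the cohort bit-exactly, substreams are independent,
and the prediction stub's conformal draw coincides with the conformal
plan's. σ defaults to 0.3 Gy, a small run-to-run optimizer variability;
σ = 0 makes the whole pipeline a deterministic closed-form computation,
which the tests exploit as an analytic oracle.

**Prediction stub.** `predict_dvh_stub` models a knowledge-based DVH
estimator that is blind to the actual jaw positions: it returns the
conformal-setting DVHs for every input, byte-identical at fixed seed. It is
a negative control — its output cannot rank jaw settings — and its block in
each plan record is identical across the grid.

## Statistics

Endpoints are V_D (relative volume at dose D, by linear interpolation of
the cumulative curve) and mean dose (fine-grid MDVP/100). Best-vs-conformal
comparisons across patients use the classical two-sided paired t-test
(scipy) with n−1 degrees of freedom; zero-variance differences raise a
degenerate-variance error rather than reporting p = 0 or 1. Cohort
summaries report min/max/mean and sample (n−1) SD; singleton selections are
flagged degenerate with SD 0. Raw p-values are reported; Holm-adjusted
values are available (`holm_adjust`) and clearly labeled as such.

## Numerical choices and edge cases

* Metric computation resamples to a 0.1 Gy grid (configurable) so threshold
  sums do not depend on the export grid; queries use linear interpolation
  with volume 0 beyond the last sample.
* `dose_at_volume` returns the largest dose whose interpolated volume still
  meets the query — the far edge of a 100 % plateau, the last sample at
  v = 0 — which makes D95 normalization well defined on step-like curves.
* `max_dose` is the support endpoint: the dose where the cumulative volume
  first reaches a configurable epsilon (default 0).
* Normalization is idempotent; a target with zero dose at the coverage
  level raises a degenerate-plan error and the plan is flagged, not
  silently dropped.
* DVH CSV and heat-map serializations write floats with Python's shortest
  round-trip repr, so write → read → write is byte-identical; excluded
  heat-map cells carry `HOTSPOT`/`INVALID` tokens instead of numbers.
* All stochastic tests and the acceptance script derive every stream from a
  single seed.

## What the synthetic tests do and do not show

Passing the suite demonstrates that the search machinery is correct: grid
construction, normalization algebra, the exact MDVP/HDVP sums, the strict
hotspot boundary, cohort-normalization identities, deterministic
reproduction of records, and agreement of the full pipeline with an
independent closed-form oracle in the noise-free case. It does not
demonstrate dosimetric realism: the surrogate has smooth unimodal
aperture-response curves, independent Gaussian noise and no anatomy, so
real TPS cohorts (where dose results from MLC sequencing, scatter and
optimizer behavior) can and will rank differently. Conclusions about any
particular clinic's plans require running the scoring path on exported
DVHs (`jawsearch score`) rather than the surrogate.

## Problem sizes

The shipped defaults — a 100-candidate grid, 0.1 Gy metric grids, and a
10-patient synthetic cohort in the acceptance script — run in seconds and
are the sizes at which all reported numbers are computed.
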