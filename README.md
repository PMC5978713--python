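# jawsearch

Automated search for optimal VMAT X-jaw settings.

In Volumetric Modulated Arc Therapy (VMAT) the collimator jaws define the
maximum rectangular field within which the multi-leaf collimator (MLC) can
modulate the beam. Treatment planning systems typically do not optimize the
X-jaw positions: planners set them by convention, usually conformal to the
planning target volume (PTV). Jaws that are too open increase
organ-at-risk (OAR) exposure through MLC leakage; jaws that are too closed
starve the optimizer of modulation room, under-dose the target, and — after
normalization to prescription — amplify hotspots. `jawsearch` explores this
trade-off systematically: it sweeps a grid of X-jaw apertures around the
PTV-conformal baseline, obtains a dose–volume histogram (DVH) per candidate
plan, normalizes each plan to prescription, excludes plans with
unacceptable hotspots, and ranks the survivors by an OAR-sparing score.

It is aimed at medical physicists and planning-automation researchers who
want a reusable, testable implementation of the search-and-score loop. A
parametric synthetic dose engine is shipped so the entire pipeline runs
without a treatment planning system; externally exported DVHs can be scored
through the same path (`jawsearch score`).

## Plan scoring

For each OAR *i*, with cumulative DVH samples (d_j, V_{d_j}) and the
trailing convention V_{n+1} = 0:

```
MDVP_i = Σ_j d_j (V_{d_j} − V_{d_{j+1}})            (mean dose volume product, Gy·%)
HDVP_i = Σ_{d_j > d_t} d_j (V_{d_j} − V_{d_{j+1}})  (high dose volume product, Gy·%)

score  = Σ_i (MDVP_i + HDVP_i) / mean_cohort(MDVP_i + HDVP_i)
```

MDVP is 100× the mean dose as the grid refines; HDVP restricts the sum to
doses above an organ-specific threshold d_t (35 Gy for small bowel, 40 Gy
for femoral head and urinary bladder, following RTOG 0822-style
constraints). Dividing each organ's combined value by its mean over the
plan cohort makes every organ contribute a dimensionless score with cohort
mean exactly 1; the plan score is the sum over organs, and **lower is
better**. Plans whose maximum dose exceeds 107 % of prescription (strict
inequality) after normalization are excluded from ranking.

## Worked example

```
$ jawsearch run --seed 1
candidates: 100  accepted: 72  hotspot-excluded: 28  invalid: 0
best: plan_072  score=2.7332
worst: plan_075  score=3.0594
conformal: plan_001  score=2.9096
```

The default configuration sweeps a 10×10 grid of inward X-jaw offsets
(0–45 mm per bank in 5 mm steps) around a 120 mm conformal field, with a
50 Gy prescription and three OARs. Of 100 candidates, 28 over-closed
settings develop a > 107 % hotspot after normalization and are excluded.
Among the 72 accepted plans, the best (total score 2.73, summed over three
organs) spares the OARs better than the conformal baseline (2.91), which
ranks mid-pack — neither best nor worst (3.06): conformal jaws are a
reasonable but not optimal choice. `--records-dir` writes one text record
per plan (jaw coordinates, status, normalization factor, predicted and
final DVH blocks); `--heatmap` exports the 10×10 score matrix with
`HOTSPOT`/`INVALID` sentinels for excluded cells.

The same library surface is available in Python:

```python
from jawsearch import BEVExtent, SearchConfig, run_search

result = run_search(SearchConfig(seed=1), BEVExtent(-60, 60, -70, 70))
print(result.counts, result.rank.best, result.table.total_score(result.rank.best))
```

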