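# pollinet

Species-based connectivity modelling for urban landscapes: from occurrence
records and land-cover rasters to habitat-suitability surfaces,
circuit-theory current maps, pinch points, and a gap analysis against an
independently supplied (planner-defined) corridor network.

The package is aimed at landscape ecologists and urban planners who want to
compare a *species-based* corridor delineation — grounded in occurrence data
for focal taxa such as bumblebees and grassland butterflies — with corridor
networks drawn up through planning processes. Because the real inputs of such
studies (verified biological records, national land-cover products, planner
corridor layers) are rarely redistributable, the package ships a synthetic-data
generator that emulates all of them with known ground truth, so the entire
pipeline is testable end to end.

## The model

Per species *s*, occurrence probability is modelled by a penalized additive
logistic regression on focal environmental predictors:

    logit p(x) = β₀ + Σⱼ fⱼ(zⱼ(x)) + g(E(x), N(x))

* each `zⱼ` is a focal predictor at 100 m resolution — the proportion of a
  land-cover class (woodland, wetland, arable, grassland, gardens, allotments,
  impervious) within a 100 m radius, or a focal mean (√altitude, population
  density) — standardised to zero mean and unit variance;
* each `fⱼ` is a cubic regression spline with at most 4 effective degrees of
  freedom, carrying both a second-derivative wiggliness penalty and a
  null-space shrinkage penalty (the *double penalty*), so uninformative terms
  are removed from the model entirely;
* `g` is a low-rank radial smooth over the coordinates absorbing residual
  spatial autocorrelation;
* presences are contrasted with background points drawn at 10× the presence
  count, weighted by a kernel density of the presences (to mirror observer
  bias), with observation weights equalising the two classes.

Models are validated by random and spatially blocked 10-fold cross-validation
(AUC, continuous Boyce index, TSS at the maxSSS threshold). The per-species
maps are summed and min–max normalised into one combined suitability map `S`;
its multiplicative inverse `r = 1/max(S, ε)` is the movement-resistance
surface. Contiguous groups of ≥ 2 cells with `S ≥ 0.5` (within 300 m of
another group) become circuit nodes; solving the graph-Laplacian system
`Lv = i` for every node pair yields cumulative current — the circuit-theory
measure of movement probability — and effective resistances. Between
*critical* cores (`S > 0.9`), least-cost corridors are cut at a
cost-weighted-distance cutoff and re-solved in isolation; clusters of ≥ 2
adjacent cells in the top 1 % of current are reported as pinch points. The
top 10 % of cumulative current defines the species-based corridor mask, which
is compared with planner corridor polygons in a four-way gap analysis
(both / species-only / planner-only / neither) validated with independent
records via relative probabilities.

## Worked example

The numbered scripts under `analysis/` run the whole study on the bundled
demo scenario (6.4 km × 6.4 km, 10 m land cover analysed at 100 m, three
pollinator-like species with 200 presence records each, seed 1), writing
artefacts to `results/analysis/`:

```sh
cd analysis
python 01_simulate_landscape.py   # landscape + records + planner polygons
python 02_filter_records.py       # quality filtering, audited vs the ledger
python 03_build_covariates.py     # focal predictors, screening, z-scoring
python 04_fit_suitability.py      # per-species penalized additive models
python 05_validate_models.py      # random + spatially blocked 10-fold CV
python 06_connectivity.py         # combined map, resistance, current
python 07_pinchpoints.py          # corridors between critical cores
python 08_compare_corridors.py    # gap analysis + relative probabilities
```

Output of the demo run (abridged):

```
filtered 672 -> 600 records (10.7% removed)
  audit matches ledger [duplicate]: yes
bombus [random]: AUC 0.74±0.05  Boyce 0.60±0.22  TSS 0.47±0.09
bombus [spatial_block]: AUC 0.74±0.05  Boyce 0.56±0.19  TSS 0.45±0.08
core areas (suitability >= 0.5): 10 groups, 7.65 km2 (18.7% of study area)
critical cores (suitability > 0.9): 3 (0.07 km2)
pinch points (top 1% of corridor current, >= 2 adjacent cells): 2 clusters, 0.06 km2
gap analysis (km2): both 2.6, species_only 1.5, planner_only 24.8, neither 12.0
relative probability of independent presences:
  both: 1.104 ... neither: 0.428
```

Reading this: filtering removed exactly the contamination the generator
injected; the models discriminate presences from KDE-weighted background at
AUC ≈ 0.7 under both validation schemes; ~19 % of the landscape qualifies as
core habitat; and independent presence records are over-represented inside
either corridor network (relative probability > 1) and strongly
under-represented outside both (0.43) — the qualitative signature expected
when both corridor delineations capture real habitat structure.

The same analysis is available as a single call:

```python
from pollinet import PipelineConfig, run_pipeline
results = run_pipeline(PipelineConfig(seed=1, out_dir="results/pipeline"))
```

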