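# Methods

This note records the modelling decisions behind `pollinet`: what each stage
assumes, which parameters matter and why their defaults are what they are,
what the synthetic generator does and does not emulate, and the numerical
choices that keep the pipeline deterministic and testable.

## Study design being emulated

The pipeline reproduces a species-based urban connectivity workflow:
citizen-science occurrence records for a handful of generalist pollinator
taxa are filtered, contrasted against bias-matched background points, and
used to fit per-species habitat-suitability models over a 100 m analysis
grid; the combined suitability surface is inverted into movement resistance;
circuit theory yields current maps between core habitat patches; and the
resulting species-based corridors are compared against an independently
drawn planner corridor network. Real inputs of that design (verified record
archives, 10 m national land cover, census population surfaces, planner
corridor polygons) are proprietary or third-party, so the package treats
them as exchangeable with synthetic stand-ins of the same shape.

## Synthetic study system

`synth.SyntheticScenario` defines the study conditions. Defaults: a
6.4 × 6.4 km extent; 10 m categorical land cover analysed at 100 m (64 × 64
analysis cells); seven land-cover classes with urban-mosaic weights
(impervious 0.25, grassland 0.25, woodland 0.15, gardens 0.15, arable 0.10,
wetland 0.05, allotments 0.05); spatial correlation length 300 m; three
species with 200 presences each; observer-bias strength 1; contamination
fractions 5 % duplicates, 3 % high-uncertainty, 2 % undated, 2 %
out-of-window records (the archives such pipelines ingest typically lose
~5–10 % of records to such defects); record years 2015–2022.

* **Land cover.** One unit-variance Gaussian random field per class
  (white noise smoothed at the stated correlation length, periodic
  boundaries); a cell takes the class whose offset-shifted field is largest,
  with offsets calibrated iteratively so realised class fractions track the
  requested weights to ±0.002 in expectation. This gives patchy, spatially
  coherent mosaics whose focal proportions span (0, 1) — the regime the
  suitability model must handle — at the cost of stylised patch geometry
  (no roads, rivers, or linear features).
* **Elevation and population.** Smooth fields; population is peaked around
  three random "city centres" with multiplicative lognormal noise, giving
  the garden/impervious/population collinearity structure typical of cities.
* **Ground truth suitability.** Per species, a known additive function
  (linear + quadratic terms) of the focal predictors, passed through the
  inverse logit. Default effect sizes are chosen so that habitat genuinely
  structures occurrence: suitability spans ≈ 0.01–0.95 across the landscape
  and a correctly specified model achieves cross-validated AUC ≈ 0.7 against
  KDE-weighted background — the regime reported for real urban pollinator
  models. (Against *uniform* background the same models score higher; the
  KDE contrast is deliberately conservative.)
* **Occurrences.** Presences are drawn over analysis cells with probability
  ∝ suitability × bias surface, then jittered uniformly within the cell;
  the bias surface is a KDE-style bump around the city centres, emulating
  accessibility bias in citizen science. Contaminated rows are appended with
  exactly one defect each, and their counts form a ledger against which the
  filter audit is asserted (the closed-loop test).
* **Planner corridors.** Grassland patches ≥ 0.5 ha (queen-adjacent
  components) are buffered by 300 m and joined by buffered straight
  connectors along the minimum spanning tree of between-patch distances —
  a stand-in for a least-cost habitat network on near-uniform resistance,
  not a re-derivation of any particular planning tool.

What passing tests on this generator show: that every algorithmic stage is
correct and that the pipeline recovers known generating structure at
realistic signal strength. What they cannot show: robustness to the messiness
of real archives (taxonomic error, spatially structured effort that is not a
smooth bump, linear barriers, class imbalance across species).

## Records

Filtering keeps records that are in the year window (2015–2022), carry a
coordinate uncertainty ≤ 100 m (the analysis resolution; *missing*
uncertainty fails the rule, a conservative choice), are dated, and are unique
on (species, x, y, year) — that tuple being the natural duplicate key when
sub-annual dates are unreliable. Removal reasons are counted once each, in
the fixed order year → uncertainty → undated → duplicate; filtering is
idempotent.

Background points are drawn per species (models are per species) at 10× the
presence count, over valid analysis cells with probability proportional to an
isotropic Gaussian KDE of that species' presences at cell centres. The
bandwidth defaults to Silverman's rule on the presence coordinates;
sampling is without replacement when enough cells exist, otherwise with
replacement (flagged). Model-frame weights give each presence weight
n_background/n_presence and each background point weight 1, rescaled to mean
one — total presence weight equals total background weight, neutralising the
10:1 class imbalance.

## Predictors

Focal summaries use a circular disc: a fine cell belongs to an analysis
cell's neighbourhood when its centre lies within 100 m of the analysis-cell
centre (the centre cell always qualifies; at the study edge only in-grid
cells count). Altitude is square-root transformed *after* focal averaging.
Standardisation uses the sample (n−1) standard deviation and stores the
constants for scoring new data. Collinearity screening computes Spearman's ρ
at the model points and groups layers transitively over |ρ| > 0.7 (a chain
A~B~C loses two layers even if A and C are only moderately correlated);
within a group the survivor is the earliest layer in a total preference
order that puts gardens ahead of impervious cover and population density —
gardens being the directly manageable greenspace measure.

## Suitability model

Each univariate smooth is a natural cubic regression spline with 5 knots at
quantiles of the observed predictor (rank 5 ⇒ ≤ 4 effective df), penalized
by the integrated squared second derivative; a second, identity penalty on
the wiggliness penalty's null space (constant + linear) implements double
penalty shrinkage, so a term can leave the model entirely. The spatial smooth
is a thin-plate-kernel (r² log r) radial basis at ~30 k-means centres of the
data coordinates, ridge-penalized at 1/100 of the global multiplier (the
kernel columns are small on the unit-scaled plane; a full-strength ridge
would extinguish the term before the univariate smooths shrink).

Fitting is penalized weighted IRLS with step-halving, so the penalized
deviance is non-increasing; non-convergence and coefficient blow-up
(|β| > 10⁴, indicating separation) raise errors. Smoothing strength is a
single global multiplier on all penalties, selected on a log grid
(10⁻²…10⁵) by 3-fold cross-validated weighted deviance with a
one-standard-error rule (the strongest smoothing within one SE of the
minimum). This is a deliberate simplification of marginal-likelihood (REML)
smoothness selection: it is cheap, deterministic, and sufficient for the
package's validation surface — recovery of the generating linear predictor
(median r > 0.9 at n = 2000) and held-out discrimination — rather than
coefficient-level equality with any external implementation (one test does,
however, cross-check fitted probabilities against an independent
shrinkage-GAM fit, requiring r > 0.95). Effective degrees of freedom per
term are the trace of that term's block of the IRLS hat matrix; terms under
0.1 edf are reported "shrunk out" (a reporting convention, not a refit).

The combined map is the cellwise sum of per-species maps min–max rescaled to
[0, 1] — chosen over division by the species count because the downstream
rules (0.5 / 0.9 thresholds, top-10 %) operate on relative suitability, and
min–max makes the combined scale exactly span the unit interval; the
rescaling is invariant to adding a constant to any single input map.

## Validation

Random k-fold (default k = 10) and spatially blocked CV are both provided.
Spatial blocks are squares allocated whole to folds; the block size should
match the autocorrelation range of the predictors — 5 km in a full-scale
urban region, 1.6 km for the bundled demo extent (6.4 km, 300 m correlation
length), which also guarantees ≥ k non-empty blocks. A repeated 75/25 split
mode is provided separately for designs that quote a single training
fraction; k-fold remains the default. Metrics per fold: rank-based AUC (ties
half), the continuous Boyce index (101 overlapping windows of width 0.1 on
the landscape-score range, zero-expectation windows skipped, Spearman of P/E
against window midpoint), and TSS at the maxSSS threshold with ties broken
toward the smaller threshold; the threshold grid is the union of observed
scores and {0, 0.01, …, 1}. Folds with single-class test sets are skipped
and reported.

## Connectivity

Resistance is the multiplicative inverse r = 1/max(S, ε) with floor
ε = 10⁻³ (so "unsuitable" saturates at resistance 1000 rather than ∞);
r = (1−S)+ε is available as an alternative. The lattice uses queen
(8-neighbour) adjacency with √2 diagonal lengths; edge conductance between
neighbouring cells is 1/(d·(rᵢ+rⱼ)/2) — the mean-resistance convention.
Core areas are queen-connected components of cells ≥ τ (τ = 0.5; critical
cores τ = 0.9) with ≥ 2 cells; groups farther than 300 m
(centre-to-centre) from every other group are dropped — 300 m being the
smallest maximum dispersal distance among the focal taxa. Filtering (rather
than merging nearby groups into super-nodes) is the default; merging is left
to configuration since the two readings answer different questions.

Pair solves collapse each core to a supernode (infinite internal
conductance), ground the target, and factor the reduced Laplacian with
sparse LU; per-cell current is half the sum of absolute currents on incident
edges (core cells excluded); effective resistance is the terminal voltage
difference. Kirchhoff residuals (net current at non-terminal nodes, source
flux) are exposed for auditing and asserted < 10⁻⁹ in tests. Cumulative
current sums all unordered core pairs; a pair subset can be supplied when
the number of cores makes all-pairs impractical.

## Pinch points

Cost-weighted distance uses Dijkstra on the same lattice with edge cost
d·(rᵢ+rⱼ)/2·cellsize. The corridor between two cores is the set of cells
whose summed cost distance to the two cores lies within a cutoff of the
least-cost-path cost; the cutoff defaults to 5 crossing-costs at the mean
landscape resistance (no canonical value exists; it is exposed as a
parameter, and corridors are nested in it). The circuit is re-solved
restricted to corridor cells; pinch points are queen-connected clusters of
≥ 2 cells at or above the 99th percentile of the corridor's finite current
values (percentile over corridor cells, since pinch values exist only
there). Per-pair clusters are merged by union before reporting.

## Corridor comparison

The species-based corridor mask is the top 10 % of cumulative current (ties
at the threshold included). Planner polygons are rasterised by cell-centre
coverage — bit-exact and checkable against a point-in-polygon oracle —
and every valid cell is labelled both / species-only / planner-only /
neither. Relative probabilities divide each category's share of independent
presences by its share of 20,000 background points drawn uniformly over
valid cells (uniform, not KDE-weighted: this is validation of a map, not
model fitting). Pinch clusters count as overlapping the planner network when
any member cell centre falls inside it, and their whole area is then
attributed inside (clusters are counted, not split). Descriptive statistics
report per-category distance-to-centre summaries and fine land-cover
composition.

## Determinism and problem sizes

All randomness descends from one integer seed via numpy seed-sequence
spawning with fixed stream ids, so identical configurations give
byte-identical artefacts. The bundled demo (64 × 64 analysis grid, 3
species, 200 presences each) runs the full pipeline in well under a minute
on one CPU; solver-oracle comparisons use grids up to 20 × 20 against dense
linear algebra, and parameter-recovery checks use 20 replicates of n = 2000
— sizes at which the properties under test are already fully expressed.

## I/O and limitations

Rasters travel as plain-text ESRI ASCII grids written at full double
precision (bit-identical round trips), vectors as GeoJSON (invalid
geometries repaired area-preservingly via `make_valid` or rejected),
records as CSV. The format carries no CRS, so a single projected,
metre-based CRS across all inputs is an assumption, not a checked
invariant; there is no reprojection. Other known limitations: no
anisotropic or directed movement; the smoothing-selection approximation
above; stylised synthetic landscapes; and Shapefile input is not supported
(convert to GeoJSON upstream).
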