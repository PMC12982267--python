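"""Gap analysis between the species-based corridors (top 10% of the
cumulative current map) and the planner corridor polygons, validated with
an independent draw of presence records, plus descriptive statistics and
pinch-point overlap counts."""

import json

import numpy as np

from common import CONFIG, RESULTS
from pollinet import comparison as cp
from pollinet import synth
from pollinet.grid import read_raster, write_raster
from pollinet.pinchpoints import PinchPointCluster
from pollinet.pipeline import read_vector

current = read_raster(RESULTS / "current.asc")
landcover = read_raster(RESULTS / "landcover.asc")
planner = read_vector(RESULTS / "planner_corridors.geojson")

species_mask = cp.top_fraction_mask(current, CONFIG.top_fraction)
grid = current.like(np.zeros(current.shape))
partition = cp.gap_analysis(species_mask, planner, grid)
write_raster(
    grid.like(np.select([partition.labels == c for c in cp.CATEGORIES],
                        [1.0, 2.0, 3.0, 4.0], default=np.nan)),
    RESULTS / "gap_partition.asc",
)
areas = partition.area_km2()

# independent presences: a fresh draw from the same generating truth
scenario = synth.SyntheticScenario(
    seed=CONFIG.seed + 1, extent=CONFIG.extent, fine_res=CONFIG.fine_res,
    analysis_res=CONFIG.analysis_res,
    n_presence_per_species=max(50, CONFIG.n_presence_per_species // 2),
    bias_strength=CONFIG.bias_strength,
    contamination={"duplicate": 0, "uncertain": 0, "undated": 0, "out_of_year": 0},
    year_range=(CONFIG.year_max + 1, CONFIG.year_max + 3),
)
truth = {
    sp: read_raster(RESULTS / f"true_suitability_{sp}.asc")
    for sp in scenario.species
}
independent, _ = synth.generate_occurrences(scenario, truth)
relprob = cp.relative_probability(
    partition, independent, n_background=CONFIG.n_validation_background,
    seed=np.random.default_rng(np.random.SeedSequence([CONFIG.seed, 30])),
)
relprob.to_csv(RESULTS / "relative_probability.csv", index=False)

centre = (CONFIG.extent[0] / 2, CONFIG.extent[1] / 2)
desc = cp.corridor_descriptives(partition, landcover, centre, synth.CLASS_CODES)
desc.to_csv(RESULTS / "corridor_descriptives.csv", index=False)

raw = json.loads((RESULTS / "pinch_clusters.json").read_text())
clusters = [
    PinchPointCluster(cells=np.array(c["cells"]), area_m2=c["area_m2"],
                      max_current=c["max_current"], mean_current=c["mean_current"])
    for c in raw
]
overlap = cp.pinch_overlap(clusters, planner, grid)
(RESULTS / "pinch_overlap.json").write_text(json.dumps(overlap, indent=1))

print("gap analysis (km2): " + ", ".join(f"{k} {v:.1f}" for k, v in areas.items()))
print("relative probability of independent presences:")
for _, row in relprob.iterrows():
    print(f"  {row['category']}: {row['ratio']:.3f}")
print(f"pinch clusters inside planner corridors: {overlap['n_in']} "
      f"({overlap['area_in_km2']:.2f} km2); outside: {overlap['n_out']} "
      f"({overlap['area_out_km2']:.2f} km2)")
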