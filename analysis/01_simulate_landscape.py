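"""Generate the synthetic study system: land cover, elevation, population,
per-species ground-truth suitability, occurrence records with a known
contamination ledger, and planner-style corridor polygons.

Everything downstream is conditioned on these artefacts; the ledger is
kept so step 02 can be audited against it."""

import json

from common import CONFIG, ensure_results
from pollinet import synth
from pollinet.grid import write_raster
from pollinet.pipeline import write_vector

out = ensure_results()
scenario = synth.SyntheticScenario(
    seed=CONFIG.seed,
    extent=CONFIG.extent,
    fine_res=CONFIG.fine_res,
    analysis_res=CONFIG.analysis_res,
    n_presence_per_species=CONFIG.n_presence_per_species,
    bias_strength=CONFIG.bias_strength,
    year_range=(CONFIG.year_min, CONFIG.year_max),
)

landcover, elevation, population = synth.generate_landscape(scenario)
for name, grid in [("landcover", landcover), ("elevation", elevation), ("population", population)]:
    write_raster(grid, out / f"{name}.asc")

predictors = synth.true_predictors(scenario, landcover, elevation, population)
truth = {}
for sp in scenario.species:
    truth[sp] = synth.true_suitability(
        landcover, elevation, population, scenario.true_coefficients, sp,
        predictors=predictors,
    )
    write_raster(truth[sp], out / f"true_suitability_{sp}.asc")

table, ledger = synth.generate_occurrences(scenario, truth)
table.to_csv(out / "occurrences_raw.csv", index=False)
(out / "contamination_ledger.json").write_text(json.dumps(ledger, indent=1))

planner = synth.generate_planner_corridors(
    landcover, min_patch_ha=CONFIG.planner_min_patch_ha, buffer_m=CONFIG.planner_buffer_m
)
write_vector(planner, out / "planner_corridors.geojson")

print(f"landscape: {landcover.shape} fine cells at {landcover.cell_size:.0f} m")
print(f"records: {ledger['n_total']} total, {ledger['n_clean']} clean "
      f"(+{ledger['duplicate']} dup, +{ledger['uncertain']} uncertain, "
      f"+{ledger['undated']} undated, +{ledger['out_of_year']} out-of-year)")
print(f"planner corridors: {len(planner)} polygons")
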