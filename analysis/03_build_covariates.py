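"""Build the 100 m predictor stack from the fine rasters: focal class
proportions, square-root focal-mean altitude, focal-mean population
density; screen collinear layers by Spearman rank correlation at the
record locations; and standardise what remains."""

import json

from common import CONFIG, RESULTS, PREDICTORS
from pollinet import covariates as cov
from pollinet.grid import RasterGrid, read_raster, write_raster
from pollinet.pipeline import read_records
from pollinet.synth import CLASS_CODES

import numpy as np

landcover = read_raster(RESULTS / "landcover.asc")
elevation = read_raster(RESULTS / "elevation.asc")
population = read_raster(RESULTS / "population.asc")
records = read_records(RESULTS / "occurrences_filtered.csv")

n = int(round(CONFIG.extent[1] / CONFIG.analysis_res))
m = int(round(CONFIG.extent[0] / CONFIG.analysis_res))
analysis = RasterGrid(np.zeros((n, m)), CONFIG.analysis_res)

layers = {
    name: cov.focal_proportion(landcover, [CLASS_CODES[name]], analysis,
                               radius_m=CONFIG.focal_radius_m)
    for name in CLASS_CODES
}
layers["alt"] = cov.focal_mean(elevation, analysis, CONFIG.focal_radius_m, transform="sqrt")
layers["popdensity"] = cov.focal_mean(population, analysis, CONFIG.focal_radius_m)
raw = cov.PredictorStack({k: layers[k] for k in PREDICTORS})

retained, rho = cov.correlation_screen(
    raw, records["x"].to_numpy(), records["y"].to_numpy(),
    rho_threshold=CONFIG.rho_threshold,
)
stack = cov.standardise(raw.subset(retained))
for name, grid in stack.layers.items():
    write_raster(grid, RESULTS / f"predictor_{name}.asc")
manifest = {
    "layers": retained,
    "constants": {k: list(v) for k, v in stack.constants.items()},
    "spearman": rho,
}
(RESULTS / "stack_manifest.json").write_text(json.dumps(manifest, indent=1))

dropped = [p for p in PREDICTORS if p not in retained]
print(f"predictors retained after |rho|>{CONFIG.rho_threshold} screen: {retained}")
print(f"dropped as collinear: {dropped if dropped else 'none'}")
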