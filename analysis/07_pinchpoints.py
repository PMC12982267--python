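"""Pinch-point analysis between critical core areas (suitability > 0.9):
least-cost corridors, circuit solves restricted to each corridor, and
top-1% current clusters of two or more adjacent cells."""

import json

from common import CONFIG, RESULTS
from pollinet import connectivity as cn
from pollinet import pinchpoints as pp
from pollinet.grid import read_raster, write_raster

combined = read_raster(RESULTS / "suitability_combined.asc")
surface = cn.ResistanceSurface(read_raster(RESULTS / "resistance.asc"),
                               CONFIG.resistance_epsilon)

clusters, critical, pinch_current = pp.pinch_point_analysis(
    surface, combined, tau_critical=CONFIG.tau_critical,
    percentile=CONFIG.pinch_percentile, min_cells=CONFIG.core_min_cells,
    link_dist_m=CONFIG.link_dist_m,
)
write_raster(pinch_current, RESULTS / "pinch_current.asc")
(RESULTS / "pinch_clusters.json").write_text(json.dumps([
    {
        "cells": c.cells.tolist(),
        "area_m2": c.area_m2,
        "max_current": c.max_current,
        "mean_current": c.mean_current,
    }
    for c in clusters
], indent=1))

area_km2 = sum(c.area_m2 for c in clusters) / 1e6
print(f"critical cores (suitability > {CONFIG.tau_critical}): {critical.n_groups} "
      f"({critical.area_km2():.2f} km2)")
print(f"pinch points (top {100 - CONFIG.pinch_percentile:.0f}% of corridor current, "
      f">= {CONFIG.core_min_cells} adjacent cells): {len(clusters)} clusters, "
      f"{area_km2:.2f} km2")
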