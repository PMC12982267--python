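"""Draw KDE-weighted background points and fit the per-species penalized
additive logistic suitability models; predict each species' map and
report which terms survived shrinkage."""

import json

import numpy as np

from common import CONFIG, RESULTS
from pollinet import records as rec
from pollinet import suitability
from pollinet.covariates import PredictorStack
from pollinet.grid import read_raster, write_raster
from pollinet.pipeline import read_records

manifest = json.loads((RESULTS / "stack_manifest.json").read_text())
retained = manifest["layers"]
stack = PredictorStack(
    {name: read_raster(RESULTS / f"predictor_{name}.asc") for name in retained},
    {k: tuple(v) for k, v in manifest["constants"].items()},
)
filtered = read_records(RESULTS / "occurrences_filtered.csv")
presences = filtered[filtered["is_presence"]]

rng = np.random.default_rng(np.random.SeedSequence([CONFIG.seed, 10]))
background = rec.kde_background(
    presences, stack.grid, multiplier=CONFIG.background_multiplier, seed=rng
)
background.to_csv(RESULTS / "background.csv", index=False)

for i, sp in enumerate(sorted(presences["species"].unique())):
    frame = rec.assemble_model_frame(
        presences[presences["species"] == sp],
        background[background["species"] == sp],
        stack,
    )
    seed = int(np.random.default_rng(np.random.SeedSequence([CONFIG.seed, 20 + i])).integers(2**31))
    model = suitability.fit_model(
        frame, retained, species=sp, df_max=CONFIG.df_max,
        spatial_rank=CONFIG.spatial_rank, seed=seed,
        standardisation={k: stack.constants[k] for k in retained},
    )
    (RESULTS / f"model_{sp}.json").write_text(model.to_json())
    write_raster(suitability.predict_map(model, stack), RESULTS / f"suitability_{sp}.asc")
    kept = [t for t in retained if t not in model.shrunk_out]
    print(f"{sp}: deviance {model.deviance:.1f}, terms kept {kept}, "
          f"shrunk out {model.shrunk_out or 'none'}")
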