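"""Random and spatially blocked 10-fold cross-validation of each species
model, reporting AUC, the continuous Boyce index, and TSS at the maxSSS
threshold (mean +- SD across folds)."""

import json

import numpy as np
import pandas as pd

from common import CONFIG, RESULTS
from pollinet import evaluation as ev
from pollinet import records as rec
from pollinet import suitability
from pollinet.covariates import PredictorStack
from pollinet.grid import read_raster
from pollinet.pipeline import read_records

manifest = json.loads((RESULTS / "stack_manifest.json").read_text())
retained = manifest["layers"]
stack = PredictorStack(
    {name: read_raster(RESULTS / f"predictor_{name}.asc") for name in retained},
    {k: tuple(v) for k, v in manifest["constants"].items()},
)
filtered = read_records(RESULTS / "occurrences_filtered.csv")
presences = filtered[filtered["is_presence"]]
background = pd.read_csv(RESULTS / "background.csv")

rows = []
for i, sp in enumerate(sorted(presences["species"].unique())):
    frame = rec.assemble_model_frame(
        presences[presences["species"] == sp],
        background[background["species"] == sp],
        stack,
    )
    seed = int(np.random.default_rng(np.random.SeedSequence([CONFIG.seed, 20 + i])).integers(2**31))

    def fit(train, _sp=sp, _seed=seed):
        return suitability.fit_model(
            train, retained, species=_sp, df_max=CONFIG.df_max,
            spatial_rank=CONFIG.spatial_rank, seed=_seed,
            standardisation={k: stack.constants[k] for k in retained},
        )

    def score(model, test):
        data = {p: test[p].to_numpy(float) for p in retained}
        return model.predict(data, test["x"].to_numpy(float), test["y"].to_numpy(float))

    for mode in ("random", "spatial_block"):
        folds = ev.make_folds(frame, mode=mode, k=CONFIG.k_folds,
                              block_size_m=CONFIG.block_size_m, seed=seed)
        report = ev.cross_validate(frame, folds, fit, score)
        s = report.summary
        rows.append({
            "species": sp, "mode": mode,
            "auc_mean": s["auc"][0], "auc_sd": s["auc"][1],
            "boyce_mean": s["boyce"][0], "boyce_sd": s["boyce"][1],
            "tss_mean": s["tss"][0], "tss_sd": s["tss"][1],
            "threshold_mean": s["threshold"][0],
            "n_skipped_folds": len(report.skipped_folds),
        })
        print(f"{sp} [{mode}]: AUC {s['auc'][0]:.2f}±{s['auc'][1]:.2f}  "
              f"Boyce {s['boyce'][0]:.2f}±{s['boyce'][1]:.2f}  "
              f"TSS {s['tss'][0]:.2f}±{s['tss'][1]:.2f}")

pd.DataFrame(rows).to_csv(RESULTS / "cross_validation.csv", index=False)
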