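"""Shared paths and configuration for the numbered analysis scripts.

Each script reads the artefacts of its predecessors from RESULTS and
writes its own there, so the sequence 01..08 can be run step by step (or
compared against the one-shot `pollinet.run_pipeline`, which executes the
same library calls)."""

from pathlib import Path

from pollinet import PipelineConfig

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results" / "analysis"

CONFIG = PipelineConfig(seed=1, out_dir=str(RESULTS))

PREDICTORS = ["wood", "wet", "arable", "grass", "garden", "allot", "imperv",
              "alt", "popdensity"]


def ensure_results() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
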