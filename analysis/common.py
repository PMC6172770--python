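"""Shared paths and configuration for the numbered analysis drivers.

The heavyweight run directory (reads, alignments) lives under scratch/;
only small summary tables are copied into results/.
"""

from pathlib import Path

from thawvir.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parent.parent
RUN_DIR = ROOT / "scratch" / "demo_run"
RESULTS = ROOT / "results"
SEED = 1


def default_config() -> PipelineConfig:
    return PipelineConfig(seed=SEED)


def ensure_dirs() -> None:
    RUN_DIR.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
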