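import numpy as np
import pytest

from thawvir.pipeline import PipelineConfig, run_pipeline
from thawvir.synthio import CommunityConfig, random_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(20140716)


@pytest.fixture
def random_seq(rng):
    def make(n, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        return random_sequence(r, n)

    return make


def small_pipeline_config(seed: int = 5) -> PipelineConfig:
    """A scaled-down scenario for fast pipeline-level tests."""
    cfg = PipelineConfig(seed=seed)
    cfg.community = CommunityConfig(
        votus_per_habitat=4,
        overlaps={("palsa", "bog"): 1, ("bog", "fen"): 1, ("palsa", "fen"): 0},
        genome_length_range=(6_000, 9_000),
        seed=seed,
    )
    cfg.reads.reads_per_habitat = {"palsa": 4_000, "bog": 2_500, "fen": 1_200}
    cfg.reads.replicates = 1
    cfg.hosts.host_length = 15_000
    cfg.genes.n_clusters = 2
    return cfg


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run at the default study-emulating conditions.

    Session-scoped: the end-to-end recovery checks all read from this run.
    """
    outdir = tmp_path_factory.mktemp("default_run")
    return run_pipeline(PipelineConfig(seed=123), outdir)
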