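import numpy as np
import pytest

from orfamily.pipeline import PipelineConfig, run_pipeline
from orfamily.synthetic import SynthConfig, build_dataset

SMALL_SYNTH = dict(
    n_chromosomes=2, chrom_length=6_000_000, n_intact=20, n_truncated=5,
    n_pseudo=2, n_clusters=3,
    dup_events=[(0, 0.30, 0.10), (1, 0.20, 0.08), (2, 0.10, 0.25)],
)


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic study shared across tests (fixed seed)."""
    return build_dataset(SynthConfig(seed=7, **SMALL_SYNTH))


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One full pipeline run on the small synthetic study."""
    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = PipelineConfig(
        outdir=str(outdir), seed=7,
        synth={k: ([list(e) for e in v] if k == "dup_events" else v)
               for k, v in SMALL_SYNTH.items()})
    report, artifacts = run_pipeline(cfg)
    return cfg, report, artifacts


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
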