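import numpy as np
import pytest

from silencerkit.pipeline import run_demo
from silencerkit.simulate import SimulationConfig


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full demo pipeline run on generator defaults, shared by
    integration and acceptance tests (seed fixed for reproducibility)."""
    out = tmp_path_factory.mktemp("demo")
    return run_demo(out, seed=1, n_perm=300)


@pytest.fixture(scope="session")
def small_config():
    """Compact simulation config for per-test synthetic runs."""
    return SimulationConfig(seed=11, n_chroms=2, chrom_length=10_000_000,
                            n_peaks=400, n_genes=240, methylation_run=1000)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
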