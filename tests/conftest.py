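import numpy as np
import pytest

from famreg import cli
from famreg.synthetic_data import SynthConfig, generate


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """Seeded 10-gene dataset with 4 planted binding sites."""
    config = SynthConfig(
        n_chroms=2, n_genes=10, n_planted_e2fat=4,
        n_tf=2, n_targets=3, n_true_edges=2, seed=7,
    )
    outdir = tmp_path_factory.mktemp("synth_small")
    paths, truth = generate(config, outdir)
    return config, paths, truth


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("demo")
    report = cli.make_demo(42, outdir)
    return outdir, report


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
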