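import numpy as np
import pytest

import venomscaffold as vs


@pytest.fixture(scope="session")
def default_fixture():
    """Default synthetic study: 5 family cohorts x 25 members, 10%
    divergence, 20% decoys."""
    cfg = vs.SimConfig(seed=11)
    records, refs, truth, counts = vs.generate(cfg)
    return cfg, records, refs, truth, counts


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small on-disk fixture (FASTA per dataset, counts TSV, truth)."""
    out = tmp_path_factory.mktemp("fixture")
    cfg = vs.SimConfig(seed=3, n_per_family=6)
    paths = vs.make_dataset(cfg, out)
    return cfg, paths


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
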