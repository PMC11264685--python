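import numpy as np
import pytest

from talocus.align import ScoringScheme
from talocus.synthio import default_templates


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme().calibrated()


@pytest.fixture(scope="session")
def unit_scheme():
    """+1/-1 scoring with closed-form lambda = ln 3."""
    return ScoringScheme(1, -1, 5, 2, word_size=4).calibrated()


@pytest.fixture(scope="session")
def template():
    return default_templates()[0]


@pytest.fixture(scope="session")
def query(template):
    return template.as_query()


def random_dna(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def noise_free_pangenome(tmp_path_factory, template):
    """Small noise-free pan-genome shared across locus/CLI tests."""
    from talocus.synthio import generate_pangenome, default_mix

    out = tmp_path_factory.mktemp("pg")
    return generate_pangenome(15, default_mix(), None, [template], seed=11,
                              out_dir=out)
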