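import numpy as np
import pytest

from ecoscope import synthetic_data as sd
from ecoscope.tables_io import read_newick
from ecoscope.pipeline_cli import make_fixture


@pytest.fixture
def balanced4():
    """Four-tip balanced tree with unit branches."""
    return read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def yule50():
    return sd.simulate_tree(50, birth_rate=1.0, seed=17)


@pytest.fixture(scope="session")
def fixture_data(tmp_path_factory):
    """The bundled small dataset: 20 libraries, 12 lineages, 60 OTUs, 60-tip tree."""
    out = tmp_path_factory.mktemp("fixture")
    table, metadata, taxonomy, tree, truth = make_fixture(out, seed=7)
    return {
        "dir": out,
        "table": table,
        "metadata": metadata,
        "taxonomy": taxonomy,
        "tree": tree,
        "truth": truth,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
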