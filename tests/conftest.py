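import pytest
from hypothesis import HealthCheck, settings

from oncomatch import (
    build_indexes,
    neoplasm_subset,
    parse_drug_catalog,
    parse_mesh_tree,
    parse_sif,
)
from oncomatch import fixtures

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def workspace(tmp_path_factory):
    """A complete synthetic demo workspace (all six input files)."""
    out = tmp_path_factory.mktemp("workspace")
    return fixtures.make_all(out, seed=7)


@pytest.fixture(scope="session")
def vocab(workspace):
    return neoplasm_subset(parse_mesh_tree(workspace["mesh"]))


@pytest.fixture(scope="session")
def catalog(workspace, vocab):
    return build_indexes(parse_drug_catalog(workspace["catalog"]), vocab)


@pytest.fixture(scope="session")
def graph(workspace):
    return parse_sif([workspace["sif_reactome"], workspace["sif_pid"]])
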