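import pytest

from tricksterbiogeo.synthetic_data import default_config, generate_world


@pytest.fixture(scope="session")
def world():
    """The frozen default synthetic world (16 categories, seed 1)."""
    return generate_world(default_config(seed=1))


@pytest.fixture(scope="session")
def world_files(world, tmp_path_factory):
    """The default world written to disk (occurrences CSV, surface CSV, truth)."""
    from tricksterbiogeo.synthetic_data import write_world

    out = tmp_path_factory.mktemp("world")
    return write_world(world, out)
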