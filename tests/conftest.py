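import pytest

from assemblyline.config import RunConfig
from assemblyline.design import Strategy, parse_design
from assemblyline.fixtures import FixtureSpec, chromoprotein_like_fixture, generate_design


@pytest.fixture
def small_design(tmp_path):
    """A 1-construct, 2-fragment design (the minimal PCR workflow input)."""
    spec = FixtureSpec(n_assemblies=1, fragments_per_assembly=2, seed=3)
    path, manifest = generate_design(spec, tmp_path / "small")
    return path, manifest


@pytest.fixture
def small_bundle(small_design):
    path, _ = small_design
    return parse_design(path)


@pytest.fixture
def chromo_gg(tmp_path):
    """Chromoprotein-panel-like fixture: 7 PCRs, 4 constructs x 4 pieces,
    3 shared backbone pieces, Golden Gate strategy."""
    path, manifest = chromoprotein_like_fixture(tmp_path / "gg", Strategy.GOLDEN_GATE)
    return parse_design(path, Strategy.GOLDEN_GATE), manifest


@pytest.fixture
def chromo_aqua(tmp_path):
    path, manifest = chromoprotein_like_fixture(tmp_path / "aqua", Strategy.AQUA)
    return parse_design(path, Strategy.AQUA), manifest


@pytest.fixture
def config():
    return RunConfig()
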