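import pytest

from gffmend.config import Config, default_config_path
from gffmend.naming import assign_names
from gffmend.parser import parse_gff
from gffmend.rules import apply_all
from gffmend.simulate import generate, small_spec


@pytest.fixture(scope="session")
def default_cfg():
    return Config.load(str(default_config_path()))


@pytest.fixture(scope="session")
def bundle():
    """A small but structurally diverse synthetic genome: 20 genes over two
    scaffolds, mixed strands, a quarter single-exon."""
    return generate(small_spec(seed=11, genes=20))


@pytest.fixture(scope="session")
def truth_graph(bundle, default_cfg):
    """The truth annotation parsed and normalised (multiline CDS merged)."""
    graph = parse_gff(bundle.gff3.splitlines(True))
    apply_all(graph, default_cfg.rules())
    assign_names(graph, default_cfg)
    return graph
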