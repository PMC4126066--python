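import io

import pytest

from mutenrich import build_index, make_hcm_fixture, parse_gaf, parse_obo

CHAIN_OBO = """format-version: 1.2
ontology: test

[Term]
id: T:0001
name: root
namespace: biological_process

[Term]
id: T:0002
name: middle
namespace: biological_process
is_a: T:0001

[Term]
id: T:0003
name: leaf
namespace: biological_process
is_a: T:0002
"""

DIAMOND_OBO = """format-version: 1.2
ontology: test

[Term]
id: D:0001
name: root
namespace: biological_process

[Term]
id: D:0002
name: left
namespace: biological_process
is_a: D:0001

[Term]
id: D:0003
name: right
namespace: biological_process
is_a: D:0001

[Term]
id: D:0004
name: bottom
namespace: biological_process
is_a: D:0002
is_a: D:0003
"""


def gaf_row(gene, term, evidence="IEA", qualifier="", aspect="P"):
    cols = ["DB", gene, gene, qualifier, term, "REF:1", evidence, "", aspect,
            "", "", "gene", "taxon:9606", "20121004", "DB", "", ""]
    return "\t".join(cols)


@pytest.fixture
def chain_graph():
    return parse_obo(io.StringIO(CHAIN_OBO))


@pytest.fixture
def diamond_graph():
    return parse_obo(io.StringIO(DIAMOND_OBO))


@pytest.fixture
def chain_index(chain_graph):
    gaf = "!gaf-version: 2.1\n" + "\n".join(
        [gaf_row("geneA", "T:0003"), gaf_row("geneB", "T:0002")]
    )
    annotations, _ = parse_gaf(io.StringIO(gaf))
    return build_index(annotations, chain_graph)


@pytest.fixture(scope="session")
def hcm():
    """(cohort, graph, index) of the deterministic case-study fixture."""
    return make_hcm_fixture()
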