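import pytest

from trnaflux import geneset, wobble


@pytest.fixture(scope="session")
def sbw25_genes():
    return geneset.load_sbw25()


@pytest.fixture(scope="session")
def sbw25_types(sbw25_genes):
    return geneset.group_types(sbw25_genes)


@pytest.fixture(scope="session")
def sbw25_matrix(sbw25_types):
    return wobble.build_match_matrix(sbw25_types, wobble.default_rules())


@pytest.fixture(scope="session")
def deletion_types(sbw25_genes):
    """The serCGA-deletion gene set: 65 genes, 38 types."""
    genes = [g for g in sbw25_genes if g.locus_id != "serCGA"]
    return geneset.group_types(genes)
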