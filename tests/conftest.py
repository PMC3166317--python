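import pytest

from eblnkit import synthetic_data as sd

#: 6-taxon primate-like species topology; branch lengths in expected
#: substitutions per codon
PRIMATE_NEWICK = (
    "((((human:0.02,chimp:0.02)hc:0.01,gorilla:0.03)hcg:0.02,"
    "orangutan:0.05)hcgo:0.03,macaque:0.08,marmoset:0.25);"
)


@pytest.fixture(scope="session")
def primate_newick() -> str:
    return PRIMATE_NEWICK


@pytest.fixture(scope="session")
def primate_tree():
    from eblnkit.codon_ml import PhyloTree

    return PhyloTree.from_newick(PRIMATE_NEWICK)


@pytest.fixture()
def stop_free_300():
    return sd.random_stop_free_sequence(300, seed=42, id="anc300")
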