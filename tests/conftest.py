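import pytest

from regionstrat import default_ladder, load_substitution_matrix


@pytest.fixture(scope="session")
def blosum():
    return load_substitution_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def ladder():
    return default_ladder()


@pytest.fixture
def toy_tree_text():
    """Small rooted NHX tree: mammals + chicken + yeast, one duplication."""
    return (
        "(((((human|P1:1,mouse|P2:1)n1[&&NHX:D=N:T=Mammalia]:1,"
        "(human|P1b:1,mouse|P2b:1)n2[&&NHX:D=N:T=Mammalia]:1)"
        "d1[&&NHX:D=Y:T=Mammalia]:1,chicken|P3:1)n3[&&NHX:D=N:T=Amniota]:1,"
        "zebrafish|P4:1)n4[&&NHX:D=N:T=Vertebrata]:1,yeast|P5:1)"
        "root[&&NHX:D=N:T=Opisthokonta];"
    )


@pytest.fixture
def toy_tree(tmp_path, toy_tree_text):
    from regionstrat import read_gene_tree

    p = tmp_path / "toy.nhx"
    p.write_text(toy_tree_text + "\n")
    return read_gene_tree(p)
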