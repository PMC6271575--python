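import pytest

from molclas import WeightScheme, load_table1, similarity_matrix


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table1_vectors(table1):
    return [r.vector for r in table1]


@pytest.fixture(scope="session")
def raw_matrix(table1_vectors, table1):
    w = WeightScheme.equal(6, 0.5)
    return similarity_matrix(table1_vectors, w, tuple(r.name for r in table1))
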