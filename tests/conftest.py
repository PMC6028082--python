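import pytest

from mims18o.synthetic import build_layout, standard_conditions


@pytest.fixture(scope="session")
def conditions():
    """Standard assay conditions: pH 7.4, 16 degC, 25 mM species, 2 mL."""
    return standard_conditions()


@pytest.fixture(scope="session")
def caix_ghost():
    return build_layout("CAIX")


@pytest.fixture(scope="session")
def caxii_ghost():
    return build_layout("CAXII")
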