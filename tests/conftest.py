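import pytest

from famasym.asymmetry import load_sister_study_table


@pytest.fixture(scope="session")
def sister_table():
    return load_sister_study_table()
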