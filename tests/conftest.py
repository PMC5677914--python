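import pytest

from pgxcall.panel import (default_panel, default_star_table,
                           load_actionability_rules, load_genotype_phenotypes)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def stars(panel):
    return default_star_table(panel)


@pytest.fixture(scope="session")
def rules():
    return load_actionability_rules()


@pytest.fixture(scope="session")
def geno_table():
    return load_genotype_phenotypes()
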