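import pytest
from hypothesis import HealthCheck, settings

from sargmito import (GeneratorConfig, build_references, generate_cohort,
                      layout_genes, load_primer_panel, load_variant_table)
from sargmito.assay import derive_diagnostic_profile

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def variant_table():
    return load_variant_table()


@pytest.fixture(scope="session")
def primer_panel():
    return load_primer_panel()


@pytest.fixture(scope="session")
def config():
    return GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def layout(variant_table, config, primer_panel):
    return layout_genes(variant_table, config, primer_panel)


@pytest.fixture(scope="session")
def references(layout, variant_table, config):
    genomes, annotation = build_references(layout, variant_table, config)
    return genomes, annotation


@pytest.fixture(scope="session")
def genomes(references):
    return references[0]


@pytest.fixture(scope="session")
def by_form(genomes):
    return {g.form: g for g in genomes}


@pytest.fixture(scope="session")
def annotation(references):
    return references[1]


@pytest.fixture(scope="session")
def profiles(genomes, primer_panel, variant_table):
    return derive_diagnostic_profile(genomes, primer_panel, variant_table)


@pytest.fixture(scope="session")
def cohort(genomes, primer_panel, config):
    return generate_cohort(genomes, primer_panel, config)
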