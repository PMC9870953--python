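import pytest

from kelppop.haplotypes import collapse_haplotypes, complete_deletion
from kelppop.synthetic import make_paper_fixture


@pytest.fixture(scope="session")
def paper_fixture():
    """The deterministic 119 x 658 bp study fixture (alignment, partition, manifest)."""
    return make_paper_fixture(seed=1)


@pytest.fixture(scope="session")
def fixture_table(paper_fixture):
    """Collapsed haplotype table + site filter for the study fixture."""
    seqs, partition, manifest = paper_fixture
    filtered, site_filter = complete_deletion(seqs)
    table = collapse_haplotypes(filtered, partition)
    return table, site_filter, manifest


@pytest.fixture(scope="session")
def hap_ids_by_label(fixture_table):
    """Map the fixture's haplotype labels (H1, H12, ...) to assigned hap ids."""
    table, _, manifest = fixture_table
    return {label: table.hap_ids[i] for i, label in enumerate(manifest["expected_order"])}
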