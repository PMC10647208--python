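import pytest

from asvdb import PrimerPair, FixtureSpec, generate


@pytest.fixture(scope="session")
def ef1a_primers():
    """Fusarium EF1-alpha pair (non-degenerate, length 20 each)."""
    return PrimerPair("CCGGTCACTTGATCTACCAG", "ATGACGGTGACATAGTAGCG",
                      threshold=0.9, keep_primers=False)


@pytest.fixture(scope="session")
def v4v5_primers():
    """16S V4-V5 pair: degenerate, exercises IUPAC matching."""
    return PrimerPair("GTGYCAGCMGCCGCGGTAA", "CCGYCAATTYMTTTRAGTTT",
                      threshold=0.9, keep_primers=False)


@pytest.fixture(scope="session")
def small_fixture(ef1a_primers):
    """3 species x 2 records, one shared amplicon, some noise records."""
    spec = FixtureSpec(genus="Fusarium", n_species=3, n_records_per_species=2,
                       n_shared_amplicons=1, insert_length=50, flank_length=25,
                       offgenus_fraction=0.2, unwanted_taxa_fraction=0.2,
                       seed=7)
    return spec, generate(spec, ef1a_primers)
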