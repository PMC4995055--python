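import pytest

from mitokit import packaged_annotation_path
from mitokit.genome_model import read_feature_table
from mitokit.synthetic import default_spec, generate_mitogenome


@pytest.fixture(scope="session")
def whitefly_table():
    """The packaged whitefly annotation table (36 genes + CR, 15,220 bp)."""
    return read_feature_table(packaged_annotation_path())


@pytest.fixture(scope="session")
def synthetic_genome():
    """One default whitefly-like synthetic mitogenome (fixed seed)."""
    return generate_mitogenome(default_spec(seed=101))


@pytest.fixture(scope="session")
def synthetic_cr(synthetic_genome):
    from mitokit.genome_model import extract_sequence

    g = synthetic_genome
    return extract_sequence(g.sequence, g.annotation.get("CR"))
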