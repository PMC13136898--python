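import pytest

from prosplice.fixtures import make_genome_and_annotation
from prosplice.genome_model import read_annotation, read_genome

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("fixture")
    make_genome_and_annotation(d, seed=FIXTURE_SEED)
    return d


@pytest.fixture(scope="session")
def fx(fixture_dir):
    # regenerate in memory (deterministic) so manifest includes digested extras
    from prosplice.fixtures import build_fixture, digest_and_sample_peptides
    import tempfile

    fx = build_fixture(seed=FIXTURE_SEED)
    with tempfile.TemporaryDirectory() as d:
        digest_and_sample_peptides(fx, d, seed=FIXTURE_SEED)
    return fx


@pytest.fixture(scope="session")
def genome(fixture_dir):
    return read_genome(fixture_dir / "genome.fa")


@pytest.fixture(scope="session")
def models(fixture_dir, genome):
    return read_annotation(fixture_dir / "annotation.gff3", genome)


@pytest.fixture(scope="session")
def models_by_id(models):
    return {t.transcript_id: t for t in models}


@pytest.fixture(scope="session")
def proteins(models):
    return {t.transcript_id: t.protein_sequence for t in models if t.protein_sequence}
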