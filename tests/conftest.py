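import pytest

from codonuse import (
    CodingSequence,
    SyntheticSpec,
    count_codons,
    generate_corpus,
    write_fasta,
)


@pytest.fixture(scope="session")
def small_corpus():
    """A 19-sequence synthetic corpus with its generation ground truth."""
    spec = SyntheticSpec(n_sequences=19, length_range=(801, 2400), seed=11)
    return generate_corpus(spec)


@pytest.fixture(scope="session")
def corpus_fasta(small_corpus, tmp_path_factory):
    seqs, _ = small_corpus
    path = tmp_path_factory.mktemp("data") / "corpus.fasta"
    write_fasta(seqs, path)
    return path


@pytest.fixture
def mini_cds():
    return CodingSequence(id="mini", sequence="ATGTTTTAA")


@pytest.fixture
def mini_counts(mini_cds):
    return count_codons(mini_cds)
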