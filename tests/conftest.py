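import pytest

from comention.corpus_io import CoMentionRecord, Lexicon
from comention.preprocessing import PreprocessConfig, Preprocessor
from comention.synthetic import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic dataset shared by read-only tests."""
    cfg = SynthConfig(
        n_proteins=10,
        n_phenotypes=10,
        n_labeled=120,
        n_unlabeled=150,
        n_test=80,
        signal_strength=1.0,
        label_noise=0.0,
        seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_preprocessor(small_dataset):
    pre = Preprocessor(small_dataset.proteins, small_dataset.phenotypes, PreprocessConfig(max_len=40))
    pre.fit_vocab(small_dataset.labeled)
    return pre


@pytest.fixture
def tiny_lexicons():
    proteins = Lexicon(kind="protein", entries={"P1": ("BRCA1",), "P2": ("TP53", "tumor protein p53")})
    phenotypes = Lexicon(kind="phenotype", entries={"H1": ("breast cancer",), "H2": ("cancer",)})
    return proteins, phenotypes


def make_record(
    sentence="BRCA1 causes breast cancer.",
    protein_span=(0, 5),
    phenotype_span=(13, 26),
    **kwargs,
):
    defaults = dict(
        doc_id="d1",
        sentence_index=0,
        sentence=sentence,
        protein_id="P1",
        protein_span=protein_span,
        phenotype_id="H1",
        phenotype_span=phenotype_span,
    )
    defaults.update(kwargs)
    return CoMentionRecord(**defaults)
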