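import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comention.corpus_io import Lexicon
from comention.preprocessing import (
    PAD_ID,
    UNK_ID,
    PreprocessConfig,
    SplitConfig,
    Vocabulary,
    build_vocab,
    encode_pad,
    mask_entities,
    stratified_split,
    tokenize,
)

from conftest import make_record

BRCA_SENTENCE = (
    "BRCA1, BRCA2, PALB2 and RAD51C should be included in the genetic testing "
    "panel of breast cancer patients in Argentina."
)


class TestMaskEntities:
    def test_forced_substitution(self):
        proteins = Lexicon(kind="protein", entries={"P1": ("BRCA1",)})
        phenotypes = Lexicon(kind="phenotype", entries={"H1": ("breast cancer",)})
        rec = make_record(sentence=BRCA_SENTENCE, protein_span=(0, 5), phenotype_span=(85, 98))
        masked = mask_entities(rec, proteins, phenotypes)
        assert masked == (
            "PROT, BRCA2, PALB2 and RAD51C should be included in the genetic testing "
            "panel of PHENO patients in Argentina."
        )

    def test_sentinels_literally_present(self):
        proteins = Lexicon(kind="protein", entries={"P1": ("AML1",)})
        phenotypes = Lexicon(kind="phenotype", entries={"H1": ("Acute myeloid leukemia",)})
        sentence = "Heterozygous mutations in patients with Acute myeloid leukemia (AML), the fusion gene AML1-ETO."
        rec = make_record(sentence=sentence, protein_span=(87, 91), phenotype_span=(40, 62))
        masked = mask_entities(rec, proteins, phenotypes)
        assert "patients with PHENO (AML)" in masked
        assert "fusion gene PROT-ETO" in masked

    def test_all_entities_masked_not_only_focal_pair(self):
        proteins = Lexicon(kind="protein", entries={"P1": ("BRCA1",), "P2": ("BRCA2",)})
        phenotypes = Lexicon(kind="phenotype", entries={"H1": ("breast cancer",)})
        rec = make_record(sentence=BRCA_SENTENCE, protein_span=(0, 5), phenotype_span=(85, 98))
        masked = mask_entities(rec, proteins, phenotypes)
        assert "BRCA2" not in masked
        assert masked.count("PROT") == 2

    def test_no_matches_is_identity(self):
        proteins = Lexicon(kind="protein", entries={"P1": ("XYZQ",)})
        phenotypes = Lexicon(kind="phenotype", entries={"H1": ("no such thing",)})
        rec = make_record()
        assert mask_entities(rec, proteins, phenotypes) == rec.sentence

    def test_idempotent(self, small_dataset):
        from comention.preprocessing import mask_sentence
        from comention.extraction import _LexiconMatcher

        pm = _LexiconMatcher(small_dataset.proteins)
        hm = _LexiconMatcher(small_dataset.phenotypes)
        for rec in small_dataset.labeled[:20]:
            once = mask_sentence(rec.sentence, pm, hm)
            assert mask_sentence(once, pm, hm) == once

    def test_masking_removes_all_surface_forms(self, small_dataset):
        rng = np.random.default_rng(0)
        idx = rng.choice(len(small_dataset.labeled), size=100, replace=False)
        names = [n.casefold() for _, n in small_dataset.proteins.all_names()]
        names += [n.casefold() for _, n in small_dataset.phenotypes.all_names()]
        for i in idx:
            rec = small_dataset.labeled[int(i)]
            masked = mask_entities(rec, small_dataset.proteins, small_dataset.phenotypes).casefold()
            for name in names:
                assert name not in masked

    def test_sentinel_count_matches_mention_oracle(self, small_dataset):
        # every synthetic sentence embeds exactly one protein + one phenotype
        for rec in small_dataset.labeled[:50]:
            masked = mask_entities(rec, small_dataset.proteins, small_dataset.phenotypes)
            toks = tokenize(masked)
            assert toks.count("PROT") == 1
            assert toks.count("PHENO") == 1


class TestTokenize:
    def test_basic(self):
        assert tokenize("PROT causes PHENO.") == ["PROT", "causes", "PHENO"]

    def test_hyphen_split_and_sentinel_preserved(self):
        assert tokenize("PROT-ETO fusion") == ["PROT", "eto", "fusion"]

    def test_empty(self):
        assert tokenize("") == []

    def test_no_lowercase_option(self):
        cfg = PreprocessConfig(lowercase=False)
        assert tokenize("The Gene", cfg) == ["The", "Gene"]


class TestBuildVocab:
    def test_frequency_then_lex_order(self):
        vocab = build_vocab([["PROT", "x", "PHENO"], ["x", "y"]])
        assert vocab.token_to_id["<pad>"] == PAD_ID
        assert vocab.token_to_id["<unk>"] == UNK_ID
        assert vocab.token_to_id["PROT"] == 2
        assert vocab.token_to_id["PHENO"] == 3
        assert vocab.token_to_id["x"] < vocab.token_to_id["y"]

    def test_min_freq_excludes(self):
        cfg = PreprocessConfig(min_token_freq=2)
        vocab = build_vocab([["PROT", "x", "PHENO"], ["x", "y"]], cfg)
        assert "y" not in vocab
        assert "x" in vocab

    def test_deterministic(self):
        seqs = [["b", "a", "c"], ["a", "c"], ["c"]]
        assert build_vocab(seqs).token_to_id == build_vocab(seqs).token_to_id

    def test_empty_input_reserved_only(self):
        vocab = build_vocab([])
        assert len(vocab) == 4


class TestEncodePad:
    def setup_method(self):
        self.cfg = PreprocessConfig(max_len=5)
        self.vocab = build_vocab([["a", "b", "c"]], self.cfg)

    def test_padding(self):
        ids = encode_pad(["a", "b", "c"], self.vocab, self.cfg)
        assert len(ids) == 5
        assert ids[3:] == (PAD_ID, PAD_ID)

    def test_truncation(self):
        ids = encode_pad(["a"] * 7, self.vocab, self.cfg)
        assert len(ids) == 5
        assert all(i == self.vocab.token_to_id["a"] for i in ids)

    def test_unknown_token(self):
        ids = encode_pad(["a", "zzz"], self.vocab, self.cfg)
        assert ids[1] == UNK_ID

    @given(st.lists(st.sampled_from(["a", "b", "c", "zzz"]), max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_length_always_exact(self, tokens):
        assert len(encode_pad(tokens, self.vocab, self.cfg)) == self.cfg.max_len

    def test_decode_recovers_in_vocab_input(self):
        tokens = ["a", "c", "b"]
        ids = encode_pad(tokens, self.vocab, self.cfg)
        assert self.vocab.decode(ids) == tokens


class TestStratifiedSplit:
    def _records(self, n_pos, n_neg):
        recs = []
        for i in range(n_pos + n_neg):
            recs.append(make_record(doc_id=f"d{i}", label=1 if i < n_pos else 0))
        return recs

    def test_balanced_100(self):
        train, val, test = stratified_split(self._records(50, 50), SplitConfig(seed=1))
        assert (len(train), len(val), len(test)) == (60, 20, 20)
        for part, expected in ((train, 30), (val, 10), (test, 10)):
            assert sum(r.label for r in part) == expected

    def test_unbalanced_10_derived_by_hand(self):
        # 7 pos: test=round(1.4)=1, val=1, train=5; 3 neg: test=round(0.6)=1, val=1, train=1
        train, val, test = stratified_split(self._records(7, 3), SplitConfig(seed=0))
        assert (len(train), len(val), len(test)) == (6, 2, 2)
        assert sum(r.label for r in train) == 5
        assert sum(r.label for r in val) == 1
        assert sum(r.label for r in test) == 1

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="need >= 3"):
            stratified_split(self._records(5, 2), SplitConfig())

    def test_disjoint_exhaustive_deterministic(self):
        recs = self._records(31, 18)
        out1 = stratified_split(recs, SplitConfig(seed=9))
        out2 = stratified_split(recs, SplitConfig(seed=9))
        assert out1 == out2
        all_ids = sorted(r.doc_id for part in out1 for r in part)
        assert all_ids == sorted(r.doc_id for r in recs)

    def test_proportions_near_global(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n_pos = int(rng.integers(10, 60))
            n_neg = int(rng.integers(10, 60))
            frac = n_pos / (n_pos + n_neg)
            parts = stratified_split(self._records(n_pos, n_neg), SplitConfig(seed=int(rng.integers(1000))))
            for part in parts:
                got = sum(r.label for r in part)
                assert abs(got - frac * len(part)) <= 1.0

    def test_unlabeled_rejected(self):
        with pytest.raises(ValueError):
            stratified_split([make_record()], SplitConfig())


class TestConfigs:
    def test_same_sentinels_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(protein_token="X", phenotype_token="X")

    def test_tiny_max_len_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(max_len=3)

    def test_fractions_must_sum(self):
        with pytest.raises(ValueError):
            SplitConfig(fractions=(0.5, 0.2, 0.2))

    def test_vocab_roundtrip(self):
        vocab = build_vocab([["a", "b"]])
        assert Vocabulary.from_dict(vocab.to_dict()).token_to_id == vocab.token_to_id
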