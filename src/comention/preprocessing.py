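"""Entity masking, tokenization, vocabulary, fixed-length encoding and the
stratified train/validation/test split."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .corpus_io import CoMentionRecord, Lexicon
from .extraction import _LexiconMatcher, resolve_cross_kind_overlaps

__all__ = [
    "PreprocessConfig",
    "SplitConfig",
    "Vocabulary",
    "EncodedExample",
    "mask_entities",
    "tokenize",
    "build_vocab",
    "encode_pad",
    "encode_records",
    "stratified_split",
    "Preprocessor",
]

PAD_ID = 0
UNK_ID = 1


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs for masking, tokenization and fixed-length encoding.

    ``max_len`` is the truncation/padding threshold applied to every token
    sequence so all encoded sentences share one dimensionality.
    """

    protein_token: str = "PROT"
    phenotype_token: str = "PHENO"
    max_len: int = 128
    lowercase: bool = True
    min_token_freq: int = 1

    def __post_init__(self) -> None:
        if self.protein_token == self.phenotype_token:
            raise ValueError("protein_token and phenotype_token must differ")
        if self.max_len < 4:
            raise ValueError("max_len must be >= 4")
        if self.min_token_freq < 1:
            raise ValueError("min_token_freq must be >= 1")


@dataclass(frozen=True)
class SplitConfig:
    """Stratified split fractions (train, validation, test) and seed."""

    fractions: tuple[float, float, float] = (0.60, 0.20, 0.20)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


class Vocabulary:
    """Token -> contiguous integer ids with four reserved slots.

    Ids 0..3 are pad, unk, the protein sentinel and the phenotype sentinel,
    in that order; remaining tokens are ordered by (descending frequency,
    lexicographic), making construction deterministic.
    """

    def __init__(self, token_to_id: dict[str, int], pad_token: str = "<pad>", unk_token: str = "<unk>"):
        self.token_to_id = token_to_id
        self.pad_token = pad_token
        self.unk_token = unk_token
        self.id_to_token = {i: t for t, i in token_to_id.items()}
        ids = sorted(token_to_id.values())
        if ids != list(range(len(ids))):
            raise ValueError("vocabulary ids must be contiguous from 0")

    def __len__(self) -> int:
        return len(self.token_to_id)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    def id_of(self, token: str) -> int:
        return self.token_to_id.get(token, UNK_ID)

    def decode(self, ids: Iterable[int], strip_pad: bool = True) -> list[str]:
        toks = [self.id_to_token[int(i)] for i in ids]
        if strip_pad:
            toks = [t for t in toks if t != self.pad_token]
        return toks

    def to_dict(self) -> dict:
        return {"token_to_id": self.token_to_id, "pad_token": self.pad_token, "unk_token": self.unk_token}

    @classmethod
    def from_dict(cls, d: dict) -> "Vocabulary":
        return cls({k: int(v) for k, v in d["token_to_id"].items()}, d["pad_token"], d["unk_token"])


@dataclass(frozen=True)
class EncodedExample:
    """A fixed-length integer-encoded co-mention sentence."""

    ids: tuple[int, ...]
    label: int | None = None
    source: CoMentionRecord | None = None


def mask_entities(
    record: CoMentionRecord,
    proteins: Lexicon,
    phenotypes: Lexicon,
    cfg: PreprocessConfig = PreprocessConfig(),
) -> str:
    """Replace every lexicon protein/phenotype match with the sentinel tokens.

    All entities are masked, not only the record's focal pair; overlapping
    cross-kind matches are resolved longer-first as in extraction.  The
    operation is idempotent because sentinels are not lexicon names.
    """
    return mask_sentence(record.sentence, _LexiconMatcher(proteins), _LexiconMatcher(phenotypes), cfg)


def mask_sentence(
    sentence: str,
    protein_matcher: _LexiconMatcher,
    phenotype_matcher: _LexiconMatcher,
    cfg: PreprocessConfig = PreprocessConfig(),
) -> str:
    p_mentions, h_mentions = resolve_cross_kind_overlaps(
        protein_matcher.find(sentence), phenotype_matcher.find(sentence)
    )
    repl = [(m.span, cfg.protein_token) for m in p_mentions]
    repl += [(m.span, cfg.phenotype_token) for m in h_mentions]
    repl.sort()
    out: list[str] = []
    pos = 0
    for (a, b), token in repl:
        out.append(sentence[pos:a])
        out.append(token)
        pos = b
    out.append(sentence[pos:])
    return "".join(out)


_TOKEN_RE = re.compile(r"[0-9A-Za-z]+")


def tokenize(masked_sentence: str, cfg: PreprocessConfig = PreprocessConfig()) -> list[str]:
    """Split on non-alphanumeric runs; sentinels survive verbatim, everything
    else is lowercased when ``cfg.lowercase`` is set."""
    sentinels = {cfg.protein_token, cfg.phenotype_token}
    tokens: list[str] = []
    for m in _TOKEN_RE.finditer(masked_sentence):
        tok = m.group(0)
        if tok in sentinels:
            tokens.append(tok)
        else:
            tokens.append(tok.lower() if cfg.lowercase else tok)
    return tokens


def build_vocab(
    token_sequences: Iterable[Sequence[str]], cfg: PreprocessConfig = PreprocessConfig()
) -> Vocabulary:
    """Build the vocabulary from (training-split) token sequences.

    Reserved ids: 0 pad, 1 unk, 2 protein sentinel, 3 phenotype sentinel.
    Other tokens require frequency >= ``cfg.min_token_freq`` and are ordered
    by (descending frequency, lexicographic).
    """
    freqs: dict[str, int] = {}
    for seq in token_sequences:
        for tok in seq:
            freqs[tok] = freqs.get(tok, 0) + 1
    reserved = ["<pad>", "<unk>", cfg.protein_token, cfg.phenotype_token]
    token_to_id = {tok: i for i, tok in enumerate(reserved)}
    candidates = [
        (tok, n)
        for tok, n in freqs.items()
        if n >= cfg.min_token_freq and tok not in token_to_id
    ]
    candidates.sort(key=lambda p: (-p[1], p[0]))
    for tok, _n in candidates:
        token_to_id[tok] = len(token_to_id)
    return Vocabulary(token_to_id)


def encode_pad(
    tokens: Sequence[str], vocab: Vocabulary, cfg: PreprocessConfig = PreprocessConfig()
) -> tuple[int, ...]:
    """Map tokens to ids, truncate to ``max_len`` and right-pad with pad_id."""
    ids = [vocab.id_of(t) for t in tokens[: cfg.max_len]]
    ids.extend([PAD_ID] * (cfg.max_len - len(ids)))
    return tuple(ids)


class Preprocessor:
    """Bundles lexicon matchers, config and a fitted vocabulary.

    The vocabulary is built from the training records only, to avoid
    leaking validation/test tokens.
    """

    def __init__(self, proteins: Lexicon, phenotypes: Lexicon, cfg: PreprocessConfig = PreprocessConfig()):
        self.cfg = cfg
        self._pm = _LexiconMatcher(proteins)
        self._hm = _LexiconMatcher(phenotypes)
        self.vocab: Vocabulary | None = None

    def tokens_for(self, record: CoMentionRecord) -> list[str]:
        return tokenize(mask_sentence(record.sentence, self._pm, self._hm, self.cfg), self.cfg)

    def fit_vocab(self, train_records: Sequence[CoMentionRecord]) -> Vocabulary:
        self.vocab = build_vocab((self.tokens_for(r) for r in train_records), self.cfg)
        return self.vocab

    def encode(self, records: Sequence[CoMentionRecord]) -> list[EncodedExample]:
        if self.vocab is None:
            raise RuntimeError("vocabulary not fitted; call fit_vocab first")
        out = []
        for r in records:
            ids = encode_pad(self.tokens_for(r), self.vocab, self.cfg)
            out.append(EncodedExample(ids=ids, label=r.label, source=r))
        return out


def encode_records(
    records: Sequence[CoMentionRecord],
    proteins: Lexicon,
    phenotypes: Lexicon,
    vocab: Vocabulary,
    cfg: PreprocessConfig = PreprocessConfig(),
) -> list[EncodedExample]:
    """One-shot encoding with an existing vocabulary."""
    pre = Preprocessor(proteins, phenotypes, cfg)
    pre.vocab = vocab
    return pre.encode(records)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(
    records: Sequence[CoMentionRecord], cfg: SplitConfig = SplitConfig()
) -> tuple[list[CoMentionRecord], list[CoMentionRecord], list[CoMentionRecord]]:
    """Deterministic stratified split into (train, validation, test).

    Per class c with n_c members: test gets round-half-up(f_test * n_c),
    validation gets round-half-up(f_val * n_c), train the remainder.
    Classes with fewer than 3 members cannot populate all three splits and
    raise ``ValueError``.
    """
    if any(r.label is None for r in records):
        raise ValueError("stratified_split requires labeled records")
    _f_train, f_val, f_test = cfg.fractions
    rng = np.random.default_rng(cfg.seed)
    by_class: dict[int, list[int]] = {}
    for i, r in enumerate(records):
        by_class.setdefault(r.label, []).append(i)
    train_idx: list[int] = []
    val_idx: list[int] = []
    test_idx: list[int] = []
    for label in sorted(by_class):
        idx = np.array(by_class[label])
        if len(idx) < 3:
            raise ValueError(f"class {label} has {len(idx)} member(s); need >= 3 to populate all splits")
        n_test = _round_half_up(f_test * len(idx))
        n_val = _round_half_up(f_val * len(idx))
        if n_test + n_val >= len(idx):
            raise ValueError(f"class {label}: split fractions leave no training data")
        perm = rng.permutation(len(idx))
        shuffled = idx[perm]
        test_idx.extend(shuffled[:n_test].tolist())
        val_idx.extend(shuffled[n_test : n_test + n_val].tolist())
        train_idx.extend(shuffled[n_test + n_val :].tolist())
    return (
        [records[i] for i in sorted(train_idx)],
        [records[i] for i in sorted(val_idx)],
        [records[i] for i in sorted(test_idx)],
    )
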