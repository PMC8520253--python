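"""Synthetic lexicons, corpora and co-mention datasets with controllable
signal, so every pipeline stage is testable without any download.

Sentences are template-based, which keeps the Bayes-optimal decision rule
known by construction: a true-positive sentence contains a relational
phrase with probability ``signal_strength`` and otherwise falls back to the
same co-occurrence phrasing that negative sentences use, so the residual
ambiguity is exactly 1 - s.  Entity pseudowords and filler pseudowords are
built from disjoint letter sets, which (together with an explicit
substring-freedom check) keeps the dictionary-matching oracle trivial.

True generative labels are a side channel for test oracles only: the
pipeline-facing records of the unlabeled pool carry no label, and the CLI
writes truths to a separate ``*.truth.tsv`` sidecar file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_io import CoMentionRecord, Document, Lexicon

__all__ = ["SynthConfig", "SynthDataset", "generate_lexicons", "generate_dataset"]

# entity syllables use letters {j,k,q,v,w,x,z} + vowels; fillers never do
_ENTITY_SYLLABLES = (
    "zor", "vax", "qui", "jex", "wib", "kuz", "xel", "zun", "vok", "jarn",
    "quv", "wex", "zyx", "kev", "jol", "vyn", "xat", "zem", "wuk", "qav",
)
_FILLER_SYLLABLES = (
    "ba", "do", "fi", "gu", "lem", "nor", "pat", "rud", "sim", "tog",
    "hul", "mer", "cab", "del", "fos", "gan", "hip", "lob", "nid", "pes",
)

POSITIVE_TEMPLATES = (
    "mutations in {P} cause {H}",
    "{P} is associated with {H}",
    "loss of {P} leads to {H}",
    "{P} deficiency results in {H}",
    "variants of {P} are linked to {H}",
    "{P} mutations underlie {H}",
    "inactivation of {P} induces {H}",
    "{P} overexpression promotes {H}",
)

# co-occurrence-only phrasing; also the fallback for ambiguous positives
NEGATIVE_TEMPLATES = (
    "{P} and {H} were discussed",
    "{P} , {H} and further terms were listed",
    "the study measured {P} and separately recorded {H}",
    "{P} was assayed while {H} was noted in the cohort",
    "both {P} and {H} appeared in the survey",
    "the panel included {P} among markers and {H} among conditions",
)


@dataclass(frozen=True)
class SynthConfig:
    n_proteins: int = 30
    n_phenotypes: int = 30
    max_name_words: int = 3
    n_labeled: int = 200
    n_unlabeled: int = 1000
    n_test: int = 200
    positive_fraction: float = 0.5
    signal_strength: float = 0.9
    label_noise: float = 0.05
    filler_vocab_size: int = 200
    sentence_length: tuple[int, int] = (8, 18)
    sentences_per_doc: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("positive_fraction", "signal_strength", "label_noise"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_proteins", "n_phenotypes", "n_labeled", "n_unlabeled", "n_test"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.max_name_words < 1:
            raise ValueError("max_name_words must be >= 1")


@dataclass
class SynthDataset:
    labeled: list[CoMentionRecord]
    unlabeled: list[CoMentionRecord]
    test: list[CoMentionRecord]
    documents: list[Document]
    proteins: Lexicon
    phenotypes: Lexicon
    #: record key -> true generative label, for test oracles only
    truth: dict[tuple, int] = field(default_factory=dict)


def _pseudoword(rng: np.random.Generator, syllables: Sequence[str], n_syll: tuple[int, int]) -> str:
    k = int(rng.integers(n_syll[0], n_syll[1] + 1))
    return "".join(rng.choice(syllables) for _ in range(k))


def _make_names(
    rng: np.random.Generator, n_ids: int, prefix: str, max_words: int, existing: list[str]
) -> dict[str, tuple[str, ...]]:
    entries: dict[str, tuple[str, ...]] = {}
    for i in range(n_ids):
        for _attempt in range(1000):
            n_words = int(rng.integers(1, max_words + 1))
            name = " ".join(_pseudoword(rng, _ENTITY_SYLLABLES, (2, 3)) for _ in range(n_words))
            folded = name.casefold()
            if all(folded not in other and other not in folded for other in existing):
                existing.append(folded)
                entries[f"{prefix}{i + 1:04d}"] = (name,)
                break
        else:  # pragma: no cover - practically unreachable
            raise RuntimeError("could not generate a substring-free name")
    return entries


def generate_lexicons(cfg: SynthConfig = SynthConfig()) -> tuple[Lexicon, Lexicon]:
    """Deterministic synthetic lexicons (ids SP0001..., SH0001...) whose
    names are mutually substring-free."""
    rng = np.random.default_rng(cfg.seed)
    existing: list[str] = []
    proteins = Lexicon(kind="protein", entries=_make_names(rng, cfg.n_proteins, "SP", cfg.max_name_words, existing))
    phenotypes = Lexicon(kind="phenotype", entries=_make_names(rng, cfg.n_phenotypes, "SH", cfg.max_name_words, existing))
    return proteins, phenotypes


def _filler_vocab(rng: np.random.Generator, size: int, forbidden: set[str]) -> list[str]:
    vocab: list[str] = []
    seen: set[str] = set()
    while len(vocab) < size:
        w = _pseudoword(rng, _FILLER_SYLLABLES, (2, 3))
        if w not in seen and w not in forbidden:
            seen.add(w)
            vocab.append(w)
    return vocab


def _build_sentence(
    rng: np.random.Generator,
    template: str,
    p_name: str,
    h_name: str,
    fillers: list[str],
    length_range: tuple[int, int],
) -> tuple[str, tuple[int, int], tuple[int, int]]:
    """Render a template with pre/post filler padding; return the sentence
    and the character spans of the two entity names."""
    core_words = template.split(" ")
    target_len = int(rng.integers(length_range[0], length_range[1] + 1))
    n_extra = max(0, target_len - len(core_words))
    n_pre = int(rng.integers(0, n_extra + 1))
    pre = [str(rng.choice(fillers)) for _ in range(n_pre)]
    post = [str(rng.choice(fillers)) for _ in range(n_extra - n_pre)]
    words = pre + core_words + post
    out: list[str] = []
    pos = 0
    p_span = h_span = None
    for i, w in enumerate(words):
        if w == "{P}":
            w = p_name
            p_span = (pos, pos + len(w))
        elif w == "{H}":
            w = h_name
            h_span = (pos, pos + len(w))
        out.append(w)
        pos += len(w) + 1  # the joining space
    sentence = " ".join(out) + "."
    sentence = sentence[0].upper() + sentence[1:]
    assert p_span is not None and h_span is not None
    return sentence, p_span, h_span


def generate_dataset(cfg: SynthConfig = SynthConfig()) -> SynthDataset:
    """Generate labeled/unlabeled/test co-mention records plus the corpus.

    Every sentence embeds exactly one protein and one phenotype name.  Each
    split independently receives exactly round(positive_fraction * n) true
    positives; observed labels flip with probability ``label_noise``.
    Unlabeled records carry no label; true labels live in ``truth``.
    """
    proteins, phenotypes = generate_lexicons(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    forbidden = {w for _eid, name in list(proteins.all_names()) + list(phenotypes.all_names()) for w in name.split()}
    fillers = _filler_vocab(rng, cfg.filler_vocab_size, forbidden)
    pids = list(proteins.entries)
    hids = list(phenotypes.entries)

    documents: list[Document] = []
    truth: dict[tuple, int] = {}
    splits: dict[str, list[CoMentionRecord]] = {}
    doc_counter = 0

    for split_name, n in (("labeled", cfg.n_labeled), ("unlabeled", cfg.n_unlabeled), ("test", cfg.n_test)):
        n_pos = int(np.floor(cfg.positive_fraction * n + 0.5))
        true_labels = np.array([1] * n_pos + [0] * (n - n_pos))
        rng.shuffle(true_labels)
        sentences: list[tuple[str, tuple[int, int], tuple[int, int], str, str, int, int]] = []
        for t in true_labels:
            pid = pids[int(rng.integers(len(pids)))]
            hid = hids[int(rng.integers(len(hids)))]
            p_name = proteins.names(pid)[0]
            h_name = phenotypes.names(hid)[0]
            if t == 1 and rng.random() < cfg.signal_strength:
                template = POSITIVE_TEMPLATES[int(rng.integers(len(POSITIVE_TEMPLATES)))]
            else:
                template = NEGATIVE_TEMPLATES[int(rng.integers(len(NEGATIVE_TEMPLATES)))]
            sentence, p_span, h_span = _build_sentence(
                rng, template, p_name, h_name, fillers, cfg.sentence_length
            )
            observed = int(t) if rng.random() >= cfg.label_noise else 1 - int(t)
            sentences.append((sentence, p_span, h_span, pid, hid, int(t), observed))

        records: list[CoMentionRecord] = []
        for start in range(0, len(sentences), cfg.sentences_per_doc):
            chunk = sentences[start : start + cfg.sentences_per_doc]
            doc_counter += 1
            doc_id = f"SD{doc_counter:05d}"
            year = int(rng.integers(1990, 2025))
            doc_text = " ".join(s[0] for s in chunk)
            documents.append(Document(doc_id=doc_id, text=doc_text, year=year))
            for sent_idx, (sentence, p_span, h_span, pid, hid, t, observed) in enumerate(chunk):
                record = CoMentionRecord(
                    doc_id=doc_id,
                    sentence_index=sent_idx,
                    sentence=sentence,
                    protein_id=pid,
                    protein_span=p_span,
                    phenotype_id=hid,
                    phenotype_span=h_span,
                    year=year,
                    label=None if split_name == "unlabeled" else observed,
                )
                truth[record.key()] = t
                records.append(record)
        splits[split_name] = records

    return SynthDataset(
        labeled=splits["labeled"],
        unlabeled=splits["unlabeled"],
        test=splits["test"],
        documents=documents,
        proteins=proteins,
        phenotypes=phenotypes,
        truth=truth,
    )
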