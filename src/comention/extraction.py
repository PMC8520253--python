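"""Sentence splitting, dictionary-based entity matching and co-mention
extraction.

Matching is deliberately dictionary-based (not statistical NER): matches are
case-insensitive, anchored at token boundaries (a transition between
alphanumeric and non-alphanumeric characters), leftmost-longest, and
non-overlapping.  When a protein match and a phenotype match overlap, the
longer match wins (ties go to the protein, arbitrarily but deterministically).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .corpus_io import CoMentionRecord, Document, Lexicon

__all__ = [
    "EntityMention",
    "split_sentences",
    "match_entities",
    "extract_comentions",
    "DEFAULT_ABBREVIATIONS",
]

#: Abbreviations that must not terminate a sentence.
DEFAULT_ABBREVIATIONS = frozenset(
    {
        "e.g.", "i.e.", "etc.", "cf.", "vs.", "al.", "fig.", "figs.",
        "dr.", "prof.", "no.", "st.", "approx.", "ca.", "resp.",
    }
)

_BOUNDARY_RE = re.compile(r"[.?!]+\s+(?=[A-Z0-9])")


@dataclass(frozen=True)
class EntityMention:
    """One lexicon match inside a sentence."""

    entity_id: str
    span: tuple[int, int]
    matched_text: str


def split_sentences(
    text: str, abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS
) -> list[tuple[str, int]]:
    """Split ``text`` into (sentence, start_offset) pairs.

    Rule-based: a sentence ends at ``.``, ``?`` or ``!`` followed by
    whitespace and an uppercase letter or digit, unless the terminator
    belongs to a known abbreviation.  Offsets index into ``text``.
    """
    if not text.strip():
        return []
    breaks: list[int] = []
    for m in _BOUNDARY_RE.finditer(text):
        # word containing the terminator, e.g. "al." in "et al. The"
        head = text[: m.end(0) - len(m.group(0).lstrip(".?!"))]
        last_word = head.split()[-1].casefold() if head.split() else ""
        if last_word in abbreviations:
            continue
        breaks.append(m.end(0))
    sentences: list[tuple[str, int]] = []
    start = 0
    for b in breaks + [len(text)]:
        chunk = text[start:b]
        stripped = chunk.strip()
        if stripped:
            offset = start + chunk.index(stripped[0])
            sentences.append((text[offset : offset + len(stripped)], offset))
        start = b
    return sentences


def _is_alnum(ch: str) -> bool:
    return ch.isalnum()


class _LexiconMatcher:
    """Compiled leftmost-longest matcher for one lexicon.

    Every surface name is scanned independently (zero-width lookahead, so
    occurrences overlapping a rejected longer candidate are still seen);
    boundary-valid candidates are then resolved greedily by
    (start, -length, name) into a non-overlapping, leftmost-longest set.
    """

    def __init__(self, lexicon: Lexicon):
        self._lexicon = lexicon
        self._patterns: list[tuple[re.Pattern, int, str]] = []
        seen: set[str] = set()
        for eid, name in lexicon.all_names():
            folded = name.casefold()
            if folded in seen:
                continue
            seen.add(folded)
            pat = re.compile(rf"(?=({re.escape(name)}))", re.IGNORECASE)
            self._patterns.append((pat, len(name), eid))

    def find(self, sentence: str) -> list[EntityMention]:
        n = len(sentence)
        candidates: list[tuple[int, int, str, str]] = []  # (start, -len, eid, text)
        for pat, length, eid in self._patterns:
            for m in pat.finditer(sentence):
                a = m.start()
                b = a + length
                before_ok = a == 0 or not _is_alnum(sentence[a - 1])
                after_ok = b == n or not _is_alnum(sentence[b])
                if before_ok and after_ok:
                    candidates.append((a, -length, eid, m.group(1)))
        candidates.sort()
        mentions: list[EntityMention] = []
        taken_until = 0
        for a, neg_len, eid, text in candidates:
            b = a - neg_len
            if a >= taken_until:
                mentions.append(EntityMention(entity_id=eid, span=(a, b), matched_text=text))
                taken_until = b
        return mentions


def match_entities(sentence: str, lexicon: Lexicon) -> list[EntityMention]:
    """Find all non-overlapping lexicon mentions in ``sentence``.

    Case-insensitive, token-boundary anchored, leftmost-longest; returned in
    span order.
    """
    return _LexiconMatcher(lexicon).find(sentence)


def resolve_cross_kind_overlaps(
    protein_mentions: Sequence[EntityMention], phenotype_mentions: Sequence[EntityMention]
) -> tuple[list[EntityMention], list[EntityMention]]:
    """Drop the shorter of any overlapping protein/phenotype match pair.

    On equal length the protein match is kept.  Within-lexicon matches are
    already non-overlapping by construction.
    """
    drop_p: set[int] = set()
    drop_h: set[int] = set()
    for i, pm in enumerate(protein_mentions):
        for j, hm in enumerate(phenotype_mentions):
            a1, b1 = pm.span
            a2, b2 = hm.span
            if max(a1, a2) < min(b1, b2):  # overlap
                if (b2 - a2) > (b1 - a1):
                    drop_p.add(i)
                else:
                    drop_h.add(j)
    kept_p = [m for i, m in enumerate(protein_mentions) if i not in drop_p]
    kept_h = [m for j, m in enumerate(phenotype_mentions) if j not in drop_h]
    return kept_p, kept_h


def extract_comentions(
    doc: Document,
    proteins: Lexicon,
    phenotypes: Lexicon,
    protein_matcher: _LexiconMatcher | None = None,
    phenotype_matcher: _LexiconMatcher | None = None,
) -> list[CoMentionRecord]:
    """Emit one record per (sentence, protein id, phenotype id) pair.

    A sentence mentioning m distinct proteins and n distinct phenotypes
    yields m*n records; spans point at the first mention of each entity id.
    Prebuilt matchers may be passed to amortize regex compilation over a
    corpus.
    """
    if proteins.kind != "protein" or phenotypes.kind != "phenotype":
        raise ValueError("lexicon kinds must be (protein, phenotype)")
    pm = protein_matcher or _LexiconMatcher(proteins)
    hm = phenotype_matcher or _LexiconMatcher(phenotypes)
    records: list[CoMentionRecord] = []
    for sentence_index, (sentence, _offset) in enumerate(split_sentences(doc.text)):
        p_mentions, h_mentions = resolve_cross_kind_overlaps(pm.find(sentence), hm.find(sentence))
        first_p: dict[str, EntityMention] = {}
        for m in p_mentions:
            first_p.setdefault(m.entity_id, m)
        first_h: dict[str, EntityMention] = {}
        for m in h_mentions:
            first_h.setdefault(m.entity_id, m)
        for pid, pmention in first_p.items():
            for hid, hmention in first_h.items():
                records.append(
                    CoMentionRecord(
                        doc_id=doc.doc_id,
                        sentence_index=sentence_index,
                        sentence=sentence,
                        protein_id=pid,
                        protein_span=pmention.span,
                        phenotype_id=hid,
                        phenotype_span=hmention.span,
                        year=doc.year,
                    )
                )
    return records


def extract_corpus(
    docs: Sequence[Document], proteins: Lexicon, phenotypes: Lexicon
) -> list[CoMentionRecord]:
    """Extract co-mentions from every document, in corpus order."""
    pm = _LexiconMatcher(proteins)
    hm = _LexiconMatcher(phenotypes)
    out: list[CoMentionRecord] = []
    for doc in docs:
        out.extend(extract_comentions(doc, proteins, phenotypes, pm, hm))
    return out
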