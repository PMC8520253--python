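"""Curation-assistant engine: score co-mentions with a fitted ensemble and
answer ranked queries by protein, phenotype, or pair."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .corpus_io import CoMentionRecord, Lexicon
from .models import EnsembleModel, ensemble_predict
from .preprocessing import Preprocessor

logger = logging.getLogger(__name__)

__all__ = ["ScoredStore", "score_store", "query_rank", "resolve_entity"]


@dataclass
class ScoredStore:
    """Confidence-scored co-mention records with id indexes.

    Sorted query output uses the total order (confidence descending,
    doc_id ascending, sentence_index ascending) so results are reproducible.
    """

    records: list[CoMentionRecord] = field(default_factory=list)
    _by_protein: dict[str, list[int]] = field(default_factory=dict, repr=False)
    _by_phenotype: dict[str, list[int]] = field(default_factory=dict, repr=False)

    def add(self, record: CoMentionRecord) -> None:
        if record.confidence is None:
            raise ValueError("ScoredStore records must carry a confidence")
        i = len(self.records)
        self.records.append(record)
        self._by_protein.setdefault(record.protein_id, []).append(i)
        self._by_phenotype.setdefault(record.phenotype_id, []).append(i)

    def __len__(self) -> int:
        return len(self.records)

    def candidates(self, protein_id: str | None, phenotype_id: str | None) -> list[CoMentionRecord]:
        if protein_id is not None and phenotype_id is not None:
            idx = set(self._by_protein.get(protein_id, ())) & set(self._by_phenotype.get(phenotype_id, ()))
        elif protein_id is not None:
            idx = set(self._by_protein.get(protein_id, ()))
        elif phenotype_id is not None:
            idx = set(self._by_phenotype.get(phenotype_id, ()))
        else:
            raise ValueError("at least one of protein_id/phenotype_id is required")
        return [self.records[i] for i in sorted(idx)]


def score_store(
    records: Sequence[CoMentionRecord],
    ensemble: EnsembleModel,
    preprocessor: Preprocessor,
) -> ScoredStore:
    """Score every record with the ensemble's positive-class mean probability
    and build the indexed store.  Records that fail encoding are skipped
    with a logged warning rather than aborting the batch."""
    store = ScoredStore()
    encodable: list[CoMentionRecord] = []
    encoded = []
    for r in records:
        try:
            encoded.append(preprocessor.encode([r])[0])
            encodable.append(r)
        except Exception as exc:  # malformed record: skip, keep scoring the rest
            logger.warning("skipping unencodable record %s: %s", r.key(), exc)
    if encodable:
        preds = ensemble_predict(ensemble, encoded)
        for r, p in zip(encodable, preds):
            store.add(r.with_confidence(p.confidence))
    return store


def query_rank(
    store: ScoredStore,
    protein_id: str | None = None,
    phenotype_id: str | None = None,
    top_k: int = 10,
) -> list[CoMentionRecord]:
    """Top-k records matching all given ids, by descending confidence.

    Ties break on (doc_id, sentence_index) ascending for a deterministic
    total order.  No matches is an empty result, not an error.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    matches = store.candidates(protein_id, phenotype_id)
    matches.sort(key=lambda r: (-r.confidence, r.doc_id, r.sentence_index))
    return matches[:top_k]


def resolve_entity(lexicon: Lexicon, query: str) -> str:
    """Resolve a query string to an entity id.

    An exact id hit wins; otherwise the query is matched case-insensitively
    against surface names.  Ambiguity raises with the candidate ids listed.
    """
    if query in lexicon.entries:
        return query
    folded = query.casefold()
    hits = sorted({eid for eid, name in lexicon.all_names() if name.casefold() == folded})
    if not hits:
        raise KeyError(f"no {lexicon.kind} with id or name {query!r}")
    if len(hits) > 1:
        raise KeyError(f"ambiguous {lexicon.kind} name {query!r}: candidates {hits}")
    return hits[0]
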