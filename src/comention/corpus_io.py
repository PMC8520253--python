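"""Readers and writers for documents, entity lexicons and co-mention files.

All downstream modules consume only the types defined here.  Text I/O is
UTF-8 throughout and strings are Unicode-normalized to NFC on read.

On-disk formats
---------------
* Documents: JSON-lines with keys ``doc_id``, ``year`` (optional) and
  ``text``, or plain text with one document per line (ids are the 1-based
  line numbers).
* Lexicons: 2-column TSV ``entity_id <TAB> surface_name``, one row per
  (id, name) pair.
* Co-mentions: TSV with a fixed column order (see :data:`COMENTION_COLUMNS`);
  absent values are serialized as the empty string.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Document",
    "Lexicon",
    "CoMentionRecord",
    "read_documents",
    "write_documents",
    "read_lexicon",
    "write_lexicon",
    "read_comentions",
    "write_comentions",
    "COMENTION_COLUMNS",
]

_HPO_ID = re.compile(r"^HP:\d{7}$")

COMENTION_COLUMNS = (
    "doc_id",
    "sentence_index",
    "sentence",
    "protein_id",
    "protein_start",
    "protein_end",
    "phenotype_id",
    "phenotype_start",
    "phenotype_end",
    "year",
    "label",
    "confidence",
)


def _nfc(s: str) -> str:
    return unicodedata.normalize("NFC", s)


@dataclass(frozen=True)
class Document:
    """A single corpus document (e.g. one abstract)."""

    doc_id: str
    text: str
    year: int | None = None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")


@dataclass(frozen=True)
class Lexicon:
    """Mapping from entity ids to an ordered tuple of surface names.

    ``kind`` is either ``"protein"`` or ``"phenotype"``.  When
    ``validate_ids`` is enabled for a phenotype lexicon, every id must match
    the HPO pattern ``HP:`` followed by seven digits.
    """

    kind: str
    entries: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("protein", "phenotype"):
            raise ValueError(f"unknown lexicon kind: {self.kind!r}")
        for eid, names in self.entries.items():
            if not eid:
                raise ValueError("empty entity id")
            for name in names:
                if not name.strip():
                    raise ValueError(f"empty surface name for id {eid!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def names(self, entity_id: str) -> tuple[str, ...]:
        return self.entries[entity_id]

    def all_names(self) -> Iterator[tuple[str, str]]:
        """Yield (entity_id, name) pairs in insertion order."""
        for eid, names in self.entries.items():
            for name in names:
                yield eid, name

    def has_name(self, entity_id: str, text: str) -> bool:
        folded = text.casefold()
        return any(n.casefold() == folded for n in self.entries.get(entity_id, ()))


@dataclass(frozen=True)
class CoMentionRecord:
    """One sentence-level co-occurrence of a protein and a phenotype.

    Spans are 0-based half-open character intervals over ``sentence``.
    ``label`` is 1 for a good (valid) co-mention, 0 for a bad one, and
    ``None`` for unlabeled records.  ``confidence`` is the model-assigned
    positive-class probability, when scored.
    """

    doc_id: str
    sentence_index: int
    sentence: str
    protein_id: str
    protein_span: tuple[int, int]
    phenotype_id: str
    phenotype_span: tuple[int, int]
    year: int | None = None
    label: int | None = None
    confidence: float | None = None

    def __post_init__(self) -> None:
        n = len(self.sentence)
        for name, (a, b) in (
            ("protein_span", self.protein_span),
            ("phenotype_span", self.phenotype_span),
        ):
            if not (0 <= a < b <= n):
                raise ValueError(f"{name} {(a, b)} out of bounds for sentence of length {n}")
        pa, pb = self.protein_span
        ha, hb = self.phenotype_span
        if max(pa, ha) < min(pb, hb):
            raise ValueError("protein and phenotype spans overlap")
        if self.sentence_index < 0:
            raise ValueError("sentence_index must be >= 0")
        if self.label not in (None, 0, 1):
            raise ValueError(f"label must be 0, 1 or absent, got {self.label!r}")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence!r}")

    @property
    def protein_text(self) -> str:
        return self.sentence[slice(*self.protein_span)]

    @property
    def phenotype_text(self) -> str:
        return self.sentence[slice(*self.phenotype_span)]

    def with_confidence(self, confidence: float) -> "CoMentionRecord":
        return replace(self, confidence=confidence)

    def key(self) -> tuple:
        """Identity key used for disjointness bookkeeping."""
        return (self.doc_id, self.sentence_index, self.protein_id, self.phenotype_id)


# ---------------------------------------------------------------------------
# documents
# ---------------------------------------------------------------------------

def read_documents(path: str | Path, format: str = "jsonl") -> list[Document]:
    """Read a corpus file into a list of :class:`Document`, order preserved.

    ``format`` is ``"jsonl"`` (keys: doc_id, year, text) or ``"text"``
    (one document per line; ids are 1-based line numbers).  Duplicate
    doc_ids raise ``ValueError``.
    """
    path = Path(path)
    docs: list[Document] = []
    seen: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if format == "jsonl":
                try:
                    obj = json.loads(line)
                    doc_id = str(obj["doc_id"])
                    text = _nfc(str(obj.get("text", "")))
                    year = obj.get("year")
                    year = int(year) if year is not None else None
                except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                    raise ValueError(f"{path}:{lineno}: malformed document record: {exc}") from exc
            elif format == "text":
                doc_id, text, year = str(lineno), _nfc(line), None
            else:
                raise ValueError(f"unknown corpus format: {format!r}")
            if doc_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate doc_id {doc_id!r}")
            seen.add(doc_id)
            docs.append(Document(doc_id=doc_id, text=text, year=year))
    return docs


def write_documents(docs: Iterable[Document], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in docs:
            obj: dict = {"doc_id": doc.doc_id, "text": doc.text}
            if doc.year is not None:
                obj["year"] = doc.year
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# lexicons
# ---------------------------------------------------------------------------

def read_lexicon(path: str | Path, kind: str, validate_ids: bool | None = None) -> Lexicon:
    """Read a 2-column (id, name) TSV into a :class:`Lexicon`.

    Names are grouped by id preserving file order and whitespace-normalized
    (NFC, internal runs collapsed to single spaces).  ``validate_ids``
    defaults to True for phenotype lexicons (HP:ddddddd pattern) and False
    otherwise; pass explicitly to override, e.g. for synthetic lexicons.
    """
    path = Path(path)
    if validate_ids is None:
        validate_ids = kind == "phenotype"
    entries: dict[str, list[str]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 tab-separated columns")
            eid = parts[0].strip()
            name = _nfc(" ".join(parts[1].split()))
            if not name:
                raise ValueError(f"{path}:{lineno}: empty surface name for id {eid!r}")
            if validate_ids and kind == "phenotype" and not _HPO_ID.match(eid):
                raise ValueError(f"{path}:{lineno}: invalid HPO id {eid!r} (expected HP:\\d{{7}})")
            entries.setdefault(eid, [])
            if name not in entries[eid]:
                entries[eid].append(name)
    return Lexicon(kind=kind, entries={k: tuple(v) for k, v in entries.items()})


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for eid, name in lexicon.all_names():
            fh.write(f"{eid}\t{name}\n")


# ---------------------------------------------------------------------------
# co-mention files
# ---------------------------------------------------------------------------

_ESCAPES = {"\\": "\\\\", "\t": "\\t", "\n": "\\n", "\r": "\\r"}
_UNESCAPES = {"\\\\": "\\", "\\t": "\t", "\\n": "\n", "\\r": "\r"}
_UNESCAPE_RE = re.compile(r"\\[\\tnr]")


def _escape(s: str) -> str:
    return re.sub(r"[\\\t\n\r]", lambda m: _ESCAPES[m.group(0)], s)


def _unescape(s: str) -> str:
    return _UNESCAPE_RE.sub(lambda m: _UNESCAPES[m.group(0)], s)


def write_comentions(records: Iterable[CoMentionRecord], path: str | Path) -> None:
    """Write records as TSV in the fixed :data:`COMENTION_COLUMNS` order.

    Absent (None) fields are written as empty strings.  Confidences are
    serialized via ``repr`` so the round trip is bit-exact.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(COMENTION_COLUMNS) + "\n")
        for r in records:
            row = [
                _escape(r.doc_id),
                str(r.sentence_index),
                _escape(r.sentence),
                _escape(r.protein_id),
                str(r.protein_span[0]),
                str(r.protein_span[1]),
                _escape(r.phenotype_id),
                str(r.phenotype_span[0]),
                str(r.phenotype_span[1]),
                "" if r.year is None else str(r.year),
                "" if r.label is None else str(r.label),
                "" if r.confidence is None else repr(float(r.confidence)),
            ]
            fh.write("\t".join(row) + "\n")


def read_comentions(path: str | Path) -> list[CoMentionRecord]:
    """Read a co-mention TSV written by :func:`write_comentions`."""
    path = Path(path)
    records: list[CoMentionRecord] = []
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != COMENTION_COLUMNS:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.rstrip("\n"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(COMENTION_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected {len(COMENTION_COLUMNS)} columns, got {len(parts)}")
            (doc_id, sidx, sentence, pid, ps, pe, hid, hs, he, year, label, conf) = parts
            try:
                records.append(
                    CoMentionRecord(
                        doc_id=_unescape(doc_id),
                        sentence_index=int(sidx),
                        sentence=_unescape(sentence),
                        protein_id=_unescape(pid),
                        protein_span=(int(ps), int(pe)),
                        phenotype_id=_unescape(hid),
                        phenotype_span=(int(hs), int(he)),
                        year=int(year) if year else None,
                        label=int(label) if label else (0 if label == "0" else None),
                        confidence=float(conf) if conf else None,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records
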