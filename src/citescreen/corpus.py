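"""Labeled bibliographic corpora: the in-memory container and its readers/writers.

A screening corpus is an ordered list of articles, each with an opaque
identifier (typically a PMID), a title, an abstract, and a relevance label.
``relevant`` means the article was actually included by the target
systematic review; ``irrelevant`` means it was retrieved by the search
strategy but excluded; ``unknown`` is permitted at the I/O level so that
prospective (not-yet-screened) corpora can be represented.

Supported formats: CSV/TSV/JSONL with ``id,title,abstract,label`` fields,
PubMed MEDLINE/nbib exports (via Bio.Medline), and RIS. Writers emit CSV and
JSONL only. All files are read and written as strict UTF-8.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import Medline

__all__ = [
    "Label",
    "Article",
    "LabeledCorpus",
    "CorpusFormatError",
    "CorpusValidationError",
    "read_table",
    "read_medline",
    "read_ris",
    "write_table",
    "attach_labels",
]


class CorpusFormatError(ValueError):
    """A file does not conform to its declared bibliographic format."""


class CorpusValidationError(ValueError):
    """A structurally valid corpus violates a content invariant."""


class Label(str, Enum):
    RELEVANT = "relevant"
    IRRELEVANT = "irrelevant"
    UNKNOWN = "unknown"


# Case-insensitive aliases accepted on input for each label.
_LABEL_ALIASES = {
    "relevant": Label.RELEVANT,
    "include": Label.RELEVANT,
    "included": Label.RELEVANT,
    "correct": Label.RELEVANT,
    "1": Label.RELEVANT,
    "true": Label.RELEVANT,
    "yes": Label.RELEVANT,
    "irrelevant": Label.IRRELEVANT,
    "exclude": Label.IRRELEVANT,
    "excluded": Label.IRRELEVANT,
    "incorrect": Label.IRRELEVANT,
    "0": Label.IRRELEVANT,
    "false": Label.IRRELEVANT,
    "no": Label.IRRELEVANT,
    "unknown": Label.UNKNOWN,
    "": Label.UNKNOWN,
}


def _coerce_label(raw: object) -> Label:
    if raw is None:
        return Label.UNKNOWN
    text = str(raw).strip().lower()
    if text in ("nan", "none"):
        return Label.UNKNOWN
    try:
        return _LABEL_ALIASES[text]
    except KeyError:
        raise CorpusValidationError(f"unrecognized relevance label: {raw!r}") from None


@dataclass(frozen=True)
class Article:
    """One bibliographic record (id, title, abstract, relevance label)."""

    id: str
    title: str = ""
    abstract: str = ""
    label: Label = Label.UNKNOWN

    def __post_init__(self) -> None:
        if not self.id:
            raise CorpusValidationError("article id must be non-empty")

    @property
    def text(self) -> str:
        """Title and abstract concatenated with a single space."""
        return f"{self.title} {self.abstract}".strip()


@dataclass(frozen=True)
class LabeledCorpus:
    """An ordered, id-unique collection of articles.

    ``m`` is the total article count (the N of the workload formulas) and
    ``n_relevant`` the number of relevant articles (the P of the seed-pair
    combinatorics).
    """

    articles: tuple[Article, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for art in self.articles:
            if art.id in seen:
                raise CorpusValidationError(f"duplicate article id: {art.id!r}")
            seen.add(art.id)

    @classmethod
    def from_articles(cls, articles: Iterable[Article]) -> "LabeledCorpus":
        return cls(tuple(articles))

    def __len__(self) -> int:
        return len(self.articles)

    def __iter__(self) -> Iterator[Article]:
        return iter(self.articles)

    def __getitem__(self, key: int | str) -> Article:
        if isinstance(key, str):
            for art in self.articles:
                if art.id == key:
                    return art
            raise KeyError(key)
        return self.articles[key]

    @property
    def m(self) -> int:
        return len(self.articles)

    @property
    def n_relevant(self) -> int:
        return sum(1 for a in self.articles if a.label is Label.RELEVANT)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(a.id for a in self.articles)

    def labels(self) -> dict[str, Label]:
        return {a.id: a.label for a in self.articles}

    def relevant_ids(self) -> tuple[str, ...]:
        return tuple(a.id for a in self.articles if a.label is Label.RELEVANT)

    def fully_labeled(self) -> bool:
        return all(a.label is not Label.UNKNOWN for a in self.articles)

    def label_counts(self) -> Counter:
        return Counter(a.label for a in self.articles)


_REQUIRED_COLUMNS = ("id", "title", "abstract", "label")


def read_table(path: str | Path, dialect: str = "csv") -> LabeledCorpus:
    """Read a corpus from a delimited table or JSON-lines file.

    ``dialect`` is one of ``csv``, ``tsv``, ``jsonl``. Records must carry
    ``id``, ``title``, ``abstract`` and ``label`` columns/keys; labels are
    normalized case-insensitively (``include``/``correct`` -> relevant,
    ``exclude``/``incorrect`` -> irrelevant, empty -> unknown).
    """
    path = Path(path)
    if dialect == "jsonl":
        rows = []
        with path.open(encoding="utf-8", errors="strict") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rows.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"line {lineno}: invalid JSON: {exc}") from exc
    elif dialect in ("csv", "tsv"):
        delim = "," if dialect == "csv" else "\t"
        with path.open(encoding="utf-8", errors="strict", newline="") as fh:
            reader = csv.DictReader(fh, delimiter=delim)
            if reader.fieldnames is None:
                raise CorpusFormatError("empty file: no header row")
            rows = list(reader)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    articles = []
    for i, row in enumerate(rows):
        for col in _REQUIRED_COLUMNS:
            if col not in row:
                raise CorpusFormatError(f"record {i}: missing required column {col!r}")
        articles.append(
            Article(
                id=str(row["id"]),
                title=str(row["title"] or ""),
                abstract=str(row["abstract"] or ""),
                label=_coerce_label(row["label"]),
            )
        )
    return LabeledCorpus.from_articles(articles)


def write_table(corpus: LabeledCorpus, path: str | Path, dialect: str = "csv") -> None:
    """Write a corpus as CSV or JSONL (the two emitted dialects)."""
    path = Path(path)
    if dialect == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_REQUIRED_COLUMNS)
            for a in corpus:
                writer.writerow([a.id, a.title, a.abstract, a.label.value])
    elif dialect == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for a in corpus:
                fh.write(
                    json.dumps(
                        {"id": a.id, "title": a.title, "abstract": a.abstract, "label": a.label.value},
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unsupported output dialect: {dialect!r}")


def read_medline(path: str | Path) -> LabeledCorpus:
    """Read a PubMed MEDLINE/nbib export.

    One article per record: id from PMID, title from TI, abstract from AB
    (empty when absent). Multi-line values are joined with single spaces by
    the MEDLINE parser. Labels start as ``unknown``; use
    :func:`attach_labels` to mark the included articles.
    """
    path = Path(path)
    with path.open(encoding="utf-8", errors="strict") as fh:
        records = list(Medline.parse(fh))
    articles = []
    for i, rec in enumerate(records):
        pmid = rec.get("PMID")
        if not pmid:
            raise CorpusFormatError(f"MEDLINE record {i}: missing PMID")
        articles.append(
            Article(id=str(pmid), title=rec.get("TI", ""), abstract=rec.get("AB", ""))
        )
    return LabeledCorpus.from_articles(articles)


_RIS_ID_TAGS = ("AN", "ID")
_RIS_TITLE_TAGS = ("TI", "T1")
_RIS_ABSTRACT_TAGS = ("AB", "N2")


def read_ris(path: str | Path) -> LabeledCorpus:
    """Read an RIS reference file.

    Records run from a ``TY`` tag to ``ER``; the id comes from ``AN`` (or
    ``ID``), the title from ``TI`` (or ``T1``), the abstract from ``AB``
    (``N2`` as fallback). A record not closed by ``ER`` is a format error.
    """
    path = Path(path)
    articles: list[Article] = []
    current: dict[str, str] | None = None
    last_tag: str | None = None
    with path.open(encoding="utf-8", errors="strict") as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if len(line) >= 5 and line[2:5] == "  -" and line[:2].strip():
                tag, value = line[:2], line[6:].strip()
            elif current is not None and line.strip() and last_tag is not None:
                # continuation line of the previous tag
                current[last_tag] = f"{current.get(last_tag, '')} {line.strip()}".strip()
                continue
            else:
                continue
            if tag == "TY":
                if current is not None:
                    raise CorpusFormatError(
                        f"RIS record {len(articles)}: new TY before ER"
                    )
                current = {}
                last_tag = None
                continue
            if current is None:
                raise CorpusFormatError("RIS tag outside of a TY..ER record")
            if tag == "ER":
                articles.append(_ris_record_to_article(current, len(articles)))
                current = None
                last_tag = None
                continue
            if tag not in current:  # first occurrence wins
                current[tag] = value
            last_tag = tag
    if current is not None:
        raise CorpusFormatError(f"RIS record {len(articles)}: truncated (missing ER)")
    return LabeledCorpus.from_articles(articles)


def _ris_record_to_article(rec: dict[str, str], index: int) -> Article:
    rid = next((rec[t] for t in _RIS_ID_TAGS if rec.get(t)), None)
    if rid is None:
        raise CorpusFormatError(f"RIS record {index}: missing AN/ID identifier")
    title = next((rec[t] for t in _RIS_TITLE_TAGS if rec.get(t)), "")
    abstract = next((rec[t] for t in _RIS_ABSTRACT_TAGS if rec.get(t)), "")
    return Article(id=rid, title=title, abstract=abstract)


def attach_labels(corpus: LabeledCorpus, relevant_ids: Iterable[str]) -> LabeledCorpus:
    """Return a corpus where the listed ids are relevant and all others irrelevant.

    Every id in ``relevant_ids`` must exist in the corpus.
    """
    wanted = set(relevant_ids)
    known = set(corpus.ids)
    missing = wanted - known
    if missing:
        raise CorpusValidationError(
            f"relevant ids not present in corpus: {sorted(missing)}"
        )
    return LabeledCorpus.from_articles(
        replace(a, label=Label.RELEVANT if a.id in wanted else Label.IRRELEVANT)
        for a in corpus
    )
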