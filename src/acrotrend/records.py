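"""Reading, writing and normalising bibliographic records.

The unit of analysis is one publication with a title, an optional abstract,
a journal identifier, a language code and a best-resolved publication date.
Records arrive either from MEDLINE/PubMed citation XML (baseline-file
dialect, optionally gzipped) or from the package's own JSON-lines
intermediate format, which streams arbitrarily large corpora one record
per line.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import gzip
import io
import json
import logging
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from lxml import etree

logger = logging.getLogger(__name__)

_MONTHS = {
    "jan": 1, "feb": 2, "mar": 3, "apr": 4, "may": 5, "jun": 6,
    "jul": 7, "aug": 8, "sep": 9, "oct": 10, "nov": 11, "dec": 12,
}


@dataclasses.dataclass(frozen=True)
class PaperRecord:
    """One parsed publication.

    ``pub_date`` is the best-resolved publication date; a missing month or
    day is imputed to the earliest value (January / the 1st) so downstream
    time-to-re-use intervals are conservative and reproducible.  ``year``
    always equals ``pub_date.year`` when a date exists.
    """

    paper_id: str
    year: int | None
    pub_date: _dt.date | None
    journal_id: str
    title: str
    abstract: str | None = None
    language: str = "eng"
    article_types: tuple[str, ...] = ()

    def field_text(self, field: str) -> str | None:
        if field == "title":
            return self.title
        if field == "abstract":
            return self.abstract
        raise ValueError(f"unknown field {field!r}; expected 'title' or 'abstract'")


class RecordFormatError(ValueError):
    """Raised when an input file cannot be decoded as records."""


def resolve_pub_date(raw: dict) -> _dt.date | None:
    """Resolve raw PubDate parts to a calendar date.

    Accepts ``year``, ``month`` (number or English name/abbreviation) and
    ``day``; also a ``medline_date`` free-text range such as
    ``"1999 Jan-Feb"``, in which case the earliest period is used.
    Missing month maps to January, missing day to the 1st.  Returns ``None``
    when no year is recoverable — a missing date is a value, not an error.
    """
    year = raw.get("year")
    month = raw.get("month")
    day = raw.get("day")
    if year is None and raw.get("medline_date"):
        year, month, day = _parse_medline_date(str(raw["medline_date"]))
    if year is None:
        return None
    try:
        y = int(year)
    except (TypeError, ValueError):
        return None
    m = _coerce_month(month)
    try:
        d = int(day) if day is not None else 1
    except (TypeError, ValueError):
        d = 1
    try:
        return _dt.date(y, m, d)
    except ValueError:
        return _dt.date(y, m, 1)


def _coerce_month(month) -> int:
    if month is None:
        return 1
    try:
        m = int(month)
        return m if 1 <= m <= 12 else 1
    except (TypeError, ValueError):
        return _MONTHS.get(str(month).strip()[:3].lower(), 1)


def _parse_medline_date(text: str) -> tuple:
    """Best-effort parse of free-text MedlineDate like '1999 Jan-Feb' or '2000 Spring'."""
    year = None
    month = None
    for tok in text.replace("-", " ").replace("/", " ").split():
        if year is None and len(tok) == 4 and tok.isdigit():
            year = int(tok)
        elif month is None and tok[:3].lower() in _MONTHS:
            month = tok[:3].lower()
    return year, month, None


# ---------------------------------------------------------------------------
# MEDLINE XML
# ---------------------------------------------------------------------------

def _open_maybe_gzip(source) -> IO[bytes]:
    if isinstance(source, (str, Path)):
        path = Path(source)
        fh = open(path, "rb")
        if path.suffix == ".gz":
            return gzip.open(fh)
        return fh
    head = source.peek(2) if hasattr(source, "peek") else b""
    if head[:2] == b"\x1f\x8b":
        return gzip.open(source)
    return source


def _text(elem, path: str) -> str | None:
    node = elem.find(path)
    if node is None:
        return None
    return "".join(node.itertext()).strip() or None


def parse_medline_xml(source: Union[str, Path, IO[bytes]]) -> Iterator[PaperRecord]:
    """Stream ``PaperRecord``s out of MEDLINE/PubMed citation XML.

    Yields one record per ``MedlineCitation`` element in file order.
    Citations missing both an article title and an abstract, or missing a
    PMID, are skipped with a logged warning rather than aborting the run.
    Duplicated PMIDs are yielded as-is; deduplication is :func:`dedupe`'s job.
    """
    try:
        stream = _open_maybe_gzip(source)
    except OSError as exc:
        raise IOError(f"cannot read MEDLINE source {source!r}: {exc}") from exc
    try:
        context = etree.iterparse(stream, events=("end",), tag="MedlineCitation",
                                  recover=False)
        for _event, cite in context:
            rec = _citation_to_record(cite)
            if rec is not None:
                yield rec
            cite.clear()
            while cite.getprevious() is not None:
                del cite.getparent()[0]
    except etree.XMLSyntaxError as exc:
        raise RecordFormatError(
            f"not parseable as MEDLINE XML near byte offset "
            f"{getattr(exc, 'position', '?')}: {exc}") from exc


def _citation_to_record(cite) -> PaperRecord | None:
    pmid = _text(cite, "PMID")
    if not pmid:
        logger.warning("skipping citation without PMID")
        return None
    article = cite.find("Article")
    if article is None:
        logger.warning("skipping citation %s without Article element", pmid)
        return None
    title = _text(article, "ArticleTitle")
    abstract_parts = [
        "".join(t.itertext()).strip()
        for t in article.findall("Abstract/AbstractText")
    ]
    abstract = " ".join(p for p in abstract_parts if p) or None
    if title is None and abstract is None:
        logger.warning("skipping citation %s with neither title nor abstract", pmid)
        return None

    journal_id = (
        _text(cite, "MedlineJournalInfo/NlmUniqueID")
        or _text(article, "Journal/ISSN")
        or _text(article, "Journal/Title")
        or "unknown-journal"
    )
    language = _text(article, "Language") or "unk"
    types = tuple(
        t for t in (
            "".join(pt.itertext()).strip()
            for pt in article.findall("PublicationTypeList/PublicationType")
        ) if t
    )
    pub_date = _resolve_citation_date(cite, article)
    return PaperRecord(
        paper_id=pmid,
        year=pub_date.year if pub_date else None,
        pub_date=pub_date,
        journal_id=journal_id,
        title=title or "",
        abstract=abstract,
        language=language,
        article_types=types,
    )


def _resolve_citation_date(cite, article) -> _dt.date | None:
    # Precedence: ArticleDate > Journal issue PubDate > DateCompleted.
    # The choice of field is logged once per run via module docs; see
    # resolve_pub_date for the imputation rule.
    for node, kind in (
        (article.find("ArticleDate"), "parts"),
        (article.find("Journal/JournalIssue/PubDate"), "pubdate"),
        (cite.find("DateCompleted"), "parts"),
    ):
        if node is None:
            continue
        raw = {
            "year": _text(node, "Year"),
            "month": _text(node, "Month"),
            "day": _text(node, "Day"),
        }
        if kind == "pubdate":
            raw["medline_date"] = _text(node, "MedlineDate")
        date = resolve_pub_date(raw)
        if date is not None:
            return date
    return None


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

def dedupe(records: Iterable[PaperRecord]) -> tuple[list[PaperRecord], int]:
    """Keep the first occurrence of each ``paper_id``; report removals.

    First-wins in input order is deterministic and order-stable, which keeps
    the rest of the pipeline reproducible run-to-run.
    """
    seen: set[str] = set()
    kept: list[PaperRecord] = []
    removed = 0
    for rec in records:
        if rec.paper_id in seen:
            removed += 1
        else:
            seen.add(rec.paper_id)
            kept.append(rec)
    return kept, removed


# ---------------------------------------------------------------------------
# JSON-lines intermediate format
# ---------------------------------------------------------------------------

def _record_to_json(rec: PaperRecord) -> str:
    payload = {
        "paper_id": rec.paper_id,
        "year": rec.year,
        "pub_date": rec.pub_date.isoformat() if rec.pub_date else None,
        "journal_id": rec.journal_id,
        "title": rec.title,
        "abstract": rec.abstract,
        "language": rec.language,
        "article_types": list(rec.article_types),
    }
    return json.dumps(payload, ensure_ascii=False)


def _record_from_json(obj: dict) -> PaperRecord:
    date = obj.get("pub_date")
    return PaperRecord(
        paper_id=obj["paper_id"],
        year=obj.get("year"),
        pub_date=_dt.date.fromisoformat(date) if date else None,
        journal_id=obj.get("journal_id", "unknown-journal"),
        title=obj.get("title", ""),
        abstract=obj.get("abstract"),
        language=obj.get("language", "unk"),
        article_types=tuple(obj.get("article_types", ())),
    )


def write_records(path: Union[str, Path, IO[str]], records: Iterable[PaperRecord]) -> int:
    """Write records to a JSON-lines file; returns the number written."""
    n = 0
    if hasattr(path, "write"):
        for rec in records:
            path.write(_record_to_json(rec) + "\n")
            n += 1
        return n
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(_record_to_json(rec) + "\n")
            n += 1
    return n


def read_records(path: Union[str, Path, IO[str]]) -> Iterator[PaperRecord]:
    """Stream records back from a JSON-lines file.

    A corrupt or truncated line raises :class:`RecordFormatError` naming the
    1-based line number.
    """
    fh: IO[str]
    close = False
    if hasattr(path, "read"):
        fh = path
    else:
        fh = open(path, encoding="utf-8")
        close = True
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                yield _record_from_json(json.loads(line))
            except (json.JSONDecodeError, KeyError) as exc:
                raise RecordFormatError(f"corrupt record at line {lineno}: {exc}") from exc
    finally:
        if close:
            fh.close()


def export_tsv(path: Union[str, Path], records: Iterable[PaperRecord]) -> int:
    """Plain TSV export for spreadsheet inspection (word counts included)."""
    from .detect import tokenize_surfaces

    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("paper_id\tyear\tjournal_id\tlanguage\tn_title_words\tn_abstract_words\n")
        for rec in records:
            nt = len(tokenize_surfaces(rec.title))
            na = len(tokenize_surfaces(rec.abstract)) if rec.abstract else 0
            fh.write(f"{rec.paper_id}\t{rec.year}\t{rec.journal_id}\t"
                     f"{rec.language}\t{nt}\t{na}\n")
            n += 1
    return n
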