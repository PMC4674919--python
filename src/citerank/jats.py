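"""Ingest of PMC/JATS full-text article XML.

Each article file contributes one :class:`ArticleRecord`: the article's own
PMID (read from the front-matter ``article-id`` of ``pub-id-type="pmid"``)
and the ordered set of PMIDs it cites (every ``pub-id`` of
``pub-id-type="pmid"`` found under the back-matter reference list).
References that carry no PMID — books, URLs, DOI-only entries — are dropped:
the citation network is keyed exclusively on PMIDs. Duplicate references are
collapsed and self-citations removed at parse time, since both would distort
the out-degree used by PageRank.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Literal, Union

from lxml import etree

from .errors import MalformedXMLError, UnidentifiableArticleError

logger = logging.getLogger(__name__)

_OWN_PMID_XPATH = 'front/article-meta/article-id[@pub-id-type="pmid"]'
_REF_PMID_XPATH = 'back//ref-list//pub-id[@pub-id-type="pmid"]'


@dataclass(frozen=True)
class ArticleRecord:
    """One parsed article: its PMID and its deduplicated outbound citations.

    Invariants: ``pmid > 0``; ``outbound`` holds distinct positive PMIDs in
    first-seen order; ``pmid not in outbound`` (self-loops removed).
    """

    pmid: int
    outbound: tuple[int, ...]
    source_path: str = "<memory>"

    def __post_init__(self) -> None:
        if self.pmid <= 0:
            raise ValueError(f"PMID must be positive, got {self.pmid}")
        if len(set(self.outbound)) != len(self.outbound):
            raise ValueError("outbound citations contain duplicates")
        if self.pmid in self.outbound:
            raise ValueError(f"record {self.pmid} cites itself")
        if any(p <= 0 for p in self.outbound):
            raise ValueError("outbound PMIDs must be positive")


@dataclass
class ParseSummary:
    """Counts accumulated while walking a corpus directory."""

    parsed: int = 0
    skipped: int = 0
    skipped_paths: list[str] = field(default_factory=list)


def _parse_pmid_text(text: str | None) -> int | None:
    """Return the integer PMID held in an element's text, or None."""
    if text is None:
        return None
    text = text.strip()
    if not text.isdigit():
        return None
    value = int(text)
    return value if value > 0 else None


def parse_article(source: Union[str, Path, IO[bytes]], source_path: str | None = None) -> ArticleRecord:
    """Parse one JATS article document into an :class:`ArticleRecord`.

    Parameters
    ----------
    source
        Path to an XML file (optionally gzip-compressed, by ``.gz`` suffix)
        or an open binary file object.
    source_path
        Provenance string for error messages; defaults to the file path.

    Raises
    ------
    MalformedXMLError
        If the document is not well-formed XML.
    UnidentifiableArticleError
        If the article's own PMID is missing or non-numeric.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if source_path is None:
            source_path = str(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rb") as handle:  # type: ignore[operator]
            return _parse_article_stream(handle, source_path)
    return _parse_article_stream(source, source_path or "<stream>")


def _parse_article_stream(handle: IO[bytes], source_path: str) -> ArticleRecord:
    try:
        tree = etree.parse(handle)
    except (etree.XMLSyntaxError, gzip.BadGzipFile, OSError) as exc:
        raise MalformedXMLError(source_path, str(exc)) from exc
    root = tree.getroot()

    own = None
    for el in root.iterfind(_OWN_PMID_XPATH):
        own = _parse_pmid_text(el.text)
        if own is not None:
            break
    if own is None:
        raise UnidentifiableArticleError(source_path)

    outbound: list[int] = []
    seen: set[int] = set()
    for el in root.iterfind(_REF_PMID_XPATH):
        cited = _parse_pmid_text(el.text)
        if cited is None:
            logger.debug("%s: non-numeric reference pub-id %r skipped", source_path, el.text)
            continue
        if cited == own or cited in seen:
            continue
        seen.add(cited)
        outbound.append(cited)
    return ArticleRecord(pmid=own, outbound=tuple(outbound), source_path=source_path)


def iter_corpus_paths(directory: Union[str, Path]) -> list[Path]:
    """XML(.gz) files of a corpus directory in sorted-path order."""
    root = Path(directory)
    if not root.is_dir():
        raise NotADirectoryError(f"not a corpus directory: {root}")
    paths = [p for p in root.iterdir() if p.is_file() and (p.suffix == ".xml" or p.name.endswith(".xml.gz"))]
    return sorted(paths)


def parse_corpus(
    directory: Union[str, Path],
    on_error: Literal["skip", "abort"] = "skip",
    summary: ParseSummary | None = None,
) -> Iterator[ArticleRecord]:
    """Stream :class:`ArticleRecord` objects from a directory of JATS files.

    Files are visited in sorted-path order so output is deterministic; memory
    use is constant in corpus size. Per-file parse failures are handled
    according to ``on_error``: ``"skip"`` logs and continues, ``"abort"``
    re-raises. Pass a :class:`ParseSummary` to collect parsed/skipped counts.
    """
    if on_error not in ("skip", "abort"):
        raise ValueError(f"on_error must be 'skip' or 'abort', got {on_error!r}")
    if summary is None:
        summary = ParseSummary()
    for path in iter_corpus_paths(directory):
        try:
            record = parse_article(path)
        except (MalformedXMLError, UnidentifiableArticleError) as exc:
            if on_error == "abort":
                raise
            summary.skipped += 1
            summary.skipped_paths.append(str(path))
            logger.warning("skipping %s: %s", path, exc)
            continue
        summary.parsed += 1
        yield record
    logger.info("corpus %s: parsed=%d skipped=%d", directory, summary.parsed, summary.skipped)
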