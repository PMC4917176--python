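"""Article parsing and corpus partitioning.

Articles arrive either as JATS-like XML (``<article>`` with front-matter
journal/year, ``<sec>`` sections with ``<title>`` headings, and ``<caption>``
elements) or as plain text.  Parsing produces a flat body string with heading
offsets, plus a *separate* caption stream — caption text never shares offsets
with the body.  Corpora are split into medicine / biology / bioinformatics
sub-corpora by the journal's hierarchical subject codes, where the dot
hierarchy makes bioinformatics a strict subset of biology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from lxml import etree

logger = logging.getLogger(__name__)

MISSING_YEAR = -1

#: default partition rules: name -> subject-code prefix
DEFAULT_PARTITION_RULES: dict[str, str] = {
    "medicine": "H02.403",
    "biology": "H01.158.273",
    "bioinformatics": "H01.158.273.180",
}


@dataclass
class Article:
    """A parsed document: stripped body text, headings, captions, metadata.

    Body offsets are 0-based half-open over the stripped body string.  The
    caption list is a separate stream in document order.
    """

    doc_id: str
    journal: str = ""
    year: int = MISSING_YEAR
    title: str = ""
    body: str = ""
    captions: list[str] = field(default_factory=list)
    heading_spans: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def year_missing(self) -> bool:
        return self.year < 1900

    def validate(self) -> None:
        n = len(self.body)
        for text, start, end in self.heading_spans:
            if not (0 <= start <= end <= n):
                raise ValueError(f"heading span ({start},{end}) outside body[0,{n})")
            if self.body[start:end] != text:
                raise ValueError(f"heading span text mismatch at {start}")


class ArticleParseError(ValueError):
    """Raised when markup cannot be interpreted; names the offending element."""


def _elem_text(el: etree._Element) -> str:
    """Inner text with markup stripped and whitespace collapsed per line."""
    return " ".join("".join(el.itertext()).split())


def parse_article(raw: str | bytes, format: str = "jats_xml", doc_id: str = "") -> Article:
    """Parse one document into an Article.

    jats_xml: body text is the concatenation of section titles and paragraph
    texts (one block per line); captions are collected separately; journal and
    year come from front matter (a missing/bad year is flagged, not fatal).
    plain_text: the raw string is the body; no headings, no captions.
    """
    if isinstance(raw, bytes):
        raw = raw.decode("utf-8")
    if not raw:
        raise ArticleParseError("empty document")
    if format == "plain_text":
        return Article(doc_id=doc_id, body=raw)
    if format != "jats_xml":
        raise ValueError(f"unknown format {format!r}")

    try:
        root = etree.fromstring(raw.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise ArticleParseError(f"malformed XML: {exc}") from exc
    if root.tag != "article":
        raise ArticleParseError(f"expected <article> root, got <{root.tag}>")

    journal = ""
    jt = root.find(".//journal-title")
    if jt is not None:
        journal = _elem_text(jt)
    year = MISSING_YEAR
    ye = root.find(".//pub-date/year")
    if ye is not None and ye.text:
        try:
            year = int(ye.text.strip())
        except ValueError:
            logger.warning("doc %s: unparseable year %r", doc_id, ye.text)
    if year != MISSING_YEAR and year < 1900:
        logger.warning("doc %s: implausible year %d flagged missing", doc_id, year)
        year = MISSING_YEAR
    title = ""
    te = root.find(".//article-title")
    if te is not None:
        title = _elem_text(te)
    if not doc_id:
        ide = root.find(".//article-id")
        if ide is not None:
            doc_id = _elem_text(ide)

    captions = [_elem_text(c) for c in root.iter("caption")]

    blocks: list[tuple[str, bool]] = []  # (text, is_heading)
    body_el = root.find("body")
    if body_el is not None:
        for sec in body_el.iter("sec"):
            for child in sec:
                if child.tag == "title":
                    blocks.append((_elem_text(child), True))
                elif child.tag == "p":
                    # skip paragraphs that live inside captions
                    if any(a.tag == "caption" for a in child.iterancestors()):
                        continue
                    blocks.append((_elem_text(child), False))
        if not body_el.findall(".//sec"):
            for p in body_el.iter("p"):
                if any(a.tag == "caption" for a in p.iterancestors()):
                    continue
                blocks.append((_elem_text(p), False))

    body_parts: list[str] = []
    heading_spans: list[tuple[str, int, int]] = []
    pos = 0
    for text, is_heading in blocks:
        if body_parts:
            pos += 1  # newline separator
        if is_heading:
            heading_spans.append((text, pos, pos + len(text)))
        body_parts.append(text)
        pos += len(text)
    art = Article(doc_id=doc_id, journal=journal, year=year, title=title,
                  body="\n".join(body_parts), captions=captions,
                  heading_spans=heading_spans)
    art.validate()
    return art


def extract_captions(raw: str | bytes, format: str = "jats_xml") -> list[str]:
    """All caption texts in document order, inner markup stripped."""
    return parse_article(raw, format=format).captions


def serialize_article(a: Article) -> str:
    """Render an Article back to JATS-like XML.

    Round-trips through parse_article losslessly for body text, headings and
    captions when heading spans delimit the body blocks (as the synthetic
    generator guarantees).
    """
    root = etree.Element("article")
    front = etree.SubElement(root, "front")
    jm = etree.SubElement(front, "journal-meta")
    etree.SubElement(jm, "journal-title").text = a.journal
    am = etree.SubElement(front, "article-meta")
    etree.SubElement(am, "article-id").text = a.doc_id
    tg = etree.SubElement(am, "title-group")
    etree.SubElement(tg, "article-title").text = a.title
    pd = etree.SubElement(am, "pub-date")
    if not a.year_missing:
        etree.SubElement(pd, "year").text = str(a.year)
    body = etree.SubElement(root, "body")

    # split body into blocks on newlines; blocks matching heading spans
    # become <sec><title>, the rest <p> inside the current section
    heading_starts = {start: text for text, start, end in a.heading_spans}
    sec = None
    pos = 0
    for block in a.body.split("\n") if a.body else []:
        if pos in heading_starts and heading_starts[pos] == block:
            sec = etree.SubElement(body, "sec")
            etree.SubElement(sec, "title").text = block
        else:
            if sec is None:
                sec = etree.SubElement(body, "sec")
            etree.SubElement(sec, "p").text = block
        pos += len(block) + 1
    for cap in a.captions:
        fig = etree.SubElement(body, "fig")
        capel = etree.SubElement(fig, "caption")
        etree.SubElement(capel, "p").text = cap
    return etree.tostring(root, pretty_print=True, encoding="unicode")


# ---------------------------------------------------------------------------
# corpus partitioning


@dataclass
class JournalCatalog:
    """journal name -> set of hierarchical subject-term codes."""

    codes: dict[str, set[str]] = field(default_factory=dict)

    def __contains__(self, journal: str) -> bool:
        return journal in self.codes

    @classmethod
    def from_tsv(cls, path: str | Path) -> "JournalCatalog":
        codes: dict[str, set[str]] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            codes.setdefault(cols[0].strip(), set()).update(
                c.strip() for c in cols[1:] if c.strip()
            )
        return cls(codes=codes)


def code_matches(journal_code: str, partition_code: str) -> bool:
    """Hierarchical subsumption: equal, or journal code sits under the prefix."""
    return journal_code == partition_code or journal_code.startswith(partition_code + ".")


@dataclass
class CorpusPartition:
    name: str
    journal_names: set[str] = field(default_factory=set)
    doc_ids: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.doc_ids)


def partition_corpus(
    articles: Iterable[Article],
    catalog: JournalCatalog,
    rules: Mapping[str, str] | None = None,
) -> list[CorpusPartition]:
    """Split a corpus into 'full' plus subject sub-corpora.

    An article belongs to a partition iff its journal carries a code equal to,
    or prefixed by, the partition's code; journals with several codes join
    every matching partition.  Uncatalogued journals land only in 'full'.
    """
    rules = dict(DEFAULT_PARTITION_RULES) if rules is None else dict(rules)
    parts = {name: CorpusPartition(name=name) for name in rules}
    full = CorpusPartition(name="full")
    for a in articles:
        full.doc_ids.add(a.doc_id)
        full.journal_names.add(a.journal)
        codes = catalog.codes.get(a.journal)
        if not codes:
            logger.debug("journal %r not in catalog; doc %s -> full only", a.journal, a.doc_id)
            continue
        for name, pcode in rules.items():
            if any(code_matches(c, pcode) for c in codes):
                parts[name].doc_ids.add(a.doc_id)
                parts[name].journal_names.add(a.journal)
    return [full] + [parts[name] for name in rules]


def corpus_summary(partition: CorpusPartition) -> tuple[int, int]:
    """(distinct journal count, document count)."""
    return len(partition.journal_names), len(partition.doc_ids)


def read_corpus_dir(directory: str | Path, format: str = "jats_xml") -> tuple[list[Article], int]:
    """Parse every file in a directory; returns (articles, n_failed).

    Documents that fail to parse are skipped and counted — a bad document
    never aborts the pipeline.
    """
    articles: list[Article] = []
    failed = 0
    paths = sorted(Path(directory).iterdir())
    for p in paths:
        if not p.is_file():
            continue
        try:
            articles.append(parse_article(p.read_text(encoding="utf-8"), format=format,
                                          doc_id=p.stem))
        except ArticleParseError as exc:
            failed += 1
            logger.warning("skipping %s: %s", p.name, exc)
    return articles, failed
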