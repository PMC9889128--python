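"""Citation corpus containers and readers (PubMed XML, JSON Lines).

A citation is the unit of analysis: a PMID, a title, an optional
abstract, and the list of MeSH descriptors under which the article was
indexed.  Only title and abstract text is analysed downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from lxml import etree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MeshDescriptor:
    descriptor_id: str
    name: str


@dataclass(frozen=True)
class Citation:
    pmid: str
    title: str
    abstract: str | None = None
    mesh_descriptors: tuple[MeshDescriptor, ...] = ()
    publication_types: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("pmid must be non-empty")
        if not self.title:
            raise ValueError(f"citation {self.pmid}: title must be non-empty")

    @property
    def mesh_ids(self) -> frozenset[str]:
        return frozenset(d.descriptor_id for d in self.mesh_descriptors)

    def field_text(self, which: str) -> str | None:
        if which == "title":
            return self.title
        if which == "abstract":
            return self.abstract
        raise ValueError(f"unknown citation field {which!r}")


class Corpus:
    """Ordered, PMID-unique collection of citations."""

    def __init__(self, citations: Iterable[Citation], source: str | None = None):
        self._citations: list[Citation] = []
        self._by_pmid: dict[str, Citation] = {}
        self.source = source
        for c in citations:
            if c.pmid in self._by_pmid:
                raise ValueError(f"duplicate pmid {c.pmid!r} in corpus")
            self._by_pmid[c.pmid] = c
            self._citations.append(c)

    def __len__(self) -> int:
        return len(self._citations)

    def __iter__(self) -> Iterator[Citation]:
        return iter(self._citations)

    def __contains__(self, pmid: str) -> bool:
        return pmid in self._by_pmid

    def __getitem__(self, pmid: str) -> Citation:
        try:
            return self._by_pmid[pmid]
        except KeyError:
            raise KeyError(f"unknown pmid {pmid!r}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self._citations == other._citations


# ---------------------------------------------------------------------------
# PubMed / MEDLINE XML
# ---------------------------------------------------------------------------

def _text(el) -> str:
    return "".join(el.itertext())


def read_pubmed_xml(path: str | Path) -> Corpus:
    """Parse a PubmedArticleSet XML file into a :class:`Corpus`.

    Structured abstracts (multiple AbstractText sections) are joined
    with single spaces in document order.  MeSH qualifiers are ignored;
    only descriptor id and name are kept.  Articles lacking a PMID are
    skipped with a warning.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed PubMed XML {path}: {exc}") from exc

    citations = []
    for idx, article in enumerate(tree.iter("PubmedArticle")):
        pmid_el = article.find(".//MedlineCitation/PMID")
        if pmid_el is None or not (pmid_el.text or "").strip():
            logger.warning("article #%d has no PMID; skipped", idx)
            continue
        pmid = pmid_el.text.strip()
        title_el = article.find(".//Article/ArticleTitle")
        if title_el is None:
            raise ValueError(f"article #{idx} (pmid {pmid}): missing ArticleTitle")
        title = _text(title_el).strip()

        abstract_parts = [
            _text(el).strip()
            for el in article.findall(".//Article/Abstract/AbstractText")
        ]
        abstract_parts = [p for p in abstract_parts if p]
        abstract = " ".join(abstract_parts) if abstract_parts else None

        mesh = []
        for heading in article.findall(".//MeshHeadingList/MeshHeading"):
            desc = heading.find("DescriptorName")
            if desc is None:
                continue
            mesh.append(
                MeshDescriptor(
                    descriptor_id=desc.get("UI", "").strip(),
                    name=(desc.text or "").strip(),
                )
            )
        pubtypes = tuple(
            (el.text or "").strip()
            for el in article.findall(".//PublicationTypeList/PublicationType")
        )
        citations.append(
            Citation(
                pmid=pmid,
                title=title,
                abstract=abstract,
                mesh_descriptors=tuple(mesh),
                publication_types=pubtypes,
            )
        )
    return Corpus(citations, source=str(path))


# ---------------------------------------------------------------------------
# JSON Lines
# ---------------------------------------------------------------------------

def write_jsonl(corpus: Corpus, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for c in corpus:
            obj = {
                "pmid": c.pmid,
                "title": c.title,
                "abstract": c.abstract,
                "mesh": [
                    {"id": d.descriptor_id, "name": d.name}
                    for d in c.mesh_descriptors
                ],
                "pubtypes": list(c.publication_types),
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def read_jsonl(path: str | Path) -> Corpus:
    citations = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: malformed JSON: {exc}") from exc
            citations.append(
                Citation(
                    pmid=obj["pmid"],
                    title=obj["title"],
                    abstract=obj.get("abstract"),
                    mesh_descriptors=tuple(
                        MeshDescriptor(d["id"], d["name"])
                        for d in obj.get("mesh", [])
                    ),
                    publication_types=tuple(obj.get("pubtypes", [])),
                )
            )
    return Corpus(citations, source=str(path))


def percent_without_abstract(n_total: int, n_without: int) -> float:
    """``100 * n_without / n_total`` reported at 2 decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_without <= n_total:
        raise ValueError("n_without must lie in [0, n_total]")
    return round(100.0 * n_without / n_total, 2)


def abstract_stats(corpus: Corpus) -> tuple[int, int, float]:
    """Count citations without an abstract.

    Returns ``(n_total, n_without_abstract, percent_without)`` with the
    percentage as ``100 * n_without / n_total`` rounded to 2 decimals.
    """
    n_total = len(corpus)
    if n_total == 0:
        raise ValueError("abstract_stats requires a non-empty corpus")
    n_without = sum(1 for c in corpus if not c.abstract)
    return n_total, n_without, percent_without_abstract(n_total, n_without)
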