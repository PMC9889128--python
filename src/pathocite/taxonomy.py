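"""Taxonomy parsing and pathogen term dictionary construction.

The matching dictionary for pathogenic organisms is built from an OBO
release of an organism taxonomy (for example the NCBI Taxonomy as
distributed by the OBO Foundry).  For each pathogen of interest the
scientific name and synonyms of its taxon and of every transitive
subspecies are collected, then passed through a normalization cascade
that trades a small amount of precision for recall: the token
``subtype`` is dropped, bulk influenza strain entries are discarded,
virus names gain a variant with the trailing ``virus`` token removed,
single-letter virus names are discarded, and any term of three or
fewer characters is discarded.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import obonet

logger = logging.getLogger(__name__)

_SYNONYM_RE = re.compile(r'^"(?P<text>.*)"\s+(?P<scope>EXACT|RELATED|BROAD|NARROW)\b')

#: Synonym scopes harvested into the lexicon.  BROAD synonyms are
#: excluded: they name supersets of the taxon and inflate false positives.
HARVESTED_SCOPES = frozenset({"EXACT", "RELATED", "NARROW"})


class Category(str, Enum):
    """What kind of pathogen a record describes; selects the recognizer."""

    ORGANISM = "organism"
    PRION = "prion"
    TOXIN = "toxin"


class Provenance(str, Enum):
    SCIENTIFIC_NAME = "scientific_name"
    SYNONYM = "synonym"
    SUBSPECIES = "subspecies"
    MESH_SYNONYM = "mesh_synonym"


@dataclass(frozen=True)
class TaxonomyNode:
    taxon_id: str
    scientific_name: str
    other_names: tuple[str, ...] = ()
    parent_id: str | None = None


class Taxonomy:
    """Immutable id-keyed collection of :class:`TaxonomyNode`."""

    def __init__(self, nodes: Iterable[TaxonomyNode]):
        self._nodes: dict[str, TaxonomyNode] = {}
        self._children: dict[str, list[str]] = {}
        for node in nodes:
            if node.taxon_id in self._nodes:
                raise ValueError(f"duplicate taxon id {node.taxon_id!r}")
            self._nodes[node.taxon_id] = node
        for node in self._nodes.values():
            if node.parent_id is not None:
                self._children.setdefault(node.parent_id, []).append(node.taxon_id)

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._nodes

    def __iter__(self):
        return iter(self._nodes.values())

    def __getitem__(self, taxon_id: str) -> TaxonomyNode:
        try:
            return self._nodes[taxon_id]
        except KeyError:
            raise KeyError(f"unknown taxon id {taxon_id!r}") from None

    def children(self, taxon_id: str) -> list[str]:
        return list(self._children.get(taxon_id, ()))


@dataclass
class PathogenRecord:
    """One pathogen of interest with its identifiers and raw term set."""

    pathogen_id: str
    canonical_name: str
    category: Category
    taxon_ids: frozenset[str] = frozenset()
    mesh_descriptors: frozenset[str] = frozenset()
    raw_terms: list[str] = field(default_factory=list)
    #: provenance per raw term, parallel to ``raw_terms`` (best effort).
    term_provenance: list[Provenance] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.category = Category(self.category)
        if self.category is Category.ORGANISM and not self.taxon_ids:
            raise ValueError(
                f"organism record {self.pathogen_id!r} requires taxon_ids"
            )
        if self.category is not Category.ORGANISM and self.taxon_ids:
            raise ValueError(
                f"non-organism record {self.pathogen_id!r} must not carry taxon_ids"
            )
        # raw_terms deduplicated, first occurrence wins
        seen: set[str] = set()
        terms, prov = [], []
        provenance = self.term_provenance or [Provenance.SYNONYM] * len(self.raw_terms)
        for t, p in zip(self.raw_terms, provenance):
            if t not in seen:
                seen.add(t)
                terms.append(t)
                prov.append(p)
        self.raw_terms = terms
        self.term_provenance = prov


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    pathogen_id: str
    provenance: Provenance


class TermDictionary:
    """Normalized surface terms keyed for the dictionary matcher.

    Deduplication of ``(surface, pathogen_id)`` is case-insensitive;
    the first-seen casing is stored (matching is case-insensitive
    downstream, so casing is cosmetic).
    """

    def __init__(self, entries: Iterable[LexiconEntry]):
        self.entries: list[LexiconEntry] = []
        seen: set[tuple[str, str]] = set()
        for e in entries:
            key = (e.surface.lower(), e.pathogen_id)
            if key in seen:
                continue
            seen.add(key)
            self.entries.append(e)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def pathogen_ids(self) -> set[str]:
        return {e.pathogen_id for e in self.entries}

    def term_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries:
            counts[e.pathogen_id] = counts.get(e.pathogen_id, 0) + 1
        return counts

    # -- serialization ---------------------------------------------------
    def write_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            for e in self.entries:
                fh.write(f"{e.surface}\t{e.pathogen_id}\t{e.provenance.value}\n")
        stats = {"n_entries": len(self.entries), "per_pathogen": self.term_counts()}
        path.with_suffix(path.suffix + ".stats.json").write_text(
            json.dumps(stats, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TermDictionary":
        entries = []
        with Path(path).open("r", encoding="utf-8") as fh:
            for i, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(f"{path}:{i}: expected 3 tab-separated fields")
                entries.append(LexiconEntry(parts[0], parts[1], Provenance(parts[2])))
        return cls(entries)


# ---------------------------------------------------------------------------
# OBO loading
# ---------------------------------------------------------------------------

def _parse_synonyms(raw: Iterable[str]) -> list[str]:
    out = []
    for line in raw:
        m = _SYNONYM_RE.match(line)
        if m is None:
            # untyped synonym line: `"text" []`
            m2 = re.match(r'^"(?P<text>.*)"', line)
            if m2:
                out.append(m2.group("text"))
            continue
        if m.group("scope") in HARVESTED_SCOPES:
            out.append(m.group("text"))
    return out


def load_taxonomy(path: str | Path) -> Taxonomy:
    """Load an OBO taxonomy file into a :class:`Taxonomy`.

    Obsolete terms are excluded.  Synonym scopes EXACT, RELATED and
    NARROW are harvested; BROAD synonyms are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        graph = obonet.read_obo(str(path))
    except Exception as exc:  # obonet raises assorted ValueError subtypes
        raise ValueError(f"malformed OBO file {path}: {exc}") from exc

    nodes = []
    for taxon_id, data in graph.nodes(data=True):
        name = data.get("name")
        if not name:
            logger.warning("term %s has no name; skipped", taxon_id)
            continue
        parents = data.get("is_a", [])
        parent_id = parents[0] if parents else None
        nodes.append(
            TaxonomyNode(
                taxon_id=taxon_id,
                scientific_name=name,
                other_names=tuple(_parse_synonyms(data.get("synonym", []))),
                parent_id=parent_id,
            )
        )
    return Taxonomy(nodes)


def collect_subtree_terms(
    taxonomy: Taxonomy, root_taxon_id: str
) -> list[tuple[str, str]]:
    """Names and synonyms of ``root_taxon_id`` and all transitive descendants.

    Returns ``(term, taxon_id)`` pairs in depth-first order, scientific
    name before synonyms at each node.
    """
    if root_taxon_id not in taxonomy:
        raise KeyError(f"unknown taxon id {root_taxon_id!r}")
    out: list[tuple[str, str]] = []
    stack = [root_taxon_id]
    seen: set[str] = set()
    while stack:
        tid = stack.pop()
        if tid in seen:  # defensive: taxonomies are trees, but be safe
            continue
        seen.add(tid)
        node = taxonomy[tid]
        out.append((node.scientific_name, tid))
        out.extend((syn, tid) for syn in node.other_names)
        stack.extend(sorted(taxonomy.children(tid), reverse=True))
    return out


# ---------------------------------------------------------------------------
# Normalization cascade
# ---------------------------------------------------------------------------

_INFLUENZA_PREFIXES = ("influenza a virus (", "influenza b virus (")


def _is_virus_term(term: str) -> bool:
    """A term is a virus term iff its last whitespace token is 'virus'."""
    tokens = term.split()
    return bool(tokens) and tokens[-1].lower() == "virus"


def _is_single_letter_virus(term: str) -> bool:
    tokens = term.split()
    return len(tokens) == 2 and len(tokens[0]) == 1 and tokens[1].lower() == "virus"


def normalize_organism_terms(raw_terms: Iterable[str]) -> list[str]:
    """Apply the organism-term normalization cascade.

    In order: (1) delete the token ``subtype``; (2) discard terms whose
    lower-cased form starts with ``influenza a virus (`` or
    ``influenza b virus (``; (3) for virus terms, additionally emit the
    variant with the trailing ``virus`` token removed; (4) discard
    single-letter virus names such as ``B virus``; (5) discard any
    resulting term of length <= 3 characters.  Output is deduplicated
    case-insensitively, original order preserved.
    """
    out: list[str] = []
    seen: set[str] = set()

    def emit(term: str) -> None:
        term = term.strip()
        if len(term) <= 3:  # rule 5
            return
        key = term.lower()
        if key not in seen:
            seen.add(key)
            out.append(term)

    for term in raw_terms:
        term = term.strip()
        if not term:
            continue
        # rule 1: drop the token "subtype" wherever it appears
        tokens = [t for t in term.split() if t.lower() != "subtype"]
        term = " ".join(tokens)
        if not term:
            continue
        # rule 2: bulk influenza strain entries
        if term.lower().startswith(_INFLUENZA_PREFIXES):
            continue
        # rule 4 applies to the full form too ("B virus" is discarded outright)
        if _is_single_letter_virus(term):
            continue
        emit(term)
        # rule 3: trailing-"virus" variant kept alongside the full form
        if _is_virus_term(term):
            stripped = " ".join(term.split()[:-1])
            if stripped and not _is_single_letter_virus(stripped):
                emit(stripped)
    return out


def build_dictionary(records: Iterable[PathogenRecord]) -> TermDictionary:
    """Normalize each record's raw terms and assemble the matching dictionary.

    Organism terms go through :func:`normalize_organism_terms`; prion and
    toxin record terms are kept verbatim apart from the length rule.
    A shared surface maps to every pathogen that carries it — ambiguity
    is retained and resolved at match time.
    """
    records = list(records)
    ids = [r.pathogen_id for r in records]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate pathogen_id(s) in records: {dupes}")

    entries: list[LexiconEntry] = []
    for rec in records:
        prov_by_term = {
            t.lower(): p for t, p in zip(rec.raw_terms, rec.term_provenance)
        }
        if rec.category is Category.ORGANISM:
            surfaces = normalize_organism_terms(rec.raw_terms)
        else:
            surfaces = []
            seen: set[str] = set()
            for t in rec.raw_terms:
                t = t.strip()
                if len(t) > 3 and t.lower() not in seen:
                    seen.add(t.lower())
                    surfaces.append(t)
        if not surfaces:
            logger.warning(
                "pathogen %s contributed zero dictionary entries", rec.pathogen_id
            )
        for s in surfaces:
            prov = prov_by_term.get(s.lower(), Provenance.SYNONYM)
            entries.append(LexiconEntry(s, rec.pathogen_id, prov))
    return TermDictionary(entries)


def assemble_organism_record(
    taxonomy: Taxonomy,
    pathogen_id: str,
    root_taxon_id: str,
    mesh_descriptors: Iterable[str] = (),
) -> PathogenRecord:
    """Build an organism :class:`PathogenRecord` from a taxonomy subtree."""
    terms = collect_subtree_terms(taxonomy, root_taxon_id)
    root = taxonomy[root_taxon_id]
    raw_terms, prov = [], []
    for term, tid in terms:
        raw_terms.append(term)
        if tid != root_taxon_id:
            prov.append(Provenance.SUBSPECIES)
        elif term == root.scientific_name:
            prov.append(Provenance.SCIENTIFIC_NAME)
        else:
            prov.append(Provenance.SYNONYM)
    return PathogenRecord(
        pathogen_id=pathogen_id,
        canonical_name=root.scientific_name,
        category=Category.ORGANISM,
        taxon_ids=frozenset(tid for _, tid in terms) | {root_taxon_id},
        mesh_descriptors=frozenset(mesh_descriptors),
        raw_terms=raw_terms,
        term_provenance=prov,
    )


def read_pathogen_list(path: str | Path) -> list[dict]:
    """Read a pathogen-of-interest table (TSV/CSV).

    Columns: ``name``, ``category``, optional ``taxon_id``, optional
    ``mesh_id``.  Delimiter inferred from the extension.
    """
    import csv

    path = Path(path)
    delim = "," if path.suffix.lower() == ".csv" else "\t"
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        rows = []
        for row in reader:
            if "name" not in row or "category" not in row:
                raise ValueError(f"{path}: required columns are name, category")
            rows.append(
                {
                    "name": row["name"].strip(),
                    "category": Category(row["category"].strip().lower()),
                    "taxon_id": (row.get("taxon_id") or "").strip() or None,
                    "mesh_id": (row.get("mesh_id") or "").strip() or None,
                }
            )
    return rows
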