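"""Dataset construction against an abstract record service.

The acquisition methodology routes each pathogen of interest by
category: organisms are resolved against a taxonomy name index
(scientific names first, then all name fields, keeping only unambiguous
single-record hits), expanded to all transitive subspecies, and linked
to literature through MeSH-indexed searches and gene-record links;
misfolded prion proteins use a per-species template query over MeSH;
toxins use their MeSH mapping directly.  The service contract is
abstract so the same build runs against a deterministic mock backend
(a directory of TSV tables) or, with network access, a live Entrez
client with on-disk caching.
"""

from __future__ import annotations

import json
import time
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .taxonomy import Category

FOUND = "found"
NOT_FOUND = "not_found"
AMBIGUOUS = "ambiguous"

PRION_QUERY_TEMPLATE = '"PrPSc Proteins"[MH] AND {species}[MH]'

#: species with a MeSH heading usable in the prion template query.
PRION_MESH_SPECIES = frozenset(
    {"humans", "sheep", "cattle", "cats", "deer", "goats", "mink"}
)


class ServiceError(RuntimeError):
    """Transport-level failure of a record service (distinct from not-found)."""


class RecordService(ABC):
    """Contract the dataset builder depends on."""

    @abstractmethod
    def search_taxon_scientific(self, name: str) -> list[str]:
        """Taxon ids whose scientific name matches ``name``."""

    @abstractmethod
    def search_taxon_all_fields(self, name: str) -> list[str]:
        """Taxon ids matching ``name`` in any name field."""

    @abstractmethod
    def taxon_children(self, taxon_id: str) -> list[str]:
        """Direct child taxon ids."""

    @abstractmethod
    def search_pmids_by_mesh(self, descriptor: str) -> set[str]:
        """PMIDs of citations indexed with the MeSH descriptor."""

    @abstractmethod
    def gene_link_pmids(self, taxon_id: str) -> set[str]:
        """PMIDs linked from gene records of the taxon."""

    @abstractmethod
    def mesh_descriptor_for_taxon(self, taxon_id: str) -> str | None:
        """MeSH descriptor mapped to the taxon, if any."""


class MockRecordService(RecordService):
    """Deterministic in-memory service backed by a directory of TSV tables.

    Expected files: ``names.tsv`` (taxon_id, name, kind in
    {scientific, other}), ``children.tsv`` (parent_id, child_id),
    ``mesh_index.tsv`` (descriptor, pmid), ``gene_links.tsv``
    (taxon_id, pmid), ``taxon_mesh.tsv`` (taxon_id, descriptor).
    Missing files are treated as empty tables.
    """

    def __init__(self, directory: str | Path):
        d = Path(directory)

        def rows(name: str) -> list[list[str]]:
            p = d / name
            if not p.exists():
                return []
            # plain tab splitting: query strings may contain quote characters
            with p.open("r", encoding="utf-8") as fh:
                return [
                    line.rstrip("\n").split("\t")
                    for line in fh
                    if line.strip()
                ]

        self._scientific: dict[str, list[str]] = {}
        self._all_names: dict[str, list[str]] = {}
        for taxon_id, name, kind in rows("names.tsv"):
            key = name.lower()
            self._all_names.setdefault(key, []).append(taxon_id)
            if kind == "scientific":
                self._scientific.setdefault(key, []).append(taxon_id)
        self._children: dict[str, list[str]] = {}
        for parent, child in rows("children.tsv"):
            self._children.setdefault(parent, []).append(child)
        self._mesh: dict[str, set[str]] = {}
        for descriptor, pmid in rows("mesh_index.tsv"):
            self._mesh.setdefault(descriptor, set()).add(pmid)
        self._gene: dict[str, set[str]] = {}
        for taxon_id, pmid in rows("gene_links.tsv"):
            self._gene.setdefault(taxon_id, set()).add(pmid)
        self._taxon_mesh: dict[str, str] = {}
        for taxon_id, descriptor in rows("taxon_mesh.tsv"):
            self._taxon_mesh[taxon_id] = descriptor

    def search_taxon_scientific(self, name: str) -> list[str]:
        return sorted(self._scientific.get(name.lower(), []))

    def search_taxon_all_fields(self, name: str) -> list[str]:
        return sorted(self._all_names.get(name.lower(), []))

    def taxon_children(self, taxon_id: str) -> list[str]:
        return sorted(self._children.get(taxon_id, []))

    def search_pmids_by_mesh(self, descriptor: str) -> set[str]:
        return set(self._mesh.get(descriptor, ()))

    def gene_link_pmids(self, taxon_id: str) -> set[str]:
        return set(self._gene.get(taxon_id, ()))

    def mesh_descriptor_for_taxon(self, taxon_id: str) -> str | None:
        return self._taxon_mesh.get(taxon_id)


@dataclass
class Resolution:
    status: str  # found | not_found | ambiguous
    taxon_id: str | None = None
    candidates: tuple[str, ...] = ()


@dataclass
class PathogenReport:
    name: str
    category: Category
    status: str
    taxon_ids: tuple[str, ...] = ()
    mesh_descriptor: str | None = None
    mesh_pmids: frozenset[str] = frozenset()
    gene_pmids: frozenset[str] = frozenset()
    query: str | None = None
    note: str = ""


@dataclass
class AcquisitionReport:
    rows: list[PathogenReport] = field(default_factory=list)

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write(
                "name\tcategory\tstatus\ttaxon_ids\tmesh_descriptor"
                "\tn_mesh_pmids\tn_gene_pmids\tmesh_pmids\tgene_pmids"
                "\tquery\tnote\n"
            )
            for r in self.rows:
                fh.write(
                    "\t".join(
                        [
                            r.name,
                            r.category.value,
                            r.status,
                            ",".join(sorted(r.taxon_ids)),
                            r.mesh_descriptor or "",
                            str(len(r.mesh_pmids)),
                            str(len(r.gene_pmids)),
                            ",".join(sorted(r.mesh_pmids)),
                            ",".join(sorted(r.gene_pmids)),
                            r.query or "",
                            r.note,
                        ]
                    )
                    + "\n"
                )


def resolve_taxon(name: str, service: RecordService) -> Resolution:
    """Resolve a pathogen name to a single taxon id.

    Scientific-name search first; on zero hits the search widens to all
    name fields.  Exactly one hit resolves; more than one is ambiguous
    and the pathogen is skipped.
    """
    if not name:
        raise ValueError("name must be non-empty")
    hits = service.search_taxon_scientific(name)
    if not hits:
        hits = service.search_taxon_all_fields(name)
    if not hits:
        return Resolution(NOT_FOUND)
    if len(hits) > 1:
        return Resolution(AMBIGUOUS, candidates=tuple(hits))
    return Resolution(FOUND, taxon_id=hits[0])


def expand_subspecies(taxon_id: str, service: RecordService) -> set[str]:
    """Transitive closure of child links, including the root."""
    seen = {taxon_id}
    frontier = [taxon_id]
    while frontier:
        nxt = []
        for tid in frontier:
            for child in service.taxon_children(tid):
                if child in seen:
                    raise ValueError(
                        f"cycle detected in taxonomy at {child!r}"
                    )
                seen.add(child)
                nxt.append(child)
        frontier = nxt
    return seen


def pmids_via_mesh(descriptors: Iterable[str], service: RecordService) -> set[str]:
    """Union of MeSH-indexed search results over the given descriptors."""
    out: set[str] = set()
    for d in descriptors:
        out |= service.search_pmids_by_mesh(d)
    return out


def prion_query(species_name: str) -> str | None:
    """Template query for one prion species, or None if the species has
    no MeSH heading (e.g. elk, greater kudu, moose)."""
    if species_name.lower() not in PRION_MESH_SPECIES:
        return None
    return PRION_QUERY_TEMPLATE.format(species=species_name)


def build(
    pathogens: Sequence[dict], service: RecordService
) -> AcquisitionReport:
    """Run the acquisition pipeline for a pathogen-of-interest list.

    Each entry is a dict with keys ``name``, ``category`` and optional
    ``mesh_id`` (used directly for toxins).  Partial failures are
    recorded per pathogen and never abort the batch.
    """
    report = AcquisitionReport()
    for p in pathogens:
        name = p["name"]
        category = Category(p["category"])
        try:
            if category is Category.ORGANISM:
                report.rows.append(_build_organism(name, service))
            elif category is Category.PRION:
                report.rows.append(_build_prion(name, service))
            else:
                report.rows.append(_build_toxin(name, p.get("mesh_id"), service))
        except ServiceError as exc:
            report.rows.append(
                PathogenReport(
                    name=name,
                    category=category,
                    status=NOT_FOUND,
                    note=f"service error: {exc}",
                )
            )
    return report


def _build_organism(name: str, service: RecordService) -> PathogenReport:
    res = resolve_taxon(name, service)
    if res.status != FOUND:
        return PathogenReport(
            name=name,
            category=Category.ORGANISM,
            status=res.status,
            note=",".join(res.candidates),
        )
    taxa = expand_subspecies(res.taxon_id, service)
    descriptors = []
    for tid in sorted(taxa):
        d = service.mesh_descriptor_for_taxon(tid)
        if d:
            descriptors.append(d)
    mesh_pmids = pmids_via_mesh(descriptors, service)
    gene_pmids: set[str] = set()
    for tid in sorted(taxa):
        gene_pmids |= service.gene_link_pmids(tid)
    note = "" if descriptors else "no MeSH mapping"
    return PathogenReport(
        name=name,
        category=Category.ORGANISM,
        status=FOUND,
        taxon_ids=tuple(sorted(taxa)),
        mesh_descriptor=";".join(descriptors) or None,
        mesh_pmids=frozenset(mesh_pmids),
        gene_pmids=frozenset(gene_pmids),
        note=note,
    )


def _build_prion(species: str, service: RecordService) -> PathogenReport:
    query = prion_query(species)
    if query is None:
        return PathogenReport(
            name=species,
            category=Category.PRION,
            status=NOT_FOUND,
            note="species has no MeSH heading",
        )
    pmids = service.search_pmids_by_mesh(query)
    return PathogenReport(
        name=species,
        category=Category.PRION,
        status=FOUND,
        mesh_pmids=frozenset(pmids),
        query=query,
    )


def _build_toxin(
    name: str, mesh_id: str | None, service: RecordService
) -> PathogenReport:
    if not mesh_id:
        return PathogenReport(
            name=name,
            category=Category.TOXIN,
            status=NOT_FOUND,
            note="no MeSH mapping",
        )
    pmids = service.search_pmids_by_mesh(mesh_id)
    return PathogenReport(
        name=name,
        category=Category.TOXIN,
        status=FOUND,
        mesh_descriptor=mesh_id,
        mesh_pmids=frozenset(pmids),
    )


# ---------------------------------------------------------------------------
# Live Entrez client (optional; requires network, never used in tests)
# ---------------------------------------------------------------------------

class EntrezRecordService(RecordService):
    """Thin NCBI E-utilities client with on-disk response caching.

    Requests are rate-limited and every response cached to
    ``cache_dir`` keyed by query, so a repeated build replays from disk.
    """

    def __init__(
        self, email: str, cache_dir: str | Path, min_interval: float = 0.34
    ):
        from Bio import Entrez

        Entrez.email = email
        self._entrez = Entrez
        self._cache = Path(cache_dir)
        self._cache.mkdir(parents=True, exist_ok=True)
        self._min_interval = min_interval
        self._last_request = 0.0

    def _cached(self, key: str, fetch):
        import hashlib

        path = self._cache / (hashlib.sha256(key.encode()).hexdigest() + ".json")
        if path.exists():
            return json.loads(path.read_text(encoding="utf-8"))
        wait = self._min_interval - (time.monotonic() - self._last_request)
        if wait > 0:
            time.sleep(wait)
        self._last_request = time.monotonic()
        try:
            value = fetch()
        except Exception as exc:
            raise ServiceError(str(exc)) from exc
        path.write_text(json.dumps(value), encoding="utf-8")
        return value

    def _esearch(self, db: str, term: str) -> list[str]:
        def fetch():
            handle = self._entrez.esearch(db=db, term=term, retmax=100000)
            record = self._entrez.read(handle)
            handle.close()
            return list(record["IdList"])

        return self._cached(f"esearch:{db}:{term}", fetch)

    def search_taxon_scientific(self, name: str) -> list[str]:
        return self._esearch("taxonomy", f"{name}[Scientific Name]")

    def search_taxon_all_fields(self, name: str) -> list[str]:
        return self._esearch("taxonomy", f"{name}[All Names]")

    def taxon_children(self, taxon_id: str) -> list[str]:
        return self._esearch("taxonomy", f"txid{taxon_id}[Next Level]")

    def search_pmids_by_mesh(self, descriptor: str) -> set[str]:
        term = descriptor if "[MH]" in descriptor else f"{descriptor}[MH]"
        return set(self._esearch("pubmed", term))

    def gene_link_pmids(self, taxon_id: str) -> set[str]:
        def fetch():
            handle = self._entrez.elink(
                dbfrom="gene", db="pubmed", id=taxon_id, linkname="gene_pubmed"
            )
            record = self._entrez.read(handle)
            handle.close()
            pmids = []
            for linkset in record:
                for db in linkset.get("LinkSetDb", []):
                    pmids.extend(link["Id"] for link in db.get("Link", []))
            return pmids

        return set(self._cached(f"elink:gene-pubmed:{taxon_id}", fetch))

    def mesh_descriptor_for_taxon(self, taxon_id: str) -> str | None:
        def fetch():
            handle = self._entrez.efetch(db="taxonomy", id=taxon_id)
            records = self._entrez.read(handle)
            handle.close()
            if not records:
                return None
            return records[0].get("ScientificName")

        return self._cached(f"efetch:taxonomy:{taxon_id}", fetch)
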