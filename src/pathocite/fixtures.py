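"""Deterministic synthetic fixtures: taxonomies, corpora, mock backends.

The generator emulates the data shapes the pipeline consumes: a small
OBO taxonomy with subspecies and synonyms, citation corpora with
planted pathogen mentions at known offsets, MeSH descriptor lists
consistent with a gold relevance standard, and a mock record-service
directory.  Relevance is made learnable by construction: citations in
which the pathogen is experimentally studied carry experimental cue
words (cultured, sequenced, ...), incidental mentions carry background
cue words (review, surveillance, ...), and the two cue vocabularies are
disjoint.  The pathogen's MeSH descriptor is planted on a citation iff
the pair is relevant, which realizes the weak-labeling assumption
exactly — so end-to-end closure (recognize, label, evaluate) can be
asserted against the gold standard.

Everything is driven by a single integer seed; equal configs produce
byte-identical outputs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .corpus import Citation, Corpus, MeshDescriptor
from .recognizer import Mention
from .taxonomy import (
    PathogenRecord,
    Taxonomy,
    TermDictionary,
    assemble_organism_record,
    build_dictionary,
    load_taxonomy,
)

EXPERIMENTAL_CUES = (
    "cultured", "isolated", "sequenced", "purified", "characterized",
    "assayed", "inoculated", "cloned", "expressed", "mutagenesis",
    "immunoblotting", "titration",
)

BACKGROUND_CUES = (
    "review", "surveillance", "policy", "outbreak", "historical",
    "epidemiology", "guidelines", "commentary", "perspective",
    "education", "economics", "prevalence",
)

_GENUS_SYLLABLES = (
    "bor", "rel", "lia", "myco", "bac", "ter", "vib", "rio", "stra",
    "lep", "to", "spi", "ra", "cam", "pylo", "ner", "visc", "ella",
)
_EPITHETS = (
    "montica", "fluvialis", "arenosa", "pallida", "rubra", "silvae",
    "borealis", "australis", "marina", "petraea", "umbrosa", "nivalis",
    "lacustris", "arvensis", "litoralis", "glacialis",
)
_STRAIN_TOKENS = ("N40", "K12x", "HB21", "RZ57", "MF93", "QX08", "TV66", "LP34")


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_species: int = 6
    subspecies_per_species: int = 2
    synonyms_per_node: int = 1
    n_citations: int = 200
    fraction_without_abstract: float = 0.2
    relevant_fraction: float = 0.5
    experimental_cues: tuple[str, ...] = EXPERIMENTAL_CUES
    background_cues: tuple[str, ...] = BACKGROUND_CUES
    #: weights for planting 1, 2, ... mentions of the pathogen per citation
    mentions_per_citation: tuple[float, ...] = (0.6, 0.3, 0.1)
    #: fraction of planted mentions using an out-of-dictionary variant
    #: (tokens of the name fused into one), exercising recall loss
    variant_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("fraction_without_abstract", "relevant_fraction",
                     "variant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_species < 1 or self.n_citations < 0:
            raise ValueError("n_species must be >= 1 and n_citations >= 0")
        if set(self.experimental_cues) & set(self.background_cues):
            raise ValueError(
                "experimental and background cue vocabularies overlap"
            )
        if not self.mentions_per_citation or min(self.mentions_per_citation) < 0:
            raise ValueError("mentions_per_citation weights must be non-negative")


@dataclass(frozen=True)
class GoldMention:
    pmid: str
    field: str
    start: int
    end: int
    surface: str
    pathogen_id: str
    variant: bool = False


@dataclass
class GoldStandard:
    mentions: list[GoldMention] = field(default_factory=list)
    #: (pmid, pathogen_id) -> True when the pathogen is experimentally studied
    relevance: dict[tuple[str, str], bool] = field(default_factory=dict)
    #: pathogen_id -> MeSH descriptor id used in planted headings
    descriptors: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Taxonomy generation
# ---------------------------------------------------------------------------

def _fresh_name(rng: random.Random, used: set[str], make) -> str:
    """Draw names from ``make`` until one is globally unused."""
    for _ in range(1000):
        name = make()
        if name.lower() not in used:
            used.add(name.lower())
            return name
    raise RuntimeError("name space exhausted; reduce n_species")


def generate_taxonomy_obo(config: GeneratorConfig) -> str:
    """Valid OBO text: ``n_species`` roots, each with the configured
    subspecies (strain) children and synonyms per node.

    All names and synonyms are globally unique, so no dictionary surface
    is shared between pathogens and planted mentions resolve
    unambiguously.
    """
    rng = random.Random(config.seed)
    used: set[str] = set()
    lines = ["format-version: 1.2", "ontology: synthetic-taxon", ""]
    species = [
        _fresh_name(
            rng,
            used,
            lambda: "".join(rng.sample(_GENUS_SYLLABLES, 3)).capitalize()
            + " "
            + rng.choice(_EPITHETS),
        )
        for _ in range(config.n_species)
    ]
    tid = 0
    for name in species:
        tid += 1
        root_id = f"SYN:{tid:07d}"
        genus = name.split()[0]
        lines += ["[Term]", f"id: {root_id}", f"name: {name}"]
        for _ in range(config.synonyms_per_node):
            syn = _fresh_name(
                rng, used, lambda: f"{genus} {rng.choice(_EPITHETS)}"
            )
            lines.append(f'synonym: "{syn}" EXACT []')
        lines.append("")
        for _ in range(config.subspecies_per_species):
            tid += 1
            strain = rng.choice(_STRAIN_TOKENS) + str(tid)
            sub_name = f"{name} strain {strain}"
            used.add(sub_name.lower())
            lines += [
                "[Term]",
                f"id: SYN:{tid:07d}",
                f"name: {sub_name}",
            ]
            for _ in range(config.synonyms_per_node):
                syn = f"{genus} strain {strain}"
                used.add(syn.lower())
                lines.append(f'synonym: "{syn}" RELATED []')
            lines.append(f"is_a: {root_id}")
            lines.append("")
    return "\n".join(lines)


def write_taxonomy(config: GeneratorConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(generate_taxonomy_obo(config), encoding="utf-8")
    return path


def fixture_lexicon(
    config: GeneratorConfig, taxonomy: Taxonomy | None = None, obo_path=None
) -> tuple[list[PathogenRecord], TermDictionary]:
    """Pathogen records and matching dictionary for a generated taxonomy.

    One pathogen per species root, with id ``org-NNNN`` and MeSH
    descriptor ``DPATHNNNN``.
    """
    if taxonomy is None:
        if obo_path is not None:
            taxonomy = load_taxonomy(obo_path)
        else:
            import tempfile

            with tempfile.TemporaryDirectory() as tmp:
                p = Path(tmp) / "taxonomy.obo"
                p.write_text(generate_taxonomy_obo(config), encoding="utf-8")
                taxonomy = load_taxonomy(p)
    roots = sorted(
        (n.taxon_id for n in taxonomy if n.parent_id is None),
        key=lambda t: int(t.split(":")[1]),
    )
    records = []
    for i, root in enumerate(roots, 1):
        records.append(
            assemble_organism_record(
                taxonomy,
                pathogen_id=f"org-{i:04d}",
                root_taxon_id=root,
                mesh_descriptors={f"DPATH{i:04d}"},
            )
        )
    return records, build_dictionary(records)


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

_NEUTRAL_FILLERS = (
    "samples", "results", "findings", "methods", "data", "analysis",
    "report", "evidence", "observations", "measurements",
)


class _TextBuilder:
    """Accumulates text while recording planted-mention offsets."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.length = 0
        self.spans: list[tuple[int, int, str]] = []  # start, end, surface

    def add(self, text: str) -> None:
        if self.parts:
            self.parts.append(" ")
            self.length += 1
        self.parts.append(text)
        self.length += len(text)

    def add_mention(self, surface: str) -> tuple[int, int]:
        if self.parts:
            self.parts.append(" ")
            self.length += 1
        start = self.length
        self.parts.append(surface)
        self.length += len(surface)
        self.spans.append((start, self.length, surface))
        return start, self.length

    def text(self) -> str:
        return "".join(self.parts)


def _surfaces_by_pathogen(
    records: Sequence[PathogenRecord], dictionary: TermDictionary
) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for e in dictionary:
        out.setdefault(e.pathogen_id, []).append(e.surface)
    return out


def generate_corpus(
    config: GeneratorConfig,
    records: Sequence[PathogenRecord],
    dictionary: TermDictionary,
) -> tuple[Corpus, GoldStandard]:
    """Citation corpus with planted mentions, cues and MeSH headings.

    Each citation features one pathogen.  Its relevance (experimental
    vs incidental) is drawn with probability ``relevant_fraction``; the
    pathogen's descriptor is included in the MeSH heading list iff the
    pair is relevant; cue words of the corresponding class appear in
    title and abstract.  Planted mention offsets are exact.
    """
    if len(dictionary) == 0:
        raise ValueError("dictionary must be non-empty")
    rng = random.Random(config.seed + 1)
    surfaces = _surfaces_by_pathogen(records, dictionary)
    descriptor_of = {}
    for i, rec in enumerate(records, 1):
        descriptor_of[rec.pathogen_id] = (
            sorted(rec.mesh_descriptors)[0]
            if rec.mesh_descriptors
            else f"DPATH{i:04d}"
        )
    pathogen_ids = sorted(surfaces)
    gold = GoldStandard(descriptors=dict(descriptor_of))
    citations = []
    weights = list(config.mentions_per_citation)
    for k in range(config.n_citations):
        pmid = str(90_000_001 + k)
        pathogen_id = rng.choice(pathogen_ids)
        relevant = rng.random() < config.relevant_fraction
        cues = (
            config.experimental_cues if relevant else config.background_cues
        )
        n_mentions = rng.choices(
            range(1, len(weights) + 1), weights=weights, k=1
        )[0]
        has_abstract = rng.random() >= config.fraction_without_abstract

        def plant(builder: _TextBuilder, field_name: str) -> None:
            surface = rng.choice(surfaces[pathogen_id])
            variant = rng.random() < config.variant_fraction
            if variant:
                fused = surface.replace(" ", "")
                s, e = builder.add_mention(fused)
                gold.mentions.append(
                    GoldMention(pmid, field_name, s, e, fused, pathogen_id, True)
                )
            else:
                s, e = builder.add_mention(surface)
                gold.mentions.append(
                    GoldMention(pmid, field_name, s, e, surface, pathogen_id, False)
                )

        title = _TextBuilder()
        title.add(rng.choice(_NEUTRAL_FILLERS).capitalize())
        title.add("of")
        plant(title, "title")
        title.add(rng.choice(cues))
        title.add(rng.choice(_NEUTRAL_FILLERS))

        abstract = None
        remaining = n_mentions - 1
        if has_abstract:
            ab = _TextBuilder()
            n_sentences = rng.randint(2, 3)
            for _ in range(n_sentences):
                ab.add(rng.choice(_NEUTRAL_FILLERS).capitalize())
                if remaining > 0:
                    ab.add("from")
                    plant(ab, "abstract")
                    remaining -= 1
                ab.add("were")
                ab.add(rng.choice(cues))
                ab.add("and")
                ab.add(rng.choice(cues) + ".")
            abstract = ab.text()

        mesh = []
        if relevant:
            canonical = next(
                r.canonical_name for r in records if r.pathogen_id == pathogen_id
            )
            mesh.append(MeshDescriptor(descriptor_of[pathogen_id], canonical))
        # distractor heading, never a pathogen descriptor
        mesh.append(MeshDescriptor("D000000", "Research"))
        rng.shuffle(mesh)

        gold.relevance[(pmid, pathogen_id)] = relevant
        citations.append(
            Citation(
                pmid=pmid,
                title=title.text(),
                abstract=abstract,
                mesh_descriptors=tuple(mesh),
            )
        )
    return Corpus(citations, source="synthetic"), gold


# ---------------------------------------------------------------------------
# Mock backend generation
# ---------------------------------------------------------------------------

def generate_mock_backend(
    config: GeneratorConfig,
    out_dir: str | Path,
    taxonomy: Taxonomy | None = None,
    records: Sequence[PathogenRecord] | None = None,
    corpus: Corpus | None = None,
    gold: GoldStandard | None = None,
) -> Path:
    """Write a mock record-service directory consistent with a corpus.

    The MeSH index maps each pathogen's descriptor to exactly the PMIDs
    of citations where the pair is relevant, so a dataset build against
    the mock reproduces the gold citation sets.  Gene links are a
    deterministic subset of each pathogen's relevant PMIDs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    obo = write_taxonomy(config, out_dir / "taxonomy.obo")
    if taxonomy is None:
        taxonomy = load_taxonomy(obo)
    if records is None:
        records, dictionary = fixture_lexicon(config, taxonomy)
    else:
        dictionary = build_dictionary(records)
    if corpus is None or gold is None:
        corpus, gold = generate_corpus(config, records, dictionary)

    rng = random.Random(config.seed + 2)
    root_of = {}
    for rec in records:
        roots = [t for t in rec.taxon_ids if taxonomy[t].parent_id is None]
        root_of[rec.pathogen_id] = roots[0]

    with (out_dir / "names.tsv").open("w", encoding="utf-8") as fh:
        for node in sorted(taxonomy, key=lambda n: n.taxon_id):
            fh.write(f"{node.taxon_id}\t{node.scientific_name}\tscientific\n")
            for syn in node.other_names:
                fh.write(f"{node.taxon_id}\t{syn}\tother\n")
    with (out_dir / "children.tsv").open("w", encoding="utf-8") as fh:
        for node in sorted(taxonomy, key=lambda n: n.taxon_id):
            if node.parent_id is not None:
                fh.write(f"{node.parent_id}\t{node.taxon_id}\n")
    relevant_pmids: dict[str, list[str]] = {}
    for (pmid, pid), rel in sorted(gold.relevance.items()):
        if rel:
            relevant_pmids.setdefault(pid, []).append(pmid)
    with (out_dir / "mesh_index.tsv").open("w", encoding="utf-8") as fh:
        for pid in sorted(relevant_pmids):
            desc = gold.descriptors[pid]
            for pmid in relevant_pmids[pid]:
                fh.write(f"{desc}\t{pmid}\n")
    with (out_dir / "taxon_mesh.tsv").open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f"{root_of[rec.pathogen_id]}\t{gold.descriptors[rec.pathogen_id]}\n")
    with (out_dir / "gene_links.tsv").open("w", encoding="utf-8") as fh:
        for pid in sorted(relevant_pmids):
            pmids = relevant_pmids[pid]
            n = max(1, len(pmids) // 3)
            subset = sorted(rng.sample(pmids, min(n, len(pmids))))
            for pmid in subset:
                fh.write(f"{root_of[pid]}\t{pmid}\n")
    return out_dir
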