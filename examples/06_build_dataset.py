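"""Run the dataset acquisition pipeline against a mock record service.

Organisms are resolved to a single taxon (scientific name first, then
all name fields), expanded to subspecies, and linked to PMIDs through
MeSH indexing and gene records; prion species use a MeSH template
query; toxins use their MeSH mapping.  The mock backend is a directory
of TSV tables, so the whole build is offline and deterministic.
"""

import tempfile
from pathlib import Path

from pathocite.dataset import MockRecordService, build, prion_query
from pathocite.fixtures import GeneratorConfig, generate_mock_backend
from pathocite.taxonomy import Category

with tempfile.TemporaryDirectory() as tmp:
    config = GeneratorConfig(seed=11, n_species=3, n_citations=60)
    backend_dir = generate_mock_backend(config, Path(tmp) / "mock")
    service = MockRecordService(backend_dir)

    roots = sorted(
        line.split("\t")[1]
        for line in (backend_dir / "names.tsv").read_text().splitlines()
        if line.endswith("\tscientific") and "strain" not in line
    )
    pathogens = [{"name": n, "category": Category.ORGANISM} for n in roots]
    pathogens.append({"name": "sheep", "category": Category.PRION})
    pathogens.append({"name": "moose", "category": Category.PRION})

    report = build(pathogens, service)
    for row in report.rows:
        print(
            f"{row.name:<28} {row.category.value:<9} {row.status:<10} "
            f"taxa={len(row.taxon_ids)} mesh_pmids={len(row.mesh_pmids)} "
            f"gene_pmids={len(row.gene_pmids)}"
        )
    print("\nprion template for sheep:", prion_query("sheep"))
    print("prion template for moose:", prion_query("moose"))
# Each organism resolves to its root taxon plus subspecies and recovers
# the PMIDs indexed under its descriptor; "moose" has no MeSH heading,
# so its prion query cannot be built and the row is flagged not_found.
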