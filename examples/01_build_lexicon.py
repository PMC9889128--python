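"""Build a pathogen matching dictionary from an OBO taxonomy.

Demonstrates subtree term collection (species + subspecies + synonyms)
and the normalization cascade that trades dictionary size for recall.
"""

import tempfile
from pathlib import Path

from pathocite import (
    build_dictionary,
    collect_subtree_terms,
    load_taxonomy,
    normalize_organism_terms,
)
from pathocite.taxonomy import assemble_organism_record

OBO = """\
format-version: 1.2
ontology: demo

[Term]
id: DEMO:1
name: Borrelia burgdorferi
synonym: "Lyme disease spirochete" EXACT []

[Term]
id: DEMO:2
name: Borrelia burgdorferi strain N40
is_a: DEMO:1

[Term]
id: DEMO:3
name: Influenza A virus
synonym: "influenza A virus (A/PR/8/34(H1N1))" RELATED []
synonym: "H1N1 subtype" RELATED []
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "demo.obo"
    path.write_text(OBO)
    taxonomy = load_taxonomy(path)

print(f"loaded {len(taxonomy)} taxa")

terms = collect_subtree_terms(taxonomy, "DEMO:1")
print(f"subtree of DEMO:1 contributes {len(terms)} raw terms:")
for term, taxon_id in terms:
    print(f"  {term!r} from {taxon_id}")

# The cascade: "subtype" dropped, influenza strain entries discarded,
# virus names get a stripped variant, short terms removed.
raw = ["H1N1 subtype", "Influenza A virus",
       "influenza A virus (A/PR/8/34(H1N1))", "B virus", "TBE"]
print("\nnormalization of", raw)
print(" ->", normalize_organism_terms(raw))

records = [
    assemble_organism_record(taxonomy, "org-borrelia", "DEMO:1"),
    assemble_organism_record(taxonomy, "org-influenza-a", "DEMO:3"),
]
dictionary = build_dictionary(records)
print(f"\nfinal dictionary: {len(dictionary)} entries")
for e in dictionary:
    print(f"  {e.surface!r} -> {e.pathogen_id} ({e.provenance.value})")
# Every surviving entry is > 3 characters and case-insensitively unique
# per pathogen; the subspecies term will win at match time by length.
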