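"""Recognize pathogen mentions with the three recognizers.

Longest-match dictionary lookup (organisms), embedded-form regular
expressions (toxins) and species/prion-term co-occurrence (misfolded
prion proteins) each emit character-offset mentions.
"""

from pathocite import Citation, annotate_citation, build_toxin_regexes
from pathocite.recognizer import PrionRule, compile as compile_matcher
from pathocite.taxonomy import LexiconEntry, Provenance, TermDictionary

dictionary = TermDictionary(
    [
        LexiconEntry("Borrelia burgdorferi", "org-borrelia", Provenance.SCIENTIFIC_NAME),
        LexiconEntry("Borrelia burgdorferi strain N40", "org-borrelia", Provenance.SUBSPECIES),
    ]
)
matcher = compile_matcher(dictionary)
bank = build_toxin_regexes()
rule = PrionRule()

citation = Citation(
    pmid="1001",
    title="Borrelia burgdorferi strain N40 outer surface proteins",
    abstract=(
        "Cultures were compared after onabotulinumtoxinA exposure. "
        "PrPSc deposits were also found in sheep controls."
    ),
)

mentions = annotate_citation(citation, matcher, bank, rule)
print(f"{len(mentions)} mentions in PMID {citation.pmid}:")
for m in mentions:
    print(
        f"  [{m.field}:{m.start}-{m.end}] {m.surface!r} -> "
        f"{m.pathogen_id} via {m.method}"
    )
# The dictionary match covers the full subspecies surface (longest match
# beats the bare species term); the toxin regex catches the embedded
# "botulinumtoxin" stem; the prion rule fires because a prion term and a
# species term co-occur in the citation.
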