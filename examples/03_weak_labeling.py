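"""Weakly label (citation, pathogen) pairs from MeSH indexing.

If a pathogen's MeSH descriptor indexes the citation, the pair is
labeled relevant (the pathogen is a focus of the article); otherwise
irrelevant.  Mentions are masked with @PATHOGEN$ so the classifier
learns from context, not from the name itself.
"""

from pathocite import Citation, MeshDescriptor, MeshLink, build_training_set
from pathocite.corpus import Corpus
from pathocite.recognizer import Mention

corpus = Corpus(
    [
        Citation(
            pmid="2001",
            title="Vibrio cholerae toxin secretion",
            abstract="We cultured Vibrio cholerae under biofilm conditions.",
            mesh_descriptors=(MeshDescriptor("D014735", "Vibrio cholerae"),),
        ),
        Citation(
            pmid="2002",
            title="Cholera surveillance in coastal regions",
            abstract="Cases of Vibrio cholerae infection were reviewed.",
            mesh_descriptors=(MeshDescriptor("D000073", "Public Health"),),
        ),
    ]
)
mentions = [
    Mention("2001", "title", 0, 15, "Vibrio cholerae", "org-vibrio", "dictionary"),
    Mention("2001", "abstract", 12, 27, "Vibrio cholerae", "org-vibrio", "dictionary"),
    Mention("2002", "abstract", 9, 24, "Vibrio cholerae", "org-vibrio", "dictionary"),
]
link = MeshLink({"org-vibrio": {"D014735"}})

examples = build_training_set(corpus, mentions, link)
for ex in examples:
    print(f"PMID {ex.pmid} / {ex.pathogen_id}: {ex.label}")
    print(f"  masked: {ex.masked_text!r}\n")
# 2001 is relevant (descriptor D014735 indexes it); 2002 is irrelevant
# (the pathogen is mentioned but not an index term).  Both mentions of
# the pathogen in 2001 are masked, the surrounding text is untouched.
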