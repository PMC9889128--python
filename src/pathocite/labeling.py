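"""Weak labeling of (citation, pathogen) pairs from MeSH indexing.

The labeling assumption: if a pathogen's MeSH descriptor is among the
index terms of a citation, the pathogen is a focus entity of that
article (experimentally studied); otherwise the mention is incidental.
For each (citation, pathogen) pair with at least one recognized
mention, the pathogen's mentions are replaced in the citation text by
the placeholder ``@PATHOGEN$`` and the pair becomes one training
example for the relevance filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus import Citation, Corpus
from .recognizer import Mention

MASK_TOKEN = "@PATHOGEN$"

RELEVANT = "relevant"
IRRELEVANT = "irrelevant"


@dataclass(frozen=True)
class LabeledExample:
    pmid: str
    pathogen_id: str
    masked_text: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in (RELEVANT, IRRELEVANT):
            raise ValueError(f"invalid label {self.label!r}")


class MeshLink:
    """Total lookup pathogen_id -> set of MeSH descriptor ids/names."""

    def __init__(self, mapping: Mapping[str, Iterable[str]]):
        self._map = {pid: frozenset(descs) for pid, descs in mapping.items()}

    def __contains__(self, pathogen_id: str) -> bool:
        return pathogen_id in self._map

    def __getitem__(self, pathogen_id: str) -> frozenset[str]:
        try:
            return self._map[pathogen_id]
        except KeyError:
            raise KeyError(f"unknown pathogen {pathogen_id!r}") from None

    def pathogen_ids(self) -> set[str]:
        return set(self._map)

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for pid in sorted(self._map):
                for desc in sorted(self._map[pid]):
                    fh.write(f"{pid}\t{desc}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MeshLink":
        mapping: dict[str, set[str]] = {}
        with Path(path).open("r", encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                pid, desc = line.split("\t")
                mapping.setdefault(pid, set()).add(desc)
        return cls(mapping)


def label_pair(citation: Citation, pathogen_id: str, mesh_link: MeshLink) -> str:
    """Relevant iff the citation's MeSH descriptors intersect the pathogen's."""
    descriptors = mesh_link[pathogen_id]
    cited = citation.mesh_ids | {d.name for d in citation.mesh_descriptors}
    return RELEVANT if cited & descriptors else IRRELEVANT


def mask(citation: Citation, mentions: Sequence[Mention]) -> str:
    """Replace one pathogen's mention spans with ``@PATHOGEN$``.

    Replacement proceeds right-to-left per field so earlier offsets
    stay valid.  Title and abstract are joined with a single newline.
    """
    pathogen_ids = {m.pathogen_id for m in mentions}
    if len(pathogen_ids) > 1:
        raise ValueError(f"mask expects mentions of one pathogen, got {pathogen_ids}")
    for m in mentions:
        if m.pmid != citation.pmid:
            raise ValueError(
                f"mention pmid {m.pmid!r} does not match citation {citation.pmid!r}"
            )
    by_field: dict[str, list[Mention]] = {"title": [], "abstract": []}
    for m in mentions:
        by_field[m.field].append(m)
    for field_mentions in by_field.values():
        field_mentions.sort(key=lambda m: m.start)
        for a, b in zip(field_mentions, field_mentions[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping mentions [{a.start},{a.end}) and "
                    f"[{b.start},{b.end}) in {citation.pmid}"
                )

    def apply(text: str | None, field_mentions: list[Mention]) -> str | None:
        if text is None:
            return None
        for m in reversed(field_mentions):
            if m.end > len(text) or text[m.start : m.end] != m.surface:
                raise ValueError(
                    f"mention span [{m.start},{m.end}) does not match text "
                    f"in {citation.pmid}/{m.field}"
                )
            text = text[: m.start] + MASK_TOKEN + text[m.end :]
        return text

    title = apply(citation.title, by_field["title"])
    abstract = apply(citation.abstract, by_field["abstract"])
    return title if abstract is None else f"{title}\n{abstract}"


def build_training_set(
    corpus: Corpus,
    annotations: Sequence[Mention],
    mesh_link: MeshLink,
) -> list[LabeledExample]:
    """One masked, labeled example per (citation, pathogen) mention pair.

    Pathogens absent from the MeSH link table generate no examples
    (their label is undecidable); they are still recognized at
    inference time.  Output order is deterministic: (pmid, pathogen_id).
    """
    groups: dict[tuple[str, str], list[Mention]] = {}
    for m in annotations:
        if m.pmid not in corpus:
            raise KeyError(f"annotation references unknown pmid {m.pmid!r}")
        groups.setdefault((m.pmid, m.pathogen_id), []).append(m)

    examples = []
    for (pmid, pathogen_id) in sorted(groups):
        if pathogen_id not in mesh_link:
            continue
        citation = corpus[pmid]
        examples.append(
            LabeledExample(
                pmid=pmid,
                pathogen_id=pathogen_id,
                masked_text=mask(citation, groups[(pmid, pathogen_id)]),
                label=label_pair(citation, pathogen_id, mesh_link),
            )
        )
    return examples


def write_examples_jsonl(examples: Iterable[LabeledExample], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for ex in examples:
            fh.write(
                json.dumps(
                    {
                        "pmid": ex.pmid,
                        "pathogen_id": ex.pathogen_id,
                        "text": ex.masked_text,
                        "label": ex.label,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_examples_jsonl(path: str | Path) -> list[LabeledExample]:
    out = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: malformed JSON: {exc}") from exc
            out.append(
                LabeledExample(
                    pmid=obj["pmid"],
                    pathogen_id=obj["pathogen_id"],
                    masked_text=obj["text"],
                    label=obj["label"],
                )
            )
    return out
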