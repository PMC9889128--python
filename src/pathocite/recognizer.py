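"""Pathogen mention recognition in citation text.

Three recognizers run over title and abstract text:

* a dictionary matcher over the organism/prion term lexicon, matching
  case-insensitively at token boundaries with longest-match preference
  (so a subspecies term beats its parent species term at the same
  position);
* a regular-expression bank for toxins, deliberately not
  boundary-constrained so embedded forms such as ``onabotulinumtoxinA``
  or ``antiaflatoxinB1`` are caught;
* a co-occurrence rule for misfolded prion proteins, which emits a
  species-scoped mention whenever a prion term (``PrPSc``, ``prion``
  ...) occurs anywhere in the citation together with the species term.

Offsets are 0-based, half-open, per field; slicing the field text with
a mention's span always reproduces its surface.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus import Citation
from .taxonomy import TermDictionary

# Tokens are maximal runs of letters, digits and hyphens; everything
# else is a separator.  This is shared by the matcher and the term
# side of the dictionary so both sides tokenize identically.
_TOKEN_RE = re.compile(r"[^\W_]+(?:-[^\W_]+)*", re.UNICODE)


def tokenize_with_offsets(text: str) -> list[tuple[str, int, int]]:
    """``(token, start, end)`` triples over ``text``."""
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text)


@dataclass(frozen=True, order=True)
class Mention:
    pmid: str
    field: str  # "title" | "abstract"
    start: int
    end: int
    surface: str
    pathogen_id: str
    method: str  # "dictionary" | "regex" | "prion"
    ambiguous_with: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        if self.field not in ("title", "abstract"):
            raise ValueError(f"invalid field {self.field!r}")


class CompiledMatcher:
    """Token-indexed longest-match lookup over a term dictionary.

    Entries are tokenized and stored lower-cased under their first
    token; at match time candidate token sequences at each position are
    tried longest first.  Matching is case-insensitive.
    """

    def __init__(self, dictionary: TermDictionary):
        if len(dictionary) == 0:
            raise ValueError("cannot compile an empty dictionary")
        # first token -> {token tuple -> sorted pathogen ids}
        self._index: dict[str, dict[tuple[str, ...], list[str]]] = {}
        self._max_len = 0
        for entry in dictionary:
            toks = tuple(t.lower() for t in tokenize(entry.surface))
            if not toks:
                continue
            bucket = self._index.setdefault(toks[0], {})
            ids = bucket.setdefault(toks, [])
            if entry.pathogen_id not in ids:
                ids.append(entry.pathogen_id)
            self._max_len = max(self._max_len, len(toks))
        for bucket in self._index.values():
            for ids in bucket.values():
                ids.sort()

    def __contains__(self, surface: str) -> bool:
        toks = tuple(t.lower() for t in tokenize(surface))
        return bool(toks) and toks in self._index.get(toks[0], {})

    def lookup(self, tokens: Sequence[str]) -> list[str] | None:
        """Pathogen ids for an exact (lower-cased) token sequence, or None."""
        toks = tuple(tokens)
        return self._index.get(toks[0], {}).get(toks) if toks else None


def compile(dictionary: TermDictionary) -> CompiledMatcher:  # noqa: A001
    return CompiledMatcher(dictionary)


def find_dictionary_mentions(
    matcher: CompiledMatcher, text: str, *, pmid: str = "", field: str = "title"
) -> list[Mention]:
    """Longest-match left-to-right scan of ``text``.

    Matches begin and end at token boundaries; among candidates starting
    at the same token the longest (in tokens, ties broken by character
    span) wins; matched spans never overlap.  When several pathogens
    share the winning surface, the lexicographically lowest pathogen id
    is chosen and the rest are recorded on the mention.
    """
    tokens = tokenize_with_offsets(text)
    lowered = [t.lower() for t, _, _ in tokens]
    mentions: list[Mention] = []
    i = 0
    n = len(tokens)
    while i < n:
        first = lowered[i]
        bucket = matcher._index.get(first)
        hit = None
        if bucket:
            limit = min(matcher._max_len, n - i)
            for length in range(limit, 0, -1):
                ids = bucket.get(tuple(lowered[i : i + length]))
                if ids:
                    hit = (length, ids)
                    break
        if hit is None:
            i += 1
            continue
        length, ids = hit
        start = tokens[i][1]
        end = tokens[i + length - 1][2]
        mentions.append(
            Mention(
                pmid=pmid,
                field=field,
                start=start,
                end=end,
                surface=text[start:end],
                pathogen_id=ids[0],
                method="dictionary",
                ambiguous_with=tuple(ids[1:]),
            )
        )
        i += length
    return mentions


# ---------------------------------------------------------------------------
# Toxin regular expressions
# ---------------------------------------------------------------------------

class RegexBank:
    """Case-insensitive toxin patterns, one or more per pathogen."""

    def __init__(self, patterns: Iterable[tuple[str, str]]):
        self.patterns: list[tuple[str, str]] = []
        self._compiled: list[tuple[re.Pattern, str]] = []
        for pattern, pathogen_id in patterns:
            if "(?i)" not in pattern:
                pattern = "(?i)" + pattern
            try:
                compiled = re.compile(pattern)
            except re.error as exc:
                raise ValueError(
                    f"toxin pattern for {pathogen_id!r} does not compile: {exc}"
                ) from exc
            self.patterns.append((pattern, pathogen_id))
            self._compiled.append((compiled, pathogen_id))

    def __len__(self) -> int:
        return len(self.patterns)

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for pattern, pid in self.patterns:
                fh.write(f"{pattern}\t{pid}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "RegexBank":
        pairs = []
        with Path(path).open("r", encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line:
                    pattern, pid = line.split("\t")
                    pairs.append((pattern, pid))
        return cls(pairs)


#: Toxin stems used to derive the default pattern bank.  Each stem is
#: matched embedded inside longer tokens (optional letter prefix, and
#: letter/digit inflection after), which is what catches forms such as
#: "onabotulinumtoxinA" and "antiaflatoxinB1".
DEFAULT_TOXIN_STEMS: dict[str, Sequence[str]] = {
    "toxin-aflatoxins": ("aflatox",),
    "toxin-botulinum": ("botulinum ?(?:neuro)?tox", "onabotulinumtox"),
    "toxin-ciguatoxins": ("ciguatox",),
    "toxin-conotoxins": ("conotox",),
    "toxin-enterotoxins": ("enterotox",),
    "toxin-saxitoxins": ("saxitox",),
    "toxin-tetrodotoxin": ("tetrodotox",),
}


def build_toxin_regexes(
    stems: Mapping[str, Sequence[str]] | None = None,
) -> RegexBank:
    """Build the default toxin pattern bank from stem alternations."""
    stems = DEFAULT_TOXIN_STEMS if stems is None else stems
    pairs = []
    for pathogen_id, stem_list in stems.items():
        alternation = "|".join(stem_list)
        pairs.append((rf"(?i)[a-z]*(?:{alternation})[a-z0-9]*", pathogen_id))
    return RegexBank(pairs)


def find_toxin_mentions(
    bank: RegexBank, text: str, *, pmid: str = "", field: str = "title"
) -> list[Mention]:
    mentions = []
    for compiled, pathogen_id in bank._compiled:
        for m in compiled.finditer(text):
            if m.start() == m.end():
                continue
            mentions.append(
                Mention(
                    pmid=pmid,
                    field=field,
                    start=m.start(),
                    end=m.end(),
                    surface=m.group(0),
                    pathogen_id=pathogen_id,
                    method="regex",
                )
            )
    mentions.sort()
    return mentions


# ---------------------------------------------------------------------------
# Prion co-occurrence rule
# ---------------------------------------------------------------------------

DEFAULT_PRION_TERMS = ("prpsc", "prp-sc", "prion", "prions", "scrapie")

#: species pathogen id -> surface terms (common name + plural).
DEFAULT_PRION_SPECIES: dict[str, Sequence[str]] = {
    "prpsc-human": ("human", "humans"),
    "prpsc-sheep": ("sheep",),
    "prpsc-cattle": ("cattle", "bovine"),
    "prpsc-cat": ("cat", "cats"),
    "prpsc-deer": ("deer",),
    "prpsc-goat": ("goat", "goats"),
    "prpsc-mink": ("mink", "minks"),
}


@dataclass
class PrionRule:
    prion_terms: tuple[str, ...] = DEFAULT_PRION_TERMS
    species_lexicon: dict[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_PRION_SPECIES)
    )

    def _token_positions(self, text: str, terms: Iterable[str]):
        wanted = {t.lower() for t in terms}
        for tok, s, e in tokenize_with_offsets(text):
            if tok.lower() in wanted:
                yield s, e


def find_prion_mentions(rule: PrionRule, citation: Citation) -> list[Mention]:
    """Species mentions conditioned on a prion term anywhere in the citation."""
    fields = [("title", citation.title)]
    if citation.abstract:
        fields.append(("abstract", citation.abstract))
    prion_present = any(
        next(rule._token_positions(text, rule.prion_terms), None) is not None
        for _, text in fields
    )
    if not prion_present:
        return []
    mentions = []
    for field_name, text in fields:
        for pathogen_id in sorted(rule.species_lexicon):
            for s, e in rule._token_positions(
                text, rule.species_lexicon[pathogen_id]
            ):
                mentions.append(
                    Mention(
                        pmid=citation.pmid,
                        field=field_name,
                        start=s,
                        end=e,
                        surface=text[s:e],
                        pathogen_id=pathogen_id,
                        method="prion",
                    )
                )
    mentions.sort()
    return mentions


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

_METHOD_PRIORITY = {"dictionary": 0, "regex": 1, "prion": 2}


def _resolve_overlaps(mentions: list[Mention]) -> list[Mention]:
    """Keep the longer of any two overlapping mentions; ties favour the
    dictionary path, then the regex path."""
    ordered = sorted(
        mentions,
        key=lambda m: (-(m.end - m.start), _METHOD_PRIORITY[m.method], m.start,
                       m.pathogen_id),
    )
    kept: list[Mention] = []
    for m in ordered:
        if all(
            m.field != k.field or m.end <= k.start or k.end <= m.start
            for k in kept
        ):
            kept.append(m)
    kept.sort(key=lambda m: (0 if m.field == "title" else 1, m.start, m.end))
    return kept


def annotate_citation(
    citation: Citation,
    matcher: CompiledMatcher | None = None,
    bank: RegexBank | None = None,
    rule: PrionRule | None = None,
) -> list[Mention]:
    """Run all configured recognizers over a citation's title and abstract."""
    mentions: list[Mention] = []
    fields = [("title", citation.title)]
    if citation.abstract:
        fields.append(("abstract", citation.abstract))
    for field_name, text in fields:
        if matcher is not None:
            mentions.extend(
                find_dictionary_mentions(
                    matcher, text, pmid=citation.pmid, field=field_name
                )
            )
        if bank is not None:
            mentions.extend(
                find_toxin_mentions(bank, text, pmid=citation.pmid, field=field_name)
            )
    if rule is not None:
        mentions.extend(find_prion_mentions(rule, citation))
    return _resolve_overlaps(mentions)


def annotate_corpus(corpus, matcher=None, bank=None, rule=None) -> list[Mention]:
    out: list[Mention] = []
    for citation in corpus:
        out.extend(annotate_citation(citation, matcher, bank, rule))
    return out


# -- annotation serialization ------------------------------------------------

def write_mentions_jsonl(mentions: Iterable[Mention], path: str | Path) -> None:
    import json

    with Path(path).open("w", encoding="utf-8") as fh:
        for m in mentions:
            fh.write(
                json.dumps(
                    {
                        "pmid": m.pmid,
                        "field": m.field,
                        "start": m.start,
                        "end": m.end,
                        "surface": m.surface,
                        "pathogen_id": m.pathogen_id,
                        "method": m.method,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_mentions_jsonl(path: str | Path) -> list[Mention]:
    import json

    out = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            out.append(Mention(**obj))
    return out
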