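"""Independent brute-force oracles used across test modules.

These deliberately re-derive expected behaviour by enumeration, without
touching the implementation paths they check.
"""

from __future__ import annotations

import re

_TOKEN_RE = re.compile(r"[^\W_]+(?:-[^\W_]+)*", re.UNICODE)


def oracle_tokenize(text: str) -> list[tuple[str, int, int]]:
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def oracle_dictionary_scan(
    surfaces: dict[str, list[str]], text: str
) -> list[tuple[int, int, str]]:
    """Brute-force longest-match scan.

    ``surfaces`` maps each dictionary surface (as written) to its
    sorted pathogen ids.  Every surface is tested at every token
    position; at each position the candidate covering the most tokens
    wins; matched regions never overlap; the scan is left to right.
    Returns ``(start, end, pathogen_id)`` triples.
    """
    toks = oracle_tokenize(text)
    lowered = [t.lower() for t, _, _ in toks]
    entries = [
        (tuple(t.lower() for t, _, _ in oracle_tokenize(surface)), ids)
        for surface, ids in surfaces.items()
    ]
    out = []
    i = 0
    while i < len(toks):
        best = None
        for seq, ids in entries:
            if not seq or i + len(seq) > len(toks):
                continue
            if tuple(lowered[i : i + len(seq)]) == seq:
                if best is None or len(seq) > len(best[0]):
                    best = (seq, sorted(ids))
                elif len(seq) == len(best[0]):
                    best = (seq, sorted(set(best[1]) | set(ids)))
        if best is None:
            i += 1
            continue
        seq, ids = best
        start = toks[i][1]
        end = toks[i + len(seq) - 1][2]
        out.append((start, end, ids[0]))
        i += len(seq)
    return out


def oracle_ngrams(tokens: list[str], order: int) -> set[str]:
    """Enumerate all n-grams up to ``order`` as space-joined strings."""
    out: set[str] = set()
    for n in range(1, order + 1):
        for i in range(len(tokens) - n + 1):
            out.add(" ".join(tokens[i : i + n]))
    return out


def dfs_collect_terms(nodes: dict, children: dict, root: str) -> set[tuple[str, str]]:
    """Recursive DFS term collection: (term, taxon_id) over the subtree."""
    out = set()

    def visit(tid: str) -> None:
        name, synonyms = nodes[tid]
        out.add((name, tid))
        for s in synonyms:
            out.add((s, tid))
        for child in children.get(tid, ()):
            visit(child)

    visit(root)
    return out
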