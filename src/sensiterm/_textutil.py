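"""Shared low-level text primitives: casefolding with offset maps, tokenization,
and restricted Damerau-Levenshtein edit distance.

These are deliberately dependency-free; match offsets must refer to the
verbatim note text, so casefolding keeps a per-character source map (full
Unicode casefolding may change string length, e.g. "ß" -> "ss").
"""

from __future__ import annotations

import re

_TOKEN_RE = re.compile(r"[0-9a-zÀ-ɏ']+")


def casefold_with_map(text: str) -> tuple[str, list[int]]:
    """Casefold *text*, returning the folded string and a source-index map.

    ``srcmap[i]`` is the index in *text* of the character whose casefolding
    produced ``folded[i]``; a folded span [s, e) maps back to the original
    span [srcmap[s], srcmap[e-1] + 1).
    """
    parts: list[str] = []
    srcmap: list[int] = []
    for i, ch in enumerate(text):
        f = ch.casefold()
        parts.append(f)
        srcmap.extend([i] * len(f))
    return "".join(parts), srcmap


def tokenize(text: str) -> list[str]:
    """Casefolded word tokens (letters, digits, internal apostrophes)."""
    return _TOKEN_RE.findall(text.casefold())


def normalize_surface(surface: str) -> str:
    """Casefold and collapse internal whitespace to single spaces."""
    return " ".join(surface.casefold().split())


def damerau_levenshtein(a: str, b: str) -> int:
    """Restricted Damerau-Levenshtein (optimal string alignment) distance.

    Counts substitutions, insertions, deletions, and adjacent transpositions
    as single edits; each substring may be rearranged at most once.
    """
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                d = min(d, prev2[j - 2] + 1)
            cur[j] = d
        prev2, prev = prev, cur
    return prev[lb]


def edit_similarity(a: str, b: str) -> float:
    """Normalized edit similarity 1 - d/max(|a|, |b|), in [0, 1]."""
    m = max(len(a), len(b))
    if m == 0:
        return 1.0
    return 1.0 - damerau_levenshtein(a, b) / m
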