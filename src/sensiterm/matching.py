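"""Exact string matching of lexicon terms in note text.

This is the core classification step: a note is "sensitive" iff at least one
lexicon surface occurs in its text. Matching is casefolded, negation-agnostic
("denies etoh" counts), and comes in two modes:

``token``
    Boundary-aware: a surface matches where it appears with non-alphanumeric
    characters (or the text boundary) on both flanks, and internal single
    spaces in a phrase match any whitespace run. This is the default —
    short abbreviations like "si" or "sti" would otherwise fire inside
    ordinary words ("basin", "sting").
``substring``
    Any casefolded substring occurrence counts, mirroring a literal reading
    of direct string matching.

Each surface is matched independently, so spans of different surfaces may
overlap ("suicidal" inside "suicidal ideation"); spans of the same surface
are found left-to-right without overlap. Reported spans are 0-based
half-open character offsets into the verbatim note text.

No stemming, lemmatization, or negation detection is performed, by design.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from ._textutil import casefold_with_map
from .corpus_io import Note
from .lexicon import LexiconEntry

MODES = ("token", "substring")


class MatcherError(Exception):
    pass


@dataclass
class MatchRecord:
    """Occurrences of one lexicon surface in one note."""

    note_id: str
    surface: str
    category: str
    positions: list[tuple[int, int]] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.positions)


class TermMatcher:
    """Compiled multi-surface matcher over a lexicon.

    Surfaces are compiled to per-surface regexes on casefolded text; matched
    spans are mapped back through the casefold offset map, so offsets always
    index the verbatim note text even when casefolding changes string length.
    """

    def __init__(self, entries: Sequence[LexiconEntry], mode: str = "token"):
        if mode not in MODES:
            raise MatcherError(f"unknown mode {mode!r}; allowed: {MODES}")
        entries = list(entries)
        if not entries:
            raise MatcherError("empty lexicon")
        self.mode = mode
        self.entries = entries
        self._category = {e.surface: e.category for e in entries}
        # phrase-internal single spaces match any whitespace run
        self._patterns = {
            e.surface: re.compile(
                r"\s+".join(re.escape(tok) for tok in e.surface.split(" ")))
            for e in entries
        }

    @property
    def surfaces(self) -> list[str]:
        return [e.surface for e in self.entries]

    def provenance(self) -> dict:
        return {"mode": self.mode, "lexicon_size": len(self.entries)}

    def match_text(self, text: str, note_id: str = "") -> list[MatchRecord]:
        folded, srcmap = casefold_with_map(text)
        n = len(folded)
        records: list[MatchRecord] = []
        for surface, pattern in self._patterns.items():
            spans: list[tuple[int, int]] = []
            pos = 0
            while pos <= n:
                m = pattern.search(folded, pos)
                if m is None:
                    break
                s, e = m.start(), m.end()
                if self.mode == "token":
                    left_ok = s == 0 or not folded[s - 1].isalnum()
                    right_ok = e == n or not folded[e].isalnum()
                    if not (left_ok and right_ok):
                        pos = s + 1  # flank failed; retry overlapping start
                        continue
                spans.append((srcmap[s], srcmap[e - 1] + 1))
                pos = e if e > s else s + 1
            if spans:
                records.append(MatchRecord(
                    note_id=note_id, surface=surface,
                    category=self._category[surface], positions=spans))
        return records


def compile_matcher(entries: Sequence[LexiconEntry],
                    mode: str = "token") -> TermMatcher:
    """Compile a matcher recognizing every lexicon surface."""
    return TermMatcher(entries, mode=mode)


def match_note(text: str, matcher: TermMatcher,
               note_id: str = "") -> list[MatchRecord]:
    """Match one note's text; empty text yields no matches."""
    return matcher.match_text(text, note_id=note_id)


def match_corpus(notes: Iterable[Note], matcher: TermMatcher
                 ) -> tuple[list[MatchRecord], pd.DataFrame]:
    """Match a whole corpus and aggregate per-term frequencies.

    Returns the match records plus a per-term table with ``term_frequency``
    (total occurrences across notes) and ``note_frequency`` (distinct notes
    with at least one occurrence); ``note_frequency <= term_frequency``
    always holds.
    """
    records: list[MatchRecord] = []
    term_freq: dict[str, int] = {}
    note_freq: dict[str, int] = {}
    for note in notes:
        recs = matcher.match_text(note.text, note_id=note.note_id)
        records.extend(recs)
        for rec in recs:
            term_freq[rec.surface] = term_freq.get(rec.surface, 0) + rec.count
            note_freq[rec.surface] = note_freq.get(rec.surface, 0) + 1
    rows = [
        {"surface": s, "category": matcher._category[s],
         "term_frequency": term_freq[s], "note_frequency": note_freq[s]}
        for s in sorted(term_freq)
    ]
    aggregates = pd.DataFrame(
        rows, columns=["surface", "category", "term_frequency",
                       "note_frequency"])
    return records, aggregates


def write_matches_jsonl(records: Iterable[MatchRecord], path) -> None:
    import json
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps({
                "note_id": r.note_id, "surface": r.surface,
                "category": r.category,
                "positions": [list(p) for p in r.positions],
                "count": r.count}) + "\n")


def read_matches_jsonl(path) -> list[MatchRecord]:
    import json
    out: list[MatchRecord] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            out.append(MatchRecord(
                note_id=obj["note_id"], surface=obj["surface"],
                category=obj["category"],
                positions=[tuple(p) for p in obj["positions"]]))
    return out
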