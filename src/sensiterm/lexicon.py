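"""The categorized sensitive-term lexicon.

A lexicon is a set of casefolded surface forms (tokens or multi-token
phrases), each assigned to exactly one of four sensitive-content categories:
substance use, mental health, reproductive health, and home environment.
Entries record their origin (an expert seed term, or an expansion-derived
related term, abbreviation, or misspelling) and the seed that produced them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._textutil import normalize_surface

CATEGORIES = ("substance_use", "mental_health", "reproductive_health",
              "home_environment")
ORIGINS = ("seed", "related", "abbreviation", "misspelling")


class LexiconError(Exception):
    """Base class for lexicon construction/load failures."""


class ConflictError(LexiconError):
    """A surface form was assigned to more than one category."""


@dataclass(frozen=True)
class LexiconEntry:
    """A surface term/phrase with category, origin, and source seed."""

    surface: str
    category: str
    origin: str = "seed"
    source_seed: str = ""

    def __post_init__(self) -> None:
        surface = normalize_surface(self.surface)
        if not surface:
            raise LexiconError("surface: must be nonempty")
        object.__setattr__(self, "surface", surface)
        if self.category not in CATEGORIES:
            raise LexiconError(
                f"category: unknown {self.category!r}; allowed: "
                f"{', '.join(CATEGORIES)}")
        if self.origin not in ORIGINS:
            raise LexiconError(
                f"origin: unknown {self.origin!r}; allowed: {', '.join(ORIGINS)}")


def _check_no_conflicts(entries: Iterable[LexiconEntry]) -> list[LexiconEntry]:
    by_surface: dict[str, LexiconEntry] = {}
    out: list[LexiconEntry] = []
    for entry in entries:
        prev = by_surface.get(entry.surface)
        if prev is None:
            by_surface[entry.surface] = entry
            out.append(entry)
        elif prev.category != entry.category:
            raise ConflictError(
                f"surface {entry.surface!r} assigned to both "
                f"{prev.category!r} and {entry.category!r}")
        # same surface, same category: collapse silently (keep first)
    return out


def build_lexicon(records: Sequence, seeds: Sequence[tuple[str, str]]
                  ) -> list[LexiconEntry]:
    """Build the lexicon from finalized annotation records plus seed terms.

    Parameters
    ----------
    records
        Finalized :class:`~sensiterm.annotation.AnnotationRecord` objects;
        only those with ``final_label == "sensitive"`` enter the lexicon.
    seeds
        ``(category, surface)`` pairs; seeds are sensitive by definition.

    Returns entries with duplicates collapsed; a surface assigned to two
    categories raises :class:`ConflictError`.
    """
    entries: list[LexiconEntry] = [
        LexiconEntry(surface=s, category=c, origin="seed", source_seed=s)
        for c, s in seeds
    ]
    for rec in records:
        if rec.final_label != "sensitive":
            continue
        origin = getattr(rec, "kind", "related")
        if origin not in ORIGINS:
            origin = "related"
        entries.append(LexiconEntry(
            surface=rec.surface, category=rec.category, origin=origin,
            source_seed=getattr(rec, "seed", "")))
    return _check_no_conflicts(entries)


def save_lexicon(entries: Iterable[LexiconEntry], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["surface", "category", "origin", "source_seed"])
        for e in entries:
            writer.writerow([e.surface, e.category, e.origin, e.source_seed])
    return path


def load_lexicon(path: str | Path,
                 columns: Mapping[str, str] | None = None) -> list[LexiconEntry]:
    """Load a lexicon CSV, validating invariants.

    ``columns`` optionally maps the canonical column names (surface,
    category, origin, source_seed) to the file's actual header names, so
    externally produced term lists with different layouts can be ingested.
    A duplicate surface with conflicting categories raises
    :class:`ConflictError`; exact duplicates raise :class:`LexiconError`.
    """
    colmap = {"surface": "surface", "category": "category",
              "origin": "origin", "source_seed": "source_seed"}
    if columns:
        colmap.update(columns)
    path = Path(path)
    entries: list[LexiconEntry] = []
    seen: set[str] = set()
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        for name in (colmap["surface"], colmap["category"]):
            if name not in reader.fieldnames:
                raise LexiconError(f"header: missing column {name!r}")
        for row in reader:
            entry = LexiconEntry(
                surface=row[colmap["surface"]],
                category=row[colmap["category"]],
                origin=row.get(colmap["origin"], "seed") or "seed",
                source_seed=row.get(colmap["source_seed"], "") or "")
            if entry.surface in seen:
                raise ConflictError(f"duplicate surface {entry.surface!r}")
            seen.add(entry.surface)
            entries.append(entry)
    return _check_no_conflicts(entries)


def load_seed_terms(path: str | Path) -> list[tuple[str, str]]:
    """Read a seed-term CSV with columns ``category,surface``."""
    path = Path(path)
    seeds: list[tuple[str, str]] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or \
                not {"category", "surface"} <= set(reader.fieldnames):
            raise LexiconError("seed file requires columns category,surface")
        for row in reader:
            seeds.append((row["category"], normalize_surface(row["surface"])))
    return seeds


def by_category(entries: Iterable[LexiconEntry]) -> dict[str, list[LexiconEntry]]:
    """Partition the lexicon into its four disjoint category subsets."""
    out: dict[str, list[LexiconEntry]] = {c: [] for c in CATEGORIES}
    for e in entries:
        out[e.category].append(e)
    return out
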