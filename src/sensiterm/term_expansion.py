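"""Seed-term expansion via corpus-trained distributional embeddings.

Each expert seed keyword is expanded into up to k candidate terms drawn from
the corpus vocabulary: distributionally related terms (embedding cosine),
plus surface variants — misspellings (high normalized edit similarity, rare
relative to the seed) and abbreviations (a small conventional map plus an
initial-letter heuristic).

The embedding model is a deterministic count-based distributional model:
windowed token co-occurrence counts over the corpus (windows do not cross
line boundaries — clinical notes are line-structured), positive pointwise
mutual information (PPMI) reweighting, and truncated SVD. Multi-token
phrases in the vocabulary get compositional vectors (the mean of their
component token vectors). The whole stage is closed-form and reproducible:
identical corpus and parameters give identical vectors bit-for-bit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._textutil import edit_similarity, tokenize
from .corpus_io import Note

#: Conventional clinical abbreviations (surface -> expansion). These are
#: domain conventions, not derivable from surface form alone.
DEFAULT_ABBREVIATIONS: dict[str, str] = {
    "etoh": "alcohol",
    "thc": "marijuana",
    "mj": "marijuana",
    "cps": "child protective services",
    "si": "suicidal ideation",
    "sti": "sexually transmitted infection",
    "std": "sexually transmitted disease",
    "hiv": "human immunodeficiency virus",
    "dv": "domestic violence",
    "ocp": "oral contraceptive pill",
}


class ExpansionError(Exception):
    pass


class NotFoundError(ExpansionError, KeyError):
    """A requested token/seed is absent from the vocabulary."""


@dataclass
class Vocabulary:
    """Exact counts of casefolded tokens and multi-token phrases."""

    counts: dict[str, int]
    max_phrase_len: int
    min_count: int

    def __contains__(self, surface: str) -> bool:
        return surface in self.counts

    def __len__(self) -> int:
        return len(self.counts)

    def count(self, surface: str) -> int:
        return self.counts.get(surface, 0)


def _token_lines(text: str) -> list[list[str]]:
    return [toks for line in text.split("\n") if (toks := tokenize(line))]


def build_vocab(notes: Iterable[Note], min_count: int = 5,
                max_phrase_len: int = 4) -> Vocabulary:
    """Count all casefolded tokens and phrases of up to ``max_phrase_len``
    consecutive tokens, keeping entries with count >= ``min_count``.
    Phrases do not cross line boundaries."""
    if min_count < 1:
        raise ExpansionError(f"min_count must be >= 1, got {min_count}")
    if max_phrase_len < 1:
        raise ExpansionError(f"max_phrase_len must be >= 1, got {max_phrase_len}")
    raw: dict[str, int] = {}
    n_notes = 0
    for note in notes:
        n_notes += 1
        for toks in _token_lines(note.text):
            for i in range(len(toks)):
                for n in range(1, max_phrase_len + 1):
                    if i + n > len(toks):
                        break
                    gram = " ".join(toks[i:i + n])
                    raw[gram] = raw.get(gram, 0) + 1
    if n_notes == 0:
        raise ExpansionError("empty corpus")
    counts = {g: c for g, c in raw.items() if c >= min_count}
    return Vocabulary(counts=counts, max_phrase_len=max_phrase_len,
                      min_count=min_count)


class EmbeddingTable:
    """Fixed-length vectors over a vocabulary, with cosine neighbor lookup."""

    def __init__(self, surfaces: Sequence[str], vectors: np.ndarray):
        self.surfaces = list(surfaces)
        self.vectors = np.asarray(vectors, dtype=np.float64)
        self._index = {s: i for i, s in enumerate(self.surfaces)}
        norms = np.linalg.norm(self.vectors, axis=1)
        norms[norms == 0] = 1.0
        self._unit = self.vectors / norms[:, None]

    def __contains__(self, surface: str) -> bool:
        return surface in self._index

    def vector(self, surface: str) -> np.ndarray:
        try:
            return self.vectors[self._index[surface]]
        except KeyError:
            raise NotFoundError(f"no vector for {surface!r}") from None

    def cosine(self, a: str, b: str) -> float:
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None:
            raise NotFoundError(f"no vector for {a!r}")
        if ib is None:
            raise NotFoundError(f"no vector for {b!r}")
        return float(self._unit[ia] @ self._unit[ib])

    def similarities(self, surface: str) -> np.ndarray:
        i = self._index.get(surface)
        if i is None:
            raise NotFoundError(f"no vector for {surface!r}")
        return self._unit @ self._unit[i]

    def neighbors(self, surface: str, topn: int = 10) -> list[tuple[str, float]]:
        sims = self.similarities(surface)
        order = np.argsort(-sims, kind="stable")
        out: list[tuple[str, float]] = []
        for j in order:
            if self.surfaces[j] == surface:
                continue
            out.append((self.surfaces[j], float(sims[j])))
            if len(out) >= topn:
                break
        return out


def train_embeddings(notes: Iterable[Note], vocabulary: Vocabulary,
                     dims: int = 64, window: int = 5,
                     rng_seed: int = 0) -> EmbeddingTable:
    """Train PPMI-SVD distributional embeddings over the vocabulary.

    Token vectors come from the SVD of the PPMI-reweighted co-occurrence
    matrix; vocabulary phrases get the mean of their component token
    vectors. Tokens absent from the vocabulary still occupy stream
    positions (they widen effective context distance but contribute no
    counts); windows do not cross line boundaries. ``rng_seed`` is recorded
    for provenance; the estimator itself is closed-form and deterministic.
    """
    if dims < 2:
        raise ExpansionError(f"dims must be >= 2, got {dims}")
    if len(vocabulary) == 0:
        raise ExpansionError("empty vocabulary")
    surfaces = sorted(vocabulary.counts)
    tokens = [s for s in surfaces if " " not in s]
    index = {t: i for i, t in enumerate(tokens)}
    V = len(tokens)
    if V == 0:
        raise ExpansionError("vocabulary has no single tokens")
    cooc = np.zeros((V, V), dtype=np.float64)
    for note in notes:
        for toks in _token_lines(note.text):
            ids = [index.get(t, -1) for t in toks]
            for i, ui in enumerate(ids):
                if ui < 0:
                    continue
                for j in range(i + 1, min(i + 1 + window, len(ids))):
                    uj = ids[j]
                    if uj < 0:
                        continue
                    cooc[ui, uj] += 1.0
                    cooc[uj, ui] += 1.0
    total = cooc.sum()
    if total == 0:
        raise ExpansionError("no co-occurrences observed; corpus too small")
    row = cooc.sum(axis=1)
    row[row == 0] = 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(cooc * total / np.outer(row, row))
    ppmi = np.where(np.isfinite(pmi) & (pmi > 0), pmi, 0.0)
    k = min(dims, V)
    # dense SVD: token vocabularies here are modest and determinism matters
    u, s, _ = np.linalg.svd(ppmi, full_matrices=False)
    u, s = u[:, :k], s[:k]
    # deterministic sign convention: largest-|.| component positive
    for j in range(k):
        i_max = int(np.argmax(np.abs(u[:, j])))
        if u[i_max, j] < 0:
            u[:, j] = -u[:, j]
    token_vectors = u * np.sqrt(s)
    vectors = np.zeros((len(surfaces), k))
    for i, surface in enumerate(surfaces):
        parts = [index[t] for t in surface.split(" ") if t in index]
        if parts:
            vectors[i] = token_vectors[parts].mean(axis=0)
    return EmbeddingTable(surfaces, vectors)


@dataclass(frozen=True)
class ExpansionCandidate:
    """One candidate term produced by expanding a seed keyword."""

    surface: str
    seed: str
    distributional_score: float
    surface_score: float
    kind: str  # related | abbreviation | misspelling


@dataclass
class ExpansionConfig:
    """Ranking and classification knobs for :func:`expand_term`.

    The blended score is ``max(cosine, surface_weight * edit_similarity)``;
    candidates below the floor on both signals are excluded before the
    top-k cut. A candidate counts as a misspelling when its edit similarity
    to the seed is at least ``misspelling_similarity``, its corpus count is
    below ``misspelling_count_ratio`` of the seed's, and it is not a known
    dictionary word of the filler vocabulary.
    """

    surface_weight: float = 0.8
    floor_distributional: float = 0.2
    floor_surface: float = 0.75
    misspelling_similarity: float = 0.75
    misspelling_count_ratio: float = 0.1
    abbreviation_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ABBREVIATIONS))
    dictionary_words: frozenset[str] = frozenset()


def _is_abbreviation(candidate: str, seed: str,
                     abbrev_map: Mapping[str, str]) -> bool:
    if " " in candidate:
        return False
    expansion = abbrev_map.get(candidate)
    if expansion is not None:
        if expansion == seed or seed in expansion.split():
            return True
    seed_tokens = seed.split()
    if len(seed_tokens) > 1:
        initials = "".join(t[0] for t in seed_tokens)
        return candidate == initials
    if len(candidate) >= len(seed) or len(candidate) > (len(seed) + 1) // 2:
        return False
    if not candidate or candidate[0] != seed[0]:
        return False
    it = iter(seed)
    return all(ch in it for ch in candidate)


def expand_term(seed: str, embeddings: EmbeddingTable, vocabulary: Vocabulary,
                k: int = 60, config: ExpansionConfig | None = None
                ) -> list[ExpansionCandidate]:
    """Expand one seed into at most k ranked candidates.

    Ranking is by blended score (descending), ties broken lexicographically
    by surface; every candidate is unique and differs from the seed.
    """
    if config is None:
        config = ExpansionConfig()
    seed = " ".join(seed.casefold().split())
    if seed not in vocabulary:
        raise NotFoundError(f"seed {seed!r} not in vocabulary")
    if k <= 0:
        return []
    sims = embeddings.similarities(seed) if seed in embeddings else None
    seed_count = vocabulary.count(seed)
    scored: list[tuple[float, str, float, float]] = []
    for i, surface in enumerate(embeddings.surfaces):
        if surface == seed:
            continue
        cos = float(sims[i]) if sims is not None else 0.0
        surf = edit_similarity(surface, seed)
        if cos < config.floor_distributional and surf < config.floor_surface:
            continue
        blended = max(cos, config.surface_weight * surf)
        scored.append((blended, surface, cos, surf))
    scored.sort(key=lambda t: (-t[0], t[1]))
    out: list[ExpansionCandidate] = []
    for blended, surface, cos, surf in scored[:k]:
        if _is_abbreviation(surface, seed, config.abbreviation_map):
            kind = "abbreviation"
        elif (surf >= config.misspelling_similarity
              and surface not in config.dictionary_words
              and vocabulary.count(surface) < config.misspelling_count_ratio
              * max(seed_count, 1)):
            kind = "misspelling"
        else:
            kind = "related"
        out.append(ExpansionCandidate(
            surface=surface, seed=seed, distributional_score=cos,
            surface_score=surf, kind=kind))
    return out


@dataclass
class DedupedCandidate:
    """A unique surface form with every seed that produced it."""

    surface: str
    seeds: list[str]
    candidates: list[ExpansionCandidate]


def dedupe_candidates(per_seed_lists: Iterable[Sequence[ExpansionCandidate]]
                      ) -> list[DedupedCandidate]:
    """Collapse per-seed candidate lists to unique surfaces with provenance."""
    by_surface: dict[str, DedupedCandidate] = {}
    for lst in per_seed_lists:
        for cand in lst:
            entry = by_surface.get(cand.surface)
            if entry is None:
                by_surface[cand.surface] = DedupedCandidate(
                    surface=cand.surface, seeds=[cand.seed],
                    candidates=[cand])
            else:
                if cand.seed not in entry.seeds:
                    entry.seeds.append(cand.seed)
                entry.candidates.append(cand)
    return [by_surface[s] for s in sorted(by_surface)]


def write_candidate_worksheet(candidates_by_seed: Mapping[str, Sequence[ExpansionCandidate]],
                              seed_categories: Mapping[str, str],
                              path: str | Path) -> Path:
    """Write the annotation worksheet CSV (label columns left blank)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["surface", "seed", "category",
                         "distributional_score", "surface_score", "kind",
                         "label_a", "label_b"])
        for seed in sorted(candidates_by_seed):
            for c in candidates_by_seed[seed]:
                writer.writerow([
                    c.surface, c.seed, seed_categories[seed],
                    f"{c.distributional_score:.6f}",
                    f"{c.surface_score:.6f}", c.kind, "", ""])
    return path
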