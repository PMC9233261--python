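"""Note-level flagging and stratified prevalence analytics.

The unit of analysis is the note: a note is flagged when it contains at
least one sensitive term of any category, and per-category flags record
which categories appear. Prevalence tables stratify flags by age, note
type, provider type, care setting, specialty, or category; pairwise group
comparisons use the two-sided Fisher exact test. Percentages are rounded
half-away-from-zero at the requested precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from math import comb
from typing import Iterable, Sequence

import pandas as pd

from .corpus_io import Note
from .lexicon import CATEGORIES
from .matching import MatchRecord

STRATIFIERS = ("age_years", "note_type", "provider_type", "setting",
               "specialty", "category")


class PrevalenceError(Exception):
    pass


# ------------------------------------------------------------------ rounding

def percent(numerator: int, denominator: int, precision: int = 2) -> float:
    """Percentage rounded half-away-from-zero to ``precision`` decimals."""
    if denominator == 0:
        raise PrevalenceError("denominator must be >= 1")
    value = Decimal(numerator) * 100 / Decimal(denominator)
    quantum = Decimal(1).scaleb(-precision)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Prevalence:
    proportion: float
    percent: float
    formatted: str


def prevalence(n_flagged: int, n_notes: int, precision: int = 2) -> Prevalence:
    """Proportion and formatted percent for a flagged/total count pair."""
    if n_notes < 1:
        raise PrevalenceError("n_notes must be >= 1")
    if n_flagged < 0 or n_flagged > n_notes:
        raise PrevalenceError(
            f"n_flagged {n_flagged} outside [0, n_notes={n_notes}]")
    pct = percent(n_flagged, n_notes, precision)
    return Prevalence(proportion=n_flagged / n_notes, percent=pct,
                      formatted=f"{pct:.{precision}f}%")


# ------------------------------------------------------------------ flagging

def flag_notes(matches: Iterable[MatchRecord],
               notes: Sequence[Note]) -> pd.DataFrame:
    """Per-note flags: one boolean column per category plus ``any``.

    A note is flagged for a category iff it has at least one match of that
    category; ``any`` is the OR over categories. A match whose note_id is
    absent from the corpus raises :class:`PrevalenceError`.
    """
    ids = [n.note_id for n in notes]
    known = set(ids)
    flags = pd.DataFrame(False, index=pd.Index(ids, name="note_id"),
                         columns=list(CATEGORIES))
    for m in matches:
        if m.note_id not in known:
            raise PrevalenceError(
                f"match references unknown note_id {m.note_id!r}")
        flags.loc[m.note_id, m.category] = True
    flags["any"] = flags[list(CATEGORIES)].any(axis=1)
    return flags


@dataclass(frozen=True)
class PrevalenceCell:
    """A stratum's note count, flagged count, and proportion."""

    stratum: tuple[tuple[str, object], ...]
    n_notes: int
    n_flagged: int

    @property
    def proportion(self) -> float:
        return self.n_flagged / self.n_notes if self.n_notes else 0.0


def _notes_frame(notes: Sequence[Note]) -> pd.DataFrame:
    return pd.DataFrame(
        {"note_id": [n.note_id for n in notes],
         "age_years": [n.age_years for n in notes],
         "note_type": [n.note_type for n in notes],
         "provider_type": [n.provider_type for n in notes],
         "setting": [n.setting for n in notes],
         "specialty": [n.specialty for n in notes]}).set_index("note_id")


def stratified_prevalence(notes: Sequence[Note], flags: pd.DataFrame,
                          by: Sequence[str]) -> pd.DataFrame:
    """Prevalence cells for every observed combination of ``by`` variables.

    Cells of one stratification partition the corpus: their note counts sum
    to the corpus size. Stratifying by ``category`` repeats the partition
    per category using the per-category flags (counts then sum to corpus
    size once per category).
    """
    unknown = [v for v in by if v not in STRATIFIERS]
    if unknown:
        raise PrevalenceError(
            f"unknown stratification variable(s): {', '.join(unknown)}; "
            f"allowed: {', '.join(STRATIFIERS)}")
    if not by:
        raise PrevalenceError("need at least one stratification variable")
    df = _notes_frame(notes)
    meta_vars = [v for v in by if v != "category"]
    rows = []
    categories = list(CATEGORIES) if "category" in by else [None]
    for cat in categories:
        flag_col = flags[cat] if cat is not None else flags["any"]
        work = df.copy()
        work["_flag"] = flag_col.reindex(work.index).fillna(False)
        if meta_vars:
            grouped = work.groupby(meta_vars, observed=True)["_flag"] \
                .agg(n_notes="size", n_flagged="sum").reset_index()
        else:
            grouped = pd.DataFrame(
                {"n_notes": [len(work)], "n_flagged": [int(work["_flag"].sum())]})
        if cat is not None:
            grouped.insert(0, "category", cat)
        rows.append(grouped)
    out = pd.concat(rows, ignore_index=True)
    out["n_flagged"] = out["n_flagged"].astype(int)
    out["proportion"] = out["n_flagged"] / out["n_notes"]
    return out


def cells_from_frame(frame: pd.DataFrame) -> list[PrevalenceCell]:
    """Convert a stratified_prevalence frame to PrevalenceCell objects."""
    strat_cols = [c for c in frame.columns
                  if c not in ("n_notes", "n_flagged", "proportion")]
    return [PrevalenceCell(
        stratum=tuple((c, row[c]) for c in strat_cols),
        n_notes=int(row["n_notes"]), n_flagged=int(row["n_flagged"]))
        for _, row in frame.iterrows()]


# ----------------------------------------------------------------- top terms

def top_terms(aggregates: pd.DataFrame, category: str,
              n: int = 10) -> pd.DataFrame:
    """Top-n terms of one category by term frequency (ties lexicographic)."""
    if n < 1:
        raise PrevalenceError("n must be >= 1")
    if category not in CATEGORIES:
        raise PrevalenceError(f"unknown category {category!r}")
    sub = aggregates[aggregates["category"] == category]
    sub = sub.sort_values(["term_frequency", "surface"],
                          ascending=[False, True], kind="stable")
    return sub.head(n)[["surface", "term_frequency",
                        "note_frequency"]].reset_index(drop=True)


# -------------------------------------------------------------- fisher exact

def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Enumerates the hypergeometric distribution with the observed margins
    and sums the probabilities of all tables whose probability does not
    exceed the observed table's. Tie comparisons use exact integer
    arithmetic (products of binomial coefficients), so no floating-point
    tie tolerance is needed; only the final sum is floating point.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise PrevalenceError("table cells must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise PrevalenceError("all margins must be positive")
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    # weight(k) = C(r1,k)*C(r2,c1-k); pmf(k) = weight(k)/C(n,c1)
    weights = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    num = sum(w for w in weights if w <= w_obs)
    # Fraction handles numerator/denominator beyond float range exactly
    return float(Fraction(num, comb(n, c1)))


def compare_groups(cell_a, cell_b, alpha: float = 0.05,
                   bonferroni_m: int = 1) -> tuple[float, bool]:
    """Fisher exact comparison of two disjoint prevalence cells.

    Accepts :class:`PrevalenceCell` objects or ``(n_flagged, n_notes)``
    pairs. No multiple-testing correction is applied by default; pass
    ``bonferroni_m`` > 1 to test at alpha/m.
    """
    def _counts(cell) -> tuple[int, int]:
        if isinstance(cell, PrevalenceCell):
            return cell.n_flagged, cell.n_notes
        flagged, total = cell
        return int(flagged), int(total)

    fa, na = _counts(cell_a)
    fb, nb = _counts(cell_b)
    p = fisher_exact([[fa, na - fa], [fb, nb - fb]])
    return p, p < alpha / max(bonferroni_m, 1)


# ------------------------------------------------------------- figure tables

def age_category_curve(notes: Sequence[Note],
                       flags: pd.DataFrame) -> pd.DataFrame:
    """Per-(age, category) flagged proportions (tidy, one row per cell)."""
    return stratified_prevalence(notes, flags, by=["category", "age_years"])


def age_notetype_heatmap(notes: Sequence[Note],
                         flags: pd.DataFrame) -> pd.DataFrame:
    """Per-(age, note type) any-flag proportions; strata with no notes are
    absent from the table, not reported as zero."""
    return stratified_prevalence(notes, flags, by=["age_years", "note_type"])


def plot_heatmap(heatmap_frame: pd.DataFrame, path) -> None:
    """Optional matplotlib rendering of the age x note-type heatmap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = heatmap_frame.pivot(index="note_type", columns="age_years",
                                values="proportion")
    fig, ax = plt.subplots(figsize=(10, 4))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="viridis",
                   vmin=0, vmax=1)
    ax.set_yticks(range(len(pivot.index)), pivot.index)
    ax.set_xticks(range(len(pivot.columns)), pivot.columns)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("note type")
    fig.colorbar(im, ax=ax, label="fraction of notes flagged")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
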