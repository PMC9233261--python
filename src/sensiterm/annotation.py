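"""Two-annotator labeling of candidate terms and interrater agreement.

Candidate terms produced by expansion are labeled sensitive / not-sensitive
by two annotators; agreement is quantified with Cohen's kappa and
disagreements are resolved by explicit adjudication. Labels are term-level
— a term is sensitive or not globally, never per mention.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._textutil import normalize_surface
from .lexicon import CATEGORIES

LABELS = ("sensitive", "not_sensitive")

_LABEL_SYNONYMS = {"not sensitive": "not_sensitive", "s": "sensitive",
                   "n": "not_sensitive", "nonsensitive": "not_sensitive"}


class AnnotationError(Exception):
    pass


class UnresolvedDisagreementError(AnnotationError):
    """Disagreeing records lacked an adjudicated resolution."""

    def __init__(self, surfaces: Sequence[str]):
        self.surfaces = list(surfaces)
        super().__init__(
            "unresolved disagreement on: " + ", ".join(self.surfaces))


def _canon_label(label: str, field: str) -> str:
    v = str(label).strip().lower().replace("-", "_")
    v = _LABEL_SYNONYMS.get(v, v)
    if v not in LABELS:
        raise AnnotationError(f"{field}: unknown label {label!r}")
    return v


@dataclass
class AnnotationRecord:
    """One candidate term with both annotators' labels and the final label.

    Invariants: on agreement the final label equals both annotators' label
    and ``adjudicated`` is False; on disagreement the final label must have
    been supplied explicitly and ``adjudicated`` is True.
    """

    surface: str
    category: str
    label_a: str
    label_b: str
    final_label: str
    adjudicated: bool
    seed: str = ""
    kind: str = "related"

    def __post_init__(self) -> None:
        self.surface = normalize_surface(self.surface)
        if self.category not in CATEGORIES:
            raise AnnotationError(f"category: unknown {self.category!r}")
        self.label_a = _canon_label(self.label_a, "label_a")
        self.label_b = _canon_label(self.label_b, "label_b")
        self.final_label = _canon_label(self.final_label, "final_label")
        if self.label_a == self.label_b:
            if self.adjudicated or self.final_label != self.label_a:
                raise AnnotationError(
                    f"{self.surface!r}: agreeing labels must carry "
                    "final_label equal to both and adjudicated=False")
        elif not self.adjudicated:
            raise AnnotationError(
                f"{self.surface!r}: disagreeing labels require adjudication")


def cohen_kappa(labels_a: Sequence[str], labels_b: Sequence[str]) -> float:
    """Cohen's chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    ``p_o`` is the observed agreement fraction and ``p_e`` the chance
    agreement implied by the two annotators' marginal label frequencies.
    In the degenerate case p_e = 1 (both annotators used one identical
    label throughout) kappa is undefined; by convention this returns 1.0
    when agreement is perfect and 0.0 otherwise, with a warning.
    """
    if len(labels_a) != len(labels_b):
        raise AnnotationError(
            f"label sequences differ in length: {len(labels_a)} vs "
            f"{len(labels_b)}")
    n = len(labels_a)
    if n == 0:
        raise AnnotationError("empty label sequences")
    p_o = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    labels = set(labels_a) | set(labels_b)
    p_e = sum(
        (sum(a == lab for a in labels_a) / n)
        * (sum(b == lab for b in labels_b) / n)
        for lab in labels
    )
    if p_e >= 1.0 - 1e-15:
        warnings.warn(
            "kappa undefined (chance agreement = 1): both annotators used a "
            "single label; returning the conventional value",
            stacklevel=2)
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def adjudicate(drafts: Iterable, resolutions: Mapping[str, str] | None = None
               ) -> list[AnnotationRecord]:
    """Finalize draft annotations, applying explicit disagreement resolutions.

    ``drafts`` are objects with surface/category/label_a/label_b (e.g. rows
    from :func:`read_worksheet`); ``resolutions`` maps surface form to the
    final label for every disagreeing record. Missing resolutions raise
    :class:`UnresolvedDisagreementError` listing the offending surfaces.
    """
    resolutions = {normalize_surface(k): _canon_label(v, "resolution")
                   for k, v in (resolutions or {}).items()}
    unresolved: list[str] = []
    out: list[AnnotationRecord] = []
    for d in drafts:
        surface = normalize_surface(d.surface)
        label_a = _canon_label(d.label_a, "label_a")
        label_b = _canon_label(d.label_b, "label_b")
        if label_a == label_b:
            final, adj = label_a, False
        elif surface in resolutions:
            final, adj = resolutions[surface], True
        else:
            unresolved.append(surface)
            continue
        out.append(AnnotationRecord(
            surface=surface, category=d.category, label_a=label_a,
            label_b=label_b, final_label=final, adjudicated=adj,
            seed=getattr(d, "seed", ""), kind=getattr(d, "kind", "related")))
    if unresolved:
        raise UnresolvedDisagreementError(unresolved)
    return out


@dataclass(frozen=True)
class SensitiveFraction:
    n_sensitive: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_sensitive / self.n_total

    def percent(self, precision: int = 0) -> float:
        from .prevalence import percent
        return percent(self.n_sensitive, self.n_total, precision)


def sensitive_fraction(records: Sequence[AnnotationRecord]) -> SensitiveFraction:
    """Count records finalized as sensitive; errors on an empty collection."""
    records = list(records)
    if not records:
        raise AnnotationError("no records")
    n_sens = sum(r.final_label == "sensitive" for r in records)
    return SensitiveFraction(n_sensitive=n_sens, n_total=len(records))


# ---------------------------------------------------------------- worksheet IO

@dataclass
class WorksheetRow:
    surface: str
    seed: str
    category: str
    distributional_score: float
    surface_score: float
    kind: str
    label_a: str = ""
    label_b: str = ""


_WORKSHEET_COLS = ["surface", "seed", "category", "distributional_score",
                   "surface_score", "kind", "label_a", "label_b"]


def read_worksheet(path: str | Path) -> list[WorksheetRow]:
    """Read a candidate worksheet CSV with annotator labels filled in."""
    rows: list[WorksheetRow] = []
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or \
                not set(_WORKSHEET_COLS) <= set(reader.fieldnames):
            raise AnnotationError(
                f"worksheet requires columns {', '.join(_WORKSHEET_COLS)}")
        for row in reader:
            rows.append(WorksheetRow(
                surface=row["surface"], seed=row["seed"],
                category=row["category"],
                distributional_score=float(row["distributional_score"] or 0),
                surface_score=float(row["surface_score"] or 0),
                kind=row["kind"], label_a=row["label_a"],
                label_b=row["label_b"]))
    return rows


def read_resolutions(path: str | Path) -> dict[str, str]:
    """Read a two-column CSV ``surface,final_label`` of adjudications."""
    out: dict[str, str] = {}
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or \
                not {"surface", "final_label"} <= set(reader.fieldnames):
            raise AnnotationError(
                "resolutions file requires columns surface,final_label")
        for row in reader:
            out[normalize_surface(row["surface"])] = row["final_label"]
    return out
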