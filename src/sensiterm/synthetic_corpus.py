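"""Synthetic pediatric note corpus with exact planting ground truth.

Generates a corpus of template-based clinical notes in which sensitive terms
are planted at configured per-stratum rates, so every downstream stage
(expansion, matching, prevalence) is testable with known truth. The default
configuration emulates the statistical structure of a large single-center
pediatric cohort: ~70/25/5 ambulatory/emergency/inpatient encounter mix,
~75% of patients under 13, mental-health planting rates that rise from age
10 through adolescence, substance-use and reproductive-health rates elevated
in the first year of life (carried by maternal-history template lines), and
an overall note-level sensitive prevalence calibrated to ~37.5%.

Exactness guarantee: filler/template text is drawn from a closed vocabulary
checked at generation time to contain no lexicon surface (token mode), and
every planted term is embedded verbatim with word boundaries. A token-mode
matcher therefore recovers exactly the planted notes — precision = recall = 1.

All randomness flows through one numpy Generator seeded from the config;
identical config and seed give a byte-identical corpus and ground truth.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus_io import NOTE_TYPES, PROVIDER_TYPES, SETTINGS, Note
from .lexicon import CATEGORIES, LexiconEntry

# ----------------------------------------------------------------- age bands

AGE_BANDS: tuple[tuple[int, int, str], ...] = (
    (0, 0, "0"), (1, 5, "1-5"), (6, 9, "6-9"),
    (10, 12, "10-12"), (13, 17, "13-17"), (18, 21, "18-21"),
)
BAND_LABELS = tuple(label for _, _, label in AGE_BANDS)


def age_band(age: int) -> str:
    for lo, hi, label in AGE_BANDS:
        if lo <= age <= hi:
            return label
    raise ValueError(f"age {age} outside 0-21")


class ConfigurationError(Exception):
    pass


# -------------------------------------------------------------------- config

@dataclass
class CorpusConfig:
    """Generator parameters; all probabilities in [0, 1], all stated
    proportion vectors sum to 1 (validated to 1e-9)."""

    n_patients: int
    rng_seed: int
    encounter_mix: dict[str, float]
    age_distribution: np.ndarray  # proportions over integer ages 0..21
    plant_rates: dict[tuple[str, str, str], float]  # (category, band, note_type)
    misspelling_rate: float = 0.05
    abbreviation_rate: float = 0.10
    extra_term_rate: float = 0.30  # chance of a 2nd same-category term
    notes_per_encounter: dict[int, float] = field(
        default_factory=lambda: {1: 0.45, 2: 0.35, 3: 0.20})
    encounters_per_patient: dict[int, float] = field(
        default_factory=lambda: {1: 0.45, 2: 0.25, 3: 0.15, 4: 0.10, 5: 0.05})
    provider_mix: dict[str, float] = field(
        default_factory=lambda: {"resident": 0.3792, "attending": 0.3535,
                                 "fellow": 0.1678, "app": 0.0995})
    inpatient_note_mix: dict[str, float] = field(
        default_factory=lambda: {"hp": 0.26, "ipn": 0.44, "icn": 0.14,
                                 "ids": 0.16})
    specialty_mix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "ambulatory": {"primary_care": 0.62, "behavioral_health": 0.08,
                           "obstetrics_gynecology": 0.04,
                           "pain_management": 0.015,
                           "child_abuse_pediatrics": 0.015,
                           "subspecialty_other": 0.23},
            "emergency": {"emergency_medicine": 1.0},
            "inpatient": {"hospital_medicine": 1.0},
        })
    specialty_boosts: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "behavioral_health": {"mental_health": 2.4},
            "obstetrics_gynecology": {"reproductive_health": 3.2},
            "pain_management": {"substance_use": 2.6, "mental_health": 1.8},
            "child_abuse_pediatrics": {"home_environment": 3.4,
                                       "mental_health": 1.5},
        })
    max_rate: float = 0.97  # cap applied after boosts

    def validate(self) -> None:
        def _check_dist(d: Mapping, name: str) -> None:
            vals = np.asarray(list(d.values()), dtype=float)
            if (vals < 0).any() or (vals > 1).any():
                raise ConfigurationError(f"{name}: probabilities outside [0,1]")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"{name}: proportions sum to {vals.sum()!r}, not 1")

        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be positive")
        _check_dist(self.encounter_mix, "encounter_mix")
        if set(self.encounter_mix) != set(SETTINGS):
            raise ConfigurationError("encounter_mix must cover all settings")
        ages = np.asarray(self.age_distribution, dtype=float)
        if ages.shape != (22,):
            raise ConfigurationError("age_distribution must have 22 entries")
        if (ages < 0).any() or abs(ages.sum() - 1.0) > 1e-9:
            raise ConfigurationError("age_distribution must be a distribution")
        for key, p in self.plant_rates.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"plant_rates[{key}]: {p} outside [0,1]")
        for p in (self.misspelling_rate, self.abbreviation_rate,
                  self.extra_term_rate):
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError("rates must be in [0,1]")
        if self.misspelling_rate + self.abbreviation_rate > 1.0:
            raise ConfigurationError(
                "misspelling_rate + abbreviation_rate must be <= 1")
        _check_dist(self.notes_per_encounter, "notes_per_encounter")
        _check_dist(self.encounters_per_patient, "encounters_per_patient")
        _check_dist(self.provider_mix, "provider_mix")
        _check_dist(self.inpatient_note_mix, "inpatient_note_mix")
        for setting, mix in self.specialty_mix.items():
            _check_dist(mix, f"specialty_mix[{setting}]")

    def plant_probability(self, category: str, age: int, note_type: str,
                          specialty: str) -> float:
        """Effective planting probability for one note stratum."""
        p = self.plant_rates.get((category, age_band(age), note_type), 0.0)
        boost = self.specialty_boosts.get(specialty, {}).get(category, 1.0)
        return min(p * boost, self.max_rate)


# Per-(category, age band) base rates; multiplied by a note-type factor to
# give plant_rates. Calibrated once so the enumerated expected any-flag
# marginal under the default mix is ~0.375; adolescent mental-health rates
# rise from age 10, substance-use/reproductive-health rates peak at age 0
# (maternal history) and again in adolescence.
_BASE_RATES: dict[str, dict[str, float]] = {
    "mental_health":       {"0": 0.081, "1-5": 0.091, "6-9": 0.127,
                            "10-12": 0.199, "13-17": 0.290, "18-21": 0.299},
    "substance_use":       {"0": 0.181, "1-5": 0.045, "6-9": 0.055,
                            "10-12": 0.081, "13-17": 0.144, "18-21": 0.181},
    "reproductive_health": {"0": 0.163, "1-5": 0.027, "6-9": 0.036,
                            "10-12": 0.063, "13-17": 0.136, "18-21": 0.190},
    "home_environment":    {"0": 0.045, "1-5": 0.055, "6-9": 0.063,
                            "10-12": 0.072, "13-17": 0.081, "18-21": 0.081},
}
# H&P notes carry the most screening documentation; ambulatory progress
# notes the next most.
_NOTE_TYPE_FACTORS = {"hp": 1.60, "apn": 1.15, "epn": 0.80, "icn": 0.95,
                      "ids": 1.05, "ipn": 0.90}


def _default_age_distribution() -> np.ndarray:
    """Patient age mass: 74.84% under 13 (age 0 double-weighted for the
    birth cohort), 21.23% aged 13-17, 3.92% aged 18-21."""
    ages = np.zeros(22)
    young = 0.7484
    ages[0] = young * 2.0 / 14.0
    ages[1:13] = young / 14.0
    ages[13:18] = 0.2123 / 5.0
    ages[18:22] = 0.0393 / 4.0
    return ages / ages.sum()


def default_config(n_patients: int = 1500, rng_seed: int = 0) -> CorpusConfig:
    """The default study conditions (encounter mix, age mass, plant rates)."""
    plant_rates = {
        (cat, band, nt): min(_BASE_RATES[cat][band] * f, 0.97)
        for cat in CATEGORIES
        for band in BAND_LABELS
        for nt, f in _NOTE_TYPE_FACTORS.items()
    }
    cfg = CorpusConfig(
        n_patients=n_patients,
        rng_seed=rng_seed,
        encounter_mix={"ambulatory": 536201 / 763133,
                       "emergency": 188204 / 763133,
                       "inpatient": 38728 / 763133},
        age_distribution=_default_age_distribution(),
        plant_rates=plant_rates,
    )
    cfg.validate()
    return cfg


# ------------------------------------------------------------- seed lexicon

def default_seed_terms() -> list[tuple[str, str]]:
    """27 expert seed keywords, 5-10 per category (synthetic analogue)."""
    seeds = {
        "substance_use": ["alcohol", "tobacco", "substance", "marijuana",
                          "cocaine", "smoker", "cigarettes"],
        "mental_health": ["anxiety", "depression", "suicidal", "suicide",
                          "mood", "panic", "bipolar"],
        "reproductive_health": ["pregnancy", "sexual", "contraception",
                                "chlamydia", "gonorrhea", "menses", "hiv"],
        "home_environment": ["neglect", "bullying", "conflict", "weapons",
                             "custody", "foster"],
    }
    return [(cat, term) for cat in CATEGORIES for term in seeds[cat]]


def default_lexicon() -> list[LexiconEntry]:
    """Synthetic stand-in study lexicon: seeds plus expansion-style variants.

    Cross-category token containment is avoided by construction so that
    per-note category flags recovered by a token matcher equal the planted
    categories exactly.
    """
    entries = [LexiconEntry(surface=s, category=c, origin="seed",
                            source_seed=s)
               for c, s in default_seed_terms()]
    related = [
        ("substance_use", "heroin", "cocaine"),
        ("substance_use", "vaping", "tobacco"),
        ("substance_use", "intoxication", "alcohol"),
        ("mental_health", "suicidal ideation", "suicidal"),
        ("mental_health", "ptsd", "anxiety"),
        ("mental_health", "depressive", "depression"),
        ("reproductive_health", "sexually active", "sexual"),
        ("reproductive_health", "contraceptive", "contraception"),
        ("home_environment", "bullied", "bullying"),
        ("home_environment", "firearms", "weapons"),
    ]
    abbreviations = [
        ("substance_use", "etoh", "alcohol"),
        ("substance_use", "thc", "marijuana"),
        ("mental_health", "si", "suicidal"),
        ("reproductive_health", "sti", "sexual"),
        ("home_environment", "cps", "custody"),
    ]
    misspellings = [
        ("substance_use", "alchol", "alcohol"),
        ("substance_use", "tabacco", "tobacco"),
        ("substance_use", "marijuanna", "marijuana"),
        ("mental_health", "anxeity", "anxiety"),
        ("mental_health", "depresion", "depression"),
        ("reproductive_health", "pregnacy", "pregnancy"),
        ("home_environment", "negelct", "neglect"),
    ]
    for cat, surface, seed in related:
        entries.append(LexiconEntry(surface=surface, category=cat,
                                    origin="related", source_seed=seed))
    for cat, surface, seed in abbreviations:
        entries.append(LexiconEntry(surface=surface, category=cat,
                                    origin="abbreviation", source_seed=seed))
    for cat, surface, seed in misspellings:
        entries.append(LexiconEntry(surface=surface, category=cat,
                                    origin="misspelling", source_seed=seed))
    return entries


# ---------------------------------------------------------------- templates

@dataclass
class Templates:
    """Note templates: per-type headers/filler and per-category carrier
    lines with a ``{TERM}`` placeholder; age-0 maternal-history carriers
    reproduce the infancy elevation of substance/reproductive documentation."""

    headers: dict[str, str]
    filler: list[str]
    carriers: dict[str, list[str]]
    maternal_carriers: dict[str, list[str]]

    def validate_coverage(self) -> None:
        missing = [t for t in NOTE_TYPES if t not in self.headers]
        if missing:
            raise ConfigurationError(
                f"templates missing note type(s): {', '.join(missing)}")
        missing_c = [c for c in CATEGORIES if not self.carriers.get(c)]
        if missing_c:
            raise ConfigurationError(
                f"templates missing carrier(s) for: {', '.join(missing_c)}")

    def all_template_text(self) -> str:
        """Every template line with placeholders removed (for purity checks)."""
        parts = list(self.headers.values()) + list(self.filler)
        for lines in list(self.carriers.values()) + \
                list(self.maternal_carriers.values()):
            parts.extend(line.replace("{TERM}", " ") for line in lines)
        return "\n".join(parts)


def default_templates() -> Templates:
    headers = {
        "hp": "admission history and physical documented .",
        "apn": "ambulatory clinic progress documented today .",
        "epn": "emergency department evaluation documented .",
        "icn": "consultation requested and completed .",
        "ids": "discharge summary prepared with followup plan .",
        "ipn": "inpatient daily progress documented .",
    }
    filler = [
        "patient seen and examined today .",
        "vitals reviewed and within normal limits .",
        "growth and development appropriate for age .",
        "diet , sleep , and activity reviewed .",
        "immunizations current per record .",
        "lungs clear , heart regular , abdomen soft .",
        "alert and comfortable on examination .",
        "plan : continue current care and return in two weeks .",
        "medications and allergies reviewed , no changes .",
        "followup arranged with primary clinic .",
        "hydration encouraged , rest advised .",
        "no acute distress observed during visit .",
    ]
    carriers = {
        "substance_use": [
            "social history reviewed : patient reports {TERM} exposure .",
            "screening questions completed : {TERM} discussed .",
        ],
        "mental_health": [
            "psychosocial screening completed : {TERM} noted on review .",
            "behavioral review performed : {TERM} discussed with patient .",
        ],
        "reproductive_health": [
            "confidential history obtained : {TERM} discussed .",
            "adolescent private interview : {TERM} reviewed .",
        ],
        "home_environment": [
            "family situation reviewed : {TERM} mentioned .",
            "safety assessment completed : {TERM} discussed .",
        ],
    }
    maternal_carriers = {
        "substance_use": [
            "maternal history notable for {TERM} during gestation .",
            "birth record documents maternal {TERM} exposure .",
        ],
        "reproductive_health": [
            "maternal history notable for {TERM} .",
            "perinatal record documents maternal {TERM} .",
        ],
    }
    return Templates(headers=headers, filler=filler, carriers=carriers,
                     maternal_carriers=maternal_carriers)


def save_templates(templates: Templates, directory: str | Path) -> Path:
    """Write templates as plain-text files, one directory per note type."""
    directory = Path(directory)
    for nt in templates.headers:
        d = directory / nt
        d.mkdir(parents=True, exist_ok=True)
        (d / "header.txt").write_text(templates.headers[nt] + "\n",
                                      encoding="utf-8")
        (d / "filler.txt").write_text("\n".join(templates.filler) + "\n",
                                      encoding="utf-8")
    shared = directory / "carriers"
    shared.mkdir(parents=True, exist_ok=True)
    for cat, lines in templates.carriers.items():
        (shared / f"{cat}.txt").write_text("\n".join(lines) + "\n",
                                           encoding="utf-8")
    for cat, lines in templates.maternal_carriers.items():
        (shared / f"maternal_{cat}.txt").write_text(
            "\n".join(lines) + "\n", encoding="utf-8")
    return directory


def load_templates(directory: str | Path) -> Templates:
    directory = Path(directory)
    headers: dict[str, str] = {}
    filler: list[str] = []
    for nt in NOTE_TYPES:
        d = directory / nt
        if not d.is_dir():
            raise ConfigurationError(f"missing template directory for {nt!r}")
        headers[nt] = (d / "header.txt").read_text(encoding="utf-8").strip()
        if not filler:
            filler = [ln for ln in (d / "filler.txt").read_text(
                encoding="utf-8").splitlines() if ln.strip()]
    carriers: dict[str, list[str]] = {}
    maternal: dict[str, list[str]] = {}
    shared = directory / "carriers"
    for cat in CATEGORIES:
        f = shared / f"{cat}.txt"
        if f.exists():
            carriers[cat] = [ln for ln in f.read_text(
                encoding="utf-8").splitlines() if ln.strip()]
        m = shared / f"maternal_{cat}.txt"
        if m.exists():
            maternal[cat] = [ln for ln in m.read_text(
                encoding="utf-8").splitlines() if ln.strip()]
    return Templates(headers=headers, filler=filler, carriers=carriers,
                     maternal_carriers=maternal)


# ------------------------------------------------------------- ground truth

@dataclass(frozen=True)
class PlantedTerm:
    surface: str      # post-corruption surface form, verbatim in the note
    category: str
    canonical: str    # the canonical lexicon term that was planted
    corrupted: bool   # True when a misspelling variant was emitted


@dataclass
class GroundTruth:
    """Per-note record of every planted term."""

    planted: dict[str, list[PlantedTerm]]

    def flagged_note_ids(self, category: str | None = None) -> set[str]:
        if category is None:
            return {nid for nid, terms in self.planted.items() if terms}
        return {nid for nid, terms in self.planted.items()
                if any(t.category == category for t in terms)}

    def categories_for(self, note_id: str) -> set[str]:
        return {t.category for t in self.planted.get(note_id, [])}

    def write_jsonl(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            for nid in self.planted:
                fh.write(json.dumps({
                    "note_id": nid,
                    "planted": [{"surface": t.surface, "category": t.category,
                                 "canonical": t.canonical,
                                 "corrupted": t.corrupted}
                                for t in self.planted[nid]]}) + "\n")
        return path

    @classmethod
    def read_jsonl(cls, path: str | Path) -> "GroundTruth":
        planted: dict[str, list[PlantedTerm]] = {}
        with Path(path).open("r", encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                obj = json.loads(line)
                planted[obj["note_id"]] = [
                    PlantedTerm(surface=t["surface"], category=t["category"],
                                canonical=t["canonical"],
                                corrupted=t["corrupted"])
                    for t in obj["planted"]]
        return cls(planted=planted)


# ---------------------------------------------------------------- generator

def _categorical(rng: np.random.Generator, dist: Mapping) -> object:
    keys = list(dist.keys())
    probs = np.asarray([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _check_filler_purity(templates: Templates,
                         entries: Sequence[LexiconEntry]) -> None:
    from .matching import compile_matcher
    matcher = compile_matcher(entries, mode="token")
    hits = matcher.match_text(templates.all_template_text())
    if hits:
        offending = sorted({h.surface for h in hits})
        raise ConfigurationError(
            "template/filler text contains lexicon surface(s): "
            + ", ".join(offending))


def generate_corpus(config: CorpusConfig,
                    lexicon: Sequence[LexiconEntry] | None = None,
                    templates: Templates | None = None
                    ) -> tuple[list[Note], GroundTruth]:
    """Generate a corpus and its exact planting ground truth.

    Raises :class:`ConfigurationError` when templates do not cover all six
    note types or when template/filler text itself contains a lexicon
    surface (which would break the exactness guarantee).
    """
    if lexicon is None:
        lexicon = default_lexicon()
    if templates is None:
        templates = default_templates()
    config.validate()
    if not lexicon:
        raise ConfigurationError("lexicon must be nonempty")
    templates.validate_coverage()
    _check_filler_purity(templates, lexicon)

    canonicals: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    abbrev_for: dict[str, list[str]] = {}
    missp_for: dict[str, list[str]] = {}
    for e in lexicon:
        if e.origin in ("seed", "related"):
            canonicals[e.category].append(e.surface)
        elif e.origin == "abbreviation":
            abbrev_for.setdefault(e.source_seed, []).append(e.surface)
        elif e.origin == "misspelling":
            missp_for.setdefault(e.source_seed, []).append(e.surface)
    for cat in CATEGORIES:
        if not canonicals[cat]:
            raise ConfigurationError(f"lexicon has no plantable term for {cat}")
        canonicals[cat].sort()

    rng = np.random.default_rng(config.rng_seed)
    notes: list[Note] = []
    planted: dict[str, list[PlantedTerm]] = {}
    note_counter = 0

    for pi in range(config.n_patients):
        patient_id = f"P{pi:06d}"
        age = int(rng.choice(22, p=config.age_distribution))
        n_enc = int(_categorical(rng, config.encounters_per_patient))
        for _ in range(n_enc):
            setting = str(_categorical(rng, config.encounter_mix))
            specialty = str(_categorical(rng, config.specialty_mix[setting]))
            n_notes = int(_categorical(rng, config.notes_per_encounter))
            for _ in range(n_notes):
                if setting == "ambulatory":
                    note_type = "apn"
                elif setting == "emergency":
                    note_type = "epn"
                else:
                    note_type = str(_categorical(rng, config.inpatient_note_mix))
                provider = str(_categorical(rng, config.provider_mix))
                note_id = f"N{note_counter:07d}"
                note_counter += 1

                lines = [templates.headers[note_type]]
                n_filler = int(rng.integers(2, 5))
                for _ in range(n_filler):
                    lines.append(templates.filler[
                        int(rng.integers(len(templates.filler)))])

                plants: list[PlantedTerm] = []
                for cat in CATEGORIES:
                    p = config.plant_probability(cat, age, note_type, specialty)
                    if rng.random() >= p:
                        continue
                    n_terms = 1
                    if (len(canonicals[cat]) > 1
                            and rng.random() < config.extra_term_rate):
                        n_terms = 2
                    picks = rng.choice(len(canonicals[cat]), size=n_terms,
                                       replace=False)
                    for idx in picks:
                        canonical = canonicals[cat][int(idx)]
                        surface, corrupted = canonical, False
                        u = rng.random()
                        if u < config.abbreviation_rate and \
                                abbrev_for.get(canonical):
                            surface = abbrev_for[canonical][0]
                        elif u < config.abbreviation_rate + \
                                config.misspelling_rate and \
                                missp_for.get(canonical):
                            surface = missp_for[canonical][0]
                            corrupted = True
                        use_maternal = (age == 0 and
                                        cat in templates.maternal_carriers)
                        pool = (templates.maternal_carriers[cat] if use_maternal
                                else templates.carriers[cat])
                        line = pool[int(rng.integers(len(pool)))]
                        lines.append(line.replace("{TERM}", surface))
                        plants.append(PlantedTerm(
                            surface=surface, category=cat,
                            canonical=canonical, corrupted=corrupted))

                notes.append(Note(
                    note_id=note_id, patient_id=patient_id,
                    text="\n".join(lines), note_type=note_type,
                    age_years=age, provider_type=provider, setting=setting,
                    specialty=specialty))
                planted[note_id] = plants

    return notes, GroundTruth(planted=planted)


# -------------------------------------------------------- expected marginals

def _stratum_weights(config: CorpusConfig) -> list[tuple[int, str, str, float]]:
    """Enumerate (age, note_type, specialty, weight) cells of the per-note
    distribution implied by the config (weights sum to 1)."""
    cells: list[tuple[int, str, str, float]] = []
    for age in range(22):
        pa = float(config.age_distribution[age])
        if pa == 0:
            continue
        for setting, ps in config.encounter_mix.items():
            if setting == "ambulatory":
                type_dist = {"apn": 1.0}
            elif setting == "emergency":
                type_dist = {"epn": 1.0}
            else:
                type_dist = config.inpatient_note_mix
            for specialty, pq in config.specialty_mix[setting].items():
                for nt, pt in type_dist.items():
                    w = pa * ps * pq * pt
                    if w > 0:
                        cells.append((age, nt, specialty, w))
    return cells


def _cell_flag_prob(config: CorpusConfig, age: int, nt: str,
                    specialty: str) -> float:
    q = 1.0
    for cat in CATEGORIES:
        q *= 1.0 - config.plant_probability(cat, age, nt, specialty)
    return 1.0 - q


def expected_flag_rate(config: CorpusConfig,
                       category: str | None = None) -> float:
    """Exact expected note-level flag rate under the configured strata
    (any-category by default, or one category's marginal)."""
    num = 0.0
    for age, nt, spec, w in _stratum_weights(config):
        if category is None:
            num += w * _cell_flag_prob(config, age, nt, spec)
        else:
            num += w * config.plant_probability(category, age, nt, spec)
    return num


def expected_rate_by(config: CorpusConfig, variable: str,
                     category: str | None = None) -> dict:
    """Expected flag rate conditional on one stratification variable
    (``note_type``, ``age_years``, ``age_band``, or ``setting``)."""
    sums: dict = {}
    weights: dict = {}
    setting_of = {"apn": "ambulatory", "epn": "emergency"}
    for age, nt, spec, w in _stratum_weights(config):
        if variable == "note_type":
            key = nt
        elif variable == "age_years":
            key = age
        elif variable == "age_band":
            key = age_band(age)
        elif variable == "setting":
            key = setting_of.get(nt, "inpatient")
        else:
            raise ConfigurationError(f"unknown variable {variable!r}")
        if category is None:
            p = _cell_flag_prob(config, age, nt, spec)
        else:
            p = config.plant_probability(category, age, nt, spec)
        sums[key] = sums.get(key, 0.0) + w * p
        weights[key] = weights.get(key, 0.0) + w
    return {k: sums[k] / weights[k] for k in sums}


def synonym_substitution_corpus(
        seed_term: str = "alcohol", synonym: str = "etoh",
        misspelling: str = "alchol", substitution_rate: float = 0.35,
        misspelling_rate: float = 0.05, n_patients: int = 500,
        rng_seed: int = 11) -> tuple[list[Note], GroundTruth]:
    """Corpus where ``synonym`` is substituted for ``seed_term`` in a known
    fraction of its template slots (and ``misspelling`` in a rarer one).

    The seed's category is reduced to this single canonical term and its
    planting rate flattened high, so the seed occupies enough slots for
    stable distributional statistics. Used to verify that expansion
    recovers planted synonyms and labels planted misspellings.
    """
    cfg = default_config(n_patients=n_patients, rng_seed=rng_seed)
    cfg.abbreviation_rate = substitution_rate
    cfg.misspelling_rate = misspelling_rate
    base = default_lexicon()
    category = next(e.category for e in base if e.surface == seed_term)
    for key in list(cfg.plant_rates):
        if key[0] == category:
            cfg.plant_rates[key] = 0.5
    lex = [e for e in base if e.category != category]
    lex.append(LexiconEntry(surface=seed_term, category=category,
                            origin="seed", source_seed=seed_term))
    lex.append(LexiconEntry(surface=synonym, category=category,
                            origin="abbreviation", source_seed=seed_term))
    lex.append(LexiconEntry(surface=misspelling, category=category,
                            origin="misspelling", source_seed=seed_term))
    return generate_corpus(cfg, lex)


# ----------------------------------------------------------- misspelling op

_LETTERS = string.ascii_lowercase


def corrupt_spelling(term: str, rng: np.random.Generator) -> str:
    """Return a variant at edit distance exactly 1 from ``term`` (one
    substitution, deletion, insertion, or adjacent transposition).

    Terms shorter than 3 characters are refused: they are too short to
    corrupt meaningfully.
    """
    if len(term) < 3:
        raise ValueError(f"term {term!r} too short to corrupt (need >= 3 chars)")
    while True:
        op = int(rng.integers(4))
        if op == 0:  # substitution
            i = int(rng.integers(len(term)))
            ch = _LETTERS[int(rng.integers(26))]
            if ch == term[i]:
                continue
            variant = term[:i] + ch + term[i + 1:]
        elif op == 1:  # deletion
            i = int(rng.integers(len(term)))
            variant = term[:i] + term[i + 1:]
        elif op == 2:  # insertion
            i = int(rng.integers(len(term) + 1))
            ch = _LETTERS[int(rng.integers(26))]
            variant = term[:i] + ch + term[i:]
        else:  # adjacent transposition
            i = int(rng.integers(len(term) - 1))
            if term[i] == term[i + 1]:
                continue
            variant = (term[:i] + term[i + 1] + term[i] + term[i + 2:])
        if variant != term:
            return variant
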